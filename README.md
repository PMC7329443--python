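# ventmag

Comparative metagenome analysis of deep-sea hydrothermal sulfide
chimneys: a tested, reusable implementation of the pipeline used to
contrast an actively venting chimney community with a recently inactive
one — gene-abundance normalization and differential testing, MAG
(metagenome-assembled genome) refinement and quantification,
coverage-based replication-rate estimation (iRep), rule-based metabolic
pathway-completeness calling, and vent-fluid endmember chemistry.  A
seeded synthetic-community generator produces every input the pipeline
consumes, so all stages are testable without sequencing data or
downloads.

It is written for microbial ecologists and bioinformaticians who want
the individual analysis steps as importable, composable functions with
explicit statistical contracts, rather than as a one-shot script.

## The statistics at the core

**Gene abundance.** For gene *g* with mapped reads *r<sub>g</sub>* and
length *L<sub>g</sub>*:

    A_g = (r_g / L_g) / Σ_h (r_h / L_h) × 10⁶

so abundances sum to 10⁶ per sample.  Between two metagenomes, each gene
symbol is tested on a 2×2 table of raw counts with a two-sided Fisher's
exact test (probability-mass rule, hypergeometric enumeration), a 95%
Newcombe hybrid-Wilson confidence interval on the proportion difference,
and Benjamini-Hochberg FDR across all symbols tested.

**MAG refinement.** Candidate bins are merged when a same-taxon pair
would gain ≥ 10 completeness percentage points at ≤ 1 point extra
contamination; contigs with divergent GC / depth / tetranucleotide
signatures are stripped; bins sharing AAI ≥ 99% are dereplicated
keeping the more complete one; duplicate contigs are resolved; the
final gate keeps completeness ≥ 70% and contamination ≤ 9%.  MAG
relative abundance is the share of length-weighted depth among contigs
≥ 3 kb.

**iRep.** A population in which a fraction *f* of cells each carry one
replication fork has expected copy number 1 + *f*(1 − *x*) at
origin-distance fraction *x*, hence an origin:terminus coverage ratio of
1 + *f*.  Sorted 5-kb sliding-window coverages are tail-trimmed, log₂
depth is regressed on rank fraction with a shot-noise correction, and
iRep = 2^slope.  Bacterial MAGs with ≤ 175 scaffolds/Mb are eligible.

**Pathway completeness.** A declarative grammar (editable YAML) grades
each pathway complete / uncomplete / partial / none from gene-symbol
presence, evaluated in precedence order; rules contain no negation, so
adding a gene can never lower a level.

**Fluid endmember.** Species concentrations are regressed against Mg
over replicate vent-fluid samples; the intercept at Mg = 0 (seawater
carries ~53 mmol/kg Mg, the hot endmember ~0) is the endmember
concentration.  pH is reported as the lowest measured value, never
extrapolated.  Conservative mixing c(φ) = φ·c_sw + (1 − φ)·c_em
quantifies depletion by reaction.

## Worked example

```python
import numpy as np
from ventmag import synth
from ventmag.irep import estimate_irep, window_coverage

vals = []
for seed in range(10):
    track = synth.generate_coverage_track(
        genome_len=2_000_000, mean_depth=50.0, f_rep=0.5,
        window=100, seed=seed, n_contigs=5)
    windows = window_coverage(track, window=5000, slide=100)
    vals.append(estimate_irep(windows).irep)
print(round(float(np.mean(vals)), 3))
```

prints `1.49`: a community in which half of the cells carry a
replication fork reads out as iRep ≈ 1.5 — the interpretation scale of
the index (1.0 = not replicating, 2.0 = all cells replicating).  The
scripts under `examples/` walk through each capability the same way
(simulation, differential abundance, MAG refinement, iRep, pathway
matrix, fluid endmember); running `examples/04_replication_rates.py`
prints the full recovery grid:

```
f_rep   expected   mean iRep over 10 seeds
 0.00     1.00      1.014
 0.25     1.25      1.243
 0.50     1.50      1.490
 1.00     2.00      1.968
```

A thin CLI mirrors the stages (`ventmag simulate | abundance | diff |
mags | irep | pathways | endmember | run`); `ventmag run --config
cfg.yaml` executes the whole two-community workflow and writes one
table per stage plus a JSON report.

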