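# Methods

This note documents the models, parameter choices and numerical
decisions behind `ventmag`, and what the synthetic-data tests do and do
not establish about behavior on real data.

## Synthetic community model

`ventmag.synth` generates every input the pipeline consumes.

*Gene tables.* Mapped reads are multinomial over the community gene
catalog with cell probability ∝ taxon weight × gene length, optionally
jittered per taxon by a lognormal factor (`abundance_sigma`, default 0)
to emulate compositional dispersion.  Defaults: 100-bp reads, 10⁶
mapped reads per sample — the scale at which short-read functional
comparisons of chimney metagenomes operate.  The default two-community
contrast swaps the weights of the sulfur-oxidizer and sulfate-reducer
populations by a factor √10 each way while holding their total gene
length equal, so their marker symbols are 10-fold enriched in expected
proportion while the housekeeping symbols of the weight-stable taxa are
exact nulls.  This is what lets the differential tests be validated
against construction rather than against another implementation.

*Coverage tracks.* Replication is modeled as a single fork per
replicating cell at a uniformly random genome position: a locus at
origin-distance fraction x is already duplicated with probability
1 − x, giving expected copy number 1 + f·(1 − x) and an
origin:terminus ratio of 1 + f.  Window depths are Poisson about
mean_depth × copy number on a 100-bp tiling; the genome is cut into
contigs whose order is shuffled so estimators cannot exploit genomic
order.  The model deliberately omits GC-coverage bias, strand
asymmetry, repeats and mapping artifacts; recovery results below
therefore bound estimator error from sampling noise only, not from
real-library biases.

*Bin metadata.* Contig statistics are drawn from per-taxon signature
distributions: GC = taxon GC + N(0, 0.01); depth = taxon depth ×
lognormal(0, 0.05); tetranucleotide vector = taxon Dirichlet signature
with 10% relative component noise.  Candidate bins take a random subset
of their taxon's contigs (the covered length fraction is the truth
completeness) and, at a configurable rate, foreign contigs injected
*with their true source signatures* — the property that makes outlier-
filter recall measurable.  AAI is drawn in [99, 100] for same-taxon bin
pairs and [60, 90] otherwise.  Stats are generated directly rather than
via simulated sequences, because the refinement workflow consumes
statistics and read/assembly simulation is out of scope; a
random-sequence helper exists for validating the sequence-level
statistic computation itself.

*Fluid samples.* Each sample is a conservative mixture of a zero-Mg
endmember and seawater at seawater fraction φ, plus Gaussian
measurement noise with sd = absolute component + relative component ×
true value.  The shipped reference compositions are an active East
Pacific Rise style endmember (ΣH₂S 6.3 mmol/L, H₂ 0.83 mmol/L, CH₄ 83
µmol/L, K⁺ 18.9, Ca²⁺ 19.7, Cl⁻ 528 mmol/kg, SO₄²⁻ 0) and background
seawater (Mg 53.0 mmol/kg etc.); analytical uncertainty is quoted as
2s = 10% for dissolved gases and 3% for major ions, so the generator's
1σ relative noise defaults to half of that.

## Abundance and differential testing

Per-million abundance uses the unrestricted denominator (all genes in
the table); a key-genes-only denominator is available by passing a
symbol list.  Tests always run on raw integer counts — exact tests are
meaningless on normalized values — with abundances reported alongside.

Fisher's exact p sums hypergeometric masses ≤ the observed mass with a
10⁻⁷ relative tolerance on the comparison (guarding float ties); the
per-margin p-value vector is computed by sort + cumulative sum +
binary search, O(s log s) in the support size, which keeps exhaustive
validation over every 2×2 table with N ≤ 60 and symbol-level testing at
10⁶-read margins fast.  The Wilson score interval snaps to exactly 0/1
at x = 0 / x = n (the closed form attains them; floats do not).  The
Newcombe difference interval composes the two Wilson intervals in the
standard square-root-of-squares form.  BH is the step-up suffix-minimum,
capped at 1; the family is the set of symbols tested in one invocation.
Independent checks: an exact integer-arithmetic enumeration oracle,
`scipy.stats.fisher_exact`, `statsmodels` Wilson intervals and
`multipletests(fdr_bh)`.

The 16S summarizer reads "average sequencing depth" as depth-weighted
summation (sum of depths per label, normalized); a per-gene-average
variant is provided behind a switch since both readings coincide when
each taxon contributes one gene and the source phrasing does not
disambiguate.

## MAG refinement

The merge rule treats "increase ≥ 10% and ≤ 1%" as percentage points
relative to the better member — quality metrics are reported in
percentage units and a relative-percent reading would make the
contamination clause near-vacuous for clean bins.  Merged-bin quality
cannot be computed here (marker-gene estimation is an upstream tool),
so `refine_bins` takes a `merged_quality` callable; the synthetic
metadata provides a truth-based one, and without a callable the merge
stage is skipped.  Likewise `quality_update` re-estimates bin quality
after contig removal; without it the input values carry through.

Outlier filtering compares each contig to robust bin statistics:

* GC: |GC − median| > k × (1.4826 × MAD), k = 3, with the scale floored
  at 0.01 — within-genome GC scatter is rarely below one point, and a
  coincidentally tight bin would otherwise flag ordinary contigs;
* depth: ratio to the median outside [1/3, 3];
* tetranucleotide: Manhattan distance to the component-wise median
  composition greater than 3× the median within-bin distance.

Median-based references and fold-type cutoffs were chosen over
percentile cutoffs and weighted-mean references deliberately: a
within-bin percentile removes a fixed share of any bin (so a clean bin
is never a fixed point and the workflow cannot be idempotent), and a
length-weighted mean is dragged toward the contaminants one is trying
to detect.  The filter iterates until no contig is removed; since each
pass strictly shrinks the bin, termination is guaranteed, and the
workflow's idempotence (rerunning on its own output changes nothing) is
exact rather than approximate.  On the seeded fixture (15% injected
contaminants, ≥ 5-point GC gaps between taxa) recall is 100% with 2.2%
false removal.

Dereplication resolves connected components of the AAI ≥ 99% graph
(keeping the bin maximizing completeness, then lower contamination,
then id) rather than scanning pairs sequentially, making the result
order-independent.  All boundary comparisons are inclusive, including
exactly 175 scaffolds/Mb for iRep eligibility.

## iRep estimation

Window coverages (default 5-kb windows, 100-bp slide over a 100-bp
tiling, both configurable) are sorted ascending, the lowest and highest
5% are dropped, and log₂ depth is regressed on the rank fraction
t = i/(n−1), with trimmed windows keeping their pre-trim ranks so the
fit stays on the [0, 1] scale; iRep = 2^slope.  Median depth below
5× yields status "insufficient coverage"; fewer than 10 windows
likewise; zero depths surviving trimming are replaced by 0.5 and
flagged.

Sorting pure sampling noise also produces a positive slope — at 50×
with 5-kb windows the bias is ≈ +0.06 on a non-replicating population,
and it grows as coverage falls.  The estimator therefore subtracts the
expected noise contribution in quadrature:

    slope ← sqrt(max(slope² − (k(trim) · σ_w / (D̄ ln 2))², 0))

where σ_w is the window shot-noise sd estimated from differences of
adjacent non-overlapping windows within contigs (the smooth replication
trend cancels; the estimate needs windows in genomic order within each
contig, which is the CoverageTrack contract), D̄ the mean window depth,
and k(trim) the OLS slope of the standard-normal quantile function over
the trimmed rank range (3.02 at 5% trimming), evaluated by quadrature
and cached.  With the correction, seed-averaged recovery over
f ∈ {0, 0.25, 0.5, 1} is within ±0.05 of 1 + f at 50×/2 Mb and at
25×/1 Mb, and a perfectly flat track returns exactly 1.0.  The
uncorrected fit remains available (`correct_noise=False`) and is
exactly invariant to arbitrary window order.  No GC-bias correction is
applied (the generator has none); real-data use should treat low-R²
fits with the usual suspicion.

## Pathway rules

Rules are boolean expressions over symbol presence (ALL / ANY /
AT-LEAST-k), evaluated complete → uncomplete → partial with first match
winning and default none; binary traits use present/absent.  Because no
rule contains negation, levels are monotone in the symbol set — the
property tests exercise this over 10⁴ random sets, and every pathway is
checked exhaustively (all 2^k presence patterns) against independently
hand-coded flat decision functions.

Reading decisions baked into the shipped YAML (all user-editable):
slash-joined pairs (dsrAB, aprAB, nrfA/H) require all members; "partial"
Sox means any of soxA/soxX/soxY/soxZ (soxC/soxD alone do not trigger it,
and soxB alone takes precedence as uncomplete); "partial"
Wood-Ljungdahl means ≥ 2 of the groups (cdhC|cdhB), (cdhE|cdhD), cooS;
cytochrome oxidase counts distinct gene symbols within the
Cox/Cyd/Qox and cco/Cyo families; the fermentation marker set
{ldh, adhE, por} is a package vocabulary choice.  Hydrogenase group
labels are consumed as input, not computed.  CAZyme counting is a
plain per-MAG count with arithmetic group means.

## Fluid endmember chemistry

Per species, ordinary (unweighted) least squares of concentration on Mg
over one vent's samples; uncertainties quoted as uniform percentages
make error weighting a within-species no-op.  Below-detection values
(NaN) are excluded, not substituted.  All samples at Mg = 0 degenerate
gracefully to the mean; identical nonzero Mg raises ("no Mg leverage");
negative intercepts clip to 0 with a flag.  A "measured" mode skips
extrapolation and reports means plus seawater-relative enrichment, for
vents whose fluids mixed with seawater below the seafloor.

## Problem sizes and reproducibility

All generators are deterministic under a fixed seed.  The validation
sizes are chosen to hold Monte-Carlo error well inside each tolerance:
iRep claims average 20 seeded 2-Mb tracks; interval coverage and type-I
rates use 2000 simulated tables; the endmember recovery averages 400
seeded triplicate sample sets (per-trial intercept sd ≈ 4 µmol/L for
CH₄, so the 400-set mean carries ≈ 0.2 se against a ±1 tolerance);
exact-test enumeration covers every table with N ≤ 60.  The end-to-end
contrast is validated over 25 seeded runs: all constructed 10-fold
enriched symbols must be flagged at q < 0.05 in every run, with the
null-symbol flag rate ≤ 6% of symbol-runs (measured ≈ 3–4%; with many
true positives the BH threshold sits near α, so nulls reject at close
to, but below, the nominal rate).

## Known limitations

Two-sample designs only (no replicate-aware count models); AAI,
completeness/contamination and taxonomy labels are inputs, not
computed; the replication model is single-fork and bias-free, so iRep
accuracy on real libraries will be worse than the synthetic recovery
bounds; pathway calls are presence-based and cannot distinguish
oxidative from reductive operation of the dsr pathway (a phylogenetic
question); the fluid module does no thermodynamic speciation, pH
temperature correction or charge-balance checking.
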