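"""Seeded synthetic-community and fluid-chemistry generators.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the methods assume: multinomial read counts over a
gene catalog, coverage tracks with an origin-to-terminus replication
gradient, bin/contig metadata with taxon-specific composition signatures,
and vent-fluid samples produced by conservative seawater-endmember mixing.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .irep import CoverageTrack
from .mags import CANONICAL_TETRAMERS, AAIMatrix, BinRecord, ContigStats

log = logging.getLogger(__name__)

__all__ = [
    "TaxonSpec", "CommunitySpec", "FluidMixSpec", "BinMetadata",
    "generate_gene_table", "generate_coverage_track",
    "generate_fluid_samples", "generate_bin_metadata",
    "coverage_for_bins", "write_simulation",
    "random_sequence", "default_community",
    "NULL_SYMBOLS", "ENRICHED_IN_A", "ENRICHED_IN_B",
]


@dataclass
class TaxonSpec:
    """One synthetic population: abundance, genome, and gene content."""

    name: str
    lineage: str                      # phylum-level label (class for Proteobacteria)
    weight: float                     # relative abundance weight, >= 0
    genome_length: int                # bp
    genes: list[tuple[str, int]]      # (symbol, length bp)
    pathway_content: frozenset = frozenset()  # symbols present in the genome
    f_rep: float = 0.0                # replicating fraction, in [0, 1]
    gc: float = 0.5                   # genome GC fraction

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_rep <= 1.0:
            raise ValueError(f"f_rep must be in [0,1], got {self.f_rep}")
        if self.weight < 0:
            raise ValueError("abundance weight must be >= 0")
        self.pathway_content = frozenset(self.pathway_content)


@dataclass
class CommunitySpec:
    """A community plus sequencing parameters for one synthetic sample."""

    taxa: list[TaxonSpec]
    read_length: int = 100            # bp, 2x100 bp short-read style
    total_reads: int = 1_000_000      # mapped reads per sample
    depth_scale: float = 50.0         # mean depth of a weight-1 taxon, x-fold
    abundance_sigma: float = 0.0      # lognormal dispersion on taxon weights
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("community needs at least one taxon")
        if all(t.weight == 0 for t in self.taxa):
            raise ValueError("zero total abundance weight")


@dataclass
class FluidMixSpec:
    """Conservative seawater-endmember mixing with measurement noise.

    Each sample is a mixture ``phi`` of seawater and ``1-phi`` of the
    zero-Mg endmember fluid; species concentrations are
    ``phi*c_sw + (1-phi)*c_em`` plus Gaussian measurement noise with sd
    ``noise_sd[sp] + noise_rel[sp] * c_true`` (absolute plus
    proportional-to-measured-value components; analytical uncertainties
    are usually quoted as the latter).
    """

    endmember: dict[str, float]       # species -> concentration (Mg absent or 0)
    seawater: dict[str, float]        # species -> concentration, must include Mg
    phis: list[float]                 # seawater fraction per sample, in [0, 1]
    noise_sd: dict[str, float] = field(default_factory=dict)   # absolute sd
    noise_rel: dict[str, float] = field(default_factory=dict)  # sd / value
    seed: int = 42

    def __post_init__(self) -> None:
        if self.endmember.get("Mg", 0.0) != 0.0:
            raise ValueError("endmember Mg must be 0 (zero-Mg definition)")
        if "Mg" not in self.seawater:
            raise ValueError("seawater composition must include Mg")
        for phi in self.phis:
            if not 0.0 <= phi <= 1.0:
                raise ValueError(f"mixing fraction must be in [0,1], got {phi}")


def generate_gene_table(spec: CommunitySpec, sample_id: str,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Multinomial mapped-read counts over the community gene catalog.

    The probability of a read landing on a gene is proportional to
    (taxon weight) x (gene length), optionally jittered per taxon by a
    lognormal factor with sigma ``spec.abundance_sigma`` (sample-to-sample
    compositional dispersion).  Depth is reads x read_length / length.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    recs = []
    for t in spec.taxa:
        w = t.weight
        if spec.abundance_sigma > 0:
            w *= rng.lognormal(0.0, spec.abundance_sigma)
        for i, (symbol, length) in enumerate(t.genes):
            recs.append((f"{t.name}|{symbol}|{i:04d}", f"{t.name}_ctg",
                         symbol, length, t.lineage, w * length))
    df = pd.DataFrame(recs, columns=["gene_id", "contig_id", "symbol",
                                     "length", "taxon", "_p"])
    total_p = df["_p"].sum()
    if total_p <= 0:
        raise ValueError("zero total sampling weight")
    df["reads"] = rng.multinomial(spec.total_reads, df["_p"] / total_p)
    df = df.drop(columns="_p")
    df["depth"] = df["reads"] * spec.read_length / df["length"]
    df["sample"] = sample_id
    return df


def generate_coverage_track(genome_len: int, mean_depth: float, f_rep: float,
                            window: int = 100,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            noise: bool = True, n_contigs: int = 1,
                            contig_prefix: str = "ctg") -> CoverageTrack:
    """Coverage tiling with a single-fork replication gradient.

    Expected copy number at origin-distance fraction ``x`` is
    ``1 + f_rep*(1 - x)`` (each replicating cell carries one fork at a
    uniformly random position), so the origin:terminus depth ratio is
    ``1 + f_rep``.  Window depths are Poisson about
    ``mean_depth * copy_number`` (exact means when ``noise=False``).

    The genome is cut into ``n_contigs`` contiguous pieces whose order is
    shuffled, so downstream estimators cannot rely on genomic order.
    """
    if not 0.0 <= f_rep <= 1.0:
        raise ValueError("f_rep must be in [0,1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if genome_len < 10 * window:
        raise ValueError("genome length must be >= 10 x window")
    rng = rng if rng is not None else np.random.default_rng(seed)

    nwin = genome_len // window
    x = (np.arange(nwin) + 0.5) / nwin
    lam = mean_depth * (1.0 + f_rep * (1.0 - x))
    depths = rng.poisson(lam).astype(float) if noise else lam

    # split into contigs and shuffle contig order
    n_contigs = max(1, min(n_contigs, nwin))
    cuts = np.array_split(np.arange(nwin), n_contigs)
    order = rng.permutation(n_contigs)
    out_d, out_c = [], []
    for rank, ci in enumerate(order):
        idx = cuts[ci]
        out_d.append(depths[idx])
        out_c.append(np.repeat(f"{contig_prefix}{ci:03d}", len(idx)))
    return CoverageTrack(window, window,
                         np.concatenate(out_d), np.concatenate(out_c))


def generate_fluid_samples(mix: FluidMixSpec) -> pd.DataFrame:
    """Synthetic IGT fluid samples on (or noisily about) the mixing line."""
    rng = np.random.default_rng(mix.seed)
    species = sorted(set(mix.endmember) | set(mix.seawater) - {"Mg"})
    rows = []
    def noisy(sp, c_true):
        sd = mix.noise_sd.get(sp, 0.0) + mix.noise_rel.get(sp, 0.0) * c_true
        return c_true + (rng.normal(0.0, sd) if sd > 0 else 0.0)

    for i, phi in enumerate(mix.phis):
        row = {"sample_id": f"IGT{i + 1}",
               "Mg": noisy("Mg", phi * mix.seawater["Mg"])}
        for sp in species:
            c = (phi * mix.seawater.get(sp, 0.0)
                 + (1.0 - phi) * mix.endmember.get(sp, 0.0))
            row[sp] = noisy(sp, c)
        rows.append(row)
    df = pd.DataFrame(rows)
    neg = df.select_dtypes("number") < 0
    if neg.to_numpy().any():
        log.warning("clipped %d negative generated concentrations to 0",
                    int(neg.to_numpy().sum()))
        num = df.select_dtypes("number").clip(lower=0.0)
        df[num.columns] = num
    return df


@dataclass
class BinMetadata:
    """Synthetic binning inputs plus ground truth."""

    contigs: dict[str, ContigStats]
    bins: list[BinRecord]
    aai: AAIMatrix
    truth: pd.DataFrame   # contig_id, source_taxon, bin_id, is_contaminant

    def merged_quality(self, bin_a: BinRecord, bin_b: BinRecord):
        """Truth-based (completeness, contamination) of a merged pair.

        Stands in for a marker-gene quality estimate, using the known
        genome sizes and contig origins of the synthetic community.
        """
        contigs = set(bin_a.contigs) | set(bin_b.contigs)
        return self._quality(contigs, bin_a.taxonomy)

    def quality_of(self, bin_rec: BinRecord):
        """Truth-based (completeness, contamination) of a bin's current
        contig set; stands in for a marker-gene quality re-estimate."""
        return self._quality(bin_rec.contigs, bin_rec.taxonomy)

    def _quality(self, contigs, taxonomy):
        src = self.truth.drop_duplicates("contig_id").set_index("contig_id")
        native = foreign = 0
        for c in contigs:
            length = self.contigs[c].length
            if src.loc[c, "source_taxon"] == taxonomy:
                native += length
            else:
                foreign += length
        genome_len = self._genome_lengths[taxonomy]
        return (100.0 * native / genome_len, 100.0 * foreign / genome_len)

    _genome_lengths: dict = field(default_factory=dict)


def generate_bin_metadata(spec: CommunitySpec, n_contigs: int = 12,
                          contamination_fraction: float = 0.0,
                          bins_per_taxon: int = 1,
                          completeness_range: tuple[float, float] = (0.9, 1.0),
                          gc_sd: float = 0.01, depth_sigma: float = 0.05,
                          tetra_noise: float = 0.1,
                          seed: int | None = None) -> BinMetadata:
    """Contig stats, candidate bins, and an AAI matrix, with ground truth.

    Each taxon's genome is cut into ``n_contigs`` contigs carrying the
    taxon's GC / depth / tetranucleotide signature (small within-genome
    scatter).  Candidate bins take a random subset of their taxon's
    contigs (the covered fraction is the truth completeness) and, when
    ``contamination_fraction > 0``, additionally receive that fraction of
    contigs drawn from other taxa with their true source signatures.
    AAI between bins of the same taxon is drawn in [99, 100]; between
    different taxa in [60, 90].
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ntet = len(CANONICAL_TETRAMERS)

    contigs: dict[str, ContigStats] = {}
    by_taxon: dict[str, list[str]] = {}
    taxon_sig: dict[str, np.ndarray] = {}
    truth_rows = []
    for t in spec.taxa:
        sig = rng.dirichlet(np.full(ntet, 5.0))
        taxon_sig[t.name] = sig
        depth = spec.depth_scale * max(t.weight, 1e-9)
        # contig lengths: random composition of the genome, min 5 kb each
        raw = rng.dirichlet(np.full(n_contigs, 3.0)) * t.genome_length
        lengths = np.maximum(raw.astype(int), 5000)
        ids = []
        for j, length in enumerate(lengths):
            cid = f"{t.name}_c{j:03d}"
            tetra = sig + rng.normal(0.0, tetra_noise * sig)
            tetra = np.clip(tetra, 1e-12, None)
            tetra /= tetra.sum()
            contigs[cid] = ContigStats(
                contig_id=cid, length=int(length),
                gc=float(np.clip(t.gc + rng.normal(0.0, gc_sd), 0.0, 1.0)),
                depth=float(depth * rng.lognormal(0.0, depth_sigma)),
                tetra=tetra)
            ids.append(cid)
        by_taxon[t.name] = ids

    genome_lengths = {t.name: sum(contigs[c].length for c in by_taxon[t.name])
                      for t in spec.taxa}

    bins: list[BinRecord] = []
    for t in spec.taxa:
        others = [c for name, ids in by_taxon.items() if name != t.name
                  for c in ids]
        for b in range(bins_per_taxon):
            frac = rng.uniform(*completeness_range)
            ids = list(by_taxon[t.name])
            rng.shuffle(ids)
            take = max(1, int(round(frac * len(ids))))
            members = ids[:take]
            native_len = sum(contigs[c].length for c in members)
            n_foreign = int(round(contamination_fraction * len(members)))
            foreign = (list(rng.choice(others, size=min(n_foreign, len(others)),
                                       replace=False)) if n_foreign and others
                       else [])
            all_members = members + foreign
            foreign_len = sum(contigs[c].length for c in foreign)
            bin_id = f"{t.name}_bin{b}"
            bins.append(BinRecord(
                bin_id=bin_id, contigs=set(all_members), taxonomy=t.name,
                completeness=100.0 * native_len / genome_lengths[t.name],
                contamination=100.0 * foreign_len / genome_lengths[t.name],
                total_length=native_len + foreign_len,
                scaffold_count=len(all_members)))
            for c in members:
                truth_rows.append((c, t.name, bin_id, False))
            for c in foreign:
                src = next(n for n, ids_ in by_taxon.items() if c in ids_)
                truth_rows.append((c, src, bin_id, True))

    # also record unbinned contigs' sources
    binned = {r[0] for r in truth_rows}
    for name, ids in by_taxon.items():
        for c in ids:
            if c not in binned:
                truth_rows.append((c, name, "", False))

    ids = [b.bin_id for b in bins]
    tax = {b.bin_id: b.taxonomy for b in bins}
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for bb in ids[i + 1:]:
            if tax[a] == tax[bb]:
                v = rng.uniform(99.0, 100.0)
            else:
                v = rng.uniform(60.0, 90.0)
            mat.loc[a, bb] = mat.loc[bb, a] = v

    truth = pd.DataFrame(truth_rows, columns=["contig_id", "source_taxon",
                                              "bin_id", "is_contaminant"])
    meta = BinMetadata(contigs=contigs, bins=bins, aai=AAIMatrix(mat),
                       truth=truth)
    meta._genome_lengths = genome_lengths
    return meta


def coverage_for_bins(spec: CommunitySpec, meta: BinMetadata,
                      window: int = 100,
                      seed: int | None = None) -> CoverageTrack:
    """One coverage tiling spanning every synthetic contig.

    Each taxon's genome gets a single replication gradient (expected copy
    number ``1 + f_rep*(1-x)``) laid across its contigs in a shuffled
    order, with Poisson window noise about ``depth_scale * weight *
    copy_number``; tracks are concatenated over taxa.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    by_taxon: dict[str, list[str]] = {}
    for cid in meta.contigs:
        by_taxon.setdefault(cid.rsplit("_c", 1)[0], []).append(cid)

    depths, cids = [], []
    for t in spec.taxa:
        ids = sorted(by_taxon.get(t.name, []))
        if not ids:
            continue
        rng.shuffle(ids)
        depth = spec.depth_scale * max(t.weight, 1e-9)
        genome_len = sum(meta.contigs[c].length for c in ids)
        offset = 0
        for cid in ids:
            length = meta.contigs[cid].length
            nwin = max(length // window, 1)
            x = (offset + (np.arange(nwin) + 0.5) * window) / genome_len
            lam = depth * (1.0 + t.f_rep * (1.0 - np.clip(x, 0.0, 1.0)))
            depths.append(rng.poisson(lam).astype(float))
            cids.append(np.repeat(cid, nwin))
            offset += length
    return CoverageTrack(window, window, np.concatenate(depths),
                         np.concatenate(cids))


def write_simulation(out_dir, seed: int = 42,
                     contamination_fraction: float = 0.15,
                     bins_per_taxon: int = 2) -> dict:
    """Generate and write every pipeline input to ``out_dir``.

    Emits genes_A.tsv / genes_B.tsv, contigs.tsv, bins.tsv, aai.tsv,
    coverage.bedgraph, annotations.tsv, fluids.csv and truth.tsv, all
    derived from the default two-community contrast.  Returns the path
    map.
    """
    from pathlib import Path

    from .fluids import ACTIVE_VENT_ENDMEMBER, ANALYTICAL_2S, SEAWATER
    from .io import (write_aai, write_bedgraph, write_bins,
                     write_contig_stats, write_table)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comm_a, comm_b = default_community(seed=seed)
    rng = np.random.default_rng(seed)

    genes_a = generate_gene_table(comm_a, "A", rng=rng)
    genes_b = generate_gene_table(comm_b, "B", rng=rng)
    write_table(genes_a, out / "genes_A.tsv", ["synthetic gene table, sample A"])
    write_table(genes_b, out / "genes_B.tsv", ["synthetic gene table, sample B"])

    meta = generate_bin_metadata(comm_a, contamination_fraction=contamination_fraction,
                                 bins_per_taxon=bins_per_taxon, seed=seed + 1)
    write_contig_stats(meta.contigs, out / "contigs.tsv")
    write_bins(meta.bins, out / "bins.tsv")
    write_aai(meta.aai, out / "aai.tsv")
    write_table(meta.truth, out / "truth.tsv", ["ground truth of the simulation"])

    track = coverage_for_bins(comm_a, meta, seed=seed + 2)
    write_bedgraph(track, out / "coverage.bedgraph")

    ann = pd.DataFrame(
        [{"bin_id": b.bin_id,
          "symbols": ",".join(sorted(
              next(t for t in comm_a.taxa if t.name == b.taxonomy)
              .pathway_content)),
          "cazymes": int(rng.poisson(19))}
         for b in meta.bins])
    write_table(ann, out / "annotations.tsv", ["per-bin gene-symbol presence"])

    mix = FluidMixSpec(
        endmember=dict(ACTIVE_VENT_ENDMEMBER),
        seawater=dict(SEAWATER),
        phis=[0.1, 0.35, 0.6],
        noise_rel={sp: two_s / 2 for sp, two_s in ANALYTICAL_2S.items()},
        seed=seed + 3)
    fluids_df = generate_fluid_samples(mix)
    fluids_df["pH"] = [5.2, 5.6, 6.1]
    fluids_df.to_csv(out / "fluids.csv", index=False)

    return {name: str(out / name) for name in
            ["genes_A.tsv", "genes_B.tsv", "contigs.tsv", "bins.tsv",
             "aai.tsv", "coverage.bedgraph", "annotations.tsv",
             "fluids.csv", "truth.tsv"]}


def random_sequence(length: int, gc: float = 0.5,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> str:
    """Random nucleotide sequence with the given expected GC fraction."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=length, p=p)])


#: housekeeping symbols carried by the weight-stable taxa; their expected
#: read proportions are identical in the two default communities (nulls)
NULL_SYMBOLS = tuple(f"hk{i:02d}" for i in range(20))
#: symbols constructed ~10-fold enriched in community A / community B
ENRICHED_IN_A = ("soxA", "soxB", "soxX", "soxY", "soxZ", "soxC", "soxD",
                 "aclA", "aclB")
ENRICHED_IN_B = ("sat", "dsrA", "dsrB", "aprA", "aprB",
                 "cdhC", "cdhD", "cdhE", "cooS", "acsB")


def default_community(seed: int = 42, enriched_fold: float = 10.0) -> tuple[CommunitySpec, CommunitySpec]:
    """A two-community contrast emulating an active vs. inactive chimney.

    Community A (active-style) is dominated by a sulfur-oxidizing
    population rich in sox/rTCA genes; community B (inactive-style) by
    a sulfate-reducing population rich in dsr/WL genes.  The two varying
    taxa swap weights (``w*s`` vs ``w/s`` with ``s = sqrt(fold)``) and
    carry equal total gene length, so the symbols they own are
    ``enriched_fold``-fold enriched in expected proportion while the
    housekeeping symbols of the weight-stable taxa are exact nulls.
    """
    hk = [(s, 900) for s in NULL_SYMBOLS]
    sox = [("soxA", 840), ("soxB", 1700), ("soxX", 450), ("soxY", 420),
           ("soxZ", 330), ("soxC", 1290), ("soxD", 1200)]
    rtca = [("aclA", 1800), ("aclB", 1200)]
    ox_fill = [("campy_m01", 2000), ("campy_m02", 1500), ("campy_m03", 1070)]
    dsr = [("sat", 1200), ("dsrA", 1300), ("dsrB", 1150),
           ("aprA", 1900), ("aprB", 500)]
    wl = [("cdhC", 1500), ("cdhD", 900), ("cdhE", 1350), ("cooS", 1900),
          ("acsB", 2100)]
    # oxidizer and reducer gene catalogs both total 13800 bp
    assert sum(l for _, l in sox + rtca + ox_fill) == sum(
        l for _, l in dsr + wl) == 13800

    oxidizer = TaxonSpec(
        name="Sulfurovum_like", lineage="Campylobacteria", weight=5.0,
        genome_length=2_200_000, genes=sox + rtca + ox_fill,
        pathway_content=frozenset(s for s, _ in sox + rtca) | {"sqr", "nirB"},
        f_rep=0.5, gc=0.38)
    aquif = TaxonSpec(
        name="Aquificae_like", lineage="Aquificae", weight=2.0,
        genome_length=1_600_000, genes=hk + [("sqr", 1300), ("nifH", 900)],
        pathway_content=frozenset({"sqr", "nifH", "nifD", "nifK"}),
        f_rep=0.3, gc=0.43)
    reducer = TaxonSpec(
        name="Nitrospirae_like", lineage="Nitrospirae", weight=5.0,
        genome_length=1_900_000, genes=dsr + wl,
        pathway_content=frozenset(s for s, _ in dsr + wl) | {"cyc2", "nifH",
                                                             "nifD", "nifK"},
        f_rep=0.6, gc=0.48)
    hetero = TaxonSpec(
        name="Gamma_like", lineage="Gammaproteobacteria", weight=3.0,
        genome_length=3_000_000,
        genes=hk + [("coxL", 2400), ("coxM", 800), ("coxS", 500)],
        pathway_content=frozenset({"coxL", "coxM", "coxS", "ACSS",
                                   "coxA", "coxB"}),
        f_rep=0.4, gc=0.55)

    def reweight(t: TaxonSpec, w: float) -> TaxonSpec:
        return TaxonSpec(t.name, t.lineage, w, t.genome_length, t.genes,
                         t.pathway_content, t.f_rep, t.gc)

    scale = enriched_fold ** 0.5
    comm_a = CommunitySpec(
        taxa=[reweight(oxidizer, 5.0 * scale), aquif,
              reweight(reducer, 5.0 / scale), hetero],
        seed=seed)
    comm_b = CommunitySpec(
        taxa=[reweight(oxidizer, 5.0 / scale), aquif,
              reweight(reducer, 5.0 * scale), hetero],
        seed=seed + 1)
    return comm_a, comm_b
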