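"""MAG refinement and quantification.

Candidate bins from automated binners are refined in five steps: merge
same-taxon pairs when the combined bin would gain >= 10 completeness
percentage points at <= 1 point extra contamination; strip contigs with
divergent GC / depth / tetranucleotide signatures; dereplicate bins
sharing AAI >= 99% (keep the more complete one); assign each contig to at
most one bin; and finally keep bins with completeness >= 70% and
contamination <= 9%.  Completeness/contamination and AAI are consumed as
inputs (marker-gene and protein-identity estimation are upstream tools).

MAG relative abundance is the share of length-weighted depth among
contigs >= 3 kb; iRep eligibility requires a bacterial bin with <= 175
scaffolds per Mb.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ContigStats", "BinRecord", "AAIMatrix", "RefinementResult",
    "CANONICAL_TETRAMERS", "compute_contig_stats", "merge_decision",
    "filter_outlier_contigs", "dereplicate_by_aai",
    "resolve_duplicate_contigs", "quality_gate", "mag_relative_abundance",
    "irep_eligible", "refine_bins",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(kmer: str) -> str:
    return kmer.translate(_COMP)[::-1]


def _canonical_tetramers() -> list[str]:
    """The 136 4-mers after reverse-complement collapsing (lexicographic min)."""
    seen = set()
    for kmer in ("".join(p) for p in itertools.product("ACGT", repeat=4)):
        seen.add(min(kmer, _revcomp(kmer)))
    return sorted(seen)


CANONICAL_TETRAMERS: list[str] = _canonical_tetramers()
_TETRA_INDEX = {k: i for i, k in enumerate(CANONICAL_TETRAMERS)}


@dataclass
class ContigStats:
    contig_id: str
    length: int
    gc: float
    depth: float
    tetra: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("contig length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("GC must be in [0,1]")
        if self.tetra is not None:
            self.tetra = np.asarray(self.tetra, dtype=float)
            if abs(float(self.tetra.sum()) - 1.0) > 1e-9:
                raise ValueError("tetranucleotide vector must sum to 1")


@dataclass
class BinRecord:
    bin_id: str
    contigs: set[str]
    taxonomy: str = ""
    completeness: float = 0.0     # percent
    contamination: float = 0.0    # percent
    total_length: int = 0         # bp
    scaffold_count: int = 0
    domain: str = "Bacteria"

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("bin must contain at least one contig")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError("completeness must be in [0,100]")
        if self.contamination < 0.0:
            raise ValueError("contamination must be >= 0")
        if self.scaffold_count == 0:
            self.scaffold_count = len(self.contigs)


class AAIMatrix:
    """Symmetric average-amino-acid-identity matrix (percent) over bins."""

    def __init__(self, values: pd.DataFrame):
        if not values.index.equals(values.columns):
            raise ValueError("AAI matrix must have identical index and columns")
        arr = values.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise ValueError("AAI matrix must be symmetric")
        if not np.allclose(np.diag(arr), 100.0):
            raise ValueError("AAI diagonal must be 100")
        if arr.min() < 0 or arr.max() > 100 + 1e-9:
            raise ValueError("AAI entries must be in [0,100]")
        self.values = values

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values.loc[a, b])

    @property
    def bin_ids(self) -> list[str]:
        return list(self.values.index)


def compute_contig_stats(sequence: str, depth: float,
                         contig_id: str = "contig") -> ContigStats:
    """GC and reverse-complement-collapsed tetranucleotide frequencies.

    GC is (G+C)/(A+C+G+T); 4-mer windows containing N are skipped; each
    4-mer is pooled with its reverse complement and the 136-class vector
    is normalized to sum 1.
    """
    seq = sequence.upper()
    if len(seq) < 4:
        raise ValueError("sequence must be at least 4 bp")
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over the alphabet {A,C,G,T,N}")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    gc = (seq.count("G") + seq.count("C")) / acgt

    counts = np.zeros(len(CANONICAL_TETRAMERS))
    for i in range(len(seq) - 3):
        kmer = seq[i:i + 4]
        if "N" in kmer:
            continue
        counts[_TETRA_INDEX[min(kmer, _revcomp(kmer))]] += 1
    total = counts.sum()
    tetra = counts / total if total > 0 else None
    return ContigStats(contig_id=contig_id, length=len(seq), gc=gc,
                       depth=depth, tetra=tetra)


def merge_decision(qual_a: tuple[float, float], qual_b: tuple[float, float],
                   qual_merged: tuple[float, float],
                   tax_a: str, tax_b: str,
                   min_completeness_gain: float = 10.0,
                   max_contamination_gain: float = 1.0) -> bool:
    """Accept a bin merge iff both bins share a taxonomy and the merged bin
    gains >= 10 completeness percentage points over the better member at
    <= 1 point extra contamination (thresholds in percentage points,
    relative to the better member; boundaries inclusive)."""
    if tax_a != tax_b:
        return False
    c_gain = qual_merged[0] - max(qual_a[0], qual_b[0])
    x_gain = qual_merged[1] - max(qual_a[1], qual_b[1])
    return c_gain >= min_completeness_gain and x_gain <= max_contamination_gain


#: 1/Phi^{-1}(3/4): scales the GC MAD to the sd of a normal distribution
_MAD_NORMAL = 1.4826022185056018
#: floor on the robust GC scale (fraction): within-genome GC scatter is
#: rarely below one point, and a degenerate MAD on a near-uniform bin
#: would otherwise flag ordinary contigs
GC_SCALE_FLOOR = 0.01


def filter_outlier_contigs(bin_rec: BinRecord,
                           stats: dict[str, ContigStats],
                           gc_mad_k: float = 3.0, depth_fold: float = 3.0,
                           tetra_fold: float = 3.0):
    """Remove contigs with divergent GC, depth, or tetranucleotide signature.

    A contig is removed iff any of:

    * ``|GC - median GC| > gc_mad_k * scale`` where the scale is the GC
      MAD x 1.4826 (a robust standard deviation), floored at 0.01 so a
      coincidentally tight bin cannot flag ordinary scatter,
    * ``depth / median depth`` outside ``[1/depth_fold, depth_fold]``,
    * Manhattan distance of its tetra vector to the bin's component-wise
      median composition exceeds ``tetra_fold`` times the median of those
      distances within the bin.

    All three rules compare against robust (median-based) bin statistics,
    so a homogeneous bin is a fixed point and the filter cannot trim a
    clean bin indefinitely.  The filter is iterated until no contig is
    removed, which makes the refinement workflow idempotent.  Bins with
    fewer than 3 contigs are returned unfiltered.  Returns
    ``(kept_ids, removed_ids, reasons)`` with ``reasons`` mapping removed
    contig ids to the list of triggered criteria.
    """
    members = sorted(bin_rec.contigs)
    missing = [c for c in members if c not in stats]
    if missing:
        raise KeyError(f"missing stats for contigs: {missing}")

    reasons: dict[str, list[str]] = {}
    while len(members) >= 3:
        new_reasons = _outlier_pass(members, stats, gc_mad_k, depth_fold,
                                    tetra_fold)
        if not new_reasons:
            break
        reasons.update(new_reasons)
        members = [c for c in members if c not in new_reasons]
    return list(members), sorted(reasons), reasons


def _outlier_pass(members, stats, gc_mad_k, depth_fold, tetra_fold):
    gcs = np.array([stats[c].gc for c in members])
    depths = np.array([stats[c].depth for c in members])
    med_gc = float(np.median(gcs))
    gc_scale = max(_MAD_NORMAL * float(np.median(np.abs(gcs - med_gc))),
                   GC_SCALE_FLOOR)
    med_depth = float(np.median(depths))

    tetras = [stats[c].tetra for c in members]
    have_tetra = all(t is not None for t in tetras)
    if have_tetra:
        tarr = np.vstack(tetras)
        ref = np.median(tarr, axis=0)
        dist = np.abs(tarr - ref).sum(axis=1)
        med_dist = float(np.median(dist))

    reasons: dict[str, list[str]] = {}
    for i, c in enumerate(members):
        why = []
        if abs(gcs[i] - med_gc) > gc_mad_k * gc_scale:
            why.append("gc")
        if med_depth > 0:
            ratio = depths[i] / med_depth
            if ratio > depth_fold or ratio < 1.0 / depth_fold:
                why.append("depth")
        if have_tetra and med_dist > 0 and dist[i] > tetra_fold * med_dist:
            why.append("tetra")
        if why:
            reasons[c] = why
    return reasons


def _keep_key(b: BinRecord):
    # best bin first: higher completeness, then lower contamination, then id
    return (-b.completeness, b.contamination, b.bin_id)


def dereplicate_by_aai(bins: list[BinRecord], aai: AAIMatrix,
                       cutoff: float = 99.0) -> list[BinRecord]:
    """Keep one bin per connected component of the AAI >= cutoff graph.

    Within a component, the bin maximizing (completeness, -contamination,
    then ascending bin id) survives.  Component-based resolution makes the
    result independent of pair ordering.
    """
    ids = [b.bin_id for b in bins]
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in itertools.combinations(ids, 2):
        if aai[a, b] >= cutoff:
            parent[find(a)] = find(b)

    by_comp: dict[str, list[BinRecord]] = {}
    for b in bins:
        by_comp.setdefault(find(b.bin_id), []).append(b)
    kept = [min(group, key=_keep_key) for group in by_comp.values()]
    return sorted(kept, key=lambda b: b.bin_id)


def resolve_duplicate_contigs(bins: list[BinRecord],
                              stats: dict[str, ContigStats] | None = None
                              ) -> list[BinRecord]:
    """Assign every contig to at most one bin (the best bin by
    completeness, then contamination, then id).  Bins left empty are
    dropped; lengths/counts are recomputed when stats are supplied."""
    owner: dict[str, BinRecord] = {}
    for b in sorted(bins, key=_keep_key):
        for c in b.contigs:
            owner.setdefault(c, b)
    out = []
    for b in bins:
        keep = {c for c in b.contigs if owner[c] is b}
        if not keep:
            log.info("bin %s emptied by duplicate-contig resolution", b.bin_id)
            continue
        total = (sum(stats[c].length for c in keep) if stats
                 else b.total_length)
        out.append(replace(b, contigs=keep, scaffold_count=len(keep),
                           total_length=total))
    return out


def quality_gate(bins: list[BinRecord], min_completeness: float = 70.0,
                 max_contamination: float = 9.0) -> list[BinRecord]:
    """Keep bins with completeness >= 70% and contamination <= 9%
    (boundaries inclusive)."""
    return [b for b in bins
            if b.completeness >= min_completeness
            and b.contamination <= max_contamination]


def mag_relative_abundance(bins: list[BinRecord],
                           stats: dict[str, ContigStats],
                           min_len: int = 3000) -> dict[str, float]:
    """Share of length-weighted depth per bin among contigs >= min_len.

    The denominator runs over ALL contigs >= min_len (binned or not), so
    fractions sum to <= 1; the remainder is the unbinned community.
    """
    denom = sum(s.depth * s.length for s in stats.values()
                if s.length >= min_len)
    if denom <= 0:
        raise ValueError("no contigs pass the length threshold")
    out = {}
    for b in bins:
        num = sum(stats[c].depth * stats[c].length for c in b.contigs
                  if stats[c].length >= min_len)
        out[b.bin_id] = num / denom
    return out


def irep_eligible(bin_rec: BinRecord,
                  max_scaffolds_per_mb: float = 175.0) -> bool:
    """Bacterial bins with <= 175 scaffolds per Mb (boundary inclusive)."""
    if bin_rec.total_length <= 0:
        raise ValueError("total length must be positive")
    if bin_rec.domain.lower() != "bacteria":
        return False
    per_mb = bin_rec.scaffold_count / (bin_rec.total_length / 1e6)
    return per_mb <= max_scaffolds_per_mb


@dataclass
class RefinementResult:
    bins: list[BinRecord]
    removed_contigs: dict[str, dict[str, list[str]]]  # bin -> contig -> reasons
    merged: list[tuple[str, str, str]]                # (a, b, merged id)
    log: list[str] = field(default_factory=list)


def refine_bins(bins: list[BinRecord], stats: dict[str, ContigStats],
                aai: AAIMatrix, merged_quality=None, quality_update=None,
                gc_mad_k: float = 3.0, depth_fold: float = 3.0,
                tetra_fold: float = 3.0, aai_cutoff: float = 99.0,
                min_completeness: float = 70.0,
                max_contamination: float = 9.0) -> RefinementResult:
    """The full refinement workflow: merge, filter, dereplicate, resolve,
    gate.  ``merged_quality(bin_a, bin_b) -> (C, X)`` supplies the quality
    of a prospective merged bin (a marker-gene estimate upstream; the
    synthetic generator provides a truth-based one); without it the merge
    stage is skipped.  ``quality_update(bin) -> (C, X)`` re-estimates
    completeness/contamination after contig removal (upstream this is a
    marker-gene re-run); without it the input values are carried through.
    Output invariants (no duplicate contigs, all bins pass the gate, no
    kept pair at AAI >= cutoff) are asserted."""
    messages: list[str] = []
    working = list(bins)
    aai_values = aai.values.copy()

    merged_pairs: list[tuple[str, str, str]] = []
    if merged_quality is not None:
        changed = True
        while changed:
            changed = False
            for a, b in itertools.combinations(list(working), 2):
                if a.taxonomy != b.taxonomy:
                    continue
                c_m, x_m = merged_quality(a, b)
                if merge_decision((a.completeness, a.contamination),
                                  (b.completeness, b.contamination),
                                  (c_m, x_m), a.taxonomy, b.taxonomy):
                    mid = f"{a.bin_id}+{b.bin_id}"
                    merged = BinRecord(
                        bin_id=mid, contigs=set(a.contigs) | set(b.contigs),
                        taxonomy=a.taxonomy, completeness=c_m,
                        contamination=x_m,
                        total_length=sum(stats[c].length
                                         for c in set(a.contigs) | set(b.contigs)),
                        domain=a.domain)
                    working = [x for x in working if x not in (a, b)] + [merged]
                    row = aai_values.loc[[a.bin_id, b.bin_id]].max(axis=0)
                    aai_values[mid] = row
                    aai_values.loc[mid] = row
                    aai_values.loc[mid, mid] = 100.0
                    aai_values = aai_values.drop(index=[a.bin_id, b.bin_id],
                                                 columns=[a.bin_id, b.bin_id])
                    merged_pairs.append((a.bin_id, b.bin_id, mid))
                    messages.append(f"merged {a.bin_id}+{b.bin_id}: "
                                    f"C {c_m:.1f} X {x_m:.1f}")
                    changed = True
                    break

    removed: dict[str, dict[str, list[str]]] = {}
    filtered: list[BinRecord] = []
    for b in working:
        kept, rem, reasons = filter_outlier_contigs(
            b, stats, gc_mad_k=gc_mad_k, depth_fold=depth_fold,
            tetra_fold=tetra_fold)
        if rem:
            removed[b.bin_id] = reasons
            messages.append(f"{b.bin_id}: removed {len(rem)} outlier contigs")
        if kept:
            total = sum(stats[c].length for c in kept)
            nb = replace(b, contigs=set(kept), scaffold_count=len(kept),
                         total_length=total)
            if quality_update is not None and rem:
                c_new, x_new = quality_update(nb)
                nb = replace(nb, completeness=c_new, contamination=x_new)
            filtered.append(nb)

    aai_now = AAIMatrix(aai_values.loc[[b.bin_id for b in filtered],
                                       [b.bin_id for b in filtered]])
    dereplicated = dereplicate_by_aai(filtered, aai_now, cutoff=aai_cutoff)
    resolved = resolve_duplicate_contigs(dereplicated, stats)
    if quality_update is not None:
        resolved = [replace(b, **dict(zip(("completeness", "contamination"),
                                          quality_update(b))))
                    for b in resolved]
    final = quality_gate(resolved, min_completeness, max_contamination)

    # output invariants
    seen: set[str] = set()
    for b in final:
        assert not (b.contigs & seen), "duplicate contigs in output"
        seen |= b.contigs
        assert b.completeness >= min_completeness
        assert b.contamination <= max_contamination
    for a, b in itertools.combinations(final, 2):
        assert aai_values.loc[a.bin_id, b.bin_id] < aai_cutoff

    return RefinementResult(bins=final, removed_contigs=removed,
                            merged=merged_pairs, log=messages)
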