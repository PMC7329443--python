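"""Shared readers/writers and run configuration.

Conventions: all genomic intervals are 0-based half-open internally
(bedGraph convention); tabular outputs are TSV with a header and optional
'#' comment lines; fluid chemistry uses CSV.  Every run writes the
effective configuration next to its outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .irep import CoverageTrack
from .mags import AAIMatrix, BinRecord, ContigStats

log = logging.getLogger(__name__)

__all__ = [
    "read_fasta", "write_fasta", "read_bedgraph", "write_bedgraph",
    "bedgraph_to_track", "read_table", "write_table",
    "read_contig_stats", "write_contig_stats", "read_bins", "write_bins",
    "read_aai", "write_aai", "RunConfig",
]


def read_fasta(path) -> dict[str, str]:
    """id -> uppercase sequence; duplicate ids and empty files are errors."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{rec.id}: non-ACGTN characters in sequence")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bedgraph(path) -> pd.DataFrame:
    """4-column bedGraph (contig, start, end, depth; 0-based half-open).

    Intervals are validated per contig: end > start, no overlaps; gaps
    are allowed and treated as depth 0 downstream (with a warning).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["contig", "start", "end", "depth"])
    if df.empty:
        raise ValueError(f"empty bedGraph {path}")
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"interval end <= start at {bad['contig']}:"
                         f"{bad['start']}-{bad['end']}")
    gaps = False
    for contig, sub in df.groupby("contig", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping intervals on {contig}")
        if (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).any():
            gaps = True
    if gaps:
        log.warning("bedGraph has gaps; gap positions count as depth 0")
    return df.sort_values(["contig", "start"], kind="mergesort",
                          ignore_index=True)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a non-overlapping tiling track as 4-column bedGraph."""
    if track.slide != track.window:
        raise ValueError("only non-overlapping tilings can be written")
    pos: dict[str, int] = {}
    with open(path, "w") as fh:
        for cid, d in zip(track.contig_ids, track.depths):
            start = pos.get(cid, 0)
            fh.write(f"{cid}\t{start}\t{start + track.window}\t{d:g}\n")
            pos[cid] = start + track.window



def bedgraph_to_track(df: pd.DataFrame, window: int) -> CoverageTrack:
    """Mean depth per non-overlapping window of ``window`` bp per contig.

    Positions not covered by any interval count as depth 0; a trailing
    partial window is dropped.
    """
    depths, cids = [], []
    for contig, sub in df.groupby("contig", sort=False):
        length = int(sub["end"].max())
        per_base = np.zeros(length)
        for s, e, d in sub[["start", "end", "depth"]].itertuples(index=False):
            per_base[int(s):int(e)] = d
        nwin = length // window
        if nwin == 0:
            continue
        w = per_base[:nwin * window].reshape(nwin, window).mean(axis=1)
        depths.append(w)
        cids.append(np.repeat(contig, nwin))
    if not depths:
        raise ValueError("no contig long enough for one window")
    return CoverageTrack(window, window, np.concatenate(depths),
                         np.concatenate(cids))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, comments: list[str] | None = None
                ) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_contig_stats(stats: dict[str, ContigStats], path) -> None:
    rows = []
    for s in stats.values():
        row = {"contig_id": s.contig_id, "length": s.length, "gc": s.gc,
               "depth": s.depth}
        if s.tetra is not None:
            row.update({f"t{i:03d}": v for i, v in enumerate(s.tetra)})
        rows.append(row)
    write_table(pd.DataFrame(rows), path,
                ["contig statistics: length bp, GC fraction, mean depth, "
                 "136 canonical tetranucleotide frequencies"])


def read_contig_stats(path) -> dict[str, ContigStats]:
    df = read_table(path)
    tcols = sorted(c for c in df.columns if c.startswith("t") and c[1:].isdigit())
    out = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        tetra = np.array([d[c] for c in tcols]) if tcols else None
        out[d["contig_id"]] = ContigStats(d["contig_id"], int(d["length"]),
                                          float(d["gc"]), float(d["depth"]),
                                          tetra)
    return out


def write_bins(bins: list[BinRecord], path) -> None:
    rows = [{"bin_id": b.bin_id, "taxonomy": b.taxonomy,
             "completeness": b.completeness, "contamination": b.contamination,
             "total_length": b.total_length, "scaffold_count": b.scaffold_count,
             "domain": b.domain, "contigs": ",".join(sorted(b.contigs))}
            for b in bins]
    write_table(pd.DataFrame(rows), path,
                ["bin records; 'contigs' is a comma-joined id list"])


def read_bins(path) -> list[BinRecord]:
    df = read_table(path)
    return [BinRecord(bin_id=r.bin_id, contigs=set(r.contigs.split(",")),
                      taxonomy=r.taxonomy, completeness=float(r.completeness),
                      contamination=float(r.contamination),
                      total_length=int(r.total_length),
                      scaffold_count=int(r.scaffold_count), domain=r.domain)
            for r in df.itertuples(index=False)]


def write_aai(aai: AAIMatrix, path) -> None:
    aai.values.rename_axis("bin_id").to_csv(path, sep="\t")


def read_aai(path) -> AAIMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return AAIMatrix(df)


@dataclass
class RunConfig:
    """End-to-end run parameters; defaults are the analysis thresholds
    (3-kb binning contig floor, 70/9 quality gate, AAI 99, 175
    scaffolds/Mb, FDR alpha 0.05)."""

    out_dir: str = "ventmag_out"
    seed: int = 42
    genes_a: str | None = None
    genes_b: str | None = None
    contigs: str | None = None
    bins: str | None = None
    aai: str | None = None
    coverage: str | None = None
    annotations: str | None = None
    truth: str | None = None
    fluids: str | None = None
    symbols: list[str] | None = None
    alpha: float = 0.05
    min_contig_len: int = 3000
    min_completeness: float = 70.0
    max_contamination: float = 9.0
    aai_cutoff: float = 99.0
    max_scaffolds_per_mb: float = 175.0
    irep_window: int = 5000
    irep_slide: int = 100
    irep_trim: float = 0.05
    irep_min_cov: float = 5.0
    gc_mad_k: float = 3.0
    depth_fold: float = 3.0
    tetra_fold: float = 3.0
    read_length: int = 100
    fluid_species: list[str] = field(default_factory=lambda: [
        "K", "Ca", "Cl", "SO4", "H2S", "CO2", "CH4", "H2"])
    fluid_mode: str = "extrapolate"   # or "measured"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write_effective(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
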