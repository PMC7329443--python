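"""Length-normalized gene abundance and depth-based taxonomic summaries.

The per-million abundance of a gene g with mapped reads r_g and length
L_g is::

    A_g = (r_g / L_g) / sum_h (r_h / L_h) * 1e6

so abundances sum to 1e6 per sample and doubling every count leaves them
unchanged.  Taxonomic attribution of a functional gene and 16S-based
community summaries both weight by sequencing depth.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "normalize_abundance", "taxon_breakdown", "summarize_16s",
    "rps3_representativeness",
]


def _reads_column(genes: pd.DataFrame, sample: str | None) -> str:
    if sample is not None and f"reads_{sample}" in genes.columns:
        return f"reads_{sample}"
    if "reads" not in genes.columns:
        raise KeyError("gene table needs a 'reads' (or 'reads_<sample>') column")
    return "reads"


def normalize_abundance(genes: pd.DataFrame, sample: str | None = None,
                        symbols: list[str] | None = None) -> pd.DataFrame:
    """Per-million length-normalized abundance for one sample.

    The normalization denominator sums over every gene in the table (all
    predicted genes); pass ``symbols`` to restrict the denominator to a
    key-gene subset instead.  Genes with zero reads get abundance 0.
    Raises on an all-zero sample.
    """
    col = _reads_column(genes, sample)
    df = genes.copy()
    if symbols is not None:
        df = df[df["symbol"].isin(symbols)].copy()
    if (df["length"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = df[col] / df["length"]
    total = rate.sum()
    if total <= 0:
        raise ValueError("empty sample: no mapped reads")
    df["abundance"] = rate / total * 1e6
    return df


def taxon_breakdown(genes: pd.DataFrame, symbol: str,
                    read_length: int = 100) -> pd.Series:
    """Fraction of a functional gene's total depth carried by each taxon.

    Depth is taken from a ``depth`` column or computed as
    ``reads * read_length / length``.  Returns an empty Series (with a
    warning) when the symbol is absent.
    """
    sub = genes[genes["symbol"] == symbol].copy()
    if sub.empty:
        log.warning("symbol %r absent from gene table", symbol)
        return pd.Series(dtype=float)
    if "depth" not in sub.columns:
        sub["depth"] = sub["reads"] * read_length / sub["length"]
    by = sub.groupby("taxon")["depth"].sum()
    return by / by.sum()


def summarize_16s(rrna: pd.DataFrame, label_col: str = "label",
                  unclassified: str = "unclassified",
                  per_gene_average: bool = False) -> pd.Series:
    """Depth-weighted phylum/class relative abundance from 16S records.

    Records with an empty label fall into an ``unclassified`` bucket that
    stays in the denominator.  With ``per_gene_average`` each taxon's
    depths are first averaged over its genes before normalizing (the two
    readings coincide when each taxon has one gene).
    """
    if rrna.empty:
        raise ValueError("need at least one 16S record")
    df = rrna.copy()
    lab = df[label_col].fillna("").astype(str)
    df[label_col] = lab.where(lab.str.len() > 0, unclassified)
    grouped = df.groupby(label_col)["depth"]
    agg = grouped.mean() if per_gene_average else grouped.sum()
    return agg / agg.sum()


def rps3_representativeness(markers: pd.DataFrame, binned_ids: set[str],
                            top_n: int = 50) -> tuple[int, int]:
    """How many of the top-``top_n`` deepest RpS3 marker genes fall in a
    retained bin.

    Markers are sorted by depth descending (ties broken by id for
    determinism).  If fewer than ``top_n`` markers exist, all are used and
    the actual number is returned as the second element.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = markers.sort_values(["depth", "marker_id"],
                                 ascending=[False, True])
    if len(ranked) < top_n:
        log.info("only %d markers available (top_n=%d)", len(ranked), top_n)
    top = ranked.head(top_n)
    count = int(top["marker_id"].isin(binned_ids).sum())
    return count, len(top)
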