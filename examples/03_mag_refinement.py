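"""Refine candidate genome bins into quality-gated MAGs.

The generator cuts each genome into contigs with taxon-specific GC /
depth / tetranucleotide signatures, builds two overlapping candidate
bins per taxon, and injects 15% foreign contigs carrying their true
source signatures.  Refinement merges compatible same-taxon bins, strips
composition outliers, dereplicates at AAI >= 99%, resolves duplicate
contigs, and keeps bins with completeness >= 70% / contamination <= 9%.
"""

from ventmag import mags, synth

comm_a, _ = synth.default_community(seed=42)
meta = synth.generate_bin_metadata(comm_a, contamination_fraction=0.15,
                                   bins_per_taxon=2, seed=43)
res = mags.refine_bins(meta.bins, meta.contigs, meta.aai,
                       merged_quality=meta.merged_quality,
                       quality_update=meta.quality_of)

print(f"{len(meta.bins)} candidate bins -> {len(res.bins)} refined MAGs")
removed = sum(len(v) for v in res.removed_contigs.values())
print(f"{removed} outlier contigs removed "
      f"(reasons: GC / depth / tetranucleotide divergence)")
for b in res.bins:
    print(f"  {b.bin_id:28s} completeness {b.completeness:5.1f}%  "
          f"contamination {b.contamination:4.1f}%  {b.scaffold_count} contigs")

rel = mags.mag_relative_abundance(res.bins, meta.contigs, min_len=3000)
print(f"\nbinned fraction of the >=3-kb community: {sum(rel.values()):.1%}")
print("every retained MAG passes the 70/9 gate, holds each contig")
print("exclusively, and no kept pair shares AAI >= 99%.")
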