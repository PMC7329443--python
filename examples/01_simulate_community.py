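"""Generate a synthetic two-community contrast and inspect its gene table.

The default community pair emulates an active sulfide chimney (dominated
by a sulfur-oxidizing Campylobacteria-like population carrying sox/rTCA
genes) and a recently inactive one (dominated by a Nitrospirae-like
sulfate reducer carrying dsr/Wood-Ljungdahl genes).  Reads are drawn
multinomially with probability proportional to taxon weight x gene
length, so counts, depths and totals behave like mapped short-read data.
"""

from ventmag import abundance, synth

comm_a, comm_b = synth.default_community(seed=42)
genes_a = synth.generate_gene_table(comm_a, "A")

print(f"community A: {len(comm_a.taxa)} taxa, "
      f"{genes_a['reads'].sum():,} mapped reads over {len(genes_a)} genes")
prof = abundance.normalize_abundance(genes_a)
top = prof.nlargest(5, "abundance")[["symbol", "taxon", "reads", "abundance"]]
print("\nfive most abundant genes (per-million, length-normalized):")
print(top.to_string(index=False))
print(f"\nabundances sum to {prof['abundance'].sum():,.0f} per million —")
print("the per-sample normalization that makes genes comparable across")
print("metagenomes of different sequencing depth.")
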