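"""Call pathway completeness for annotated MAGs.

The built-in ruleset grades each pathway as complete / uncomplete /
partial / none from gene-symbol presence (binary traits as present /
absent), with rules evaluated in precedence order so adding a gene can
never lower a level.
"""

from ventmag import pathways

rules = pathways.builtin_ruleset()
anns = [
    pathways.MagAnnotation("sulfur_oxidizer",
                           frozenset({"sqr", "soxA", "soxB", "soxX", "soxY",
                                      "soxZ", "soxC", "soxD", "aclA", "aclB"}),
                           cazyme_count=6),
    pathways.MagAnnotation("sulfate_reducer",
                           frozenset({"sat", "dsrA", "dsrB", "cdhC", "cdhD",
                                      "cdhE", "cooS", "cyc2"}),
                           cazyme_count=24),
    pathways.MagAnnotation("heterotroph",
                           frozenset({"coxL", "coxM", "ACSS", "coxA", "coxB",
                                      "adhE"}),
                           cazyme_count=31),
]

matrix = pathways.classify_all(anns, rules)
shown = ["sox", "rtca", "dsr", "wood_ljungdahl", "co_oxidation",
         "cytochrome_c_oxidase", "iron_oxidation_cyc2", "fermentation"]
print(matrix[shown].T.to_string())
print(f"\nmean CAZyme count over the group: "
      f"{pathways.mean_cazymes(anns):.1f} genes per MAG")
print("\n'uncomplete' marks a pathway whose core genes are mostly present")
print("(e.g. dsr lacking aprAB); CAZyme counts index heterotrophic")
print("potential, typically higher in inactive-chimney communities.")
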