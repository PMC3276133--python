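"""Hypergeometric over-representation of a hit list.

Builds a toy annotation of 60 genes in four functional terms, takes a hit
list concentrated in one term, and tests each term with the upper-tail
hypergeometric test plus Benjamini-Hochberg adjustment.
"""

from chemscreen import AnnotationMap, hypergeometric_enrichment

universe = [f"g{i:02d}" for i in range(60)]
annotation = AnnotationMap(
    {
        "glyoxal detox": frozenset(universe[0:10]),
        "HOG signalling": frozenset(universe[10:22]),
        "glucose repression": frozenset(universe[22:40]),
        "transport": frozenset(universe[40:60]),
    },
    frozenset(universe),
)
hits = universe[0:7] + universe[10:12] + universe[55:57]

result = hypergeometric_enrichment(hits, annotation)
print(result.round(5).to_string(index=False))
print(
    "\nk of the n hits fall in a term of size K within the N-gene universe;"
    "\np is P(X >= k) for the hypergeometric, p_adj the BH-adjusted value —"
    "\nonly the term the hits were drawn from is significant."
)
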