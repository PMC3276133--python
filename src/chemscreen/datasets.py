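"""Bundled worked-example data.

Ships a small multicopy-suppressor locus table from a published glyoxal
screen of a yeast genomic library: per-locus member ORFs in genomic order,
their per-ORF log2 enrichment ratios (bracketed members are absent from the
array and scored 0.00), the printed locus average, and singleton genes with
no high-scoring neighbour.  Useful as a ground-truth fixture for the locus
caller and locus-average arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .loci import LocusCall, Singleton
from .simulate import GenomeLayout

__all__ = [
    "load_example_locus_table",
    "example_locus_calls",
    "example_layout_and_scores",
]


def load_example_locus_table() -> pd.DataFrame:
    """The raw bundled table: condition, kind (locus/singleton), members
    (;-joined, [brackets] = off-array), per-member log2 ratios, the printed
    two-decimal average and the confirmed suppressor where one was tested."""
    with resources.files("chemscreen.data").joinpath(
        "suppressor_loci_example.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def example_locus_calls() -> list[tuple[LocusCall, float]]:
    """Each multi-gene locus as a LocusCall paired with its printed average."""
    df = load_example_locus_table()
    out = []
    for i, row in enumerate(df[df["kind"] == "locus"].itertuples()):
        genes = [g.strip("[]") for g in row.members.split(";")]
        scores = [float(x) for x in row.log2_ratios.split(",")]
        out.append(
            (
                LocusCall(
                    chromosome=f"chr{i:02d}",
                    gene_ids=genes,
                    scores=scores,
                    condition=row.condition,
                ),
                float(row.printed_average),
            )
        )
    return out


def example_layout_and_scores(
    condition: str = "glyoxal+isonicotinamide",
) -> tuple[GenomeLayout, pd.Series, list[str], pd.DataFrame]:
    """Reconstruct a genome layout and ORF score vector that embed the
    example loci and singletons.

    Each locus is placed on its own chromosome, flanked by low-scoring
    (0.1) spacer genes so runs terminate; bracketed members are off-array.
    Singletons get their own chromosomes with low-scoring neighbours.
    Returns (layout, scores, singleton gene ids, the table subset used).
    """
    df = load_example_locus_table()
    sub = df[df["condition"] == condition]
    rows = []
    scores: dict[str, float] = {}
    singleton_ids: list[str] = []
    chrom_i = 0

    def add_chromosome(members: list[tuple[str, float, bool]]) -> None:
        nonlocal chrom_i
        chrom_i += 1
        chrom = f"chr{chrom_i:03d}"
        pos = 1
        padded = (
            [(f"pad{chrom_i}a", 0.1, True)]
            + members
            + [(f"pad{chrom_i}b", 0.1, True)]
        )
        for gene, score, on_array in padded:
            rows.append(
                {
                    "gene_id": gene,
                    "chromosome": chrom,
                    "start": pos,
                    "end": pos + 999,
                    "strand": "+",
                    "on_array": on_array,
                }
            )
            if on_array:
                scores[gene] = score
            pos += 1200

    for row in sub.itertuples():
        names = row.members.split(";")
        ratios = [float(x) for x in row.log2_ratios.split(",")]
        if row.kind == "locus":
            members = [
                (name.strip("[]"), score, not name.startswith("["))
                for name, score in zip(names, ratios)
            ]
            add_chromosome(members)
        else:
            add_chromosome([(names[0], ratios[0], True)])
            singleton_ids.append(names[0])
    layout = GenomeLayout(pd.DataFrame(rows))
    return layout, pd.Series(scores), singleton_ids, sub.reset_index(drop=True)
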