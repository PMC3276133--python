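"""Multicopy-suppressor locus detection.

Genomic-library screens enrich plasmids whose insert confers resistance;
because inserts carry physically contiguous DNA, true suppressors appear as
runs of adjacent over-represented ORFs.  ORF probe log2 ratios are averaged
per ORF, ordered by genomic location, and scanned for maximal runs of
adjacent ORFs scoring at or above a threshold (default log2 >= 1.6).
ORFs absent from the array score 0.00: they never break a run and never
count toward the adjacency minimum, but they do enter the locus average.
A qualifying ORF with no qualifying neighbour is reported as a singleton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "OrfScore",
    "LocusCall",
    "Singleton",
    "score_orfs",
    "detect_loci",
    "locus_average",
    "loci_to_frame",
]


@dataclass(frozen=True)
class OrfScore:
    gene_id: str
    score: float
    on_array: bool = True
    n_probes: int = 1

    @property
    def single_probe(self) -> bool:
        return self.n_probes == 1


@dataclass
class LocusCall:
    """A contiguous run of genes implicating one locus as a suppressor.

    Members are in genomic order; off-array members carry score 0.00.  The
    average is the arithmetic mean over ALL members including the zeros.
    """

    chromosome: str
    gene_ids: list[str]
    scores: list[float]
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores must align")
        if not self.gene_ids:
            raise ValueError("empty locus")

    @property
    def average(self) -> float:
        return locus_average(self)

    def display(self) -> str:
        genes = ";".join(self.gene_ids)
        ratios = ",".join(f"{s:.2f}" for s in self.scores)
        return f"{genes}\t{ratios}\t{self.average:.2f}"


@dataclass(frozen=True)
class Singleton:
    """A high-scoring gene with no qualifying neighbour."""

    gene_id: str
    score: float


def score_orfs(
    probe_table: pd.DataFrame | pd.Series,
    orf_map: Mapping[str, str],
) -> pd.DataFrame:
    """Average probe log2 ratios into one score per ORF.

    ``probe_table`` is indexed by probe id (a Series, or a frame whose
    columns are replicate arrays; all finite values are pooled into the
    mean).  ``orf_map`` maps probe id → gene id and must cover every probe.
    Returns a frame indexed by gene with ``score``, ``n_probes`` and
    ``single_probe`` columns.
    """
    if isinstance(probe_table, pd.Series):
        probe_table = probe_table.to_frame("log2_ratio")
    unknown = [p for p in probe_table.index if p not in orf_map]
    if unknown:
        raise KeyError(f"probes with no ORF assignment: {unknown[:10]}")
    long = probe_table.stack().rename("value").reset_index(level=1, drop=True)
    genes = long.index.map(orf_map.__getitem__)
    grouped = long.groupby(genes)
    probe_counts = pd.Series([orf_map[p] for p in probe_table.index]).value_counts()
    out = pd.DataFrame({"score": grouped.mean(), "n_probes": probe_counts})
    out["single_probe"] = out["n_probes"] == 1
    return out


def detect_loci(
    orf_scores: pd.DataFrame | Mapping[str, float],
    layout: GenomeLayout,
    *,
    threshold: float = 1.6,
    min_adjacent: int = 2,
    condition: str = "",
) -> tuple[list[LocusCall], list[Singleton]]:
    """Find suppressor loci as maximal runs of adjacent qualifying ORFs.

    A gene qualifies when it is on the array and scores >= ``threshold``
    (the boundary value qualifies).  Off-array genes inside a run are kept
    with score 0.00; on-array genes below threshold terminate runs.  Runs
    with at least ``min_adjacent`` qualifying members become loci; a
    qualifying gene with no qualifying neighbour becomes a singleton.
    Genes are taken in start-coordinate order per chromosome (the layout
    enforces sorting); loci never span chromosomes.
    """
    if isinstance(orf_scores, pd.DataFrame):
        score_of = orf_scores["score"].to_dict()
    else:
        score_of = dict(orf_scores)

    loci: list[LocusCall] = []
    singles: list[Singleton] = []
    genes = layout.genes  # validated: sorted by (chromosome, start)
    for chrom, sub in genes.groupby("chromosome", sort=False):
        run: list[tuple[str, float, bool]] = []  # (gene, score, qualifying)

        def close_run() -> None:
            if not run:
                return
            # trim off-array padding at both ends
            items = list(run)
            while items and not items[0][2]:
                items.pop(0)
            while items and not items[-1][2]:
                items.pop()
            n_qual = sum(1 for _, _, q in items if q)
            if n_qual >= min_adjacent:
                loci.append(
                    LocusCall(
                        chromosome=chrom,
                        gene_ids=[g for g, _, _ in items],
                        scores=[s for _, s, _ in items],
                        condition=condition,
                    )
                )
            elif n_qual == 1:
                g, s, _ = next(it for it in items if it[2])
                singles.append(Singleton(gene_id=g, score=s))
            run.clear()

        for row in sub.itertuples():
            if not row.on_array:
                # off-array: cannot break a run, scores 0.00
                run.append((row.gene_id, 0.0, False))
                continue
            s = score_of.get(row.gene_id, np.nan)
            if np.isfinite(s) and s >= threshold:
                run.append((row.gene_id, float(s), True))
            else:
                close_run()
        close_run()
    return loci, singles


def locus_average(locus: LocusCall) -> float:
    """Arithmetic mean over all locus members, off-array zeros included.

    Full precision is retained; callers round to two decimals for display.
    """
    if not locus.scores:
        raise ValueError("empty locus")
    return float(np.mean(locus.scores))


def loci_to_frame(loci: Sequence[LocusCall], singles: Sequence[Singleton] = ()) -> pd.DataFrame:
    """Tabulate calls in the shape of a published suppressor-locus table:
    members ;-joined, per-ORF scores, two-decimal average, blank
    confirmed-suppressor column."""
    rows = []
    for lc in loci:
        rows.append(
            {
                "locus": ";".join(lc.gene_ids),
                "log2_ratios": ",".join(f"{s:.2f}" for s in lc.scores),
                "average_ratio": round(lc.average, 2),
                "kind": "locus",
                "condition": lc.condition,
                "confirmed_suppressor": "",
            }
        )
    for sg in singles:
        rows.append(
            {
                "locus": sg.gene_id,
                "log2_ratios": f"{sg.score:.2f}",
                "average_ratio": np.nan,
                "kind": "singleton",
                "condition": "",
                "confirmed_suppressor": "",
            }
        )
    return pd.DataFrame(rows)
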