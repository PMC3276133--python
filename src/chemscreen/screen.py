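"""Pooled barcode deletion-screen scoring.

A pool of uniquely barcoded deletion strains is grown competitively with and
without compound; strain abundance is read out as barcode ("tag") intensity
on a hybridization array.  Scoring proceeds: per-array mean normalization,
per-tag log2(control/treatment) fold change against a control-array set,
averaging of each strain's up and down tags into a single gene score, and
rank-product significance with a permutation estimate of the proportion of
false positives (pfp).  Positive scores mark strains depleted under
treatment (sensitive); negative scores mark enriched strains (resistant).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ArraySample",
    "TagMap",
    "normalize_arrays",
    "log2_fold_change",
    "combine_tags",
    "rank_product",
    "call_sensitive",
    "call_resistant",
    "score_pooled_screen",
]


@dataclass
class ArraySample:
    """One hybridization array: a tag → intensity map plus metadata."""

    array_id: str
    role: str  # "control" | "treatment"
    intensities: pd.Series  # index: tag_id
    compound: str | None = None
    dose_mm: float = 0.0
    generations: float = 20.0

    def __post_init__(self) -> None:
        self.intensities = pd.Series(self.intensities, dtype=float)
        if self.role not in ("control", "treatment"):
            raise ValueError(f"role must be control/treatment, got {self.role!r}")
        if (self.intensities < 0).any():
            raise ValueError(f"array {self.array_id}: negative intensities")


@dataclass
class TagMap:
    """strain → (up_tag, down_tag); tags are unique across strains."""

    tags: Mapping[str, tuple[str | None, str | None]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for strain, (up, dn) in self.tags.items():
            for tag in (up, dn):
                if tag is None:
                    continue
                if tag in seen:
                    raise ValueError(
                        f"tag {tag!r} assigned to both {seen[tag]!r} and {strain!r}"
                    )
                seen[tag] = strain

    @property
    def strains(self) -> list[str]:
        return list(self.tags)

    def all_tags(self) -> list[str]:
        out = []
        for up, dn in self.tags.values():
            out.extend(t for t in (up, dn) if t is not None)
        return out


def normalize_arrays(samples: Sequence[ArraySample]) -> list[ArraySample]:
    """Rescale each array so its mean tag intensity equals the grand mean.

    The grand mean is the mean of the per-array means, so relative
    intensities within an array are untouched and a global per-array scale
    factor cancels downstream.
    """
    means = []
    for s in samples:
        m = float(s.intensities.mean())
        if not m > 0:
            raise ValueError(f"array {s.array_id} has zero total intensity")
        means.append(m)
    grand = float(np.mean(means))
    return [
        replace(s, intensities=s.intensities * (grand / m))
        for s, m in zip(samples, means)
    ]


def log2_fold_change(
    controls: Sequence[ArraySample],
    treatment: ArraySample,
) -> pd.DataFrame:
    """Per-tag log2(mean control intensity / treatment intensity).

    Zero intensities are replaced by a floor pseudo-intensity (half the
    smallest positive intensity on the relevant array side) and flagged.
    Returns a frame indexed by tag with columns ``score`` and ``floored``.
    """
    if len(controls) == 0:
        raise ValueError("need at least one control array")
    ctrl = pd.concat([c.intensities for c in controls], axis=1).mean(axis=1)
    trt = treatment.intensities.reindex(ctrl.index)
    if trt.isna().any():
        missing = list(trt.index[trt.isna()])[:5]
        raise ValueError(f"treatment array missing tags, e.g. {missing}")
    floored = (trt <= 0) | (ctrl <= 0)
    trt = trt.where(trt > 0, _positive_floor(trt))
    ctrl = ctrl.where(ctrl > 0, _positive_floor(ctrl))
    return pd.DataFrame(
        {"score": np.log2(ctrl / trt), "floored": floored}
    )


def _positive_floor(x: pd.Series) -> float:
    pos = x[x > 0]
    if pos.empty:
        raise ValueError("array has no positive intensities")
    return float(pos.min()) / 2.0


def combine_tags(tag_scores: pd.Series, tag_map: TagMap) -> pd.DataFrame:
    """Average each strain's up- and down-tag log2 ratios into one score.

    Strains with a single scored tag are flagged; strains with neither tag
    scored are dropped with a log entry.  Returns a frame indexed by strain
    with columns ``score`` and ``single_tag``.
    """
    rows = {}
    dropped = []
    for strain, (up, dn) in tag_map.tags.items():
        vals = [
            float(tag_scores[t])
            for t in (up, dn)
            if t is not None and t in tag_scores.index and np.isfinite(tag_scores[t])
        ]
        if not vals:
            dropped.append(strain)
            continue
        rows[strain] = (float(np.mean(vals)), len(vals) == 1)
    if dropped:
        logger.warning("combine_tags: dropped %d strain(s) with no scored tag: %s",
                       len(dropped), dropped[:10])
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["score", "single_tag"])
    df["single_tag"] = df["single_tag"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# rank product


def _rank_products(rank_matrix: np.ndarray) -> np.ndarray:
    """Product of per-replicate ranks (not the k-th root; exact in float)."""
    return np.prod(rank_matrix, axis=1)


def rank_product(
    scores: pd.DataFrame,
    *,
    n_permutations: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
    exhaustive_limit: int = 1_000_000,
) -> pd.DataFrame:
    """Rank-product statistic with permutation pfp per strain.

    Rows are strains, columns replicates; larger scores rank first
    (descending ranks, average ties).  RP is the geometric mean of a
    strain's ranks.  The pfp (proportion of false positives, an FDR
    estimate) is E[#null RP <= RP_g] / rank(RP_g), where the null permutes
    the rank column of each replicate independently — exhaustively when the
    permutation space (n!)^k is at most ``exhaustive_limit``, else by
    ``n_permutations`` Monte-Carlo draws seeded by ``seed``.

    Returns a frame indexed like ``scores`` with columns ``rp`` (geometric
    mean), ``pfp`` and ``rank``.
    """
    x = scores.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 strains and 2 replicates")
    for j in range(k):
        if np.ptp(x[:, j]) == 0:
            raise ValueError(
                f"replicate column {scores.columns[j]!r} is constant; ranks undefined"
            )
    ranks = np.column_stack([rankdata(-x[:, j], method="average") for j in range(k)])
    obs = _rank_products(ranks)

    space = math.factorial(n) ** k
    use_exhaustive = method == "exhaustive" or (
        method == "auto" and space <= exhaustive_limit
    )
    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")
    if use_exhaustive and space > 10 * exhaustive_limit:
        raise ValueError(
            f"exhaustive permutation space (n!)^k = {space:.3g} is intractable; "
            "use the Monte-Carlo estimator"
        )

    # c[g] = expected number of null RPs <= obs[g] in one null experiment
    thresholds = np.sort(obs) * (1.0 + 1e-12)
    counts = np.zeros(n, dtype=float)
    if use_exhaustive:
        cols = [list(itertools.permutations(ranks[:, j])) for j in range(k)]
        total = 0
        for combo in itertools.product(*cols):
            null = _rank_products(np.column_stack(combo))
            counts += np.searchsorted(np.sort(null), thresholds, side="right")
            total += 1
        counts /= total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            null = _rank_products(
                np.column_stack([rng.permutation(ranks[:, j]) for j in range(k)])
            )
            counts += np.searchsorted(np.sort(null), thresholds, side="right")
        counts /= n_permutations
    # undo the sort applied to thresholds
    order = np.argsort(obs, kind="stable")
    c = np.empty(n)
    c[order] = counts
    obs_rank = rankdata(obs, method="average")
    pfp = c / obs_rank
    return pd.DataFrame(
        {"rp": obs ** (1.0 / k), "pfp": pfp, "rank": obs_rank},
        index=scores.index,
    )


def call_sensitive(gene_scores: pd.DataFrame, fdr_cutoff: float = 0.05) -> list[str]:
    """Strains with pfp below the cutoff and a positive (depleted) mean
    score, sorted by ascending rank product."""
    hits = gene_scores[(gene_scores["pfp"] < fdr_cutoff) & (gene_scores["mean_score"] > 0)]
    return list(hits.sort_values("rp").index)


def call_resistant(
    gene_scores: pd.DataFrame,
    *,
    resistance_threshold: float = 1.0,
    background_floor: float = 64.0,
) -> list[str]:
    """Strains enriched under strong selection.

    Requires a mean log2(control/treatment) score at or below minus the
    threshold (at least 2-fold enrichment by default) AND a mean treatment
    intensity above the array background floor — a tag sitting at
    background carries no abundance information.
    """
    sel = (gene_scores["mean_score"] <= -resistance_threshold) & (
        gene_scores["treatment_intensity"] > background_floor
    )
    hits = gene_scores[sel]
    return list(hits.sort_values("mean_score").index)


def score_pooled_screen(
    samples: Sequence[ArraySample],
    tag_map: TagMap,
    *,
    mode: str = "sensitivity",
    fdr_cutoff: float = 0.05,
    n_permutations: int = 10_000,
    seed: int | None = None,
    resistance_threshold: float = 1.0,
    background_floor: float = 64.0,
) -> pd.DataFrame:
    """End-to-end screen scoring: normalize, fold-change, tag averaging,
    rank product, and sensitive/resistant calls.

    Each treatment array is one biological replicate scored against the
    whole control set.  Returns a frame indexed by strain with per-replicate
    scores, ``mean_score``, ``rp``, ``pfp``, ``treatment_intensity`` and
    ``call`` in {"sensitive", "resistant", "none"}.
    """
    if mode not in ("sensitivity", "resistance"):
        raise ValueError(f"mode must be sensitivity/resistance, got {mode!r}")
    normed = normalize_arrays(samples)
    controls = [s for s in normed if s.role == "control"]
    treatments = [s for s in normed if s.role == "treatment"]
    if not controls or not treatments:
        raise ValueError("need both control and treatment arrays")

    per_rep = {}
    for trt in treatments:
        tag_scores = log2_fold_change(controls, trt)["score"]
        per_rep[f"score_{trt.array_id}"] = combine_tags(tag_scores, tag_map)["score"]
    mat = pd.DataFrame(per_rep).dropna()

    signed = mat if mode == "sensitivity" else -mat
    rp = rank_product(signed, n_permutations=n_permutations, seed=seed)

    # mean treatment intensity per strain (mean over its tags and arrays)
    tag_to_strain = {
        t: s for s, (up, dn) in tag_map.tags.items() for t in (up, dn) if t is not None
    }
    trt_int = (
        pd.concat([t.intensities for t in treatments], axis=1)
        .mean(axis=1)
        .groupby(tag_to_strain)
        .mean()
    )

    out = mat.copy()
    out["mean_score"] = mat.mean(axis=1)
    out["rp"] = rp["rp"]
    out["pfp"] = rp["pfp"]
    out["treatment_intensity"] = trt_int.reindex(out.index)
    out["call"] = "none"
    if mode == "sensitivity":
        out.loc[call_sensitive(out, fdr_cutoff), "call"] = "sensitive"
    else:
        resist = call_resistant(
            out,
            resistance_threshold=resistance_threshold,
            background_floor=background_floor,
        )
        out.loc[resist, "call"] = "resistant"
    return out
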