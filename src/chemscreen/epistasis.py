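"""Quantitative genetic-interaction (epistasis) analysis.

Under the multiplicative model a double mutant's expected fitness is the
product of the single-mutant fitnesses, W_x·W_y; the interaction score is
the deviation ε = W_xy − W_x·W_y (negative = aggravating, positive =
alleviating/suppressing).  Each pair is built twice with swapped selection
markers; pairs whose two orientations disagree by more than
|W_xy − W_yx| / 2 > 0.2 are discarded, the rest averaged.  Interaction
profiles are hierarchically clustered with correlation distance so genes
acting in the same pathway group together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .simulate import GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "expected_fitness",
    "epsilon",
    "reciprocal_filter",
    "average_orientations",
    "reciprocal_correlation",
    "classify_sign",
    "epistasis_table",
    "ClusterResult",
    "cluster_profiles",
    "condition_contrast",
    "linked_pairs",
    "epsilon_matrix",
]

RECIPROCAL_CUTOFF = 0.2
SIGN_DEADZONE = 0.08


def expected_fitness(w_x: float, w_y: float) -> float:
    """Multiplicative expectation for a double mutant: W_x × W_y."""
    if w_x < 0 or w_y < 0:
        raise ValueError("fitness values must be non-negative")
    return w_x * w_y


def epsilon(w_xy: float, w_x: float, w_y: float) -> float:
    """Interaction score ε = W_xy − W_x·W_y."""
    if min(w_xy, w_x, w_y) < 0:
        raise ValueError("fitness values must be non-negative")
    return w_xy - w_x * w_y


def reciprocal_filter(
    w_xy_kannat: float, w_xy_natkan: float, cutoff: float = RECIPROCAL_CUTOFF
) -> bool:
    """True (keep) unless the marker orientations disagree:
    |W_xy − W_yx| / 2 > cutoff discards; the exact boundary keeps."""
    return abs(w_xy_kannat - w_xy_natkan) / 2.0 <= cutoff


def average_orientations(eps_kannat: float, eps_natkan: float) -> float:
    """Arithmetic mean of the two orientations' ε values."""
    return 0.5 * (eps_kannat + eps_natkan)


def reciprocal_correlation(
    w_orientation_a: Sequence[float], w_orientation_b: Sequence[float]
) -> float:
    """Squared Pearson correlation between the two orientations' fitness
    vectors across gene pairs — the assay's reproducibility statistic."""
    a = np.asarray(w_orientation_a, dtype=float)
    b = np.asarray(w_orientation_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need >= 3 paired fitness values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in an orientation; R^2 undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def classify_sign(mean_eps: float, deadzone: float = SIGN_DEADZONE) -> str:
    """Aggravating / alleviating / none with a symmetric dead-zone."""
    if abs(mean_eps) < deadzone:
        return "none"
    return "aggravating" if mean_eps < 0 else "alleviating"


def epistasis_table(
    singles: pd.DataFrame,
    doubles: pd.DataFrame,
    *,
    cutoff: float = RECIPROCAL_CUTOFF,
    deadzone: float = SIGN_DEADZONE,
) -> pd.DataFrame:
    """Per-pair, per-condition ε with reciprocal filtering.

    ``singles`` needs columns gene, condition, W (marker-matched single
    mutants); ``doubles`` needs gene_x, gene_y, orientation, condition, W.
    The output has one row per (pair, condition) with W_x, W_y, expected,
    ε per orientation, mean ε, ``filtered`` (orientation disagreement),
    ``single_orientation`` and the sign class.
    """
    w_single = singles.set_index(["gene", "condition"])["W"]
    rows = []
    grouped = doubles.groupby(["gene_x", "gene_y", "condition"], sort=True)
    for (gx, gy, cond), sub in grouped:
        try:
            wx = float(w_single[(gx, cond)])
            wy = float(w_single[(gy, cond)])
        except KeyError as exc:
            raise KeyError(f"missing single-mutant fitness for {exc.args[0]}") from None
        exp = expected_fitness(wx, wy)
        w_by_ori = sub.set_index("orientation")["W"].to_dict()
        e_kn = epsilon(w_by_ori["KanNat"], wx, wy) if "KanNat" in w_by_ori else np.nan
        e_nk = epsilon(w_by_ori["NatKan"], wx, wy) if "NatKan" in w_by_ori else np.nan
        single_ori = ("KanNat" not in w_by_ori) or ("NatKan" not in w_by_ori)
        if single_ori:
            filtered = False
            mean_e = e_kn if np.isfinite(e_kn) else e_nk
        else:
            filtered = not reciprocal_filter(
                w_by_ori["KanNat"], w_by_ori["NatKan"], cutoff
            )
            mean_e = average_orientations(e_kn, e_nk)
        rows.append(
            {
                "gene_x": gx,
                "gene_y": gy,
                "condition": cond,
                "W_x": wx,
                "W_y": wy,
                "expected": exp,
                "W_xy_KanNat": w_by_ori.get("KanNat", np.nan),
                "W_xy_NatKan": w_by_ori.get("NatKan", np.nan),
                "eps_KanNat": e_kn,
                "eps_NatKan": e_nk,
                "mean_eps": mean_e,
                "filtered": filtered,
                "single_orientation": single_ori,
                "sign_class": classify_sign(mean_e, deadzone) if not filtered else "none",
            }
        )
    return pd.DataFrame(rows)


def epsilon_matrix(records: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Symmetric gene × gene matrix of mean ε for one condition; filtered
    pairs and absent cells are NaN."""
    sub = records[(records["condition"] == condition) & (~records["filtered"])]
    genes = sorted(set(sub["gene_x"]) | set(sub["gene_y"]))
    mat = pd.DataFrame(np.nan, index=genes, columns=genes)
    for r in sub.itertuples():
        mat.loc[r.gene_x, r.gene_y] = r.mean_eps
        mat.loc[r.gene_y, r.gene_x] = r.mean_eps
    return mat


@dataclass
class ClusterResult:
    """Average-linkage clustering of ε profiles with correlation distance."""

    genes: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    dropped: list[str] = field(default_factory=list)

    def cut(self, n_clusters: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.genes, labels.tolist()))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.genes)
        heights = {i: 0.0 for i in range(n)}
        parts = {i: self.genes[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = max(0.0, h - heights[a])
            lb = max(0.0, h - heights[b])
            node = n + k
            parts[node] = f"({parts[a]}:{la:g},{parts[b]}:{lb:g})"
            heights[node] = h
        root = n + len(self.linkage_matrix) - 1 if len(self.linkage_matrix) else 0
        return parts[root] + ";"


def _pairwise_complete_correlation_distance(mat: pd.DataFrame) -> np.ndarray:
    """1 − Pearson r between rows using pairwise-complete observations.

    Pairs with < 2 common finite values or zero variance get the maximum
    distance (2.0) with a log entry — fabricating a correlation there
    would invent structure.
    """
    x = mat.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(x[i]) & np.isfinite(x[j])
            if ok.sum() < 2 or np.ptp(x[i, ok]) == 0 or np.ptp(x[j, ok]) == 0:
                logger.warning(
                    "no usable correlation between %s and %s; assigning max distance",
                    mat.index[i], mat.index[j],
                )
                d[i, j] = d[j, i] = 2.0
                continue
            r = float(np.corrcoef(x[i, ok], x[j, ok])[0, 1])
            d[i, j] = d[j, i] = 1.0 - r
    return d


def cluster_profiles(
    eps_mat: pd.DataFrame,
    *,
    linkage_method: str = "average",
    min_finite: int = 2,
    min_finite_frac: float = 0.5,
) -> ClusterResult:
    """Hierarchically cluster gene interaction profiles.

    Distance is 1 − Pearson r between the rows of the gene × gene ε matrix
    (pairwise-complete).  Genes with fewer than ``min_finite`` finite ε
    values, or less than ``min_finite_frac`` of their profile finite, are
    dropped with a log entry.  Constant profiles are likewise dropped —
    their correlations are undefined.
    """
    finite = eps_mat.notna()
    keep, dropped = [], []
    for g in eps_mat.index:
        row = eps_mat.loc[g]
        nfin = int(finite.loc[g].sum())
        if nfin < min_finite or nfin < min_finite_frac * len(row):
            dropped.append(g)
        elif np.ptp(row.dropna().to_numpy()) == 0:
            dropped.append(g)
        else:
            keep.append(g)
    if dropped:
        logger.warning("cluster_profiles: dropped %d gene(s): %s", len(dropped), dropped)
    if len(keep) < 3:
        raise ValueError("need >= 3 usable gene profiles to cluster")
    sub = eps_mat.loc[keep, :]
    dmat = _pairwise_complete_correlation_distance(sub)
    condensed = dmat[np.triu_indices(len(keep), k=1)]
    Z = linkage(condensed, method=linkage_method)
    order = [keep[i] for i in leaves_list(Z)]
    return ClusterResult(genes=keep, linkage_matrix=Z, leaf_order=order, dropped=dropped)


def condition_contrast(
    records: pd.DataFrame,
    *,
    control: str,
    treatment: str,
    call_threshold: float = SIGN_DEADZONE,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Δε = ε_treatment − ε_control per pair, with per-condition counts of
    interactions (|mean ε| ≥ ``call_threshold``, unfiltered pairs only)."""
    unfiltered = records[~records["filtered"]]
    keyed = unfiltered.set_index(["gene_x", "gene_y", "condition"])["mean_eps"]
    ctrl = keyed.xs(control, level="condition")
    trt = keyed.xs(treatment, level="condition")
    common = ctrl.index.intersection(trt.index)
    table = pd.DataFrame(
        {
            "eps_control": ctrl.loc[common],
            "eps_treatment": trt.loc[common],
        }
    )
    table["delta_eps"] = table["eps_treatment"] - table["eps_control"]
    counts = {
        control: int((ctrl.abs() >= call_threshold).sum()),
        treatment: int((trt.abs() >= call_threshold).sum()),
    }
    return table.reset_index(), counts


def linked_pairs(
    layout: GenomeLayout,
    pairs: Sequence[tuple[str, str]],
    *,
    max_bp: int = 50_000,
) -> set[tuple[str, str]]:
    """Pairs of genes close enough on one chromosome that a double mutant
    cannot be built by meiotic recombination; flag for exclusion."""
    pos = layout.genes.set_index("gene_id")[["chromosome", "start", "end"]]
    out: set[tuple[str, str]] = set()
    for x, y in pairs:
        if x not in pos.index or y not in pos.index:
            continue
        cx, cy = pos.loc[x, "chromosome"], pos.loc[y, "chromosome"]
        if cx != cy:
            continue
        gap = max(
            pos.loc[y, "start"] - pos.loc[x, "end"],
            pos.loc[x, "start"] - pos.loc[y, "end"],
        )
        if gap <= max_bp:
            out.add((x, y))
    return out
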