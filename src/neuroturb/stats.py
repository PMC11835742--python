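"""Group inference: permutation rank-sum tests, effect sizes, FDR control,
outcome correlations, and node-level analysis with RSN attribution.

The group test is a permutation test on the Wilcoxon rank-sum statistic
(two-sided, add-one p-value convention), not the asymptotic normal
approximation; multiplicity is controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata
from statsmodels.stats.multitest import multipletests

from .geometry import ParcelGeometry


@dataclass(frozen=True)
class GroupComparison:
    """One measure compared between two groups."""

    measure_name: str
    group_a: str
    group_b: str
    cohens_d: float
    p_perm: float
    p_fdr: float


@dataclass(frozen=True)
class NodeLevelReport:
    """Node-by-node comparison between two groups.

    ``selected_mask`` marks FDR-significant nodes whose raw p-value falls in
    the bottom quantile; ``rsn_counts`` tallies the resting-state networks of
    the selected nodes.
    """

    group_a: str
    group_b: str
    node_p: np.ndarray
    node_p_fdr: np.ndarray
    significant_mask: np.ndarray
    selected_mask: np.ndarray
    rsn_counts: dict[str, int]

    def __post_init__(self) -> None:
        if np.any(self.selected_mask & ~self.significant_mask):
            raise ValueError("selected nodes must be a subset of significant nodes")
        if sum(self.rsn_counts.values()) != int(self.selected_mask.sum()):
            raise ValueError("rsn_counts must partition the selected nodes")


def _perm_ranksum_matrix(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator,
    chunk: int = 250,
) -> np.ndarray:
    """Vectorized permutation rank-sum p-values, one per column.

    ``x`` is (n_x, m), ``y`` is (n_y, m); the same label permutations are
    applied to every column.  Two-sided p with the add-one convention:
    ``p = (1 + #{|T_perm - E| >= |T_obs - E|}) / (1 + n_perm)`` where ``E``
    is the null expectation ``n_x (n + 1) / 2`` of the rank sum.
    """
    n_x = x.shape[0]
    pooled = np.vstack([x, y])
    n = pooled.shape[0]
    if np.ptp(pooled, axis=None) == 0:
        raise ValueError("constant pooled data: rank-sum test undefined")
    ranks = rankdata(pooled, axis=0)
    expectation = n_x * (n + 1) / 2.0
    t_obs = np.abs(ranks[:n_x].sum(axis=0) - expectation)
    count = np.zeros(pooled.shape[1])
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((size, n)), axis=1)[:, :n_x]
        t_perm = np.abs(ranks[idx].sum(axis=1) - expectation)  # (size, m)
        count += (t_perm >= t_obs - 1e-9).sum(axis=0)
        done += size
    return (1.0 + count) / (1.0 + n_perm)


def perm_ranksum(
    x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> float:
    """Two-sided permutation test on the Wilcoxon rank-sum statistic.

    The smallest attainable p-value is ``1 / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    rng = np.random.default_rng(seed)
    return float(_perm_ranksum_matrix(x[:, None], y[:, None], n_perm, rng)[0])


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled (n_x + n_y - 2)-denominator SD."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx + ny - 2
    )
    if pooled_var <= 0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def fdr_bh(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(adjusted_p, rejection_mask)`` at level ``q``; adjusted p-values
    are ``min_{j >= i} (m * p_(j) / j)`` clipped at 1.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def outcome_correlation(
    measure: np.ndarray, pct_change: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between a baseline measure and the outcome score."""
    measure = np.asarray(measure, dtype=float).ravel()
    pct_change = np.asarray(pct_change, dtype=float).ravel()
    if measure.size != pct_change.size:
        raise ValueError("vectors must have equal length")
    if measure.size < 5:
        raise ValueError("need at least 5 patients")
    if np.ptp(measure) == 0 or np.ptp(pct_change) == 0:
        raise ValueError("constant input: correlation undefined")
    result = pearsonr(measure, pct_change)
    return float(result.statistic), float(result.pvalue)


def compare_measures(
    groups: dict[str, pd.DataFrame],
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise group comparisons across a family of scalar measures.

    ``groups`` maps label -> DataFrame (subjects x measures, shared columns).
    For each group pair, every measure is tested with the permutation
    rank-sum test and Cohen's d; BH-FDR is applied across the measures within
    that pair.  Returns a tidy table.
    """
    labels = list(groups)
    cols = list(groups[labels[0]].columns)
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(labels, 2)):
        ps, ds = [], []
        for j, m in enumerate(cols):
            x = groups[a][m].to_numpy()
            y = groups[b][m].to_numpy()
            ps.append(
                perm_ranksum(
                    x, y, n_perm=n_perm,
                    seed=int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % 2**31),
                )
            )
            ds.append(cohens_d(x, y))
        p_adj, _ = fdr_bh(np.asarray(ps), q=q)
        for m, d, p, pf in zip(cols, ds, ps, p_adj):
            rows.append(
                {
                    "measure": m, "group_a": a, "group_b": b,
                    "cohens_d": d, "p_perm": p, "p_fdr": pf,
                }
            )
    return pd.DataFrame(rows)


def node_level_analysis(
    groups: dict[str, np.ndarray],
    geom: ParcelGeometry,
    quantile: float = 0.30,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
    quantile_over: str = "significant",
) -> dict[tuple[str, str], NodeLevelReport]:
    """Node-by-node group comparison of per-region measures with RSN tallies.

    ``groups`` maps label -> (subjects x N) arrays of a node-level measure
    (typically node metastability at lam = 0.01).  Per node a permutation
    rank-sum p-value is computed, BH-FDR is applied across the N nodes, and
    the FDR-significant nodes whose raw p-value lies in the bottom
    ``quantile`` are attributed to their resting-state networks.

    Parameters
    ----------
    quantile_over
        "significant" (default) computes the p-value quantile over the
        FDR-significant nodes only; "all" computes it over all N nodes.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if quantile_over not in ("significant", "all"):
        raise ValueError("quantile_over must be 'significant' or 'all'")
    n = geom.n_regions
    for label, arr in groups.items():
        if np.asarray(arr).shape[1] != n:
            raise ValueError(f"group '{label}' has wrong node count")

    reports: dict[tuple[str, str], NodeLevelReport] = {}
    for i, (a, b) in enumerate(itertools.combinations(list(groups), 2)):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 17, i])
        )
        node_p = _perm_ranksum_matrix(
            np.asarray(groups[a], dtype=float),
            np.asarray(groups[b], dtype=float),
            n_perm, rng,
        )
        p_adj, reject = fdr_bh(node_p, q=q)
        if reject.any():
            pool = node_p[reject] if quantile_over == "significant" else node_p
            cutoff = np.quantile(pool, quantile)
            selected = reject & (node_p <= cutoff)
        else:
            selected = np.zeros(n, dtype=bool)
        counts: dict[str, int] = {}
        for lab in geom.rsn_labels[selected]:
            counts[lab] = counts.get(lab, 0) + 1
        reports[(a, b)] = NodeLevelReport(
            group_a=a, group_b=b, node_p=node_p, node_p_fdr=p_adj,
            significant_mask=reject, selected_mask=selected, rsn_counts=counts,
        )
    return reports
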