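"""Area aggregation, per-subject normalization, rank-sum/BH matrices.

Observable values from channels of the same cortical area are pooled and
summarized by their median (the distributions are skewed, so the median,
not the mean, is the representative parameter).  Because between-subject
variability dominates any area effect, each subject's values are divided
by the arithmetic mean of its area values before subjects are combined;
the normalized per-subject samples are then compared pairwise (areas, or
electrode pairs) with the two-sided Wilcoxon rank-sum test, and the
p-value family of each matrix is corrected with the Benjamini-Hochberg
step-up procedure to control the false discovery rate.  The electrodes
with the most significant partners are ranked as "core nodes".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests


@dataclass
class PMatrix:
    """Symmetric raw and BH-adjusted p-value matrices over labelled groups."""

    labels: list[str]
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isfinite(self.p_adj[i, j]) and self.p_adj[i, j] < self.alpha:
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        raw = pd.DataFrame(self.p_raw, index=self.labels, columns=self.labels)
        adj = pd.DataFrame(self.p_adj, index=self.labels, columns=self.labels)
        return raw, adj


@dataclass
class CoreNodeReport:
    """Electrodes ranked by number of significant partners; top three."""

    counts: dict[str, int]
    top3: list[str]
    partners: dict[str, list[str]]
    no_core_nodes: bool = False


def aggregate_by_area(
    channel_values: dict[str, "np.ndarray | float"],
    geometry,
    excluded: set[str] | None = None,
) -> dict[str, float]:
    """Area-level representative value: median of pooled retained channels.

    Duration-like observables pass a value list per channel (pooled across
    the area's channels before the median); single-valued observables (a
    slope, the peak, the frequency) pass scalars, and the median of the
    per-channel values is taken.  Areas with no retained channel are absent
    from the result.
    """
    excluded = excluded or set()
    out: dict[str, float] = {}
    for area in geometry.area_labels:
        pooled: list[float] = []
        for ch in geometry.area_channels(area):
            if ch in excluded or ch not in channel_values:
                continue
            v = channel_values[ch]
            if np.isscalar(v):
                pooled.append(float(v))
            else:
                pooled.extend(np.asarray(v, dtype=float).ravel())
        if pooled:
            out[area] = float(np.median(pooled))
    return out


def normalize_by_subject(summary: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Divide each subject's values by its across-group arithmetic mean.

    ``summary`` maps subject -> group (area or channel) -> value.  Returns
    a tidy frame (subject, group, value, factor); by construction the mean
    of each subject's normalized values is exactly 1.
    """
    rows = []
    for subject, values in summary.items():
        if len(values) < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 groups")
        factor = float(np.mean(list(values.values())))
        # sign-carrying observables (the downward slope) have a negative
        # factor; only a vanishing mean makes the normalization ill-defined
        if factor == 0 or abs(factor) < 1e-300:
            raise ValueError(f"subject {subject!r}: zero normalization factor")
        for group, v in values.items():
            rows.append({"subject": subject, "group": group, "value": v / factor, "factor": factor})
    return pd.DataFrame(rows)


def ranksum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration when both samples have <= ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with midranks, tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.r_[x, y])) < len(x) + len(y)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def wilcoxon_matrix(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    min_n: int = 2,
) -> PMatrix:
    """Pairwise rank-sum tests over labelled groups, BH-corrected as one family.

    Pairs where either group has fewer than ``min_n`` values are undefined
    (NaN) and excluded from the BH family; the family is all remaining
    unordered pairs of the matrix.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    n = len(labels)
    p_raw = np.full((n, n), np.nan)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            x, y = np.asarray(groups[labels[i]]), np.asarray(groups[labels[j]])
            if len(x) < min_n or len(y) < min_n:
                continue
            p_raw[i, j] = p_raw[j, i] = ranksum_p(x, y)
            pairs.append((i, j))
    p_adj = np.full((n, n), np.nan)
    if pairs:
        flat = np.array([p_raw[i, j] for i, j in pairs])
        adj = bh_adjust(flat)
        for (i, j), v in zip(pairs, adj):
            p_adj[i, j] = p_adj[j, i] = v
    return PMatrix(labels=labels, p_raw=p_raw, p_adj=p_adj, alpha=alpha)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def rank_core_nodes(pm: PMatrix, n_top: int = 3) -> CoreNodeReport:
    """Rank electrodes by their number of significant partners (p_adj < alpha).

    Ties are broken by matrix order (lower electrode index first) so
    reports are deterministic.
    """
    n = len(pm.labels)
    if n < n_top:
        raise ValueError(f"need >= {n_top} electrodes, got {n}")
    counts = {}
    partners = {}
    for i, lab in enumerate(pm.labels):
        sig = [
            pm.labels[j]
            for j in range(n)
            if j != i and np.isfinite(pm.p_adj[i, j]) and pm.p_adj[i, j] < pm.alpha
        ]
        counts[lab] = len(sig)
        partners[lab] = sig
    order = sorted(range(n), key=lambda i: (-counts[pm.labels[i]], i))
    top3 = [pm.labels[i] for i in order[:n_top]]
    return CoreNodeReport(
        counts=counts,
        top3=top3,
        partners={lab: partners[lab] for lab in top3},
        no_core_nodes=all(c == 0 for c in counts.values()),
    )
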