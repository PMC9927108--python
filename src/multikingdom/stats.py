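"""Community statistics: diversity indices, rarefaction, ordination,
PERMANOVA, and differential-abundance testing.

All quantities are computed from relative-abundance profiles laid out as
``samples x features`` :class:`pandas.DataFrame` objects (rows sum to 1).
The Bray-Curtis / PCoA / PERMANOVA / Benjamini-Hochberg primitives are
implemented here directly so their exact conventions (Gini-Simpson,
classical scaling without eigenvalue correction, permutation p-value with
the +1 floor) are explicit and testable.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "shannon",
    "simpson",
    "rarefaction_curve",
    "bray_curtis",
    "pcoa",
    "permanova",
    "rank_sum_test",
    "bh_adjust",
    "differential_abundance",
    "compare_diversity",
    "DifferentialResult",
]


# ---------------------------------------------------------------------------
# alpha diversity


def shannon(p: np.ndarray | pd.Series) -> float:
    """Shannon diversity index, in nats: ``-sum(p * ln p)`` over ``p > 0``."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundance in profile row")
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log(p)).sum())


def simpson(p: np.ndarray | pd.Series) -> float:
    """Gini-Simpson index ``1 - sum(p^2)`` (the vegan default)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundance in profile row")
    return float(1.0 - (p * p).sum())


def compare_diversity(
    profile: pd.DataFrame, groups: Mapping[str, str] | pd.Series, index: str = "shannon"
) -> tuple[float, float]:
    """Two-sided Student's t test on a per-sample alpha-diversity index.

    Returns ``(t, p)``. ``index`` is ``"shannon"`` or ``"simpson"``.
    """
    fn = {"shannon": shannon, "simpson": simpson}[index]
    groups = pd.Series(groups)
    values = profile.apply(fn, axis=1)
    labels = groups.loc[values.index]
    a, b = sorted(labels.unique())
    t, p = sps.ttest_ind(values[labels == a], values[labels == b])
    return float(t), float(p)


# ---------------------------------------------------------------------------
# rarefaction


def rarefaction_curve(
    profile: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_reps: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample-based rarefaction of observed feature richness.

    For each group and each subset size ``s = 1..group size``, draws
    ``n_reps`` random subsets of samples (without replacement within a
    subset) and counts the features nonzero in the subset union. Returns a
    tidy frame with columns ``group, size, median, q1, q3``.
    """
    rng = np.random.default_rng(seed)
    groups = pd.Series(groups)
    rows = []
    for g in sorted(groups.unique()):
        members = groups.index[groups == g]
        sub = profile.loc[members].to_numpy() > 0
        n = len(members)
        if n < 1:
            raise ValueError(f"group {g!r} has no samples")
        for s in range(1, n + 1):
            richness = np.empty(n_reps)
            for r in range(n_reps):
                idx = rng.choice(n, size=s, replace=False)
                richness[r] = sub[idx].any(axis=0).sum()
            q1, med, q3 = np.percentile(richness, [25, 50, 75])
            rows.append({"group": g, "size": s, "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity / ordination


def bray_curtis(profile: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix ``d(x,y) = sum|x-y| / sum(x+y)``."""
    x = profile.to_numpy(dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den == 0, 1, den), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profile.index, columns=profile.index)


def pcoa(dist: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-coordinate analysis (classical metric scaling).

    Double-centers ``-D^2/2``, eigendecomposes, and returns the top-``k``
    axes with positive eigenvalues plus the fraction of variance each axis
    explains (relative to the positive eigenvalues only; no Lingoes or
    Cailliez correction is applied).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    if not pos.any():
        raise ValueError("no positive eigenvalue; input is not a dissimilarity")
    k = min(k, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    frac = evals[:k] / evals[pos].sum()
    cols = [f"PCo{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=dist.index, columns=cols), frac


def _permanova_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from the squared-distance partition."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)][np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dist: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """PERMANOVA on a distance matrix; significance by label permutation.

    Returns ``(pseudo_F, p)`` with ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
    """
    groups = pd.Series(groups).loc[dist.index]
    codes, uniques = pd.factorize(groups)
    n_groups = len(uniques)
    if n_groups < 2 or pd.Series(codes).value_counts().min() < 2:
        raise ValueError("need >=2 groups with >=2 samples each")
    d2 = np.asarray(dist, dtype=float) ** 2
    f_obs = _permanova_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    hits = 0
    labels = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        if _permanova_f(d2, labels, n_groups) >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# differential abundance


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, normal approximation with tie
    correction (no continuity correction). Returns ``(U, p)``.

    A comparison where all values coincide carries no information and
    returns ``p = 1`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    u, p = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(u), float(p)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q(i) = min_{j >= i} p(j) * m / j`` over the ascending order of p,
    mapped back to the input order and clipped to 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclasses.dataclass
class DifferentialResult:
    """Per-feature outcome of a two-group abundance comparison."""

    feature: str
    mean_a: float
    mean_b: float
    statistic: float
    p: float
    q: float
    enriched: str | None  # group label, set only when q < the caller's threshold


def differential_abundance(
    profile: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum + BH differential-abundance screen.

    ``profile`` is samples x features; ``groups`` maps sample -> one of two
    labels. Returns a frame indexed by feature with columns
    ``mean_<a>, mean_<b>, statistic, p, q, enriched`` where ``enriched`` is
    the higher-mean group for features with ``q < q_threshold`` and ``None``
    otherwise.
    """
    groups = pd.Series(groups).loc[profile.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    a, b = labels
    xa = profile.loc[groups == a].to_numpy(dtype=float)
    xb = profile.loc[groups == b].to_numpy(dtype=float)
    stats_, ps = np.empty(profile.shape[1]), np.empty(profile.shape[1])
    for i in range(profile.shape[1]):
        stats_[i], ps[i] = rank_sum_test(xa[:, i], xb[:, i])
    qs = bh_adjust(ps)
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    enriched = np.where(mean_a > mean_b, a, b).astype(object)
    enriched[qs >= q_threshold] = None
    return pd.DataFrame(
        {
            f"mean_{a}": mean_a,
            f"mean_{b}": mean_b,
            "statistic": stats_,
            "p": ps,
            "q": qs,
            "enriched": enriched,
        },
        index=profile.columns.rename("feature"),
    )
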