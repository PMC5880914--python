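"""Permutation-based hypothesis tests on distance matrices and rank data.

All random-permutation p-values use the add-one convention
p = (b + 1)/(m + 1), so the smallest reportable p at 999 permutations is
0.001 and p is never 0. Passing ``permutations="exhaustive"`` enumerates
every relabelling (feasible for n <= ~8) and reports the exact fraction,
identity included.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DistanceMatrix, ValidationError
from .ordination import pcoa_embedding

__all__ = [
    "PermutationTestResult",
    "kruskal_multi",
    "spearman_screen",
    "mantel",
    "permanova",
    "anosim",
    "mrpp",
    "permdisp",
]


@dataclass
class PermutationTestResult:
    """Statistic, permutation p-value and bookkeeping for one test."""

    test: str
    statistic_name: str
    statistic: float
    p_value: Optional[float]
    n_permutations: Optional[int]
    seed: Optional[int]
    extras: dict = field(default_factory=dict)

    def __repr__(self) -> str:
        return (
            f"PermutationTestResult({self.test}: {self.statistic_name}="
            f"{self.statistic:.4g}, p={self.p_value})"
        )


def _as_labels(groups: Sequence) -> np.ndarray:
    return np.asarray([str(g) for g in groups])


def _group_onehot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
    uniq = sorted(set(labels))
    onehot = np.stack([(labels == g).astype(float) for g in uniq], axis=1)
    sizes = onehot.sum(axis=0)
    return onehot, sizes, uniq


def _perm_iter(n: int, n_permutations, rng: np.random.Generator):
    """Yield (is_exhaustive, iterator of index permutations)."""
    if n_permutations == "exhaustive":
        return True, itertools.permutations(range(n))
    return False, (rng.permutation(n) for _ in range(int(n_permutations)))


def _finish_p(exceed: int, count: int, exhaustive: bool) -> float:
    if exhaustive:
        return exceed / count
    return (exceed + 1) / (count + 1)


# ---------------------------------------------------------------------------
# Kruskal-Wallis with multiple comparisons
# ---------------------------------------------------------------------------

def _kw_h(ranks: np.ndarray, labels: np.ndarray, tie_correction: float) -> float:
    n = len(ranks)
    h = 0.0
    for g in set(labels):
        r = ranks[labels == g]
        h += len(r) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    return h / tie_correction if tie_correction > 0 else 0.0


def kruskal_multi(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
    method: str = "asymptotic",
) -> PermutationTestResult:
    """Tie-corrected Kruskal-Wallis H with rank-based multiple comparisons.

    The pairwise procedure compares mean-rank differences against a normal
    critical difference with a Bonferroni adjustment across pairs. With
    ``method='exact'`` the global p enumerates all distinct assignments of
    the pooled ranks to groups.
    """
    values = np.asarray(values, dtype=float)
    labels = _as_labels(groups)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = {g: int((labels == g).sum()) for g in uniq}
    if min(sizes.values()) < 2:
        small = [g for g, s in sizes.items() if s < 2]
        raise ValidationError(f"groups with < 2 samples: {small}")
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if tie_correction <= 0:  # every observation identical
        h, p = 0.0, 1.0
    else:
        h = _kw_h(ranks, labels, tie_correction)
        df = len(uniq) - 1
        if method == "exact":
            # enumerate index partitions into the observed group sizes
            count = exceed = 0
            group_order = uniq
            def recurse(remaining, gi, assignment):
                nonlocal count, exceed
                if gi == len(group_order) - 1:
                    assignment = assignment + [tuple(remaining)]
                    lab = np.empty(n, dtype=object)
                    for g, idxs in zip(group_order, assignment):
                        for i in idxs:
                            lab[i] = g
                    hp = _kw_h(ranks, lab.astype(str), tie_correction)
                    count += 1
                    if hp >= h - 1e-12:
                        exceed += 1
                    return
                g = group_order[gi]
                for combo in itertools.combinations(remaining, sizes[g]):
                    rest = tuple(i for i in remaining if i not in set(combo))
                    recurse(rest, gi + 1, assignment + [list(combo)])
            recurse(tuple(range(n)), 0, [])
            p = exceed / count
        else:
            p = float(stats.chi2.sf(h, df))
    # pairwise critical-difference comparisons on mean ranks
    mean_ranks = {g: float(ranks[labels == g].mean()) for g in uniq}
    npairs = len(uniq) * (len(uniq) - 1) // 2
    pair_p = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    sig = pd.DataFrame(False, index=uniq, columns=uniq)
    for g1, g2 in itertools.combinations(uniq, 2):
        se = math.sqrt(tie_correction * n * (n + 1) / 12.0 * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = abs(mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        praw = 2.0 * stats.norm.sf(z)
        padj = min(1.0, praw * npairs)
        pair_p.loc[g1, g2] = pair_p.loc[g2, g1] = padj
        s = padj <= alpha
        sig.loc[g1, g2] = sig.loc[g2, g1] = bool(s)
    return PermutationTestResult(
        test="kruskal_wallis",
        statistic_name="H",
        statistic=float(h),
        p_value=float(p),
        n_permutations=None,
        seed=None,
        extras={
            "pairwise_p": pair_p,
            "pairwise_significant": sig,
            "mean_ranks": mean_ranks,
            "method": method,
        },
    )


def spearman_screen(x: pd.DataFrame, y: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and t-approximation p for every x-column / y-column
    pair; constant columns yield NaN (flagged, not an error)."""
    if len(x) != len(y):
        raise ValidationError("x and y must have the same number of rows")
    if len(x) < 4:
        raise ValidationError("need at least 4 paired observations")
    rho = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    pval = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    for cx in x.columns:
        xv = np.asarray(x[cx], dtype=float)
        if np.all(xv == xv[0]):
            continue
        for cy in y.columns:
            yv = np.asarray(y[cy], dtype=float)
            if np.all(yv == yv[0]):
                continue
            r, p = stats.spearmanr(xv, yv)
            rho.loc[cx, cy] = r
            pval.loc[cx, cy] = p
    return rho, pval


# ---------------------------------------------------------------------------
# Mantel / partial Mantel
# ---------------------------------------------------------------------------

def _condensed(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    den = math.sqrt((u @ u) * (v @ v))
    return float(u @ v / den) if den > 0 else np.nan


def _residualize(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ coef


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    conditioning: Optional[DistanceMatrix] = None,
    method: str = "pearson",
    n_permutations: Union[int, str] = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """(Partial) Mantel test: correlation of off-diagonal entries, p by
    jointly permuting rows and columns of ``a``. The partial variant removes
    the conditioning matrix from both ``a`` and ``b`` by linear fit
    (equivalently the first-order partial correlation)."""
    if a.ids != b.ids or (conditioning is not None and conditioning.ids != a.ids):
        raise ValidationError("mantel matrices must share ids in the same order")
    n = a.n

    def flat(m: np.ndarray) -> np.ndarray:
        v = _condensed(m)
        return stats.rankdata(v) if method == "spearman" else v

    if method == "spearman":
        # the condensed multiset is permutation-invariant, so pre-rank once
        # and store ranks in square form
        from scipy.spatial.distance import squareform

        amat = squareform(stats.rankdata(_condensed(a.values)))
    else:
        amat = a.values
    bv = flat(b.values)
    cv = flat(conditioning.values) if conditioning is not None else None
    resid_b = _residualize(bv, cv) if cv is not None else None

    def statistic(perm) -> float:
        av = _condensed(amat[np.ix_(perm, perm)]) if perm is not None else _condensed(amat)
        if cv is None:
            return _pearson(av, bv)
        resid_a = _residualize(av, cv)
        if resid_a.std() <= 1e-12 or resid_b.std() <= 1e-12:
            return 0.0  # a residual carries no variation left to correlate
        return _pearson(resid_a, resid_b)

    r_obs = statistic(None)
    rng = np.random.default_rng(seed)
    exhaustive, perms = _perm_iter(n, n_permutations, rng)
    exceed = count = 0
    for perm in perms:
        count += 1
        if statistic(np.asarray(perm)) >= r_obs - 1e-12:
            exceed += 1
    p = _finish_p(exceed, count, exhaustive)
    return PermutationTestResult(
        test="partial_mantel" if conditioning is not None else "mantel",
        statistic_name="r",
        statistic=float(r_obs),
        p_value=p,
        n_permutations=count,
        seed=seed,
        extras={"method": method, "exhaustive": exhaustive},
    )


# ---------------------------------------------------------------------------
# PERMANOVA / ANOSIM / MRPP
# ---------------------------------------------------------------------------

def _permanova_f(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> tuple[float, float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    within = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / 2.0
    ss_within = (within / sizes).sum()
    ss_between = ss_total - ss_within
    a = len(sizes)
    if ss_within <= 0:
        return np.nan, ss_between, ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between, ss_within


def permanova(
    d: DistanceMatrix,
    groups: Sequence,
    n_permutations: Union[int, str] = 999,
    seed: int = 0,
    allow_singletons: bool = False,
) -> PermutationTestResult:
    """PERMANOVA (Adonis): pseudo-F from squared distances,
    F = (SSB/(a-1)) / (SSW/(N-a)), p by permuting group labels."""
    labels = _as_labels(groups)
    onehot, sizes, uniq = _group_onehot(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if sizes.min() < 2 and not allow_singletons:
        raise ValidationError("singleton group (pass allow_singletons=True to permit)")
    n = d.n
    d2 = d.values**2
    f_obs, ssb, ssw = _permanova_f(d2, onehot, sizes)
    if not np.isfinite(f_obs) and ssb <= 1e-12:
        return PermutationTestResult(
            test="permanova", statistic_name="pseudo-F", statistic=np.nan,
            p_value=None, n_permutations=None, seed=seed,
            extras={"degenerate": True},
        )
    rng = np.random.default_rng(seed)
    exhaustive, perms = _perm_iter(n, n_permutations, rng)
    exceed = count = 0
    for perm in perms:
        count += 1
        oh = onehot[np.asarray(perm)]
        fp, _, _ = _permanova_f(d2, oh, sizes)
        if np.isnan(fp):
            fp = np.inf  # zero within-group variance under permutation
        if fp >= f_obs - 1e-12:
            exceed += 1
    p = _finish_p(exceed, count, exhaustive)
    return PermutationTestResult(
        test="permanova", statistic_name="pseudo-F", statistic=float(f_obs),
        p_value=p, n_permutations=count, seed=seed,
        extras={"ss_between": ssb, "ss_within": ssw, "exhaustive": exhaustive},
    )


def anosim(
    d: DistanceMatrix,
    groups: Sequence,
    n_permutations: Union[int, str] = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """ANOSIM R = (mean between-group rank - mean within-group rank) /
    (n(n-1)/4), p by label permutation."""
    labels = _as_labels(groups)
    if len(set(labels)) < 2:
        raise ValidationError("need at least 2 groups")
    n = d.n
    ranks = stats.rankdata(_condensed(d.values))
    iu = np.triu_indices(n, 1)
    denom = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        same = lab[iu[0]] == lab[iu[1]]
        if same.all() or not same.any():
            return np.nan
        return (ranks[~same].mean() - ranks[same].mean()) / denom

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    exhaustive, perms = _perm_iter(n, n_permutations, rng)
    exceed = count = 0
    for perm in perms:
        count += 1
        if r_stat(labels[np.asarray(perm)]) >= r_obs - 1e-12:
            exceed += 1
    p = _finish_p(exceed, count, exhaustive)
    return PermutationTestResult(
        test="anosim", statistic_name="R", statistic=float(r_obs),
        p_value=p, n_permutations=count, seed=seed,
        extras={"exhaustive": exhaustive},
    )


def mrpp(
    d: DistanceMatrix,
    groups: Sequence,
    n_permutations: Union[int, str] = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """MRPP: delta = sum_i (n_i/N) * mean within-group distance; chance-
    corrected A = 1 - delta/E[delta_perm]; p = fraction of permuted delta <=
    observed (small delta = tight groups)."""
    labels = _as_labels(groups)
    onehot, sizes, uniq = _group_onehot(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if sizes.min() < 2:
        raise ValidationError("MRPP requires every group size >= 2")
    n = d.n
    dv = d.values

    def delta(oh: np.ndarray) -> float:
        within = np.einsum("ig,ij,jg->g", oh, dv, oh) / 2.0
        npairs = sizes * (sizes - 1) / 2.0
        return float(((sizes / n) * (within / npairs)).sum())

    delta_obs = delta(onehot)
    rng = np.random.default_rng(seed)
    exhaustive, perms = _perm_iter(n, n_permutations, rng)
    deltas = []
    for perm in perms:
        deltas.append(delta(onehot[np.asarray(perm)]))
    deltas = np.asarray(deltas)
    exceed = int((deltas <= delta_obs + 1e-12).sum())
    p = _finish_p(exceed, len(deltas), exhaustive)
    expected = float(deltas.mean())
    a_stat = 1.0 - delta_obs / expected if expected > 0 else np.nan
    return PermutationTestResult(
        test="mrpp", statistic_name="delta", statistic=float(delta_obs),
        p_value=p, n_permutations=len(deltas), seed=seed,
        extras={"A": a_stat, "expected_delta": expected, "exhaustive": exhaustive,
                "null_deltas": deltas},
    )


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def centroid_distances(d: DistanceMatrix, groups: Sequence) -> np.ndarray:
    """Distance of each sample to its group centroid in the corrected PCoA
    embedding (real-axis part minus imaginary-axis part, per the standard
    multivariate-dispersion construction)."""
    labels = _as_labels(groups)
    real, imag, _ = pcoa_embedding(d)
    z = np.empty(d.n)
    for g in set(labels):
        idx = np.where(labels == g)[0]
        rc = real[idx].mean(axis=0)
        ic = imag[idx].mean(axis=0) if imag.size else None
        d2 = ((real[idx] - rc) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[idx] - ic) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    uniq = sorted(set(labels))
    n = len(values)
    grand = values.mean()
    ssb = sum(((values[labels == g].mean() - grand) ** 2) * (labels == g).sum() for g in uniq)
    ssw = sum(((values[labels == g] - values[labels == g].mean()) ** 2).sum() for g in uniq)
    dfb, dfw = len(uniq) - 1, n - len(uniq)
    if ssw <= 0:
        return np.inf if ssb > 0 else np.nan
    return (ssb / dfb) / (ssw / dfw)


def permdisp(
    d: DistanceMatrix,
    groups: Sequence,
    n_permutations: Union[int, str] = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions: one-way F on the distances
    to group centroids, p by permuting those distances across groups (the
    residuals under the common-dispersion null)."""
    labels = _as_labels(groups)
    uniq = sorted(set(labels))
    z = centroid_distances(d, labels)
    group_means = {g: float(z[labels == g].mean()) for g in uniq}
    if len(uniq) < 2:
        return PermutationTestResult(
            test="permdisp", statistic_name="F", statistic=np.nan,
            p_value=None, n_permutations=None, seed=seed,
            extras={"centroid_distances": z, "group_mean_distance": group_means,
                    "descriptive_only": True},
        )
    f_obs = _anova_f(z, labels)
    rng = np.random.default_rng(seed)
    exhaustive, perms = _perm_iter(d.n, n_permutations, rng)
    exceed = count = 0
    for perm in perms:
        count += 1
        fp = _anova_f(z[np.asarray(perm)], labels)
        if np.isnan(fp):
            fp = 0.0
        if fp >= f_obs - 1e-12:
            exceed += 1
    p = _finish_p(exceed, count, exhaustive)
    singleton = [g for g in uniq if (labels == g).sum() == 1]
    return PermutationTestResult(
        test="permdisp", statistic_name="F", statistic=float(f_obs),
        p_value=p, n_permutations=count, seed=seed,
        extras={"centroid_distances": z, "group_mean_distance": group_means,
                "singleton_groups": singleton, "exhaustive": exhaustive},
    )
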