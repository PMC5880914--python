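"""Ordination and variation partitioning.

PCoA is the shared kernel: dbRDA regresses the positive-eigenvalue principal
coordinates on predictors, PCNM eigendecomposes a truncated geographic
distance matrix, and PERMDISP (in :mod:`permtests`) reuses the embedding
with its negative-eigenvalue correction. Variation partitioning decomposes
the adjusted R-squared of a dbRDA into pure environmental [a], spatially
structured environmental [b], pure spatial [c], and residual [d] fractions.

Null-model deviation matrices (z-scores, possibly negative) are admitted to
dbRDA after the shift d'_ij = z_max - z_ij (larger deviation similarity =
smaller distance); the shift is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.isotonic import isotonic_regression

from .containers import DistanceMatrix, ValidationError

__all__ = [
    "OrdinationResult",
    "PcnmBasis",
    "VariationPartition",
    "BootstrapFractionTest",
    "pcoa",
    "pcoa_embedding",
    "nmds",
    "cca",
    "dbrda",
    "pcnm",
    "adjusted_r2",
    "forward_select",
    "variation_partition",
    "bootstrap_fraction_test",
]

_EIG_TOL = 1e-10


@dataclass
class OrdinationResult:
    """Scores and fit statistics for one ordination."""

    method: str
    sample_ids: list[str]
    scores: np.ndarray  # samples x axes
    axis_labels: list[str]
    eigenvalues: Optional[np.ndarray] = None
    stress: Optional[float] = None
    total_inertia: Optional[float] = None
    constrained_inertia: Optional[float] = None
    r2: Optional[float] = None
    adj_r2: Optional[float] = None
    pseudo_f: Optional[float] = None
    p_value: Optional[float] = None
    n_permutations: Optional[int] = None
    seed: Optional[int] = None
    details: dict = field(default_factory=dict)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.axis_labels)


@dataclass
class PcnmBasis:
    """Positive-eigenvalue spatial eigenvectors of the truncated geographic
    distance matrix; eigenvectors are orthonormal."""

    sample_ids: list[str]
    eigenvectors: np.ndarray  # samples x k
    eigenvalues: np.ndarray
    truncation_km: float

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PCNM{i + 1}" for i in range(self.eigenvectors.shape[1])]
        return pd.DataFrame(self.eigenvectors, index=self.sample_ids, columns=cols)


def _gower_center(d_values: np.ndarray) -> np.ndarray:
    a = -0.5 * d_values**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _eig_sorted(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (metric scaling).

    Eigendecomposition of the double-centered -0.5 D^2 matrix; axes are
    returned for positive eigenvalues, negative eigenvalues are reported.
    """
    if d.kind == "similarity":
        raise ValidationError("pcoa expects a dissimilarity (or deviation) matrix")
    vals, vecs = _eig_sorted(_gower_center(d.values))
    scale = max(abs(vals[0]), abs(vals[-1]), 1.0)
    pos = vals > _EIG_TOL * scale
    scores = vecs[:, pos] * np.sqrt(vals[pos])
    return OrdinationResult(
        method="pcoa",
        sample_ids=list(d.ids),
        scores=scores,
        axis_labels=[f"PCo{i + 1}" for i in range(scores.shape[1])],
        eigenvalues=vals,
        total_inertia=float(vals[pos].sum()),
        details={"negative_inertia": float(vals[vals < 0].sum())},
    )


def pcoa_embedding(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCoA coordinates split into real axes (positive eigenvalues) and
    imaginary axes (negative eigenvalues, scaled by sqrt(-lambda)); used by
    the PERMDISP centroid-distance correction."""
    vals, vecs = _eig_sorted(_gower_center(d.values))
    scale = max(abs(vals).max(), 1.0)
    pos = vals > _EIG_TOL * scale
    neg = vals < -_EIG_TOL * scale
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag, vals


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _nmds_stress_and_disparities(d_flat, config_d, order):
    disp = np.empty_like(config_d)
    disp[order] = isotonic_regression(config_d[order])
    ss_d = (config_d**2).sum()
    if ss_d <= 0:
        return np.inf, disp
    stress = np.sqrt(((config_d - disp) ** 2).sum() / ss_d)
    return stress, disp


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling minimising Kruskal stress-1.

    Monotone (isotonic) regression with primary tie treatment supplies the
    disparities; configurations are improved by Guttman/SMACOF updates from
    ``n_starts`` random starts plus one PCoA start, keeping the best. The
    returned configuration is centered, PCA-rotated, and scaled to unit RMS.
    """
    n = d.n
    if k >= n:
        raise ValidationError("k must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    d_flat = d.values[iu]

    starts = []
    try:
        p = pcoa(d)
        if p.scores.shape[1] >= k:
            starts.append(p.scores[:, :k].copy())
    except Exception:
        pass
    for _ in range(n_starts):
        starts.append(rng.standard_normal((n, k)))

    best_stress, best_x = np.inf, None
    for x0 in starts:
        x = x0 - x0.mean(axis=0)
        prev_stress = np.inf
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
            config_d = dist[iu]
            # primary tie handling: within tied dissimilarities, order by
            # current configuration distance so ties impose no constraint
            order = np.lexsort((config_d, d_flat))
            stress, disp = _nmds_stress_and_disparities(d_flat, config_d, order)
            if abs(prev_stress - stress) < tol:
                break
            prev_stress = stress
            # Guttman transform toward the disparities
            full_disp = np.zeros((n, n))
            full_disp[iu] = disp
            full_disp += full_disp.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, full_disp / dist, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = b @ x / n
            x -= x.mean(axis=0)
        if stress < best_stress:
            best_stress, best_x = stress, x
    # deterministic orientation: principal axes, unit RMS scale
    u, s, vt = np.linalg.svd(best_x - best_x.mean(axis=0), full_matrices=False)
    x = u * s
    rms = np.sqrt((x**2).sum() / n)
    if rms > 0:
        x /= rms
    return OrdinationResult(
        method="nmds",
        sample_ids=list(d.ids),
        scores=x,
        axis_labels=[f"NMDS{i + 1}" for i in range(k)],
        stress=float(best_stress),
        seed=seed,
        details={"n_starts": n_starts},
    )


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

def _design_matrix(predictors: pd.DataFrame, weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Standardized (optionally row-weighted) design matrix; categorical
    columns are dummy-coded; constant columns raise."""
    x = pd.get_dummies(predictors, drop_first=True).astype(float).to_numpy()
    n = x.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else weights / weights.sum()
    mean = w @ x
    xc = x - mean
    var = w @ xc**2
    if np.any(var <= 1e-12):
        bad = [predictors.columns[i] if i < len(predictors.columns) else i for i in np.where(var <= 1e-12)[0]]
        raise ValidationError(f"constant predictor column(s): {bad}")
    return xc / np.sqrt(var)


def cca(table_counts, predictors: pd.DataFrame) -> OrdinationResult:
    """Canonical correspondence analysis.

    The chi-square standardized response is regressed on row-weighted
    standardized predictors; the eigen-decomposition of the fitted values
    gives the constrained axes. Total inertia equals the table's chi-square
    statistic divided by its grand total.
    """
    from .containers import OtuTable

    if isinstance(table_counts, OtuTable):
        y = table_counts.counts.astype(float)
        ids = table_counts.sample_ids
    else:
        y = np.asarray(table_counts, dtype=float)
        ids = [f"s{i}" for i in range(y.shape[0])]
    if np.any(y < 0):
        raise ValidationError("CCA requires non-negative data")
    grand = y.sum()
    if grand <= 0:
        raise ValidationError("empty table")
    p = y / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValidationError("CCA requires positive row and column sums")
    expected = np.outer(r, c)
    qbar = (p - expected) / np.sqrt(expected)
    total_inertia = float((qbar**2).sum())

    x = _design_matrix(predictors.loc[ids] if set(ids) <= set(predictors.index) else predictors, weights=r)
    xw = x * np.sqrt(r)[:, None]
    q, _ = np.linalg.qr(xw)
    fitted = q @ (q.T @ qbar)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2
    keep = eig > _EIG_TOL * max(eig.max(initial=0.0), 1.0)
    eig = eig[keep]
    scores = (u[:, keep] * s[keep]) / np.sqrt(r)[:, None]
    return OrdinationResult(
        method="cca",
        sample_ids=list(ids),
        scores=scores,
        axis_labels=[f"CCA{i + 1}" for i in range(scores.shape[1])],
        eigenvalues=eig,
        total_inertia=total_inertia,
        constrained_inertia=float(eig.sum()),
        r2=float(eig.sum() / total_inertia) if total_inertia > 0 else np.nan,
    )


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

def _deviation_to_dissimilarity(d: DistanceMatrix) -> tuple[DistanceMatrix, float]:
    shift = float(np.max(d.values))
    vals = shift - d.values
    np.fill_diagonal(vals, 0.0)
    vals = np.maximum(vals, 0.0)
    return DistanceMatrix(d.ids, vals, kind="dissimilarity"), shift


def _pcoa_response(d: DistanceMatrix) -> tuple[np.ndarray, float, Optional[float]]:
    """(Y, total inertia, shift) for dbRDA; deviation matrices are shifted
    to dissimilarities first."""
    shift = None
    if d.kind == "deviation":
        d, shift = _deviation_to_dissimilarity(d)
    elif d.kind == "similarity":
        raise ValidationError("dbrda expects a dissimilarity or deviation matrix")
    res = pcoa(d)
    y = res.scores
    return y, float(res.total_inertia), shift


def dbrda(
    d: DistanceMatrix,
    predictors: pd.DataFrame,
    n_permutations: int = 0,
    seed: int = 0,
) -> OrdinationResult:
    """Distance-based redundancy analysis: regress the positive-eigenvalue
    PCoA axes on the predictors. R^2 = constrained / total inertia; a
    permutation pseudo-F test is run when ``n_permutations`` > 0."""
    n = d.n
    y, total, shift = _pcoa_response(d)
    x = _design_matrix(predictors)
    m = np.linalg.matrix_rank(x)
    if x.shape[1] > n - 1:
        raise ValidationError("more predictors than samples - 1")
    q, _ = np.linalg.qr(x)
    q = q[:, :m]
    proj = q.T @ y
    ss_fit = float((proj**2).sum())
    r2 = ss_fit / total if total > 0 else np.nan
    resid_df = n - 1 - m
    f_obs = (ss_fit / m) / ((total - ss_fit) / resid_df) if resid_df > 0 else np.nan
    fitted = q @ proj
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2
    keep = eig > _EIG_TOL * max(eig.max(initial=0.0), 1.0)
    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            ssp = float(((q.T @ y[perm]) ** 2).sum())
            fp = (ssp / m) / ((total - ssp) / resid_df)
            if fp >= f_obs:
                exceed += 1
        p_value = (exceed + 1) / (n_permutations + 1)
    adj = adjusted_r2(r2, n, m) if n > m + 1 else np.nan
    return OrdinationResult(
        method="dbrda",
        sample_ids=list(d.ids),
        scores=u[:, keep] * s[keep],
        axis_labels=[f"dbRDA{i + 1}" for i in range(int(keep.sum()))],
        eigenvalues=eig[keep],
        total_inertia=total,
        constrained_inertia=ss_fit,
        r2=float(r2),
        adj_r2=float(adj),
        pseudo_f=float(f_obs) if np.isfinite(f_obs) else np.nan,
        p_value=p_value,
        n_permutations=n_permutations or None,
        seed=seed,
        details={"deviation_shift": shift, "rank": int(m)},
    )


# ---------------------------------------------------------------------------
# PCNM
# ---------------------------------------------------------------------------

def pcnm(geo_km: DistanceMatrix) -> PcnmBasis:
    """Principal coordinates of neighbour matrices.

    The truncation threshold t is the longest edge of the minimum spanning
    tree of the locations; distances above t are replaced by 4t, and the
    eigenvectors of the PCoA of the truncated matrix with positive
    eigenvalues form the spatial basis.
    """
    n = geo_km.n
    if n < 3:
        raise ValidationError("pcnm needs at least 3 locations")
    dvals = geo_km.values
    dmax = dvals.max()
    if dmax <= 0:
        raise ValidationError("all locations identical")
    # epsilon keeps zero-distance (duplicated) locations as real MST edges
    eps = dmax * 1e-9
    w = dvals + eps
    np.fill_diagonal(w, 0.0)
    mst = minimum_spanning_tree(csr_matrix(w))
    t = float(mst.data.max() - eps)
    trunc = np.where(dvals > t * (1 + 1e-12), 4.0 * t, dvals)
    np.fill_diagonal(trunc, 0.0)
    vals, vecs = _eig_sorted(_gower_center(trunc))
    pos = vals > _EIG_TOL * max(abs(vals).max(), 1.0)
    return PcnmBasis(
        sample_ids=list(geo_km.ids),
        eigenvectors=vecs[:, pos],
        eigenvalues=vals[pos],
        truncation_km=t,
    )


# ---------------------------------------------------------------------------
# Adjusted R2, forward selection, variation partitioning
# ---------------------------------------------------------------------------

def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValidationError("adjusted_r2 requires n > p + 1")
    if p == 0:
        return float(r2)
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def _fit_ss(q: np.ndarray, y: np.ndarray) -> float:
    return float(((q.T @ y) ** 2).sum())


def _qr_of(predictors: pd.DataFrame, cols: Sequence[str]) -> tuple[np.ndarray, int]:
    x = _design_matrix(predictors[list(cols)])
    m = np.linalg.matrix_rank(x)
    q, _ = np.linalg.qr(x)
    return q[:, :m], m


def forward_select(
    d: DistanceMatrix,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
    fallback_best: bool = False,
) -> list[str]:
    """Double-stopping forward selection on dbRDA.

    A global pre-test on the full model gates the whole procedure. At each
    step the candidate giving the largest adjusted-R^2 model is admitted only
    if its marginal permutation p <= alpha AND the cumulative adjusted R^2
    does not exceed the full-model adjusted R^2.

    With strongly collinear candidates the adjusted-R^2 cap can reject even
    the first variable (one predictor alone may exceed the global model's
    adjusted R^2, which redundant extra predictors drag down).
    ``fallback_best=True`` then retains the single best candidate provided
    its own permutation test is significant, so a block whose global model
    is significant never comes back empty.
    """
    if candidates.shape[1] < 1:
        raise ValidationError("need at least one candidate")
    # one independent permutation stream per selection step (stream 0 is the
    # global pre-test) so the procedure is reproducible step by step
    def step_rng(step: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(seed), int(step)]))

    n = d.n
    y, total, _ = _pcoa_response(d)
    cols = list(candidates.columns)

    q_full, m_full = _qr_of(candidates, cols)
    ss_full = _fit_ss(q_full, y)
    r2_full = ss_full / total
    if n <= m_full + 1:
        raise ValidationError("too many candidates for the sample size")
    adj_full = adjusted_r2(r2_full, n, m_full)
    # global pre-test
    f_obs = (ss_full / m_full) / ((total - ss_full) / (n - 1 - m_full))
    exceed = 0
    rng = step_rng(0)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        ssp = _fit_ss(q_full, y[perm])
        if (ssp / m_full) / ((total - ssp) / (n - 1 - m_full)) >= f_obs:
            exceed += 1
    if (exceed + 1) / (n_permutations + 1) > alpha:
        return []

    selected: list[str] = []
    ss_sel, m_sel = 0.0, 0
    remaining = list(cols)
    step = 0
    while remaining:
        step += 1
        best = None
        for cand in remaining:
            q_c, m_c = _qr_of(candidates, selected + [cand])
            ss_c = _fit_ss(q_c, y)
            adj_c = adjusted_r2(ss_c / total, n, m_c)
            if best is None or adj_c > best[1]:
                best = (cand, adj_c, q_c, m_c, ss_c)
        cand, adj_c, q_c, m_c, ss_c = best
        if adj_c > adj_full + 1e-12:
            break
        df_num = m_c - m_sel
        df_den = n - 1 - m_c
        if df_num <= 0 or df_den <= 0:
            break
        f_part = ((ss_c - ss_sel) / df_num) / ((total - ss_c) / df_den)
        if selected:
            q_sel, _ = _qr_of(candidates, selected)
        else:
            q_sel = None
        exceed = 0
        rng = step_rng(step)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            yp = y[perm]
            ss_cp = _fit_ss(q_c, yp)
            ss_sp = _fit_ss(q_sel, yp) if q_sel is not None else 0.0
            fp = ((ss_cp - ss_sp) / df_num) / ((total - ss_cp) / df_den)
            if fp >= f_part:
                exceed += 1
        if (exceed + 1) / (n_permutations + 1) > alpha:
            break
        selected.append(cand)
        remaining.remove(cand)
        ss_sel, m_sel = ss_c, m_c
    if not selected and fallback_best:
        best = None
        for cand in cols:
            q_c, m_c = _qr_of(candidates, [cand])
            ss_c = _fit_ss(q_c, y)
            adj_c = adjusted_r2(ss_c / total, n, m_c)
            if best is None or adj_c > best[1]:
                best = (cand, adj_c, q_c, m_c, ss_c)
        cand, _, q_c, m_c, ss_c = best
        df_den = n - 1 - m_c
        f_single = (ss_c / m_c) / ((total - ss_c) / df_den)
        rng = step_rng(1)
        exceed = 0
        for _ in range(n_permutations):
            ssp = _fit_ss(q_c, y[rng.permutation(n)])
            if (ssp / m_c) / ((total - ssp) / df_den) >= f_single:
                exceed += 1
        if (exceed + 1) / (n_permutations + 1) <= alpha:
            selected = [cand]
    return selected


@dataclass
class VariationPartition:
    """Adjusted-R^2 fractions: a (pure environmental), b (spatially
    structured environmental), c (pure spatial), d (residual)."""

    a: float
    b: float
    c: float
    d: float
    adj_r2_env: float
    adj_r2_space: float
    adj_r2_joint: float
    env_columns: list[str]
    space_columns: list[str]
    n: int

    def as_dict(self) -> dict:
        return {
            "pure_env": self.a,
            "shared": self.b,
            "pure_space": self.c,
            "residual": self.d,
        }


def variation_partition(
    d: DistanceMatrix,
    env: Optional[pd.DataFrame],
    space: Optional[pd.DataFrame],
) -> VariationPartition:
    """Four-fraction partition from three dbRDA fits (env, space, joint).

    a + b = adjR^2(env); b + c = adjR^2(space); a + b + c = adjR^2(joint);
    d = 1 - (a + b + c). An empty predictor block contributes 0.
    """
    n = d.n
    y, total, _ = _pcoa_response(d)

    def block_fit(x_df: Optional[pd.DataFrame]) -> tuple[float, int]:
        if x_df is None or x_df.shape[1] == 0:
            return 0.0, 0
        q, m = _qr_of(x_df, list(x_df.columns))
        return _fit_ss(q, y) / total, m

    r2_env, m_env = block_fit(env)
    r2_space, m_space = block_fit(space)
    if (env is not None and env.shape[1] > 0) and (space is not None and space.shape[1] > 0):
        joint = pd.concat([env, space], axis=1)
    elif env is not None and env.shape[1] > 0:
        joint = env
    elif space is not None and space.shape[1] > 0:
        joint = space
    else:
        raise ValidationError("both predictor blocks are empty")
    r2_joint, m_joint = block_fit(joint)
    if m_joint >= n - 1:
        raise ValidationError("combined predictors >= n - 1")
    ab = adjusted_r2(r2_env, n, m_env)
    bc = adjusted_r2(r2_space, n, m_space)
    abc = adjusted_r2(r2_joint, n, m_joint)
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    dres = 1.0 - abc
    return VariationPartition(
        a=a, b=b, c=c, d=dres,
        adj_r2_env=ab, adj_r2_space=bc, adj_r2_joint=abc,
        env_columns=list(env.columns) if env is not None else [],
        space_columns=list(space.columns) if space is not None else [],
        n=n,
    )


@dataclass
class BootstrapFractionTest:
    """Two-sided bootstrap comparison of the pure fractions a and c."""

    p_value: float
    observed_diff: float
    a_distribution: np.ndarray
    c_distribution: np.ndarray
    n_bootstrap: int
    seed: int


def bootstrap_fraction_test(
    d: DistanceMatrix,
    env: pd.DataFrame,
    space: pd.DataFrame,
    n_bootstrap: int = 999,
    seed: int = 0,
    max_retries: int = 100,
) -> BootstrapFractionTest:
    """Resample samples with replacement, re-partition, and compare the pure
    environmental and pure spatial fractions: two-sided
    p = 2 * min(P(a - c <= 0), P(a - c >= 0)) over replicates."""
    n = d.n
    if n < 8:
        raise ValidationError("bootstrap_fraction_test needs >= 8 samples")
    rng = np.random.default_rng(seed)
    obs = variation_partition(d, env, space)
    m_total = env.shape[1] + space.shape[1]
    a_vals = np.empty(n_bootstrap)
    c_vals = np.empty(n_bootstrap)
    ids = np.array(d.ids)
    for b in range(n_bootstrap):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, n)
            if len(np.unique(idx)) < m_total + 3:
                continue
            sub_env = env.iloc[idx].reset_index(drop=True)
            sub_space = space.iloc[idx].reset_index(drop=True)
            if (sub_env.nunique() <= 1).any() or (sub_space.nunique() <= 1).any():
                continue
            vals = d.values[np.ix_(idx, idx)]
            sub_d = DistanceMatrix([f"b{i}" for i in range(n)], vals, kind=d.kind)
            try:
                part = variation_partition(sub_d, sub_env, sub_space)
            except (ValidationError, np.linalg.LinAlgError):
                continue
            a_vals[b], c_vals[b] = part.a, part.c
            break
        else:
            raise ValidationError("could not draw a non-degenerate bootstrap resample")
    diff = a_vals - c_vals
    p = 2.0 * min(float(np.mean(diff <= 0)), float(np.mean(diff >= 0)))
    return BootstrapFractionTest(
        p_value=min(p, 1.0),
        observed_diff=float(obs.a - obs.c),
        a_distribution=a_vals,
        c_distribution=c_vals,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
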