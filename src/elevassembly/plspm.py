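"""Partial least squares path modeling (PLS-PM).

Latent variables (e.g. climate, plant, soil, bacterial community) are
estimated as weighted composites of their manifest indicator blocks through
the classical iterative algorithm: reflective outer estimation (mode A) and
the path weighting scheme for the inner estimate. Path coefficients are the
OLS coefficients of each endogenous latent on its predecessors; overall
quality is the goodness-of-fit statistic
GOF = sqrt(mean communality x mean R^2).

Usage follows the model/results idiom::

    model = PathModel(paths={("climate", "plant"): True, ...},
                      blocks={"climate": ["MAT", "MAP"], ...})
    results = model.fit(data)
    print(results.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ValidationError

__all__ = ["PathModel", "PLSPMResults", "fit_plspm", "gof", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Outer-weight iteration failed to converge; carries the last delta."""

    def __init__(self, delta: float, max_iter: int):
        self.delta = delta
        super().__init__(
            f"PLS-PM did not converge in {max_iter} iterations "
            f"(last max weight change {delta:.3g})"
        )


def _topological_order(latents: Sequence[str], edges: list[tuple[str, str]]) -> list[str]:
    indeg = {l: 0 for l in latents}
    for _, tgt in edges:
        indeg[tgt] += 1
    order, ready = [], [l for l in latents if indeg[l] == 0]
    while ready:
        node = ready.pop(0)
        order.append(node)
        for src, tgt in edges:
            if src == node:
                indeg[tgt] -= 1
                if indeg[tgt] == 0:
                    ready.append(tgt)
    if len(order) != len(latents):
        raise ValidationError("inner path matrix is cyclic")
    return order


class PathModel:
    """Specification of a PLS path model.

    Parameters
    ----------
    paths : dict[(source, target)] or iterable of (source, target)
        Directed links between latent variables; must be acyclic.
    blocks : dict[latent, list of manifest column names]
        Non-empty indicator block per latent (reflective, mode A).
    """

    def __init__(self, paths, blocks: dict):
        if isinstance(paths, dict):
            edges = [e for e, keep in paths.items() if keep]
        else:
            edges = list(paths)
        self.edges = [(str(s), str(t)) for s, t in edges]
        self.blocks = {str(k): list(v) for k, v in blocks.items()}
        self.latents = list(self.blocks)
        for s, t in self.edges:
            if s not in self.blocks or t not in self.blocks:
                raise ValidationError(f"path ({s}, {t}) references an unknown latent")
        for l, cols in self.blocks.items():
            if not cols:
                raise ValidationError(f"block {l!r} is empty")
        self.order = _topological_order(self.latents, self.edges)
        linked = {s for s, _ in self.edges} | {t for _, t in self.edges}
        isolated = [l for l in self.latents if l not in linked]
        if isolated:
            raise ValidationError(f"latents without any path: {isolated}")

    def predecessors(self, latent: str) -> list[str]:
        return [s for s, t in self.edges if t == latent]

    def successors(self, latent: str) -> list[str]:
        return [t for s, t in self.edges if s == latent]

    @property
    def endogenous(self) -> list[str]:
        return [l for l in self.order if self.predecessors(l)]

    # ------------------------------------------------------------------
    def fit(
        self,
        data: pd.DataFrame,
        max_iter: int = 300,
        tol: float = 1e-7,
        n_bootstrap: int = 0,
        seed: int = 0,
    ) -> "PLSPMResults":
        """Estimate the model on ``data`` (rows = samples, columns include
        every manifest). Bootstrap resampling (``n_bootstrap`` > 0) yields
        standard errors and percentile CIs for the path coefficients."""
        all_cols = [c for cols in self.blocks.values() for c in cols]
        missing = [c for c in all_cols if c not in data.columns]
        if missing:
            raise ValidationError(f"data lacks manifest columns: {missing}")
        n = len(data)
        if n <= len(all_cols):
            raise ValidationError("need more samples than total manifests")
        x = data[all_cols].to_numpy(float)
        core = _pls_core(self, x, all_cols, max_iter, tol)

        boot_paths = None
        if n_bootstrap > 0:
            rng = np.random.default_rng(seed)
            records = []
            for _ in range(n_bootstrap):
                idx = rng.integers(0, n, n)
                xb = x[idx]
                if np.any(xb.std(axis=0) <= 1e-12):
                    continue
                try:
                    cb = _pls_core(self, xb, all_cols, max_iter, tol)
                except (ConvergenceError, ValidationError):
                    continue
                records.append(cb["paths"])
            boot_paths = pd.DataFrame(records) if records else None
        return PLSPMResults(model=self, n=n, seed=seed, _core=core, _boot=boot_paths)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd <= 1e-12):
        raise ValidationError("constant manifest column")
    return (x - x.mean(axis=0)) / sd


def _pls_core(model: PathModel, x: np.ndarray, cols: list[str], max_iter: int, tol: float) -> dict:
    n = x.shape[0]
    xs = _standardize(x)
    col_idx = {c: i for i, c in enumerate(cols)}
    block_idx = {l: np.array([col_idx[c] for c in model.blocks[l]]) for l in model.latents}
    for l, idx in block_idx.items():
        if len(idx) > 1:
            corr = np.corrcoef(xs[:, idx], rowvar=False)
            if np.linalg.matrix_rank(corr) < len(idx):
                warnings.warn(f"collinear manifest block {l!r}", stacklevel=3)

    weights = {l: np.ones(len(block_idx[l])) for l in model.latents}

    def scores_from(w):
        y = {}
        for l in model.latents:
            s = xs[:, block_idx[l]] @ w[l]
            y[l] = s / s.std()
        return y

    y = scores_from(weights)
    delta = np.inf
    for _ in range(max_iter):
        # inner estimate, path weighting scheme
        z = {}
        for l in model.latents:
            zl = np.zeros(n)
            preds = model.predecessors(l)
            succs = model.successors(l)
            if preds:
                yp = np.column_stack([y[p] for p in preds])
                coef, *_ = np.linalg.lstsq(yp, y[l], rcond=None)
                for p, c in zip(preds, coef):
                    zl += c * y[p]
            for s in succs:
                zl += np.corrcoef(y[l], y[s])[0, 1] * y[s]
            z[l] = zl
        # outer estimate, mode A: weights = cov(manifest, inner estimate)
        new_weights = {}
        delta = 0.0
        for l in model.latents:
            w = xs[:, block_idx[l]].T @ z[l] / n
            s = xs[:, block_idx[l]] @ w
            sd = s.std()
            if sd <= 1e-12:
                raise ValidationError(f"degenerate composite for latent {l!r}")
            w = w / sd  # unit-variance composite
            if w.sum() < 0:  # sign convention: block points with its indicators
                w = -w
            delta = max(delta, float(np.max(np.abs(w - weights[l]))))
            new_weights[l] = w
        weights = new_weights
        y = scores_from(weights)
        if delta < tol:
            break
    else:
        raise ConvergenceError(delta, max_iter)

    scores = pd.DataFrame({l: y[l] for l in model.latents})
    loadings = {}
    communalities = {}
    for l in model.latents:
        lo = np.array([np.corrcoef(xs[:, j], y[l])[0, 1] for j in block_idx[l]])
        loadings[l] = lo
        communalities[l] = lo**2
    paths = {}
    r2 = {}
    for l in model.endogenous:
        preds = model.predecessors(l)
        yp = np.column_stack([y[p] for p in preds])
        coef, *_ = np.linalg.lstsq(yp, y[l], rcond=None)
        fitted = yp @ coef
        r2[l] = float(np.var(fitted) / np.var(y[l]))
        for p, c in zip(preds, coef):
            paths[(p, l)] = float(c)
    return {
        "weights": weights,
        "scores": scores,
        "loadings": loadings,
        "communalities": communalities,
        "paths": paths,
        "r2": r2,
    }


@dataclass
class PLSPMResults:
    """Fitted PLS path model: scores, weights, loadings, paths, R^2, GOF."""

    model: PathModel
    n: int
    seed: int
    _core: dict
    _boot: Optional[pd.DataFrame] = None

    @property
    def scores(self) -> pd.DataFrame:
        return self._core["scores"]

    @property
    def outer_weights(self) -> dict:
        return self._core["weights"]

    @property
    def loadings(self) -> dict:
        return self._core["loadings"]

    @property
    def communalities(self) -> dict:
        return self._core["communalities"]

    @property
    def path_coefficients(self) -> dict:
        return self._core["paths"]

    @property
    def r2(self) -> dict:
        return self._core["r2"]

    @property
    def gof(self) -> float:
        return gof(self)

    def paths_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for (src, tgt), coef in self.path_coefficients.items():
            row = {"source": src, "target": tgt, "coef": coef}
            if self._boot is not None and (src, tgt) in self._boot.columns:
                samples = self._boot[(src, tgt)].dropna().to_numpy()
                row["boot_se"] = float(samples.std(ddof=1))
                lo, hi = np.quantile(samples, [alpha / 2, 1 - alpha / 2])
                row["ci_low"], row["ci_high"] = float(lo), float(hi)
                row["significant"] = bool(lo > 0 or hi < 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["PLS path model", f"  n = {self.n}, GOF = {self.gof:.4f}", "", "Paths:"]
        for _, row in self.paths_frame().iterrows():
            extra = ""
            if "boot_se" in row and not pd.isna(row.get("boot_se", np.nan)):
                extra = (f"  se={row['boot_se']:.3f} "
                         f"CI[{row['ci_low']:.3f}, {row['ci_high']:.3f}]"
                         f"{' *' if row['significant'] else ''}")
            lines.append(f"  {row['source']} -> {row['target']}: "
                         f"{row['coef']:+.4f}{extra}")
        lines.append("")
        lines.append("R^2 (endogenous latents):")
        for l, v in self.r2.items():
            lines.append(f"  {l}: {v:.4f}")
        return "\n".join(lines)


def fit_plspm(
    data: pd.DataFrame,
    model: PathModel,
    max_iter: int = 300,
    tol: float = 1e-7,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> PLSPMResults:
    """Functional alias for :meth:`PathModel.fit`."""
    return model.fit(data, max_iter=max_iter, tol=tol, n_bootstrap=n_bootstrap, seed=seed)


def gof(results: PLSPMResults) -> float:
    """Goodness of fit: sqrt(mean communality across all manifests x mean
    R^2 across endogenous latents). GOF > 0.7 is the conventional
    acceptability threshold."""
    if not results.model.endogenous:
        raise ValidationError("model has no endogenous latent")
    comms = np.concatenate([results.communalities[l] for l in results.model.latents])
    mean_r2 = np.mean([results.r2[l] for l in results.model.endogenous])
    return float(np.sqrt(comms.mean() * mean_r2))
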