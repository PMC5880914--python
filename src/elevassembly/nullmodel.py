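"""Species-pool null model, beta-deviation z-scores, and the observed-vs-
null dispersion comparison.

The randomization is the standard Raup-Crick-style assembly: the regional
species pool is every OTU observed across all samples; each null community
redraws a sample's species set at its observed richness, selecting species
with probability proportional to their occupancy frequency across samples
(uniform and abundance weightings are available). Null ensembles are lazy
and bit-for-bit reproducible: iteration ``i`` is a pure function of
(seed, i), so arbitrarily large ensembles never need to be materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, OtuTable, ValidationError
from .ordination import pcoa_embedding
from .permtests import PermutationTestResult, permdisp

__all__ = [
    "NullEnsemble",
    "BetaDeviationResult",
    "null_randomize",
    "beta_deviation",
    "null_permdisp_test",
]


@dataclass
class NullEnsemble:
    """Richness-preserving null communities over the regional pool."""

    sample_ids: list[str]
    otu_ids: list[str]
    richness: np.ndarray  # per-sample observed richness (conserved exactly)
    log_weights: np.ndarray  # -inf for species outside the pool
    weighting: str
    n_iterations: int
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def iteration(self, i: int) -> np.ndarray:
        """Presence/absence matrix (samples x OTUs) of null iteration ``i``.

        Weighted sampling without replacement via the Gumbel top-k trick:
        perturb log-weights with Gumbel noise and take the top ``richness``
        keys per sample.
        """
        if not 0 <= i < self.n_iterations:
            raise IndexError(f"iteration {i} outside [0, {self.n_iterations})")
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), int(i)]))
        gumbel = rng.gumbel(size=(self.n_samples, self.n_otus))
        keys = self.log_weights[None, :] + gumbel
        out = np.zeros((self.n_samples, self.n_otus), dtype=bool)
        for s in range(self.n_samples):
            k = int(self.richness[s])
            if k == 0:
                continue
            top = np.argpartition(keys[s], -k)[-k:]
            out[s, top] = True
        return out

    def iter_matrices(self, chunk_size: int = 64) -> Iterator[np.ndarray]:
        """Yield stacked presence matrices (chunk, samples, OTUs)."""
        for start in range(0, self.n_iterations, chunk_size):
            stop = min(start + chunk_size, self.n_iterations)
            yield np.stack([self.iteration(i) for i in range(start, stop)])


def null_randomize(
    table: OtuTable,
    n_iterations: int = 999,
    seed: int = 0,
    weighting: str = "occupancy",
) -> NullEnsemble:
    """Build the null ensemble for ``table``.

    ``weighting``: 'occupancy' (default; selection probability proportional
    to the number of samples a species occupies), 'uniform', or 'abundance'
    (proportional to total reads).
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    presence = table.presence()
    occupancy = presence.sum(axis=0).astype(float)
    pool = occupancy > 0
    pool_size = int(pool.sum())
    if pool_size == 0:
        raise ValidationError("empty regional species pool")
    richness = presence.sum(axis=1)
    if richness.max() > pool_size:
        raise ValidationError("a sample's richness exceeds the pool size")
    if weighting == "occupancy":
        w = occupancy
    elif weighting == "uniform":
        w = pool.astype(float)
    elif weighting == "abundance":
        w = table.counts.sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    with np.errstate(divide="ignore"):
        log_w = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    return NullEnsemble(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        richness=richness,
        log_weights=log_w,
        weighting=weighting,
        n_iterations=int(n_iterations),
        seed=int(seed),
    )


def _jaccard_similarity(presence: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity for one presence matrix (samples x OTUs)
    or a stack (iters x samples x OTUs)."""
    x = presence.astype(np.float32)
    if x.ndim == 2:
        inter = x @ x.T
        r = x.sum(axis=1)
        union = r[:, None] + r[None, :] - inter
    else:
        inter = x @ x.transpose(0, 2, 1)
        r = x.sum(axis=2)
        union = r[:, :, None] + r[:, None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / union, 0.0)
    return j.astype(np.float64)


@dataclass
class BetaDeviationResult:
    """Observed Jaccard similarity, null mean/SD, and z per sample pair."""

    sample_ids: list[str]
    j_obs: np.ndarray
    j_exp: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray  # NaN where null SD is 0
    n_undefined_pairs: int
    n_iterations: int
    seed: int

    def deviation_matrix(self, fill: Optional[float] = 0.0) -> DistanceMatrix:
        """z-scores as a DistanceMatrix of kind 'deviation'; undefined pairs
        are filled with ``fill`` (at the null expectation) unless None."""
        z = self.z.copy()
        if fill is not None:
            z = np.where(np.isnan(z), fill, z)
        np.fill_diagonal(z, 0.0)
        return DistanceMatrix(self.sample_ids, z, kind="deviation")

    def mean_z(self) -> float:
        iu = np.triu_indices(len(self.sample_ids), 1)
        vals = self.z[iu]
        return float(np.nanmean(vals))


def beta_deviation(table: OtuTable, ensemble: NullEnsemble) -> BetaDeviationResult:
    """z = (J_obs - mean J_null) / sd J_null per sample pair, streaming over
    the ensemble (one shared ensemble for all pairs)."""
    if ensemble.sample_ids != table.sample_ids or ensemble.otu_ids != table.otu_ids:
        raise ValidationError("ensemble was not built from this table")
    j_obs = _jaccard_similarity(table.presence())
    n = table.n_samples
    total = np.zeros((n, n))
    total_sq = np.zeros((n, n))
    for block in ensemble.iter_matrices():
        j = _jaccard_similarity(block)
        total += j.sum(axis=0)
        total_sq += (j**2).sum(axis=0)
    m = ensemble.n_iterations
    mean = total / m
    if m > 1:
        var = np.maximum((total_sq - m * mean**2) / (m - 1), 0.0)
    else:
        var = np.zeros_like(mean)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (j_obs - mean) / sd, np.nan)
    np.fill_diagonal(z, 0.0)
    iu = np.triu_indices(n, 1)
    n_undef = int(np.isnan(z[iu]).sum())
    return BetaDeviationResult(
        sample_ids=list(table.sample_ids),
        j_obs=j_obs,
        j_exp=mean,
        null_sd=sd,
        z=z,
        n_undefined_pairs=n_undef,
        n_iterations=m,
        seed=ensemble.seed,
    )


def null_permdisp_test(
    table: OtuTable,
    ensemble: NullEnsemble,
    group_ids: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Observed-vs-null dispersion per group (typically per elevational site).

    For each group, a size-matched set of null communities (each member's
    null counterpart from an independently chosen ensemble iteration) joins
    the observed members; Jaccard distances among all of them feed a
    PERMDISP-style comparison of observed vs null distance-to-centroid.
    Because each null community is paired with one observed member (same
    sample, hence the same richness), significance comes from a paired
    permutation: each observed/null pair's labels are flipped at random and
    the centroid distances and F recomputed, which keeps the test exact
    under exchangeability within pairs. Columns: observed_centroid,
    null_centroid, F, p_value, n_samples.
    """
    if ensemble.sample_ids != table.sample_ids:
        raise ValidationError("ensemble was not built from this table")
    labels = np.asarray([str(g) for g in group_ids])
    if len(labels) != table.n_samples:
        raise ValidationError("group_ids length must match sample count")
    rng = np.random.default_rng(seed)
    presence = table.presence()
    rows = []
    for g in sorted(set(labels)):
        idx = np.where(labels == g)[0]
        if len(idx) < min_group_size:
            import logging

            logging.getLogger(__name__).warning(
                "group %s has < %d samples; skipped", g, min_group_size
            )
            continue
        m = len(idx)
        iters = rng.choice(ensemble.n_iterations, size=m, replace=False)
        null_rows = np.stack(
            [ensemble.iteration(int(it))[i] for it, i in zip(iters, idx)]
        )
        combined = np.vstack([presence[idx], null_rows])
        sim = _jaccard_similarity(combined)
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        ids = [f"obs_{k}" for k in range(m)] + [f"null_{k}" for k in range(m)]
        dm = DistanceMatrix(ids, dist, kind="dissimilarity")
        real, imag, _ = pcoa_embedding(dm)

        def group_stats(flips: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
            """F and per-group mean centroid distance for a flip pattern
            (flips[k] True swaps pair k's observed/null labels)."""
            obs_rows = np.where(flips, np.arange(m) + m, np.arange(m))
            null_rows_i = np.where(flips, np.arange(m), np.arange(m) + m)
            zs = []
            for members in (obs_rows, null_rows_i):
                rc = real[members].mean(axis=0)
                d2 = ((real[members] - rc) ** 2).sum(axis=1)
                if imag.size:
                    ic = imag[members].mean(axis=0)
                    d2 = d2 - ((imag[members] - ic) ** 2).sum(axis=1)
                zs.append(np.sqrt(np.maximum(d2, 0.0)))
            z_obs, z_null = zs
            grand = (z_obs.sum() + z_null.sum()) / (2 * m)
            ssb = m * ((z_obs.mean() - grand) ** 2 + (z_null.mean() - grand) ** 2)
            ssw = ((z_obs - z_obs.mean()) ** 2).sum() + ((z_null - z_null.mean()) ** 2).sum()
            f = np.inf if ssw <= 0 else (ssb / 1) / (ssw / (2 * m - 2))
            return f, z_obs, z_null

        f_obs, z_obs, z_null = group_stats(np.zeros(m, dtype=bool))
        exceed = 0
        for _ in range(n_permutations):
            fp, _, _ = group_stats(rng.random(m) < 0.5)
            if fp >= f_obs - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)
        rows.append(
            {
                "group": g,
                "observed_centroid": float(z_obs.mean()),
                "null_centroid": float(z_null.mean()),
                "F": float(f_obs),
                "p_value": p,
                "n_samples": m,
            }
        )
    return pd.DataFrame(rows).set_index("group")
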