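"""Synthetic elevational-gradient communities with known generating structure.

The generator emulates a mountain transect survey: ~100 topsoil samples from
12 sites between 1800 and 4100 m at roughly 200 m spacing, with soil pH
spanning 3.53-7.23 and dropping in a regime change between 2600 and 2800 m,
five elevation-banded vegetation types, and climate/soil/plant covariates
that co-vary with elevation. Communities assemble through three separable
channels — Gaussian pH filtering, multiplicative vegetation affinity, and an
exponential spatial kernel — so that the ground truth behind variation
partitioning and null-model tests is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .containers import OtuTable, SampleMetadata, ValidationError

__all__ = [
    "GradientScenario",
    "generate_metadata",
    "generate_community",
    "generate_tree",
    "generate_sem_dataset",
    "SemDataset",
    "haversine_km",
    "default_ph_profile",
    "default_vegetation_map",
]

EARTH_RADIUS_KM = 6371.0

#: the 12 site elevations of the emulated survey design (m)
DEFAULT_SITE_ELEVATIONS = (
    1800, 2000, 2200, 2400, 2600, 2800, 3000, 3200, 3600, 3800, 4000, 4100
)

PH_MIN, PH_MAX = 3.53, 7.23


def default_ph_profile(elevation: np.ndarray) -> np.ndarray:
    """Monotone decreasing pH over elevation with a step between 2600 and
    2800 m: ~7.2 -> 6.2 over the lower section, an abrupt drop across the
    gap, then 5.6 -> 3.53 over the higher section (pH 6 separates the
    sections)."""
    e = np.asarray(elevation, dtype=float)
    ph = np.empty_like(e)
    lo = e <= 2600
    mid = (e > 2600) & (e < 2800)
    hi = e >= 2800
    ph[lo] = PH_MAX - (e[lo] - 1800.0) / 800.0 * (PH_MAX - 6.2)
    ph[mid] = 6.2 - (e[mid] - 2600.0) / 200.0 * (6.2 - 5.6)
    ph[hi] = 5.6 - (e[hi] - 2800.0) / 1300.0 * (5.6 - PH_MIN)
    return ph


def default_vegetation_map(elevation: float) -> str:
    """Five elevation-banded vegetation types: broadleaf forests below the
    section break, then mixed forest, conifer forest, alpine shrub, meadow."""
    if elevation < 2700:
        return "broadleaf"
    if elevation < 2900:
        return "mixed_forest"
    if elevation < 3500:
        return "conifer"
    if elevation < 3900:
        return "alpine_shrub"
    return "alpine_meadow"


VEGETATION_TYPES = ("broadleaf", "mixed_forest", "conifer", "alpine_shrub", "alpine_meadow")


@dataclass
class GradientScenario:
    """Parameters of one synthetic transect.

    ``env_filter_strength`` is the Gaussian niche width sigma in pH units
    (smaller = stronger filtering; ``numpy.inf`` switches filtering off).
    ``spatial_decay_range`` is the e-folding distance (km) of the spatial
    kernel (``numpy.inf`` switches it off); ``vegetation_affinity_sd`` the
    log-sd of per-type OTU affinities (0 switches the channel off).
    """

    n_sites: int = 12
    samples_per_site: int = 8
    elevation_range: tuple[float, float] = (1800.0, 4100.0)
    n_otus: int = 1500
    ph_profile: Callable[[np.ndarray], np.ndarray] = default_ph_profile
    env_filter_strength: float = 0.5
    spatial_decay_range: float = 30.0
    vegetation_affinity_sd: float = 0.5
    abundance_lognormal_params: tuple[float, float] = (0.0, 1.5)
    vegetation_map: Callable[[float], str] = default_vegetation_map
    sequencing_depth: int = 10000
    depth_jitter: float = 0.0
    noise_sd: float = 1.0
    plot_scatter_km: float = 0.1
    section_extent_km: float = 7.0
    base_latitude: float = 29.57
    base_longitude: float = 102.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValidationError("n_sites must be >= 2")
        if self.env_filter_strength <= 0:
            raise ValidationError("env_filter_strength must be > 0")
        if self.sequencing_depth < 1:
            raise ValidationError("sequencing depth must be >= 1")
        lo, hi = self.elevation_range
        prof = self.ph_profile(np.linspace(lo, hi, 50))
        if np.any((prof <= 0) | (prof >= 14)):
            raise ValidationError("pH profile leaves (0, 14)")

    def site_elevations(self) -> np.ndarray:
        lo, hi = self.elevation_range
        if self.n_sites == 12 and (lo, hi) == (1800.0, 4100.0):
            return np.array(DEFAULT_SITE_ELEVATIONS, dtype=float)
        return np.linspace(lo, hi, self.n_sites)

    def rng_for(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on the sphere (radius 6371 km), degrees in."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geographic_distance_km(metadata: SampleMetadata) -> np.ndarray:
    """Pairwise great-circle distances (km) between all samples."""
    lat = metadata.data["latitude"].to_numpy(float)
    lon = metadata.data["longitude"].to_numpy(float)
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def generate_metadata(scenario: GradientScenario) -> SampleMetadata:
    """Per-sample covariates along the transect.

    In the noiseless limit MAP is exactly linear (increasing) in elevation
    and MAT/T10 strictly decreasing; pH follows the scenario profile; plant
    attributes trend with elevation. ``noise_sd`` multiplies each
    covariate's natural plot-to-plot scatter (e.g. 0.25 pH units, 60 mm
    MAP), so 1.0 is realistic field variability and 0 is the noiseless
    limit.
    """
    rng = scenario.rng_for(0)
    elevs = scenario.site_elevations()
    lo, hi = scenario.elevation_range
    span = hi - lo

    rows = []
    # lay sites on a south-north transect; each elevational section covers
    # ~section_extent_km of horizontal distance
    n_lower = int(np.sum(elevs < 2700))
    for i, e in enumerate(elevs):
        if e < 2700:
            frac = i / max(n_lower - 1, 1)
            along = frac * scenario.section_extent_km
        else:
            j = i - n_lower
            n_hi = len(elevs) - n_lower
            frac = j / max(n_hi - 1, 1)
            along = scenario.section_extent_km * (1.15 + frac)
        site_lat = scenario.base_latitude + along / 111.32
        veg = scenario.vegetation_map(float(e))
        for k in range(scenario.samples_per_site):
            rows.append((f"S{int(round(e))}_{k + 1}", f"E{int(round(e))}", float(e), site_lat, veg))

    n = len(rows)
    ids = [r[0] for r in rows]
    site_id = [r[1] for r in rows]
    elevation = np.array([r[2] for r in rows])
    site_lat = np.array([r[3] for r in rows])
    veg_type = [r[4] for r in rows]

    def noisy(trend: np.ndarray, scale: float) -> np.ndarray:
        return trend + scenario.noise_sd * scale * rng.standard_normal(n)

    scatter_deg = scenario.plot_scatter_km / 111.32
    latitude = site_lat + rng.uniform(-scatter_deg, scatter_deg, n)
    longitude = scenario.base_longitude + rng.uniform(-scatter_deg, scatter_deg, n)

    # second argument = natural plot-to-plot scatter at noise_sd = 1
    rel = (elevation - lo) / span
    ph = np.clip(noisy(scenario.ph_profile(elevation), 0.25), 0.05, 13.95)
    map_ = noisy(1050.0 + 0.74 * (elevation - 1600.0), 60.0)
    mat = noisy(12.7 - 0.0061 * (elevation - 1600.0), 0.5)
    t10 = noisy(12.0 - 9.0 * rel, 0.8)
    tc = np.clip(noisy(30.0 * np.exp(-3.0 * rel) + 1.0, 2.5), 0.05, 100.0)
    tn = np.clip(tc / 14.0 + scenario.noise_sd * 0.15 * rng.standard_normal(n), 0.01, 100.0)
    no3 = np.clip(noisy(20.0 * np.exp(-2.5 * rel) + 0.3, 2.0), 0.0, None)
    nh4 = np.exp(rng.normal(2.3, 0.6, n))  # no elevational trend by design
    cond = np.clip(noisy(240.0 * (1.0 - rel) + 8.0, 20.0), 0.0, None)
    psr = np.clip(noisy(45.0 - 40.0 * rel, 4.0), 1.0, None)
    db = np.clip(noisy(70.0 * np.clip(1.0 - (elevation - 1800.0) / 2100.0, 0.0, 1.0), 6.0), 0.0, 100.0)
    eb = np.clip(noisy(25.0 * np.clip(1.0 - (elevation - 1800.0) / 800.0, 0.0, 1.0), 4.0), 0.0, 100.0)
    dc = np.clip(noisy(75.0 * np.exp(-(((elevation - 3100.0) / 500.0) ** 2)), 5.0), 0.0, 100.0)

    df = pd.DataFrame(
        {
            "site_id": site_id,
            "elevation": elevation,
            "latitude": latitude,
            "longitude": longitude,
            "vegetation_type": veg_type,
            "pH": ph,
            "TC": tc,
            "TN": tn,
            "NH4": nh4,
            "NO3": no3,
            "conductivity": cond,
            "T10": t10,
            "MAP": map_,
            "MAT": mat,
            "PSR": psr,
            "DB": db,
            "EB": eb,
            "DC": dc,
        },
        index=ids,
    )
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------

def expected_relative_abundance(
    scenario: GradientScenario, metadata: SampleMetadata
) -> np.ndarray:
    """Deterministic mean model: expected relative abundance per sample/OTU.

    abundance ~ lognormal base x Gaussian pH niche x vegetation affinity x
    exponential spatial kernel, row-normalised.
    """
    rng = scenario.rng_for(1)
    n_otus = scenario.n_otus
    mu, sd = scenario.abundance_lognormal_params
    base = rng.lognormal(mu, sd, n_otus)
    optima = rng.uniform(PH_MIN, PH_MAX, n_otus)
    if scenario.vegetation_affinity_sd > 0:
        affinity = rng.lognormal(0.0, scenario.vegetation_affinity_sd, (len(VEGETATION_TYPES), n_otus))
    else:
        affinity = np.ones((len(VEGETATION_TYPES), n_otus))
    lat = metadata.data["latitude"].to_numpy(float)
    lon = metadata.data["longitude"].to_numpy(float)
    # each OTU originates somewhere on the transect
    origin_lat = rng.uniform(lat.min(), lat.max(), n_otus)
    origin_lon = np.full(n_otus, lon.mean())

    ph = metadata.data["pH"].to_numpy(float)
    sigma = scenario.env_filter_strength
    if np.isfinite(sigma):
        niche = np.exp(-((ph[:, None] - optima[None, :]) ** 2) / (2.0 * sigma**2))
    else:
        niche = np.ones((len(ph), n_otus))
    veg_idx = np.array([VEGETATION_TYPES.index(v) for v in metadata.data["vegetation_type"]])
    veg_term = affinity[veg_idx, :]
    if np.isfinite(scenario.spatial_decay_range):
        dist = haversine_km(lat[:, None], lon[:, None], origin_lat[None, :], origin_lon[None, :])
        space = np.exp(-dist / scenario.spatial_decay_range)
    else:
        space = 1.0
    weights = base[None, :] * niche * veg_term * space
    totals = weights.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValidationError("a sample has zero total expected abundance")
    return weights / totals


def generate_community(
    scenario: GradientScenario,
    metadata: SampleMetadata,
    depth: Optional[int] = None,
) -> OtuTable:
    """Multinomial counts at the configured sequencing depth from the mean
    model in :func:`expected_relative_abundance`."""
    depth = int(depth if depth is not None else scenario.sequencing_depth)
    if depth < 1:
        raise ValidationError("sequencing depth must be >= 1")
    probs = expected_relative_abundance(scenario, metadata)
    rng = scenario.rng_for(2)
    n = probs.shape[0]
    depths = np.full(n, depth)
    if scenario.depth_jitter > 0:
        depths = np.maximum(
            1, np.round(depth * (1.0 + scenario.depth_jitter * rng.standard_normal(n)))
        ).astype(int)
    counts = np.vstack([rng.multinomial(depths[i], probs[i]) for i in range(n)])
    otu_ids = [f"OTU{j + 1}" for j in range(scenario.n_otus)]
    return OtuTable(metadata.sample_ids, otu_ids, counts)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def generate_tree(otu_ids: Sequence[str], seed: int = 0) -> dendropy.Tree:
    """Random Kingman-style coalescent tree over the ids: at each step two
    uniformly chosen lineages merge, node heights accumulating exponential
    waiting times, so the tree is rooted, bifurcating, with positive branch
    lengths. Deterministic in the seed."""
    ids = [str(i) for i in otu_ids]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ids passed to generate_tree")
    if len(ids) < 2:
        raise ValidationError("need at least 2 ids")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node.height = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.height = t
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = parent.height - child.height
        nodes = [x for m, x in enumerate(nodes) if m not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# SEM-style dataset for path-model recovery
# ---------------------------------------------------------------------------

@dataclass
class SemDataset:
    """Manifest data plus the generating truth for path-model recovery."""

    data: pd.DataFrame
    latent_scores: pd.DataFrame
    paths: dict
    blocks: dict


def _topological_order(latents: list[str], paths: dict) -> list[str]:
    indeg = {l: 0 for l in latents}
    for (src, tgt) in paths:
        indeg[tgt] += 1
    order, ready = [], [l for l in latents if indeg[l] == 0]
    while ready:
        node = ready.pop(0)
        order.append(node)
        for (src, tgt) in paths:
            if src == node:
                indeg[tgt] -= 1
                if indeg[tgt] == 0:
                    ready.append(tgt)
    if len(order) != len(latents):
        raise ValidationError("path matrix is cyclic")
    return order


def generate_sem_dataset(
    path_coeffs: dict,
    n: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    indicators_per_latent: int = 2,
) -> SemDataset:
    """Linear recursive latent system with reflective indicators.

    ``path_coeffs`` maps (source, target) latent pairs to standardized path
    coefficients. Structural residual variances are set so every latent has
    unit variance, making the generating coefficients the standardized ones
    an estimator should recover. Each latent emits ``indicators_per_latent``
    manifests ``latent + noise_sd * eps`` (then standardized), i.e.
    high-reliability indicator pairs like the collinear covariate pairs the
    latent blocks summarise.
    """
    latents = []
    for (src, tgt) in path_coeffs:
        for l in (src, tgt):
            if l not in latents:
                latents.append(l)
    order = _topological_order(latents, path_coeffs)
    rng = np.random.default_rng(seed)
    scores = {}
    for l in order:
        preds = [(src, c) for (src, tgt), c in path_coeffs.items() if tgt == l]
        eps = rng.standard_normal(n)
        if not preds:
            lv = eps
        else:
            systematic = np.zeros(n)
            for src, c in preds:
                systematic += c * scores[src]
            resid_var = 1.0 - np.var(systematic)
            if resid_var <= 0:
                raise ValidationError(
                    f"path coefficients into {l!r} imply variance > 1"
                )
            lv = systematic + np.sqrt(resid_var) * eps
        lv = (lv - lv.mean()) / lv.std()
        scores[l] = lv
    data = {}
    blocks = {}
    for l in order:
        cols = []
        for k in range(indicators_per_latent):
            x = scores[l] + noise_sd * rng.standard_normal(n)
            x = (x - x.mean()) / x.std()
            col = f"{l}_{k + 1}"
            data[col] = x
            cols.append(col)
        blocks[l] = cols
    idx = [f"obs{i + 1}" for i in range(n)]
    return SemDataset(
        data=pd.DataFrame(data, index=idx),
        latent_scores=pd.DataFrame(scores, index=idx),
        paths=dict(path_coeffs),
        blocks=blocks,
    )
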