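"""Rarefaction, alpha-diversity, pairwise dissimilarities, distance decay.

Faith's PD follows the rooted convention: the branch-length sum of the
minimal subtree connecting a sample's observed taxa *and the root*, so a
single-taxon sample scores its root-to-leaf path length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix, GradientSections, OtuTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaDiversityResult",
    "DistanceDecayFit",
    "rarefy",
    "richness",
    "faith_pd",
    "dissimilarity_matrix",
    "distance_decay",
]


@dataclass
class AlphaDiversityResult:
    """Per-sample alpha diversity (OTU richness and/or Faith's PD)."""

    sample_ids: list[str]
    richness: Optional[np.ndarray] = None
    faith_pd: Optional[np.ndarray] = None
    rarefaction_depth: Optional[int] = None

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        if self.richness is not None:
            cols["richness"] = self.richness
        if self.faith_pd is not None:
            cols["faith_pd"] = self.faith_pd
        return pd.DataFrame(cols, index=self.sample_ids)


@dataclass
class DistanceDecayFit:
    """OLS fit of pairwise community similarity on geographic distance."""

    section: str
    slope: float  # similarity units per km
    intercept: float
    r2: float
    p_value: float
    n_pairs: int


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement
    (multivariate hypergeometric); samples with fewer reads are dropped with
    a warning."""
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d samples below rarefaction depth %d: %s",
            len(dropped), depth, dropped,
        )
    new_ids, new_rows = [], []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        row = table.counts[i]
        if totals[i] == depth:
            new_rows.append(row.copy())
        else:
            new_rows.append(rng.multivariate_hypergeometric(row, depth))
        new_ids.append(sid)
    counts = np.vstack(new_rows) if new_rows else np.zeros((0, table.n_otus), dtype=np.int64)
    return OtuTable(new_ids, table.otu_ids, counts, table.taxonomy)


def richness(table: OtuTable) -> AlphaDiversityResult:
    """Number of OTUs with count > 0 per sample."""
    return AlphaDiversityResult(
        sample_ids=list(table.sample_ids), richness=table.richness_values()
    )


def _leaf_edge_paths(tree: dendropy.Tree) -> tuple[dict[str, int], list[list[int]], np.ndarray]:
    """Per-leaf list of edge indices on its root path, plus edge lengths."""
    edges = []
    edge_index = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        edge_index[id(edge)] = len(edges)
        edges.append(edge.length if edge.length is not None else 0.0)
    leaf_ids = {}
    paths = []
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node is not tree.seed_node:
            path.append(edge_index[id(node.edge)])
            node = node.parent_node
        leaf_ids[leaf.taxon.label] = len(paths)
        paths.append(path)
    return leaf_ids, paths, np.asarray(edges, dtype=float)


def faith_pd(table: OtuTable, tree: dendropy.Tree) -> AlphaDiversityResult:
    """Rooted Faith's PD per sample: total length of the union of
    root-to-leaf paths of the observed OTUs. Empty samples score 0."""
    leaf_ids, paths, edge_lengths = _leaf_edge_paths(tree)
    observed_any = table.presence().any(axis=0)
    missing = [o for o, obs in zip(table.otu_ids, observed_any) if obs and o not in leaf_ids]
    if missing:
        raise ValidationError(f"observed OTUs absent from tree: {missing}")
    n_edges = len(edge_lengths)
    # boolean root-path incidence per OTU present in the tree
    incidence = np.zeros((table.n_otus, n_edges), dtype=bool)
    for j, otu in enumerate(table.otu_ids):
        if otu in leaf_ids:
            incidence[j, paths[leaf_ids[otu]]] = True
    presence = table.presence()
    pd_vals = np.empty(table.n_samples)
    for i in range(table.n_samples):
        used = incidence[presence[i]].any(axis=0) if presence[i].any() else np.zeros(n_edges, bool)
        pd_vals[i] = edge_lengths[used].sum()
    return AlphaDiversityResult(sample_ids=list(table.sample_ids), faith_pd=pd_vals)


def dissimilarity_matrix(
    table: OtuTable,
    metric: str = "jaccard_binary",
    zero_zero_as_zero: bool = False,
) -> DistanceMatrix:
    """Pairwise dissimilarities among samples.

    ``jaccard_binary``: 1 - |A&B|/|A|B| on presence/absence.
    ``bray_curtis``: sum|x-y|/sum(x+y) on relative abundances.
    ``jaccard_abundance`` (Ruzicka): 1 - sum min/sum max on relative abundances.
    A pair of all-zero samples is undefined and raises unless
    ``zero_zero_as_zero`` sets its distance to 0.
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    empty = table.sample_totals == 0
    if empty.sum() >= 2 and not zero_zero_as_zero:
        raise ValidationError(
            "distance between two all-zero samples is undefined "
            "(pass zero_zero_as_zero=True to define it as 0)"
        )
    if metric == "jaccard_binary":
        x = table.presence().astype(float)
        vals = squareform(pdist(x, metric="jaccard"))
    elif metric == "bray_curtis":
        rel = table.relative_abundance()
        vals = squareform(pdist(rel, metric="braycurtis"))
    elif metric == "jaccard_abundance":
        rel = table.relative_abundance()
        n = rel.shape[0]
        vals = np.zeros((n, n))
        for i in range(n):
            mins = np.minimum(rel[i], rel[i + 1:]).sum(axis=1)
            maxs = np.maximum(rel[i], rel[i + 1:]).sum(axis=1)
            with np.errstate(invalid="ignore"):
                d = 1.0 - mins / maxs
            vals[i, i + 1:] = d
            vals[i + 1:, i] = d
    else:
        raise ValueError(f"unknown metric {metric!r}")
    vals = np.nan_to_num(vals, nan=0.0)  # all-zero pairs -> 0 when allowed
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(table.sample_ids, vals, kind="dissimilarity")


def distance_decay(
    community_sim: DistanceMatrix,
    geo_km: DistanceMatrix,
    sections: GradientSections,
) -> dict[str, DistanceDecayFit]:
    """Per-section OLS of pairwise similarity on geographic distance (km).

    ``community_sim`` holds similarities (1 - dissimilarity); slope units
    are similarity per km (negative slope = distance decay)."""
    if community_sim.ids != geo_km.ids:
        raise ValidationError("similarity and geographic matrices must share ids")
    fits = {}
    for name, ids in (("lower", sections.lower_ids), ("higher", sections.higher_ids)):
        ids = [i for i in ids if i in set(community_sim.ids)]
        if len(ids) < 3:
            raise ValidationError(f"section {name!r} has too few samples")
        sim = community_sim.submatrix(ids).condensed()
        dist = geo_km.submatrix(ids).condensed()
        if sim.size < 3:
            raise ValidationError(f"section {name!r} has fewer than 3 pairs")
        if np.allclose(dist, dist[0]):
            raise ValidationError(f"section {name!r} has constant distances")
        res = stats.linregress(dist, sim)
        fits[name] = DistanceDecayFit(
            section=name,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r2=float(res.rvalue**2),
            p_value=float(res.pvalue),
            n_pairs=int(sim.size),
        )
    return fits
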