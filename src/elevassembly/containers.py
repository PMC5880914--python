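"""Core domain containers for elevational community analysis.

The observation unit is an OTU count table (samples x OTUs) with aligned
per-sample metadata (soil chemistry, climate, plant attributes, coordinates),
an optional rooted phylogeny over the OTUs, and square pairwise matrices
(dissimilarities, similarities, or null-model deviation z-scores).

Alignment between tables is always by sample id, never by position.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "DistanceMatrix",
    "GradientSections",
    "AnalysisConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} ids: {sorted(set(dups))}")
    return ids


class OtuTable:
    """Integer OTU count matrix, stored samples x OTUs.

    Parameters
    ----------
    sample_ids, otu_ids : sequences of unique identifiers.
    counts : array-like of shape (n_samples, n_otus), non-negative integers.
    taxonomy : optional mapping otu_id -> lineage string.
    """

    def __init__(self, sample_ids, otu_ids, counts, taxonomy: Optional[dict] = None):
        self.sample_ids = _check_unique(sample_ids, "sample")
        self.otu_ids = _check_unique(otu_ids, "OTU")
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.otu_ids)} OTUs)"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            flo = np.asarray(counts, dtype=float)
            if not np.all(np.isfinite(flo)):
                raise ValidationError("counts contain non-finite values")
            if not np.all(flo == np.round(flo)):
                bad = np.argwhere(flo != np.round(flo))[0]
                raise ValidationError(
                    f"non-integral count at sample {self.sample_ids[bad[0]]}, "
                    f"OTU {self.otu_ids[bad[1]]}"
                )
            counts = flo.astype(np.int64)
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]}, "
                f"OTU {self.otu_ids[bad[1]]}"
            )
        self.counts = counts
        self.taxonomy = dict(taxonomy) if taxonomy else None

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def presence(self) -> np.ndarray:
        """Boolean presence/absence matrix (samples x OTUs)."""
        return self.counts > 0

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised abundances; all-zero samples stay all-zero."""
        totals = self.sample_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals[:, None]
        rel[totals == 0] = 0.0
        return rel

    def richness_values(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=1)

    # -- selection ------------------------------------------------------
    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([lookup[i] for i in ids], dtype=int)

    def select_samples(self, ids: Sequence[str]) -> "OtuTable":
        idx = self.sample_index(ids)
        return OtuTable(list(ids), self.otu_ids, self.counts[idx], self.taxonomy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


#: columns every metadata table must carry (study covariate symbols:
#: TC/TN total carbon/nitrogen in %, NH4/NO3 in mg per kg dry soil,
#: conductivity in uS/cm, T10 soil temperature at 10 cm in degC,
#: MAP/MAT mean annual precipitation (mm) / air temperature (degC),
#: PSR plant species richness, DB/EB/DC percent of total DBH by tree type).
REQUIRED_METADATA_COLUMNS = [
    "site_id",
    "elevation",
    "latitude",
    "longitude",
    "vegetation_type",
    "pH",
    "TC",
    "TN",
    "NH4",
    "NO3",
    "conductivity",
    "T10",
    "MAP",
    "MAT",
    "PSR",
    "DB",
    "EB",
    "DC",
]

_PERCENT_COLUMNS = ["TC", "TN", "DB", "EB", "DC"]


class SampleMetadata:
    """Per-sample environmental / spatial / climate / plant covariates.

    Thin validated wrapper around a :class:`pandas.DataFrame` indexed by
    sample id. Unknown extra columns are preserved as covariates.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("SampleMetadata expects a pandas DataFrame")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"missing required metadata columns: {missing}")
        _check_unique(list(data.index), "sample")
        data = data.copy()
        data.index = data.index.map(str)
        data.index.name = "sample_id"
        ph = np.asarray(data["pH"], dtype=float)
        if np.any((ph <= 0) | (ph >= 14)):
            bad = data.index[(ph <= 0) | (ph >= 14)].tolist()
            raise ValidationError(f"pH outside (0, 14) for samples {bad}")
        for col in _PERCENT_COLUMNS:
            vals = np.asarray(data[col], dtype=float)
            if np.any((vals < 0) | (vals > 100)):
                raise ValidationError(f"column {col} outside [0, 100]")
        elev = np.asarray(data["elevation"], dtype=float)
        if np.any(elev <= 0):
            raise ValidationError("elevation must be positive")
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def align_to(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        """Reorder rows to match ``sample_ids`` (alignment by id)."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"metadata missing samples: {missing}")
        return SampleMetadata(self.data.loc[list(sample_ids)])

    def numeric(self, columns: Sequence[str]) -> pd.DataFrame:
        return self.data[list(columns)].astype(float)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"SampleMetadata({len(self.data)} samples, {self.data.shape[1]} columns)"


class DistanceMatrix:
    """Square symmetric pairwise matrix with sample ids.

    ``kind`` distinguishes ordinary dissimilarities (non-negative, zero
    diagonal), similarities (e.g. Jaccard similarity), and null-model
    deviation z-scores, which may be negative off-diagonal.
    """

    KINDS = ("dissimilarity", "similarity", "deviation")

    def __init__(self, ids, values, kind: str = "dissimilarity", tol: float = 1e-12):
        self.ids = _check_unique(ids, "sample")
        values = np.asarray(values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValidationError(f"matrix shape {values.shape} != ({n}, {n})")
        if kind not in self.KINDS:
            raise ValidationError(f"unknown kind {kind!r}")
        if not np.allclose(values, values.T, atol=tol, rtol=0, equal_nan=True):
            raise ValidationError("matrix is not symmetric (tolerance 1e-12)")
        values = (values + values.T) / 2.0
        if kind == "dissimilarity":
            if np.nanmin(values) < -tol if values.size else False:
                raise ValidationError("dissimilarity matrix has negative entries")
            if not np.allclose(np.diag(values), 0.0, atol=tol):
                raise ValidationError("dissimilarity matrix diagonal must be zero")
            np.fill_diagonal(values, 0.0)
        self.values = values
        self.kind = kind

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy ``squareform`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        lookup = {s: i for i, s in enumerate(self.ids)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"unknown ids: {missing}")
        idx = np.array([lookup[i] for i in ids], dtype=int)
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def to_similarity(self) -> "DistanceMatrix":
        if self.kind != "dissimilarity":
            raise ValidationError("to_similarity expects a dissimilarity matrix")
        return DistanceMatrix(self.ids, 1.0 - self.values, kind="similarity")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def __repr__(self) -> str:
        return f"DistanceMatrix({self.n} ids, kind={self.kind!r})"


@dataclass
class GradientSections:
    """Split of the gradient into a lower and a higher elevational section.

    The default threshold (2700 m) is the midpoint of the gap between the
    highest low-section site (2600 m) and the lowest high-section site
    (2800 m) where diversity and pH change regime.
    """

    threshold_elevation: float
    lower_ids: list[str]
    higher_ids: list[str]

    DEFAULT_THRESHOLD = 2700.0

    @classmethod
    def from_metadata(
        cls, metadata: SampleMetadata, threshold: float = DEFAULT_THRESHOLD
    ) -> "GradientSections":
        elev = metadata.data["elevation"].astype(float)
        lower = list(elev.index[elev < threshold])
        higher = list(elev.index[elev >= threshold])
        return cls(threshold, lower, higher)

    def __post_init__(self):
        overlap = set(self.lower_ids) & set(self.higher_ids)
        if overlap:
            raise ValidationError(f"samples in both sections: {sorted(overlap)}")

    def labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        """'lower'/'higher' label per sample id."""
        lower = set(self.lower_ids)
        higher = set(self.higher_ids)
        out = []
        for s in sample_ids:
            if s in lower:
                out.append("lower")
            elif s in higher:
                out.append("higher")
            else:
                raise KeyError(f"sample {s} not in either section")
        return np.array(out)


@dataclass
class AnalysisConfig:
    """Shared knobs for stochastic procedures; the seed is recorded in
    every result object so any run can be reproduced."""

    n_permutations: int = 999
    n_null_iterations: int = 999
    n_bootstrap: int = 999
    rarefaction_depth: Optional[int] = None
    random_seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("n_permutations", "n_null_iterations", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.rarefaction_depth is not None and self.rarefaction_depth < 1:
            raise ValidationError("rarefaction_depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
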