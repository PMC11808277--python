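"""Validated in-memory containers shared across the pipeline.

The phylogeny is a :class:`dendropy.Tree`; distance matrices are
:class:`skbio.DistanceMatrix`; tables are pandas DataFrames.  The helpers
here enforce the invariants downstream code relies on (unique labels,
nonnegative branch lengths, binary occupancy, finite covariates) so that
every later stage can assume clean inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix


class FpdivError(Exception):
    """Base class for pipeline errors."""


class ValidationError(FpdivError):
    """An input object violates a container invariant."""


class FormatError(FpdivError):
    """An external representation could not be parsed."""


class TraitType(str, Enum):
    CONTINUOUS = "continuous"
    ORDINAL = "ordinal"
    NOMINAL = "nominal"
    BINARY = "binary"


def normalize_name(name: str) -> str:
    """Canonicalize a species/site name: strip and use underscores.

    Newick files conventionally use underscores where tables use spaces;
    matching is done on the underscore form.
    """
    return "_".join(str(name).strip().split())


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Check the phylogeny invariants; normalize tip labels in place."""
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValidationError(f"tree has {len(leaves)} tip(s); at least 2 required")
    labels = []
    for leaf in leaves:
        if leaf.taxon is None or not str(leaf.taxon.label).strip():
            raise ValidationError("tree contains an unlabeled or empty-labeled tip")
        leaf.taxon.label = normalize_name(leaf.taxon.label)
        labels.append(leaf.taxon.label)
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(f"negative branch length {edge.length} on edge to {edge.head_node}")
    return tree


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class TraitTable:
    """Species x trait table with per-trait declared types.

    ``data`` is indexed by species name; ``types`` maps every column of
    ``data`` to a :class:`TraitType`.  Missing values (NaN for numeric,
    NaN/None for categorical) are permitted and handled downstream by
    pairwise deletion.
    """

    data: pd.DataFrame
    types: dict[str, TraitType]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = [normalize_name(s) for s in self.data.index]
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species in trait table: {dupes}")
        self.types = {k: TraitType(v) for k, v in self.types.items()}
        missing = set(self.data.columns) - set(self.types)
        if missing:
            raise ValidationError(f"traits without a declared type: {sorted(missing)}")
        for col, t in self.types.items():
            if col not in self.data.columns:
                raise ValidationError(f"declared trait {col!r} absent from table")
            if t in (TraitType.CONTINUOUS, TraitType.ORDINAL):
                vals = pd.to_numeric(self.data[col], errors="raise").astype(float)
                if np.isinf(vals.to_numpy()).any():
                    raise ValidationError(f"non-finite values in trait {col!r}")
                self.data[col] = vals

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def restrict(self, species: list[str]) -> "TraitTable":
        return TraitTable(self.data.loc[species], dict(self.types), dict(self.units))


@dataclass
class CommunityMatrix:
    """Site x species presence/absence matrix."""

    data: pd.DataFrame  # sites as index, species as columns, values in {0, 1}

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = [normalize_name(s) for s in df.index]
        df.columns = [normalize_name(s) for s in df.columns]
        if df.index.has_duplicates:
            raise ValidationError("duplicate site identifiers in community matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate species in community matrix")
        vals = df.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite community matrix entry")
        if (vals < 0).any():
            raise ValidationError("negative community matrix entry")
        if (vals > 1).any():
            n_coerced = int((vals > 1).sum())
            warnings.warn(
                f"{n_coerced} abundance value(s) > 1 coerced to presence", stacklevel=3
            )
        self.data = pd.DataFrame(
            (vals > 0).astype(np.int8), index=df.index, columns=df.columns
        )
        empty = self.data.columns[self.data.sum(axis=0) == 0].tolist()
        if empty:
            raise ValidationError(f"species occurring in no site: {empty}")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def richness(self) -> pd.Series:
        return self.data.sum(axis=1)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)

    def restrict(self, species: list[str]) -> "CommunityMatrix":
        return CommunityMatrix(self.data[species])


#: canonical covariate columns for the environment table
ENV_COVARIATES = ["TEMP", "PREC", "NDVI", "NPP", "HII", "ALT"]
COORD_COLUMNS = ["longitude", "latitude"]


@dataclass
class EnvTable:
    """Per-site environmental covariates plus site coordinates."""

    data: pd.DataFrame
    covariate_columns: list[str] = field(default_factory=lambda: list(ENV_COVARIATES))

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = [normalize_name(s) for s in df.index]
        if df.index.has_duplicates:
            raise ValidationError("duplicate site identifiers in environment table")
        self.covariate_columns = [c for c in self.covariate_columns if c in df.columns]
        if not self.covariate_columns:
            raise ValidationError("environment table has no recognized covariate column")
        cov = df[self.covariate_columns].apply(pd.to_numeric, errors="raise")
        if not np.isfinite(cov.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite environmental covariate")
        df[self.covariate_columns] = cov
        self.data = df

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[self.covariate_columns]

    def coordinates(self) -> pd.DataFrame:
        missing = [c for c in COORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"missing coordinate column(s): {missing}")
        return self.data[COORD_COLUMNS].astype(float)


def validate_distance_matrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Extra checks on top of skbio's (hollow, symmetric): finite, nonnegative."""
    vals = dm.data
    if not np.isfinite(vals).all():
        raise ValidationError("non-finite distance matrix entry")
    if (vals < 0).any():
        raise ValidationError("negative distance matrix entry")
    return dm
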