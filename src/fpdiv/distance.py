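"""Interspecific distance matrices.

Three matrices drive the analysis:

* ``FDist`` — trait-space distance: Gower dissimilarity over mixed-type
  traits, embedded by principal coordinates analysis (classical metric
  scaling), with Euclidean distances recomputed on the retained axes.
* ``PDist`` — patristic distance: summed branch lengths between tips.
* ``FPDist(a)`` — the weighted blend
  ``((a) * PDist'^p + (1 - a) * FDist'^p)^(1/p)`` after max-rescaling both
  components to [0, 1].  ``a = 0`` recovers the functional distance,
  ``a = 1`` the phylogenetic one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .containers import (
    TraitTable,
    TraitType,
    ValidationError,
    tree_tip_labels,
    validate_distance_matrix,
)

__all__ = [
    "patristic_distances",
    "gower_distance",
    "pcoa",
    "fdist_from_axes",
    "fpdist",
    "functional_distance",
    "OrdinationResult",
    "FPDistSpec",
    "RetentionRule",
]


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise sum of branch lengths along the tip-to-tip path."""
    labels = tree_tip_labels(tree)
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    # root-to-node depths, then d(i,j) = depth_i + depth_j - 2 * depth(MRCA)
    depth: dict[int, float] = {}
    tips_below: dict[int, list[tuple[int, float]]] = {}
    out = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = [(index[node.taxon.label], 0.0)]
            continue
        groups = []
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            groups.append([(i, d + bl) for i, d in tips_below.pop(id(child))])
        merged = []
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i, di in groups[gi]:
                    for j, dj in groups[gj]:
                        out[i, j] = out[j, i] = di + dj
            merged.extend(groups[gi])
        tips_below[id(node)] = merged
    return validate_distance_matrix(DistanceMatrix(out, ids=labels))


def gower_distance(traits: TraitTable) -> DistanceMatrix:
    """Gower dissimilarity over mixed trait types, in [0, 1].

    Continuous and ordinal traits contribute range-scaled absolute
    differences (ordinal values are rank-transformed first, average ranks
    for ties); nominal and binary traits contribute 0/1 mismatch.  Missing
    values are handled by pairwise deletion: each pair is averaged over the
    traits observed in both species.  Zero-range traits are dropped with a
    warning; a pair sharing no observed trait is an error.
    """
    species = traits.species
    n = len(species)
    contribs: list[np.ndarray] = []
    valids: list[np.ndarray] = []
    for col, ttype in traits.types.items():
        x = traits.data[col]
        if ttype in (TraitType.CONTINUOUS, TraitType.ORDINAL):
            vals = x.to_numpy(dtype=float)
            obs = np.isfinite(vals)
            if ttype is TraitType.ORDINAL:
                ranked = np.full(n, np.nan)
                ranked[obs] = rankdata(vals[obs])
                vals = ranked
            rng = np.nanmax(vals) - np.nanmin(vals) if obs.any() else 0.0
            if not obs.any() or rng == 0:
                warnings.warn(f"trait {col!r} has zero range; dropped from Gower distance")
                continue
            diff = np.abs(vals[:, None] - vals[None, :]) / rng
            valid = obs[:, None] & obs[None, :]
        else:
            vals = x.to_numpy(dtype=object)
            obs = np.array([v is not None and v == v for v in vals])
            if obs.sum() and len({v for v, o in zip(vals, obs) if o}) < 2:
                warnings.warn(f"trait {col!r} has zero range; dropped from Gower distance")
                continue
            diff = (vals[:, None] != vals[None, :]).astype(float)
            valid = obs[:, None] & obs[None, :]
        diff = np.where(valid, diff, 0.0)
        contribs.append(diff)
        valids.append(valid.astype(float))
    if not contribs:
        raise ValidationError("no usable trait for Gower distance")
    total = np.sum(contribs, axis=0)
    count = np.sum(valids, axis=0)
    bad = (count == 0) & ~np.eye(n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"species pair ({species[i]!r}, {species[j]!r}) shares no observed trait"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return validate_distance_matrix(DistanceMatrix(d, ids=species))


@dataclass(frozen=True)
class RetentionRule:
    """How many PCoA axes to keep.

    ``cumulative``: keep the fewest positive-eigenvalue axes whose relative
    eigenvalues sum to at least the threshold (default 0.80).  ``count``:
    keep a fixed number (capped at the number of positive axes).
    """

    kind: str = "cumulative"
    threshold: float = 0.80
    count: int | None = None

    def n_axes(self, rel_share: np.ndarray) -> int:
        n_pos = len(rel_share)
        if self.kind == "count":
            if self.count is None or self.count < 1:
                raise ValidationError("count retention rule requires count >= 1")
            return min(self.count, n_pos)
        if self.kind != "cumulative":
            raise ValidationError(f"unknown retention rule {self.kind!r}")
        cum = np.cumsum(rel_share)
        return min(int(np.searchsorted(cum, self.threshold - 1e-12)) + 1, n_pos)


@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix."""

    labels: list[str]
    eigenvalues: np.ndarray  # all eigenvalues, descending
    coordinates: np.ndarray  # n x retained_axes
    retained_axes: int
    rel_eigenvalues: np.ndarray = field(default=None)  # share among positive eigenvalues

    @property
    def proportion_explained(self) -> float:
        return float(self.rel_eigenvalues[: self.retained_axes].sum())


def pcoa(
    dm: DistanceMatrix,
    retention: RetentionRule | None = None,
    correction: str | None = None,
) -> OrdinationResult:
    """Principal coordinates analysis (Gower's classical metric scaling).

    Eigendecomposes the double-centered matrix ``-0.5 * J D^2 J``.  Axes
    with non-positive eigenvalues are never retained; if negative
    eigenvalues occur a warning is emitted (no correction by default;
    ``correction='lingoes'`` adds the Lingoes constant to off-diagonal
    squared distances, ``correction='cailliez'`` adds the Cailliez constant
    to off-diagonal distances).
    """
    retention = retention or RetentionRule()
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValidationError("PCoA requires at least 3 objects")
    if correction not in (None, "lingoes", "cailliez"):
        raise ValidationError(f"unknown correction {correction!r}")
    d = dm.data.astype(float)
    d2 = d**2
    eigvals, eigvecs = _center_and_eig(d2)
    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    if eigvals[-1] < -tol and correction is not None:
        if correction == "lingoes":
            c = -eigvals[-1]
            d2 = d2 + 2 * c * (1 - np.eye(n))
        else:
            c = _cailliez_constant(d)
            d2 = (d + c * (1 - np.eye(n))) ** 2
        eigvals, eigvecs = _center_and_eig(d2)
        tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    eigvals = np.where(np.abs(eigvals) < tol, 0.0, eigvals)
    pos = eigvals > 0
    if not pos.any():
        raise ValidationError("degenerate distance matrix: no positive PCoA eigenvalue")
    if (eigvals < 0).any():
        warnings.warn(
            f"PCoA produced {int((eigvals < 0).sum())} negative eigenvalue(s); "
            "non-positive axes excluded"
        )
    rel = eigvals[pos] / eigvals[pos].sum()
    k = retention.n_axes(rel)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    return OrdinationResult(
        labels=labels,
        eigenvalues=eigvals,
        coordinates=coords,
        retained_axes=k,
        rel_eigenvalues=rel,
    )


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making the distances Euclidean."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    delta1 = -0.5 * j @ (d**2) @ j
    delta2 = -0.5 * j @ d @ j
    block = np.block([
        [np.zeros((n, n)), 2 * delta1],
        [-np.eye(n), -4 * delta2],
    ])
    eig = np.linalg.eigvals(block)
    return float(np.max(eig.real))


def _center_and_eig(d2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = scipy.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def fdist_from_axes(ordination: OrdinationResult) -> DistanceMatrix:
    """Euclidean distances among species in the retained-axis space."""
    if ordination.retained_axes < 1:
        raise ValidationError("no retained axes")
    d = squareform(pdist(ordination.coordinates))
    return validate_distance_matrix(DistanceMatrix(d, ids=ordination.labels))


def functional_distance(
    traits: TraitTable, retention: RetentionRule | None = None
) -> tuple[DistanceMatrix, OrdinationResult]:
    """Gower -> PCoA -> Euclidean-on-retained-axes pipeline for FDist."""
    ordination = pcoa(gower_distance(traits), retention)
    return fdist_from_axes(ordination), ordination


@dataclass(frozen=True)
class FPDistSpec:
    """Blend parameters: phylogeny weight ``a`` and exponent ``p``."""

    a: float
    p: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValidationError(f"phylogeny weight a={self.a} outside [0, 1]")
        if self.p <= 0:
            raise ValidationError(f"exponent p={self.p} must be positive")


def rescale_to_unit(dm: DistanceMatrix) -> DistanceMatrix:
    """Divide by the maximum entry so distances lie in [0, 1]."""
    m = dm.data.max()
    if m == 0:
        raise ValidationError("cannot rescale an all-zero distance matrix")
    return DistanceMatrix(dm.data / m, ids=dm.ids)


def fpdist(fd: DistanceMatrix, pd_: DistanceMatrix, spec: FPDistSpec) -> DistanceMatrix:
    """Functional-phylogenetic blend of max-rescaled FDist and PDist."""
    if list(fd.ids) != list(pd_.ids):
        raise ValidationError("FDist and PDist label sets/order differ")
    f = rescale_to_unit(fd).data
    p = rescale_to_unit(pd_).data
    combined = (spec.a * p ** spec.p + (1 - spec.a) * f ** spec.p) ** (1.0 / spec.p)
    np.fill_diagonal(combined, 0.0)
    return validate_distance_matrix(DistanceMatrix(combined, ids=list(fd.ids)))
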