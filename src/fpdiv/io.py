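"""Readers and writers for the external formats.

Trees are single-tree Newick files (dendropy); community, trait and
environment tables are UTF-8 CSV with the first column holding row labels.
`align_labels` restricts a (tree, traits, community) triple to the species
common to all three, which is a precondition for every distance/SES stage.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .containers import (
    CommunityMatrix,
    EnvTable,
    FormatError,
    TraitTable,
    TraitType,
    ValidationError,
    normalize_name,
    tree_tip_labels,
    validate_tree,
)

log = logging.getLogger("fpdiv")


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a single rooted tree from a Newick string or file path."""
    text = Path(source).read_text() if _is_path(source) else str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True, rooting="force-rooted"
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate tip labels: {exc}") from exc
        raise FormatError(f"Newick parse failure: {exc}") from exc
    return validate_tree(tree)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    _atomic_write(path, tree.as_string(schema="newick", unquoted_underscores=True))


def _is_path(source: str | Path) -> bool:
    if isinstance(source, Path):
        return True
    s = str(source)
    return "(" not in s and (os.path.sep in s or os.path.exists(s))


def _read_labeled_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc


def read_community(path: str | Path) -> CommunityMatrix:
    """Site x species CSV; any abundance > 1 is coerced to presence."""
    df = _read_labeled_csv(path)
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except Exception as exc:
        raise FormatError(f"non-numeric community cell in {path}: {exc}") from exc
    return CommunityMatrix(df)


def read_traits(path: str | Path, types: Mapping[str, str]) -> TraitTable:
    """Species x trait CSV with explicitly declared trait types."""
    df = _read_labeled_csv(path)
    try:
        typed = {k: TraitType(v) for k, v in types.items()}
    except ValueError as exc:
        raise ValidationError(f"unknown trait type: {exc}") from exc
    return TraitTable(df, typed)


def read_env(path: str | Path, covariate_columns: list[str] | None = None) -> EnvTable:
    df = _read_labeled_csv(path)
    if covariate_columns is not None:
        return EnvTable(df, covariate_columns=covariate_columns)
    return EnvTable(df)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = _read_labeled_csv(path)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[normalize_name(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path)


def align_labels(
    tree: dendropy.Tree, traits: TraitTable, comm: CommunityMatrix
) -> tuple[dendropy.Tree, TraitTable, CommunityMatrix]:
    """Restrict tree, traits and community to their common species.

    The returned objects share one species order (the tree's tip order).
    Dropped names are logged.  Idempotent.
    """
    tree_sp = set(tree_tip_labels(tree))
    shared = tree_sp & set(traits.species) & set(comm.species)
    if not shared:
        raise ValidationError("no species shared by tree, traits and community")
    for name, labels in (
        ("tree", tree_sp),
        ("traits", set(traits.species)),
        ("community", set(comm.species)),
    ):
        dropped = sorted(labels - shared)
        if dropped:
            log.info("align_labels: dropping %d species from %s: %s", len(dropped), name, dropped)
    if tree_sp != shared:
        tree = tree.extract_tree_with_taxa_labels(shared)
        validate_tree(tree)
    order = [s for s in tree_tip_labels(tree)]
    return tree, traits.restrict(order), comm.restrict(order)


def _atomic_write(path: str | Path, text: str) -> None:
    """Write text to `path` via a temp file + rename (no partial outputs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv_atomic(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    _atomic_write(path, df.to_csv(**kwargs))


def write_run_report(path: str | Path, params: dict) -> None:
    """JSON run report: parameters, seeds, library versions."""
    import dendropy as _dp
    import scipy as _sp
    import skbio as _sk
    import statsmodels as _sm

    report = {
        "parameters": _jsonable(params),
        "versions": {
            "numpy": np.__version__,
            "scipy": _sp.__version__,
            "pandas": pd.__version__,
            "statsmodels": _sm.__version__,
            "dendropy": _dp.__version__,
            "scikit-bio": _sk.__version__,
        },
    }
    _atomic_write(path, json.dumps(report, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
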