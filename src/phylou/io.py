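"""File formats: trait tables, regime assignments, configs, draw exports.

Trait tables are UTF-8 CSV with a header; the required column is
``species``; measurement-error columns are named ``<var>_se``.  A missing SE
column means no measurement error for that variable.  Species matching
between tree and table is exact string match after whitespace trimming — a
mismatch is an error listing the offending names.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phylo import Phylogeny, parse_newick

__all__ = [
    "load_tree",
    "load_traits",
    "align_traits",
    "load_regimes",
    "load_config",
    "save_config",
    "file_sha256",
]


def load_tree(path) -> Phylogeny:
    return parse_newick(Path(path).read_text())


def load_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError(f"{path}: trait table must have a 'species' column")
    df["species"] = df["species"].astype(str).str.strip()
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"])
        raise ValueError(f"{path}: duplicate species rows: {dupes}")
    return df


def align_traits(df: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    """Reorder the trait table to the tree's tip order; exact-match policy."""
    tips = list(tree.tip_labels)
    have = set(df["species"])
    missing = [t for t in tips if t not in have]
    extra = sorted(have - set(tips))
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"species in tree but not in table: {missing}")
        if extra:
            parts.append(f"species in table but not in tree: {extra}")
        raise ValueError("tree/table species mismatch — " + "; ".join(parts))
    return df.set_index("species").loc[tips].reset_index()


def load_regimes(path) -> dict:
    """Node-label -> regime mapping from a delimited text file."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "node_label" not in cols or "regime" not in cols:
        raise ValueError(f"{path}: regime file needs columns node_label, regime")
    return {
        str(k).strip(): str(v).strip()
        for k, v in zip(df[cols["node_label"]], df[cols["regime"]])
    }


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: dict, path) -> None:
    path = Path(path)
    if str(path).endswith(".json"):
        path.write_text(json.dumps(config, indent=2, default=_jsonable))
    else:
        path.write_text(yaml.safe_dump(_pyify(config), sort_keys=False))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _pyify(obj):
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
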