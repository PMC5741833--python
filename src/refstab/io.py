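"""Reading and writing the pipeline's tabular formats.

Input formats
-------------
* Ct table: CSV/TSV with columns ``gene, sample, bio_rep, tech_rep, ct`` and
  optional ``condition``/``group``; header names remappable via
  ``column_map``.  Undetermined wells are encoded by a configurable token
  (default ``Undetermined``/``NA``/empty cell).
* Intensity matrix: TSV, first column probe id, remaining columns arrays;
  a companion annotation TSV with columns ``probe, gene``.

Output: every result type serializes to a TSV (scores/ranks at fixed
precision, default 4 decimals) plus a JSON twin, so re-reading reproduces
the numbers exactly at that precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import CtDataset, IntensityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_UNDETERMINED_TOKENS",
    "read_ct_table",
    "read_intensity_matrix",
    "write_result_tables",
    "write_manifest",
]

DEFAULT_UNDETERMINED_TOKENS = frozenset({"Undetermined", "NA", ""})

_MANDATORY = ("gene", "sample", "bio_rep", "tech_rep", "ct")


def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_ct_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    decimal: str = ".",
    undetermined_tokens: frozenset[str] = DEFAULT_UNDETERMINED_TOKENS,
) -> CtDataset:
    """Read a long-format Ct table into a validated :class:`CtDataset`.

    ``column_map`` maps canonical names (``gene``, ``sample``, ...) to the
    header names actually present in the file.  Cells matching one of the
    ``undetermined_tokens`` parse as missing; any other non-numeric Ct is a
    hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty Ct table")

    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    missing_cols = [c for c in _MANDATORY if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing_cols}; "
            f"found {list(df.columns)}"
        )

    raw_ct = df["ct"].str.strip()
    is_missing = raw_ct.isin(undetermined_tokens)
    ct = pd.to_numeric(raw_ct.where(~is_missing, other=None), errors="coerce")
    bad = ct.isna() & ~is_missing
    if bad.any():
        raise ValueError(
            f"{path}: non-numeric Ct value {raw_ct[bad].iloc[0]!r} is not a "
            f"recognized undetermined token {sorted(undetermined_tokens)}"
        )
    df = df.assign(ct=ct)
    n_missing = int(is_missing.sum())
    logger.info(
        "read %d Ct rows from %s (%d undetermined)", len(df), path, n_missing
    )
    return CtDataset(df)


def read_intensity_matrix(
    path: str | Path, annotation_path: str | Path, sep: str = "\t"
) -> IntensityMatrix:
    """Read a probe x array intensity TSV plus a probe->gene annotation TSV.

    Probes missing from the annotation are dropped with a warning; a
    non-positive intensity is a hard error (it would break CV/MFC and log
    transforms downstream).
    """
    path, annotation_path = Path(path), Path(annotation_path)
    mat = pd.read_csv(path, sep=sep, index_col=0)
    ann = pd.read_csv(annotation_path, sep=sep, dtype=str)
    if not {"probe", "gene"}.issubset(ann.columns):
        raise ValueError(f"{annotation_path}: needs columns 'probe' and 'gene'")
    probe_to_gene = dict(zip(ann["probe"], ann["gene"]))
    mat.index = mat.index.astype(str)

    unannotated = [p for p in mat.index if p not in probe_to_gene]
    if unannotated:
        warnings.warn(
            f"dropping {len(unannotated)} probe(s) without gene annotation: "
            f"{unannotated}",
            stacklevel=2,
        )
        mat = mat.drop(index=unannotated)
    vals = mat.to_numpy(dtype=float)
    if vals.size and ((vals <= 0).any() or not np.isfinite(vals).all()):
        raise ValueError(f"{path}: intensities must be finite and > 0")
    return IntensityMatrix(mat, {p: probe_to_gene[p] for p in mat.index})


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_result_tables(
    result: Any,
    out_dir: str | Path,
    name: str | None = None,
    decimals: int = 4,
) -> list[Path]:
    """Serialize a result object to deterministic TSV + JSON files.

    Any object exposing ``to_frame()`` (all result types in this package do)
    gets a TSV with floats rounded to ``decimals`` places, sorted by its
    natural order; the JSON twin carries the same rounded values plus
    metadata.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    name = name or type(result).__name__.lower()

    if hasattr(result, "to_frame"):
        frame = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        frame = result
    else:
        raise TypeError(f"cannot serialize object of type {type(result).__name__}")
    frame = frame.round(decimals)

    tsv = out_dir / f"{name}.tsv"
    frame.to_csv(tsv, sep="\t", float_format=f"%.{decimals}f")
    js = out_dir / f"{name}.json"
    payload = _to_jsonable(result) if not isinstance(result, pd.DataFrame) else None
    body = {
        "name": name,
        "decimals": decimals,
        "table": json.loads(frame.to_json(orient="split")),
    }
    if payload is not None and isinstance(payload, dict):
        body["object"] = payload
    js.write_text(json.dumps(body, indent=1, allow_nan=False, default=str) + "\n")
    return [tsv, js]


def write_manifest(
    out_dir: str | Path, config: dict[str, Any], seed: int | None = None
) -> Path:
    """Write a run-level manifest (config hash, seed, package versions)."""
    import refstab

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(_to_jsonable(config), sort_keys=True)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "refstab": refstab.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1) + "\n")
    return path
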