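"""CSV readers/writers, config files and the run manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .schema import FeatureSchema, default_schema
from .table import DEMOGRAPHIC_COLUMNS, GaitFeatureTable

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "load_config",
    "write_manifest",
]


def write_feature_table(table: GaitFeatureTable, path: str | Path) -> Path:
    """Write a feature table as UTF-8 CSV ('.' decimal separator)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False, encoding="utf-8")
    return path


def read_feature_table(path: str | Path, schema: FeatureSchema | None = None) -> GaitFeatureTable:
    """Read and validate a feature-table CSV.

    Columns are reconciled to schema order by name; missing/extra feature
    columns and non-numeric cells are reported explicitly.
    """
    schema = schema or default_schema()
    # round_trip parsing keeps write->read->write byte-identical
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in ("subject_id", "label", *schema.names) if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {missing}")
    known = {"subject_id", "label", *schema.names, *DEMOGRAPHIC_COLUMNS}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        raise ValueError(f"{path}: unexpected column(s): {extra}")
    for col in schema.names:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()].tolist()
        if bad or coerced.isna().any():
            rows = bad or frame.index[coerced.isna()].tolist()
            raise ValueError(f"{path}: non-numeric or missing value in column {col!r}, row(s) {rows[:5]}")
        frame[col] = coerced
    return GaitFeatureTable(frame, schema)


def load_config(path: str | Path) -> dict:
    """Flat YAML config file (also accepts JSON, a YAML subset)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: dict,
    seeds: list[int],
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> Path:
    """Write the run manifest (resolved config, seeds, digests, outputs)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "sigfall",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "config": config,
        "seeds": list(seeds),
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    return path
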