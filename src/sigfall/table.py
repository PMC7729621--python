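"""Subject-level gait feature table: 27 characteristics plus a faller label."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import FeatureSchema, default_schema

__all__ = ["GaitFeatureTable", "FALLER", "NON_FALLER", "DEMOGRAPHIC_COLUMNS"]

FALLER = "faller"
NON_FALLER = "non_faller"
DEMOGRAPHIC_COLUMNS = ("age", "height_m", "mass_kg", "bmi", "sex")


@dataclass
class GaitFeatureTable:
    """One row per subject: id, binary faller label, 27 gait characteristics.

    The feature columns of ``data`` always appear in schema order; the
    faller group is the positive class throughout the package.  Optional
    demographic columns (age, height_m, mass_kg, bmi, sex) may follow the
    features.
    """

    data: pd.DataFrame
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        required = ["subject_id", "label", *self.schema.names]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad = set(self.data["label"]) - {FALLER, NON_FALLER}
        if bad:
            raise ValueError(f"unknown label values: {sorted(bad)}")
        feats = self.data[list(self.schema.names)]
        if not np.isfinite(feats.to_numpy(dtype=float)).all():
            raise ValueError("non-finite feature values")
        # canonical column order: id, label, features, demographics, extras
        extras = [c for c in self.data.columns if c not in required]
        demo = [c for c in DEMOGRAPHIC_COLUMNS if c in extras]
        other = [c for c in extras if c not in DEMOGRAPHIC_COLUMNS]
        self.data = self.data[required + demo + other].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> np.ndarray:
        """(n_subjects, 27) float matrix in schema order."""
        return self.data[list(self.schema.names)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """Binary vector; 1 = faller (positive class)."""
        return (self.data["label"] == FALLER).to_numpy(dtype=int)

    @property
    def has_demographics(self) -> bool:
        return all(c in self.data.columns for c in DEMOGRAPHIC_COLUMNS)

    def group(self, label: str) -> np.ndarray:
        """Feature matrix restricted to one label group."""
        mask = (self.data["label"] == label).to_numpy()
        return self.features[mask]
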