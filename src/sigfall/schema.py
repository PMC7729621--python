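"""Canonical schema of the 27 spatiotemporal gait characteristics.

Wearable-sensor gait assessments of a 20 m walk summarise each subject by
the per-walk mean and stride-to-stride standard deviation of eleven
spatiotemporal characteristics, plus five scalar summaries (step count,
phase-symmetry ratios and overall gait-cycle variability).  The column
order is fixed: downstream path-signature features depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["FeatureSchema", "default_schema", "N_FEATURES"]

N_FEATURES = 27

# (characteristic stem, unit) for the eleven mean/SD pairs
_PAIRED = [
    ("stride_duration", "s"),
    ("stride_length", "m"),
    ("stride_velocity", "m/s"),
    ("stance_time", "s"),
    ("swing_time", "s"),
    ("stance_phase_pct", "%"),
    ("swing_phase_pct", "%"),
    ("single_support_time", "s"),
    ("heel_strike_angle", "deg"),
    ("toe_off_angle", "deg"),
    ("circumduction", "m"),
]

_SCALAR = [
    ("number_of_steps", "count"),
    ("stance_phase_symmetry", "dimensionless"),
    ("swing_phase_symmetry", "dimensionless"),
    ("gait_cycle_variability_spatial", "%"),
    ("gait_cycle_variability_temporal", "%"),
]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered set of gait-characteristic names with their units.

    Parameters
    ----------
    names
        Ordered, unique characteristic identifiers.
    units
        Mapping from name to unit string.
    """

    names: tuple[str, ...]
    units: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        missing = [n for n in self.names if n not in self.units]
        if missing:
            raise ValueError(f"units missing for: {missing}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_schema() -> FeatureSchema:
    """Return the canonical 27-characteristic schema.

    Mean and stride-to-stride SD of each of the eleven paired
    characteristics (paired in listing order), followed by the five scalar
    summaries.
    """
    names: list[str] = []
    units: dict[str, str] = {}
    for stem, unit in _PAIRED:
        for suffix in ("mean", "sd"):
            name = f"{stem}_{suffix}"
            names.append(name)
            units[name] = unit
    for name, unit in _SCALAR:
        names.append(name)
        units[name] = unit
    assert len(names) == N_FEATURES
    return FeatureSchema(names=tuple(names), units=units)
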