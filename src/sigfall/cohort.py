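"""Synthetic faller / non-faller cohort generator.

Emulates the statistical structure of a clinical inpatient gait cohort
(n = 190 non-fallers, 159 fallers): 27 correlated, differently-scaled gait
characteristics, group mean shifts expressed as standardised effects in
non-faller SD units, block correlation between related characteristics,
optionally lognormal (right-skewed) variability measures, and Table-style
demographics.  All randomness flows from the integer seed in the config.

The non-faller group is the reference distribution; faller feature j is
shifted by ``effect_profile[j] * base_sd[j]``.  A Gaussian copula supplies
the correlation; lognormal marginals are moment-matched so configured
means/SDs (and shifted faller means) are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import FeatureSchema, default_schema
from .table import FALLER, NON_FALLER, GaitFeatureTable

__all__ = [
    "CohortConfig",
    "default_effect_profile",
    "default_base_moments",
    "default_correlation_blocks",
    "build_correlation_matrix",
    "generate_cohort",
    "generate_demographics",
]

# Direction of the faller - non-faller difference for each characteristic
# with a reported group difference: fallers walk more slowly with shorter
# strides, reduced heel-strike angle, shorter swing phase and swing-phase
# symmetry and less circumduction; they show longer stride/stance durations,
# more steps, larger toe-off angle, higher timing variability and higher
# stance-phase symmetry.
EFFECT_SIGNS: dict[str, int] = {
    "stride_velocity_mean": -1,
    "stride_length_mean": -1,
    "heel_strike_angle_mean": -1,
    "swing_phase_pct_mean": -1,
    "swing_phase_symmetry": -1,
    "circumduction_mean": -1,
    "circumduction_sd": -1,
    "stride_duration_mean": +1,
    "stride_duration_sd": +1,
    "stride_length_sd": +1,
    "stance_time_mean": +1,
    "stance_time_sd": +1,
    "swing_time_sd": +1,
    "single_support_time_sd": +1,
    "toe_off_angle_mean": +1,
    "number_of_steps": +1,
    "stance_phase_symmetry": +1,
}

DEFAULT_EFFECT_MAGNITUDE = 0.3

# Physiologically plausible slow clinical gait (20 m walk), (mean, SD).
_BASE_MOMENTS: dict[str, tuple[float, float]] = {
    "stride_duration_mean": (1.25, 0.15),
    "stride_duration_sd": (0.08, 0.03),
    "stride_length_mean": (1.10, 0.25),
    "stride_length_sd": (0.06, 0.02),
    "stride_velocity_mean": (0.90, 0.25),
    "stride_velocity_sd": (0.08, 0.03),
    "stance_time_mean": (0.80, 0.12),
    "stance_time_sd": (0.05, 0.02),
    "swing_time_mean": (0.45, 0.06),
    "swing_time_sd": (0.03, 0.01),
    "stance_phase_pct_mean": (62.0, 3.0),
    "stance_phase_pct_sd": (2.0, 0.8),
    "swing_phase_pct_mean": (38.0, 3.0),
    "swing_phase_pct_sd": (2.0, 0.8),
    "single_support_time_mean": (0.42, 0.06),
    "single_support_time_sd": (0.03, 0.01),
    "heel_strike_angle_mean": (12.0, 5.0),
    "heel_strike_angle_sd": (2.5, 1.0),
    "toe_off_angle_mean": (32.0, 7.0),
    "toe_off_angle_sd": (3.0, 1.2),
    "circumduction_mean": (0.030, 0.015),
    "circumduction_sd": (0.010, 0.005),
    "number_of_steps": (36.0, 6.0),
    "stance_phase_symmetry": (1.00, 0.06),
    "swing_phase_symmetry": (1.00, 0.06),
    "gait_cycle_variability_spatial": (2.5, 1.0),
    "gait_cycle_variability_temporal": (2.5, 1.0),
}

DEFAULT_SKEW_FEATURES = (
    "gait_cycle_variability_spatial",
    "gait_cycle_variability_temporal",
)

# Table-style demographics per group: (mean, sd) and male counts.
DEMOGRAPHICS = {
    NON_FALLER: {"age": (61.6, 12.2), "height_m": (1.73, 0.10), "mass_kg": (81.89, 16.35), "n_male": 115, "n": 190},
    FALLER: {"age": (65.0, 12.7), "height_m": (1.70, 0.10), "mass_kg": (76.31, 14.87), "n_male": 88, "n": 159},
}
_PHYSIOLOGIC_BOUNDS = {"age": (18.0, 100.0), "height_m": (1.30, 2.20), "mass_kg": (35.0, 160.0)}


def default_effect_profile(
    schema: FeatureSchema | None = None, magnitude: float = DEFAULT_EFFECT_MAGNITUDE
) -> dict[str, float]:
    """Signed standardised mean differences (faller − non-faller), default |z| = 0.3."""
    schema = schema or default_schema()
    return {n: magnitude * EFFECT_SIGNS.get(n, 0) for n in schema.names}


def default_base_moments(schema: FeatureSchema | None = None) -> dict[str, tuple[float, float]]:
    schema = schema or default_schema()
    return {n: _BASE_MOMENTS[n] for n in schema.names}


def default_correlation_blocks(schema: FeatureSchema | None = None) -> dict[str, list[str]]:
    """Three correlated blocks: pace, phase/timing, variability."""
    schema = schema or default_schema()
    pace = ["stride_duration_mean", "stride_length_mean", "stride_velocity_mean", "number_of_steps"]
    variability = [n for n in schema.names if n.endswith("_sd") or "variability" in n]
    phase = [n for n in schema.names if n not in pace and n not in variability]
    return {"pace": pace, "phase_timing": phase, "variability": variability}


def build_correlation_matrix(
    schema: FeatureSchema,
    blocks: dict[str, list[str]],
    r_within: float = 0.7,
    r_between: float = 0.2,
) -> np.ndarray:
    """Block-exchangeable correlation matrix over the schema features."""
    p = len(schema)
    corr = np.full((p, p), r_between)
    index = {n: i for i, n in enumerate(schema.names)}
    for members in blocks.values():
        ii = [index[n] for n in members]
        for a in ii:
            for b in ii:
                if a != b:
                    corr[a, b] = r_within
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CohortConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_non_fallers: int = 190
    n_fallers: int = 159
    effect_profile: dict[str, float] = field(default_factory=default_effect_profile)
    base_moments: dict[str, tuple[float, float]] = field(default_factory=default_base_moments)
    correlation_blocks: dict[str, list[str]] = field(default_factory=default_correlation_blocks)
    r_within: float = 0.7
    r_between: float = 0.2
    correlation_matrix: np.ndarray | None = None  # overrides the block spec
    skew_features: tuple[str, ...] = DEFAULT_SKEW_FEATURES
    with_demographics: bool = True
    seed: int = 0
    schema: FeatureSchema = field(default_factory=default_schema)

    def resolve_correlation(self) -> np.ndarray:
        if self.correlation_matrix is not None:
            corr = np.asarray(self.correlation_matrix, dtype=float)
        else:
            corr = build_correlation_matrix(
                self.schema, self.correlation_blocks, self.r_within, self.r_between
            )
        if corr.shape != (len(self.schema),) * 2:
            raise ValueError("correlation matrix shape does not match schema")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(corr).max() > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite (min eigenvalue {eigmin:.3g})"
            )
        return corr

    def validate(self) -> None:
        if self.n_non_fallers < 0 or self.n_fallers < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_non_fallers + self.n_fallers == 0:
            raise ValueError("cohort must contain at least one subject")
        for name in self.schema.names:
            mean, sd = self.base_moments[name]
            if sd <= 0:
                raise ValueError(f"base SD must be positive for {name}")
            if name in self.skew_features and mean <= 0:
                raise ValueError(f"lognormal feature {name} needs a positive mean")
        unknown = set(self.effect_profile) - set(self.schema.names)
        if unknown:
            raise ValueError(f"effect profile names not in schema: {sorted(unknown)}")
        self.resolve_correlation()


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment matching: X = exp(mu + sigma Z) with E X = mean, SD X = sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(config: CohortConfig | None = None) -> GaitFeatureTable:
    """Draw a synthetic cohort with the configured structure.

    Non-faller features follow the base distribution with the configured
    correlation; faller feature ``j`` is mean-shifted by
    ``effect_profile[j] * base_sd[j]`` (for lognormal features the target
    mean is shifted, the SD kept, via re-matched moments).
    """
    config = config or CohortConfig()
    config.validate()
    schema = config.schema
    corr = config.resolve_correlation()
    rng = np.random.default_rng(config.seed)

    # PSD-safe transform (handles rank-deficient correlation, e.g. r = 1)
    eigval, eigvec = np.linalg.eigh(corr)
    transform = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))

    rows = []
    for label, n in ((NON_FALLER, config.n_non_fallers), (FALLER, config.n_fallers)):
        z = rng.standard_normal((n, len(schema))) @ transform.T
        x = np.empty_like(z)
        for j, name in enumerate(schema.names):
            mean, sd = config.base_moments[name]
            shift = config.effect_profile.get(name, 0.0) * sd if label == FALLER else 0.0
            if name in config.skew_features:
                mu, sigma = _lognormal_params(mean + shift, sd)
                x[:, j] = np.exp(mu + sigma * z[:, j])
            else:
                x[:, j] = mean + shift + sd * z[:, j]
        rows.append((label, x))

    n_total = config.n_non_fallers + config.n_fallers
    width = len(str(n_total))
    frame = pd.DataFrame(
        np.vstack([x for _, x in rows]), columns=list(schema.names)
    )
    frame.insert(0, "subject_id", [f"S{i + 1:0{width}d}" for i in range(n_total)])
    frame.insert(
        1,
        "label",
        [NON_FALLER] * config.n_non_fallers + [FALLER] * config.n_fallers,
    )
    table = GaitFeatureTable(frame, schema)
    if config.with_demographics:
        table = generate_demographics(table, config)
    return table


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_demographics(table: GaitFeatureTable, config: CohortConfig) -> GaitFeatureTable:
    """Attach age / height / mass / BMI / sex columns sampled per group.

    Age, height and mass are normal within physiologic bounds
    (out-of-range draws are resampled); BMI is derived as mass/height² so
    its group means only approximately match printed cohort BMI values;
    sex is Bernoulli with the cohort male fractions (115/190, 88/159).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    data = table.data.copy()
    for col in ("age", "height_m", "mass_kg", "bmi", "sex"):
        data[col] = 0.0 if col != "sex" else ""
    for label, params in DEMOGRAPHICS.items():
        mask = (data["label"] == label).to_numpy()
        n = int(mask.sum())
        for col in ("age", "height_m", "mass_kg"):
            mean, sd = params[col]
            lo, hi = _PHYSIOLOGIC_BOUNDS[col]
            data.loc[mask, col] = _truncated_normal(rng, mean, sd, lo, hi, n)
        p_male = params["n_male"] / params["n"]
        data.loc[mask, "sex"] = np.where(rng.random(n) < p_male, "M", "F")
    data["bmi"] = data["mass_kg"] / data["height_m"] ** 2
    return GaitFeatureTable(data, table.schema)
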