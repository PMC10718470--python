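"""Moment-calibrated synthetic lumbar cohorts.

The study cohort this package models is not publicly deposited, so a
generative stand-in is calibrated to its printed per-level summary
statistics.  The model, per vertebral level:

* manual canal area  A ~ Normal(manual_mean, manual_sd^2), truncated at 0
* product P = IPD * AP, regression-linked to A:
      P = slope * A + intercept + Normal(0, noise_sd^2)
  with closed-form parameters
      slope     = r * sd(P) / sd(A)
      intercept = mean(P) - slope * mean(A)
      noise_sd  = sd(P) * sqrt(1 - r^2)
  so that the mean and SD of P and corr(P, A) hit their targets exactly
  in expectation.

The generative direction matters: making A the latent truth and
regressing P on it is the only direction compatible with the printed
moments — an additive-noise model for A given P would force
sd(A) >= slope-scaled sd(P), which the printed SDs contradict.

P is split into IPD and AP by drawing IPD as a positive size variable
(mean ``ipd_mean``, coefficient of variation ``ipd_cv``) and setting
AP = P / IPD, so the product is reproduced exactly.  The source tables
report no IPD/AP marginals; the split is a modeling convenience that
never affects the product, the areas, or any downstream statistic.

Truncation at zero is handled by resampling; at the printed coefficients
of variation (< 0.3) the moment distortion is negligible (the zero
bound sits > 3.5 SDs below every mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import reference
from .geometry import LEVELS, Level

__all__ = [
    "LevelCalibration",
    "CohortSpec",
    "calibrate_from_tables",
    "default_calibrations",
    "load_calibrations",
    "generate_cohort",
    "split_product",
]

_MAX_ATTEMPTS = 1_000_000


@dataclass(frozen=True)
class LevelCalibration:
    """Generative parameters for one vertebral level.

    The slope/intercept/noise_sd fields are derived from the five moment
    targets; construct instances through :func:`calibrate_from_tables`
    so the closed forms stay consistent.
    """

    level: Level | None
    manual_mean: float
    manual_sd: float
    product_mean: float
    product_sd: float
    target_r: float
    slope: float
    intercept: float
    noise_sd: float
    ipd_mean: float = 24.0
    ipd_cv: float = 0.08


def calibrate_from_tables(
    manual_mean: float,
    manual_sd: float,
    product_mean: float,
    product_sd: float,
    target_r: float,
    level: Level | str | None = None,
    ipd_mean: float = 24.0,
    ipd_cv: float = 0.08,
) -> LevelCalibration:
    """Derive regression parameters from printed moments and correlation.

    Moment matching for a bivariate-normal pair (A, P): given the two
    marginal means/SDs and the correlation, the conditional law of P
    given A is linear with the closed-form slope, intercept and residual
    SD stored on the returned calibration.
    """
    if manual_sd <= 0 or product_sd <= 0:
        raise ValueError("standard deviations must be positive")
    if not (0.0 < target_r < 1.0):
        raise ValueError(f"target_r must lie strictly in (0, 1); got {target_r}")
    if manual_mean <= 0 or product_mean <= 0:
        raise ValueError("means must be positive")
    if ipd_mean <= 0 or ipd_cv <= 0:
        raise ValueError("ipd_mean and ipd_cv must be positive")
    slope = target_r * product_sd / manual_sd
    intercept = product_mean - slope * manual_mean
    noise_sd = product_sd * math.sqrt(1.0 - target_r**2)
    return LevelCalibration(
        level=Level(level) if level is not None else None,
        manual_mean=manual_mean,
        manual_sd=manual_sd,
        product_mean=product_mean,
        product_sd=product_sd,
        target_r=target_r,
        slope=slope,
        intercept=intercept,
        noise_sd=noise_sd,
        ipd_mean=ipd_mean,
        ipd_cv=ipd_cv,
    )


def _calibrations_from_mapping(
    mapping: Mapping[str, Mapping[str, float]]
) -> dict[Level, LevelCalibration]:
    out: dict[Level, LevelCalibration] = {}
    for level_name, params in mapping.items():
        level = Level(level_name)
        out[level] = calibrate_from_tables(
            manual_mean=float(params["manual_mean"]),
            manual_sd=float(params["manual_sd"]),
            product_mean=float(params["product_mean"]),
            product_sd=float(params["product_sd"]),
            target_r=float(params["target_r"]),
            level=level,
            ipd_mean=float(params.get("ipd_mean", 24.0)),
            ipd_cv=float(params.get("ipd_cv", 0.08)),
        )
    return out


def default_calibrations() -> dict[Level, LevelCalibration]:
    """Calibrations for L1-L5 from the packaged reference-cohort config."""
    text = (
        resources.files("canalarea").joinpath("data/calibration.yaml").read_text()
    )
    return _calibrations_from_mapping(yaml.safe_load(text)["levels"])


def load_calibrations(path) -> dict[Level, LevelCalibration]:
    """Calibrations from a user-supplied YAML file (same schema as packaged)."""
    with open(path) as fh:
        return _calibrations_from_mapping(yaml.safe_load(fh)["levels"])


@dataclass(frozen=True)
class CohortSpec:
    """What to simulate: cohort size, levels, seed, policies."""

    n_patients: int = reference.N_PATIENTS
    levels: tuple[Level, ...] = LEVELS
    seed: int = 0
    positivity_policy: str = "resample"
    demographics: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.positivity_policy not in ("resample", "reject"):
            raise ValueError(
                f"unknown positivity_policy {self.positivity_policy!r}"
            )
        object.__setattr__(
            self, "levels", tuple(Level(l) for l in self.levels)
        )


def split_product(product, ipd):
    """Split a product IPD * AP into its factors given IPD.

    Returns ``(ipd, ap)`` with ``ap = product / ipd`` so that
    ``ipd * ap`` reproduces the product to machine precision.
    """
    p = np.asarray(product, dtype=float)
    i = np.asarray(ipd, dtype=float)
    if np.any(p <= 0):
        raise ValueError("product must be strictly positive")
    if np.any(i <= 0):
        raise ValueError("ipd must be strictly positive")
    ap = p / i
    if np.isscalar(product) and np.isscalar(ipd):
        return float(i), float(ap)
    return i, ap


def _positive_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal sample truncated at zero by resampling offenders."""
    values = rng.normal(mean, sd, n)
    attempts = 0
    while True:
        bad = values <= 0.0
        if not bad.any():
            return values
        attempts += int(bad.sum())
        if attempts > _MAX_ATTEMPTS:
            raise RuntimeError(
                "positivity resampling exceeded the attempt budget; "
                "check the calibration moments"
            )
        values[bad] = rng.normal(mean, sd, int(bad.sum()))


def _simulate_level(
    rng: np.random.Generator, cal: LevelCalibration, n: int, policy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (manual area, product) for one level under a positivity policy.

    ``resample`` redraws only the offending noise term (preserving the
    accepted manual areas); ``reject`` discards the whole (area, noise)
    pair and redraws it jointly.
    """
    area = _positive_normal(rng, cal.manual_mean, cal.manual_sd, n)
    noise = rng.normal(0.0, cal.noise_sd, n)
    product = cal.slope * area + cal.intercept + noise
    attempts = 0
    while True:
        bad = product <= 0.0
        if not bad.any():
            return area, product
        k = int(bad.sum())
        attempts += k
        if attempts > _MAX_ATTEMPTS:
            raise RuntimeError(
                "positivity handling exceeded the attempt budget; "
                "check the calibration moments"
            )
        if policy == "reject":
            area[bad] = _positive_normal(rng, cal.manual_mean, cal.manual_sd, k)
        product[bad] = (
            cal.slope * area[bad] + cal.intercept + rng.normal(0.0, cal.noise_sd, k)
        )


def _simulate_demographics(rng: np.random.Generator, n: int) -> pd.DataFrame:
    d = reference.DEMOGRAPHICS
    p_female = d["n_female"] / (d["n_female"] + d["n_male"])
    sex = np.where(rng.random(n) < p_female, "F", "M")
    lo, hi = d["age_range"]
    # age: normal at the printed mean, clipped into the recruitment window
    # by resampling; SD chosen to roughly fill the 18-35 range.
    age = rng.normal(d["age_mean"], 5.0, n)
    while True:
        bad = (age < lo) | (age > hi)
        if not bad.any():
            break
        age[bad] = rng.normal(d["age_mean"], 5.0, int(bad.sum()))
    height = _positive_normal(rng, d["height_mean_m"], d["height_sd_m"], n)
    weight = _positive_normal(rng, d["weight_mean_kg"], d["weight_sd_kg"], n)
    bmi = _positive_normal(rng, d["bmi_mean"], d["bmi_sd"], n)
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "height": height,
            "weight": weight,
            "bmi": bmi,
        }
    )


_BASE_COLUMNS = ["patient_id", "level", "ipd_mm", "ap_mm", "canal_area_mm2"]
_DEMO_COLUMNS = ["sex", "age", "height", "weight", "bmi"]


def generate_cohort(
    spec: CohortSpec,
    calibrations: Mapping[Level, LevelCalibration] | None = None,
) -> pd.DataFrame:
    """Simulate a cohort: one row per patient x requested level.

    Deterministic given ``spec.seed``.  Returns a long-format DataFrame
    in the shared CSV schema, sorted by patient then level.
    """
    if calibrations is None:
        calibrations = default_calibrations()
    missing = [l.value for l in spec.levels if l not in calibrations]
    if missing:
        raise ValueError(f"no calibration for level(s): {missing}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patient_ids = np.array([f"P{i + 1:05d}" for i in range(n)])
    demo = _simulate_demographics(rng, n) if spec.demographics else None

    blocks: list[pd.DataFrame] = []
    for level in sorted(spec.levels, key=lambda l: l.value):
        cal = calibrations[level]
        area, product = _simulate_level(rng, cal, n, spec.positivity_policy)
        ipd = _positive_normal(rng, cal.ipd_mean, cal.ipd_cv * cal.ipd_mean, n)
        ipd, ap = split_product(product, ipd)
        block = pd.DataFrame(
            {
                "patient_id": patient_ids,
                "level": level.value,
                "ipd_mm": ipd,
                "ap_mm": ap,
                "canal_area_mm2": area,
            }
        )
        if demo is not None:
            block = pd.concat([block, demo.set_index(block.index)], axis=1)
        blocks.append(block)

    columns = _BASE_COLUMNS if demo is None else (
        ["patient_id"] + _DEMO_COLUMNS + _BASE_COLUMNS[1:]
    )
    if not blocks:
        return pd.DataFrame(columns=columns)
    table = pd.concat(blocks, ignore_index=True)
    table = table.sort_values(["patient_id", "level"], kind="stable")
    return table[columns].reset_index(drop=True)
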