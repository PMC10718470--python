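"""CSV input/output and the study-style text report.

The shared cohort schema is a long-format, comma-separated, UTF-8 table
with a mandatory header and one row per patient x level:

    patient_id, [sex, age, height, weight, bmi,] level, ipd_mm, ap_mm,
    canal_area_mm2

Data files keep full floating precision; the rounding that mimics the
published tables (2 decimals for areas and percents, 3 for correlations,
p rendered "<0.001" below 1e-3) is applied only when rendering the
report.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .agreement import AgreementResult
from .geometry import LEVELS, SHAPES, Level
from .second_order import SecondOrderFit

__all__ = [
    "REQUIRED_COLUMNS",
    "DEMOGRAPHIC_COLUMNS",
    "read_cohort",
    "write_cohort",
    "build_report",
    "report_records",
    "format_p",
]

REQUIRED_COLUMNS = ("patient_id", "level", "ipd_mm", "ap_mm", "canal_area_mm2")
DEMOGRAPHIC_COLUMNS = ("sex", "age", "height", "weight", "bmi")
_NUMERIC_COLUMNS = ("ipd_mm", "ap_mm", "canal_area_mm2")
_VALID_LEVELS = {l.value for l in LEVELS}


class CohortValidationError(ValueError):
    """A cohort file violated the shared schema."""


def _row_number(df: pd.DataFrame, mask) -> int:
    """1-based file row (header is row 1) of the first offending record."""
    return int(df.index[mask][0]) + 2


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortValidationError` naming the first offending row
    and field on any schema violation: a missing column, an unknown
    level, a duplicate (patient_id, level) pair, or a non-numeric or
    non-positive measurement.
    """
    # round_trip parsing: files carry shortest-repr floats and must load
    # back bit-identically (display rounding happens only in the report)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")
    if len(df) == 0:
        return df
    df = df.reset_index(drop=True)
    level_str = df["level"].astype(str)
    bad_level = ~level_str.isin(_VALID_LEVELS)
    if bad_level.any():
        row = _row_number(df, bad_level)
        raise CohortValidationError(
            f"row {row}: field 'level' has unknown value "
            f"{df.loc[row - 2, 'level']!r}"
        )
    dup = df.duplicated(subset=["patient_id", "level"])
    if dup.any():
        row = _row_number(df, dup)
        raise CohortValidationError(
            f"row {row}: duplicate (patient_id, level) pair "
            f"({df.loc[row - 2, 'patient_id']!r}, {df.loc[row - 2, 'level']!r})"
        )
    for col in _NUMERIC_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        not_numeric = values.isna()
        if not_numeric.any():
            row = _row_number(df, not_numeric)
            raise CohortValidationError(
                f"row {row}: field '{col}' is not numeric "
                f"({df.loc[row - 2, col]!r})"
            )
        nonpositive = values <= 0
        if nonpositive.any():
            row = _row_number(df, nonpositive)
            raise CohortValidationError(
                f"row {row}: field '{col}' must be strictly positive "
                f"(got {values[row - 2]})"
            )
        df[col] = values.astype(float)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV at full floating precision."""
    cohort.to_csv(path, index=False)


def format_p(p: float) -> str:
    """Render a p-value the way the published tables do."""
    if p < 1e-3:
        return "<0.001"
    return f"{p:.3f}"


def _fmt_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.2f}±{sd:.2f}"


def _ordered(results: Sequence[AgreementResult]) -> list[AgreementResult]:
    level_rank = {l: i for i, l in enumerate(LEVELS)}
    shape_rank = {s: i for i, s in enumerate(SHAPES)}
    return sorted(results, key=lambda r: (level_rank[r.level], shape_rank[r.shape]))


def build_report(
    results: Sequence[AgreementResult],
    fits: Sequence[SecondOrderFit] | None = None,
) -> str:
    """Render the per-level mean, agreement, and percent-error tables.

    Layout is deterministic: levels L1->L5, shapes
    ellipse/triangle/rectangle.  An optional second-order block is
    appended when fits are given.
    """
    if not results:
        raise ValueError("no agreement results to report")
    results = _ordered(results)
    by_level: dict[Level, dict] = {}
    for r in results:
        by_level.setdefault(r.level, {})[r.shape.value] = r

    lines: list[str] = []
    lines.append("Mean area by level (mm^2, mean±SD)")
    header = f"{'Level':<6}{'Manual':>16}{'Ellipse':>16}{'Triangle':>16}{'Rectangle':>16}"
    lines.append(header)
    for level, shapes in by_level.items():
        any_r = next(iter(shapes.values()))
        cells = [f"{level.value:<6}", f"{_fmt_mean_sd(any_r.mean_manual, any_r.sd_manual):>16}"]
        for shape in SHAPES:
            r = shapes.get(shape.value)
            cells.append(
                f"{_fmt_mean_sd(r.mean_estimate, r.sd_estimate):>16}" if r else f"{'-':>16}"
            )
        lines.append("".join(cells))

    lines.append("")
    lines.append("Agreement with manual measurement (difference = estimate - manual)")
    lines.append(
        f"{'Level':<6}{'Shape':<11}{'MD±SD (mm^2)':>16}{'t':>10}{'p':>9}{'r':>8}"
    )
    for r in results:
        lines.append(
            f"{r.level.value:<6}{r.shape.value:<11}"
            f"{_fmt_mean_sd(r.mean_difference, r.sd_difference):>16}"
            f"{r.t_statistic:>10.2f}{format_p(r.p_value):>9}{r.pearson_r:>8.3f}"
        )

    lines.append("")
    lines.append("Percent error vs manual measurement")
    lines.append(f"{'Level':<6}{'Ellipse':>10}{'Triangle':>10}{'Rectangle':>10}")
    for level, shapes in by_level.items():
        cells = [f"{level.value:<6}"]
        for shape in SHAPES:
            r = shapes.get(shape.value)
            cells.append(f"{r.percent_error:>9.2f}%" if r else f"{'-':>10}")
        lines.append("".join(cells))

    if fits:
        lines.append("")
        lines.append("Second-order scale factor (area ≈ k̂ · IPD · AP)")
        lines.append(
            f"{'Level':<8}{'k_hat':>8}{'w_ellipse':>11}{'w_triangle':>12}"
            f"{'train RMSE':>12}{'CV RMSE':>10}{'folds':>7}"
        )
        for f in fits:
            name = f.level.value if f.level is not None else "pooled"
            flag = " *" if f.extrapolating else ""
            lines.append(
                f"{name:<8}{f.k_hat:>8.4f}{f.ellipse_weight:>11.3f}"
                f"{f.triangle_weight:>12.3f}{f.training_rmse:>12.2f}"
                f"{f.cv_rmse:>10.2f}{f.cv_folds:>7d}{flag}"
            )
        if any(f.extrapolating for f in fits):
            lines.append("* weights extrapolate outside the ellipse-triangle bracket")

    return "\n".join(lines) + "\n"


def report_records(
    results: Sequence[AgreementResult],
    fits: Sequence[SecondOrderFit] | None = None,
) -> pd.DataFrame:
    """Machine-readable long form of the report: one statistic per row."""
    if not results:
        raise ValueError("no agreement results to report")
    rows: list[dict] = []
    for r in _ordered(results):
        base = {"level": r.level.value, "shape": r.shape.value}
        for stat in (
            "n",
            "mean_manual",
            "sd_manual",
            "mean_estimate",
            "sd_estimate",
            "mean_difference",
            "sd_difference",
            "t_statistic",
            "p_value",
            "percent_error",
            "pearson_r",
        ):
            rows.append({**base, "statistic": stat, "value": getattr(r, stat)})
    if fits:
        for f in fits:
            base = {
                "level": f.level.value if f.level is not None else "pooled",
                "shape": "second_order",
            }
            for stat in (
                "n",
                "k_hat",
                "ellipse_weight",
                "triangle_weight",
                "training_rmse",
                "cv_rmse",
                "cv_folds",
            ):
                rows.append({**base, "statistic": stat, "value": getattr(f, stat)})
    return pd.DataFrame(rows)
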