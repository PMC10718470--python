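"""Agreement between shape estimators and the measured canal area.

For each vertebral level and shape the module computes the statistics of
a classical method-comparison analysis: mean difference (estimate minus
manual) with its SD, a two-sided paired t-test on the differences, a
signed percent error, and the Pearson correlation between estimated and
measured areas.

Percent error has two conventions:

* ``aggregate`` (default) — 100 * (mean estimate - mean manual) / mean
  manual, i.e. the ratio of the mean difference to the mean reference
  area.  This is the convention whose values are internally consistent
  with the mean-difference tables (percent error == 100 * MD / mean
  manual).
* ``per_subject`` — the mean over subjects of the per-subject relative
  error.  Generally differs from the aggregate value.

Sample statistics use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    LEVELS,
    SHAPES,
    Level,
    LevelMeasurement,
    Shape,
    approximate_area,
)

__all__ = [
    "AgreementResult",
    "PairedTResult",
    "mean_difference",
    "percent_error",
    "paired_t",
    "pearson_r",
    "evaluate_level",
    "evaluate_cohort",
]


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class AgreementResult:
    """Agreement statistics for one level x one shape."""

    level: Level
    shape: Shape
    n: int
    mean_manual: float
    sd_manual: float
    mean_estimate: float
    sd_estimate: float
    mean_difference: float
    sd_difference: float
    t_statistic: float
    p_value: float
    percent_error: float
    pearson_r: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["level"] = self.level.value
        d["shape"] = self.shape.value
        return d


def mean_difference(estimates, manuals) -> tuple[float, float]:
    """Mean and SD (n-1) of paired differences estimate - manual."""
    est = np.asarray(estimates, dtype=float)
    man = np.asarray(manuals, dtype=float)
    if est.shape != man.shape:
        raise ValueError("estimates and manuals must have equal length")
    if est.size < 2:
        raise ValueError("need at least 2 pairs (SD undefined otherwise)")
    diff = est - man
    return float(np.mean(diff)), float(np.std(diff, ddof=1))


def percent_error(estimates, manuals, mode: str = "aggregate") -> float:
    """Signed percent error of the estimates relative to the manual areas.

    In ``aggregate`` mode the arguments may be the two series or the two
    means; only the means enter the formula.  In ``per_subject`` mode
    both arguments must be full series.
    """
    est = np.atleast_1d(np.asarray(estimates, dtype=float))
    man = np.atleast_1d(np.asarray(manuals, dtype=float))
    if mode == "aggregate":
        mean_manual = float(np.mean(man))
        if mean_manual <= 0:
            raise ValueError(
                f"mean manual area must be positive (got {mean_manual})"
            )
        return float(100.0 * (np.mean(est) - mean_manual) / mean_manual)
    if mode == "per_subject":
        if est.shape != man.shape:
            raise ValueError("per_subject mode needs paired series")
        if np.any(man <= 0):
            raise ValueError("manual areas must be positive")
        return float(np.mean(100.0 * (est - man) / man))
    raise ValueError(f"unknown percent-error mode {mode!r}")


def paired_t(differences) -> PairedTResult:
    """Two-sided one-sample t-test of the paired differences against 0."""
    diff = np.asarray(differences, dtype=float)
    n = diff.size
    if n < 2:
        raise ValueError("need at least 2 differences")
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        raise ValueError("differences have zero variance; t-test undefined")
    t = float(np.mean(diff) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedTResult(t=t, df=df, p=p)


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variances."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        raise ValueError("zero-variance input; correlation undefined")
    return float(stats.pearsonr(xa, ya).statistic)


def _evaluate_arrays(
    level: Level,
    shape: Shape,
    ipd: np.ndarray,
    ap: np.ndarray,
    manual: np.ndarray,
    percent_error_mode: str,
) -> AgreementResult:
    estimate = approximate_area(ipd, ap, shape)
    md, sd_d = mean_difference(estimate, manual)
    t, _, p = paired_t(estimate - manual)
    return AgreementResult(
        level=level,
        shape=shape,
        n=int(manual.size),
        mean_manual=float(np.mean(manual)),
        sd_manual=float(np.std(manual, ddof=1)),
        mean_estimate=float(np.mean(estimate)),
        sd_estimate=float(np.std(estimate, ddof=1)),
        mean_difference=md,
        sd_difference=sd_d,
        t_statistic=t,
        p_value=p,
        percent_error=percent_error(estimate, manual, mode=percent_error_mode),
        pearson_r=pearson_r(estimate, manual),
    )


def evaluate_level(
    measurements: Sequence[LevelMeasurement],
    shape: Shape | str,
    percent_error_mode: str = "aggregate",
) -> AgreementResult:
    """Agreement statistics for one shape on measurements of one level."""
    if len(measurements) == 0:
        raise ValueError("no measurements supplied")
    levels = {m.level for m in measurements}
    if len(levels) != 1:
        raise ValueError(
            f"measurements span multiple levels: {sorted(l.value for l in levels)}"
        )
    if any(m.manual_area is None for m in measurements):
        raise ValueError("every measurement needs a manual_area")
    return _evaluate_arrays(
        level=next(iter(levels)),
        shape=Shape(shape),
        ipd=np.array([m.ipd for m in measurements], dtype=float),
        ap=np.array([m.ap for m in measurements], dtype=float),
        manual=np.array([m.manual_area for m in measurements], dtype=float),
        percent_error_mode=percent_error_mode,
    )


def evaluate_cohort(
    cohort: pd.DataFrame,
    shapes: Iterable[Shape | str] = SHAPES,
    percent_error_mode: str = "aggregate",
) -> list[AgreementResult]:
    """Agreement statistics for every present level x requested shape.

    ``cohort`` is a long-format table with columns ``level``, ``ipd_mm``,
    ``ap_mm``, ``canal_area_mm2`` (the shared CSV schema).  Levels are
    processed in cranial-to-caudal order, shapes in the canonical
    ellipse/triangle/rectangle order.
    """
    shapes = [Shape(s) for s in shapes]
    results: list[AgreementResult] = []
    present = set(cohort["level"].astype(str))
    for level in LEVELS:
        if level.value not in present:
            continue
        block = cohort[cohort["level"].astype(str) == level.value]
        ipd = block["ipd_mm"].to_numpy(dtype=float)
        ap = block["ap_mm"].to_numpy(dtype=float)
        manual = block["canal_area_mm2"].to_numpy(dtype=float)
        for shape in shapes:
            results.append(
                _evaluate_arrays(level, shape, ipd, ap, manual, percent_error_mode)
            )
    if not results:
        raise ValueError("cohort contains no rows at any recognised level")
    return results


def results_frame(results: Sequence[AgreementResult]) -> pd.DataFrame:
    """Tidy one-row-per-(level, shape) DataFrame of agreement results."""
    return pd.DataFrame([r.to_dict() for r in results])
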