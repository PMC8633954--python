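"""Bioanalytical method-validation statistics for an LC-MS/MS assay.

Implements the statistics behind a standard bioanalytical validation
report: weighted least-squares calibration of the analyte/internal-standard
response ratio against nominal concentration (weighting 1, 1/x or 1/x^2),
back-calculation, accuracy as relative error RE% = 100*(mean-nominal)/nominal,
precision as RSD% = 100*SD/mean (sample SD), intra- and inter-batch
accuracy/precision blocks with regulatory acceptance flags (15% for QC
levels, 20% at the LLOQ), matrix-effect ratios, carryover checks against a
fraction of the LLOQ response, and stability expressed as percent of
nominal with a 15% acceptance band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationFit",
    "ValidationReport",
    "fit_calibration",
    "back_calculate",
    "relative_error",
    "rsd",
    "precision_accuracy_report",
    "calibration_acceptance",
    "matrix_effect",
    "carryover_check",
    "stability_assessment",
]

WEIGHTINGS = ("none", "1/x", "1/x2")

#: Regulatory acceptance bands (percent) for QC levels and for the LLOQ.
QC_TOLERANCE_PCT = 15.0
LLOQ_TOLERANCE_PCT = 20.0


@dataclass(frozen=True)
class CalibrationFit:
    """Weighted linear calibration y = a*x + b.

    ``y`` is the analyte/IS peak-area ratio, ``x`` the nominal
    concentration; ``r_squared`` is the coefficient of determination of
    the weighted fit (same weights in residual and total sums of squares).
    """

    slope_a: float
    intercept_b: float
    weighting: str
    r_squared: float


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}")


def fit_calibration(
    nominal: Sequence[float],
    response_ratio: Sequence[float],
    weighting: str = "1/x2",
) -> CalibrationFit:
    """Weighted least squares minimizing sum w_i (y_i - a x_i - b)^2."""
    x = np.asarray(nominal, dtype=float)
    y = np.asarray(response_ratio, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired (nominal, response) points")
    if np.any(x <= 0):
        raise ValueError("nominal concentrations must be positive")
    if np.unique(x).size < 2:
        raise ValueError("singular design: all nominal levels identical")
    w = _weights(x, weighting)
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx * sx
    a = (sw * sxy - sx * sy) / denom
    b = (sy - a * sx) / sw
    yhat = a * x + b
    ybar_w = sy / sw
    ss_res = (w * (y - yhat) ** 2).sum()
    ss_tot = (w * (y - ybar_w) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(slope_a=float(a), intercept_b=float(b),
                          weighting=weighting, r_squared=float(r2))


def back_calculate(fit: CalibrationFit, response_ratio) -> float | np.ndarray:
    """Invert the calibration: concentration = (y - b)/a."""
    if fit.slope_a == 0:
        raise ValueError("cannot back-calculate with zero slope")
    y = np.asarray(response_ratio, dtype=float)
    out = (y - fit.intercept_b) / fit.slope_a
    return float(out) if out.ndim == 0 else out


def relative_error(mean_measured: float, nominal: float) -> float:
    """Accuracy as RE% = 100*(mean_measured - nominal)/nominal."""
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    return 100.0 * (mean_measured - nominal) / nominal


def rsd(values: Iterable[float]) -> float:
    """Precision as RSD% = 100 * sample SD / mean (n-1 denominator)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def _level_stats(nominal: float, values: np.ndarray, tolerance: float) -> dict:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    level_rsd = float(100.0 * sd / mean) if mean != 0 else np.nan
    re = relative_error(mean, nominal)
    ok = abs(re) <= tolerance and (np.isnan(level_rsd) or level_rsd <= tolerance)
    return {
        "nominal": nominal,
        "n": int(values.size),
        "mean": mean,
        "sd": sd,
        "rsd_pct": level_rsd,
        "re_pct": re,
        "tolerance_pct": tolerance,
        "accepted": bool(ok),
    }


@dataclass(frozen=True)
class ValidationReport:
    """Intra/inter-batch accuracy-precision blocks plus acceptance flags."""

    intra_batch: pd.DataFrame
    inter_batch: pd.DataFrame
    all_accepted: bool

    def to_text(self) -> str:
        lines = ["Intra-batch accuracy and precision", "-" * 40,
                 self.intra_batch.to_string(index=False), "",
                 "Inter-batch accuracy and precision (replicates pooled over batches)",
                 "-" * 40, self.inter_batch.to_string(index=False), "",
                 f"Overall acceptance: {'PASS' if self.all_accepted else 'FAIL'}"]
        return "\n".join(lines)


def precision_accuracy_report(
    qc: pd.DataFrame,
    lloq_level: float | None = None,
    qc_tolerance_pct: float = QC_TOLERANCE_PCT,
    lloq_tolerance_pct: float = LLOQ_TOLERANCE_PCT,
) -> ValidationReport:
    """Intra- and inter-batch accuracy/precision from QC replicates.

    ``qc`` has columns ``nominal``, ``batch``, ``measured``.  Intra-batch
    rows are per (nominal, batch); inter-batch rows pool every replicate
    of a level across all batches.  Levels equal to ``lloq_level`` are
    judged at the wider LLOQ tolerance.
    """
    required = {"nominal", "batch", "measured"}
    missing = required - set(qc.columns)
    if missing:
        raise ValueError(f"QC table missing columns: {sorted(missing)}")

    def tol(level: float) -> float:
        return lloq_tolerance_pct if lloq_level is not None and level == lloq_level \
            else qc_tolerance_pct

    intra_rows = []
    for (level, batch), grp in qc.groupby(["nominal", "batch"], sort=True):
        row = _level_stats(float(level), grp["measured"].to_numpy(float), tol(level))
        row["batch"] = batch
        intra_rows.append(row)
    inter_rows = []
    for level, grp in qc.groupby("nominal", sort=True):
        inter_rows.append(
            _level_stats(float(level), grp["measured"].to_numpy(float), tol(level))
        )
    intra = pd.DataFrame(intra_rows)[
        ["nominal", "batch", "n", "mean", "sd", "rsd_pct", "re_pct",
         "tolerance_pct", "accepted"]
    ]
    inter = pd.DataFrame(inter_rows)
    return ValidationReport(
        intra_batch=intra,
        inter_batch=inter,
        all_accepted=bool(intra["accepted"].all() and inter["accepted"].all()),
    )


def calibration_acceptance(
    fit: CalibrationFit,
    nominal: Sequence[float],
    response_ratio: Sequence[float],
    tolerance_pct: float = QC_TOLERANCE_PCT,
    lloq_tolerance_pct: float = LLOQ_TOLERANCE_PCT,
) -> pd.DataFrame:
    """Back-calculated standards within +/-15% of nominal (+/-20% at LLOQ).

    The LLOQ is taken as the lowest nominal level present.
    """
    x = np.asarray(nominal, dtype=float)
    back = np.asarray(back_calculate(fit, response_ratio), dtype=float)
    lloq = x.min()
    rows = []
    for level in np.unique(x):
        mask = x == level
        re = relative_error(float(back[mask].mean()), float(level))
        band = lloq_tolerance_pct if level == lloq else tolerance_pct
        rows.append({"nominal": float(level), "back_calculated_mean": float(back[mask].mean()),
                     "re_pct": re, "tolerance_pct": band, "accepted": bool(abs(re) <= band)})
    return pd.DataFrame(rows)


def matrix_effect(
    spiked_extract_areas: Sequence[float], neat_solution_areas: Sequence[float]
) -> tuple[float, float]:
    """Mean and SD of 100*(spiked extract / neat solution) over pairs."""
    spiked = np.asarray(spiked_extract_areas, dtype=float)
    neat = np.asarray(neat_solution_areas, dtype=float)
    if spiked.size != neat.size or spiked.size == 0:
        raise ValueError("need paired, nonempty area vectors")
    if np.any(neat == 0):
        raise ValueError("neat-solution areas must be nonzero")
    ratios = 100.0 * spiked / neat
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return float(ratios.mean()), sd


def carryover_check(
    blank_signals_after_uloq: Sequence[float],
    lloq_signal: float,
    threshold_fraction: float = 0.2,
) -> bool:
    """Pass iff every post-ULOQ blank signal <= threshold * LLOQ signal.

    The boundary is inclusive (a blank at exactly the threshold passes).
    """
    if lloq_signal <= 0:
        raise ValueError("lloq_signal must be positive")
    blanks = np.asarray(blank_signals_after_uloq, dtype=float)
    return bool(np.all(blanks <= threshold_fraction * lloq_signal))


def stability_assessment(
    measured: Sequence[float],
    nominal: float,
    tolerance_pct: float = QC_TOLERANCE_PCT,
) -> pd.DataFrame:
    """Percent-of-nominal per sample; fail when |100 - value| > tolerance."""
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    m = np.asarray(measured, dtype=float)
    pct = 100.0 * m / nominal
    return pd.DataFrame(
        {
            "measured": m,
            "pct_of_nominal": pct,
            "accepted": np.abs(100.0 - pct) <= tolerance_pct,
        }
    )
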