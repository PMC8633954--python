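"""Non-compartmental pharmacokinetic analysis (NCA).

Model-free estimation of exposure parameters from sampled plasma
concentration-time profiles: Cmax/Tmax by inspection of the observed
maximum, AUC0-t by the linear trapezoidal rule, the terminal elimination
rate constant Ke from a log-linear regression over the last quantifiable
samples, the half-life t1/2 = 0.693/Ke, and the extrapolated AUC0-inf =
AUC0-t + Clast/Ke.  A cohort summary reports per-parameter mean +/- SD,
the mean AUC0-t/AUC0-inf ratio (regulatory guidance requires >= 80%), and
the fold range (max/min) of AUC and Cmax across subjects.

Concentrations below the assay's lower limit of quantification (LLOQ) are
carried as explicit flags, never as imputed numbers.  Before any AUC or
regression step: flagged values preceding the first quantifiable sample
are treated as zero (pre-absorption), and all later flagged values are
excluded from the usable curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationTimeProfile",
    "PKParameters",
    "CohortPKSummary",
    "NoQuantifiableDataError",
    "NoTerminalDeclineError",
    "extract_cmax_tmax",
    "auc_trapezoid",
    "terminal_ke",
    "half_life",
    "auc_extrapolate",
    "auc_ratio_pct",
    "compute_pk_parameters",
    "summarize_cohort",
    "read_profiles",
    "params_to_frame",
]

#: The half-life constant as printed in bioanalytical practice (not ln 2),
#: kept literal so outputs are bit-comparable with hand calculations.
HALF_LIFE_CONSTANT = 0.693


class NoQuantifiableDataError(ValueError):
    """Raised when a profile contains no quantifiable concentration."""


class NoTerminalDeclineError(ValueError):
    """Raised when the terminal log-linear slope is not negative."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's sampled drug concentrations over time.

    Parameters
    ----------
    subject_id:
        Subject identifier.
    times:
        Sampling times in hours, nonnegative and strictly increasing.
    concentrations:
        Measured concentrations in ng/ml.  Entries flagged below the LLOQ
        are stored as NaN internally; their measured value is never used.
    lloq:
        Lower limit of quantification in ng/ml.
    blq:
        Optional boolean mask marking below-LLOQ entries.  When omitted it
        is derived as ``concentrations < lloq``.
    """

    subject_id: str
    times: np.ndarray
    concentrations: np.ndarray
    lloq: float
    blq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.ndim != 1 or conc.ndim != 1 or times.size != conc.size:
            raise ValueError("times and concentrations must be 1-D and of equal length")
        if times.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if np.any(times < 0):
            raise ValueError("sampling times must be nonnegative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if not np.isfinite(self.lloq) or self.lloq < 0:
            raise ValueError("lloq must be a nonnegative finite number")
        if self.blq is None:
            blq = np.where(np.isnan(conc), True, conc < self.lloq)
        else:
            blq = np.asarray(self.blq, dtype=bool)
            if blq.shape != conc.shape:
                raise ValueError("blq mask must match concentrations")
        if np.any(conc[~blq] < 0):
            raise ValueError("quantifiable concentrations must be nonnegative")
        conc = conc.copy()
        conc[blq] = np.nan  # flagged, never a guessed value
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "blq", blq)

    @property
    def quantifiable(self) -> np.ndarray:
        """Boolean mask of quantifiable samples."""
        return ~self.blq

    def usable_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, concentrations) after below-LLOQ handling.

        Flagged values before the first quantifiable sample become 0
        (predose / pre-absorption); all flagged values after that point
        are excluded.
        """
        q = self.quantifiable
        if not np.any(q):
            raise NoQuantifiableDataError(
                f"profile {self.subject_id!r} has no quantifiable concentration"
            )
        first_q = int(np.argmax(q))
        keep = q.copy()
        keep[:first_q] = True  # leading BLQ block enters as zeros
        t = self.times[keep]
        c = self.concentrations[keep].copy()
        c[np.isnan(c)] = 0.0
        return t, c


@dataclass(frozen=True)
class PKParameters:
    """Per-subject non-compartmental outputs."""

    subject_id: str
    cmax: float
    tmax: float
    auc_0t: float
    auc_inf: float
    ke: float
    t_half: float
    extrapolated_fraction: float
    n_terminal_points: int

    def __post_init__(self) -> None:
        if not self.auc_inf >= self.auc_0t > 0:
            raise ValueError("requires auc_inf >= auc_0t > 0")
        if self.ke <= 0:
            raise ValueError("ke must be positive")
        if not np.isclose(self.t_half, HALF_LIFE_CONSTANT / self.ke, rtol=1e-9):
            raise ValueError("t_half inconsistent with 0.693/ke")
        expected = 1.0 - self.auc_0t / self.auc_inf
        if not np.isclose(self.extrapolated_fraction, expected, atol=1e-9):
            raise ValueError("extrapolated_fraction inconsistent with AUC values")
        if not 0.0 <= self.extrapolated_fraction < 1.0:
            raise ValueError("extrapolated_fraction must be in [0, 1)")


@dataclass(frozen=True)
class CohortPKSummary:
    """Cohort-level mean/SD summary and dispersion diagnostics."""

    n_subjects: int
    means: dict[str, float]
    sds: dict[str, float]
    auc_ratio_mean_pct: float
    fold_range_auc: float
    fold_range_cmax: float
    ratio_meets_80pct: bool


def extract_cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Maximum quantifiable concentration and its sampling time.

    Ties are broken to the earliest time, a deterministic stand-in for the
    visual inspection used in practice.
    """
    q = profile.quantifiable
    if not np.any(q):
        raise NoQuantifiableDataError(
            f"profile {profile.subject_id!r} has no quantifiable concentration"
        )
    conc = np.where(q, profile.concentrations, -np.inf)
    idx = int(np.argmax(conc))  # argmax returns the first maximum -> earliest time
    return float(conc[idx]), float(profile.times[idx])


def auc_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """AUC0-t by the linear trapezoidal rule over the usable curve."""
    t, c = profile.usable_curve()
    if t.size < 2:
        raise ValueError("need at least 2 usable points for the trapezoidal rule")
    return float(np.trapezoid(c, t))


def terminal_ke(profile: ConcentrationTimeProfile, n_points: int = 3) -> float:
    """Terminal elimination rate constant from the log-linear tail.

    Ordinary least-squares slope of log10(C) versus time over the last
    ``n_points`` quantifiable samples, converted to a natural-log rate
    (slope x -ln 10).
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    q = profile.quantifiable & (profile.concentrations > 0)
    t = profile.times[q]
    c = profile.concentrations[q]
    if t.size < n_points:
        raise ValueError(
            f"profile {profile.subject_id!r}: need {n_points} positive quantifiable "
            f"samples for the terminal regression, found {t.size}"
        )
    t_tail = t[-n_points:]
    c_tail = c[-n_points:]
    slope = np.polyfit(t_tail, np.log10(c_tail), 1)[0]
    ke = -slope * np.log(10.0)
    if ke <= 1e-12:  # zero slope up to regression round-off
        raise NoTerminalDeclineError(
            f"profile {profile.subject_id!r}: no terminal decline (ke={ke:.4g})"
        )
    return float(ke)


def half_life(ke: float) -> float:
    """Elimination half-life t1/2 = 0.693/Ke."""
    if ke <= 0:
        raise ValueError("ke must be positive")
    return HALF_LIFE_CONSTANT / ke


def auc_extrapolate(auc_0t: float, c_last: float, ke: float) -> float:
    """AUC0-inf = AUC0-t + Clast/Ke (Clast = last observed quantifiable value)."""
    if ke <= 0:
        raise ValueError("ke must be positive")
    if auc_0t <= 0 or c_last < 0:
        raise ValueError("auc_0t must be positive and c_last nonnegative")
    return float(auc_0t + c_last / ke)


def auc_ratio_pct(auc_0t: float, auc_inf: float) -> float:
    """100 x AUC0-t / AUC0-inf, the extrapolation-coverage percentage."""
    if auc_inf <= 0:
        raise ValueError("auc_inf must be positive")
    return 100.0 * auc_0t / auc_inf


def compute_pk_parameters(
    profile: ConcentrationTimeProfile, n_terminal_points: int = 3
) -> PKParameters:
    """Full per-subject NCA: Cmax/Tmax, AUC0-t, Ke, t1/2, AUC0-inf."""
    cmax, tmax = extract_cmax_tmax(profile)
    auc_0t = auc_trapezoid(profile)
    ke = terminal_ke(profile, n_points=n_terminal_points)
    q = profile.quantifiable & (profile.concentrations > 0)
    c_last = float(profile.concentrations[q][-1])
    auc_inf = auc_extrapolate(auc_0t, c_last, ke)
    return PKParameters(
        subject_id=profile.subject_id,
        cmax=cmax,
        tmax=tmax,
        auc_0t=auc_0t,
        auc_inf=auc_inf,
        ke=ke,
        t_half=half_life(ke),
        extrapolated_fraction=1.0 - auc_0t / auc_inf,
        n_terminal_points=n_terminal_points,
    )


_SUMMARY_FIELDS = ("cmax", "tmax", "auc_0t", "auc_inf", "ke", "t_half")


def summarize_cohort(params: Iterable[PKParameters]) -> CohortPKSummary:
    """Cohort mean +/- sample SD per parameter, AUC ratio, fold ranges."""
    params = list(params)
    if len(params) < 2:
        raise ValueError("cohort summary needs at least 2 subjects")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in _SUMMARY_FIELDS:
        values = np.array([getattr(p, name) for p in params], dtype=float)
        means[name] = float(values.mean())
        sds[name] = float(values.std(ddof=1))
    ratios = np.array([auc_ratio_pct(p.auc_0t, p.auc_inf) for p in params])
    aucs = np.array([p.auc_0t for p in params])
    cmaxs = np.array([p.cmax for p in params])
    ratio_mean = float(ratios.mean())
    return CohortPKSummary(
        n_subjects=len(params),
        means=means,
        sds=sds,
        auc_ratio_mean_pct=ratio_mean,
        fold_range_auc=float(aucs.max() / aucs.min()),
        fold_range_cmax=float(cmaxs.max() / cmaxs.min()),
        ratio_meets_80pct=bool(ratio_mean >= 80.0),
    )


# ---------------------------------------------------------------------------
# delimited-text interfaces
# ---------------------------------------------------------------------------

def read_profiles(
    path, lloq: float, require_predose: bool = True, min_samples: int = 4
) -> list[ConcentrationTimeProfile]:
    """Read long-format ``subject_id,time_h,conc_ng_ml`` CSV into profiles.

    Study profiles must start at the predose time 0 and carry at least
    ``min_samples`` samples; relax via the keyword arguments for partial
    curves.  A ``blq`` column (0/1), if present, overrides the LLOQ-derived
    flag.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "time_h", "conc_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    profiles = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        if require_predose and times[0] != 0.0:
            raise ValueError(f"subject {subject_id!r}: first sample must be predose t=0")
        if times.size < min_samples:
            raise ValueError(
                f"subject {subject_id!r}: {times.size} samples < required {min_samples}"
            )
        blq = grp["blq"].to_numpy(dtype=bool) if "blq" in grp.columns else None
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(subject_id),
                times=times,
                concentrations=grp["conc_ng_ml"].to_numpy(dtype=float),
                lloq=lloq,
                blq=blq,
            )
        )
    return profiles


def params_to_frame(params: Sequence[PKParameters]) -> pd.DataFrame:
    """Per-subject PK parameters as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in params],
            "cmax_ng_ml": [p.cmax for p in params],
            "tmax_h": [p.tmax for p in params],
            "auc_0t_ng_h_ml": [p.auc_0t for p in params],
            "auc_inf_ng_h_ml": [p.auc_inf for p in params],
            "ke_per_h": [p.ke for p in params],
            "t_half_h": [p.t_half for p in params],
            "extrapolated_fraction": [p.extrapolated_fraction for p in params],
            "n_terminal_points": [p.n_terminal_points for p in params],
        }
    )


def summary_to_frame(summary: CohortPKSummary) -> pd.DataFrame:
    """Cohort summary as a two-column (statistic, value) DataFrame."""
    rows: list[tuple[str, float]] = [("n_subjects", summary.n_subjects)]
    for name in _SUMMARY_FIELDS:
        rows.append((f"{name}_mean", summary.means[name]))
        rows.append((f"{name}_sd", summary.sds[name]))
    rows += [
        ("auc_ratio_mean_pct", summary.auc_ratio_mean_pct),
        ("fold_range_auc", summary.fold_range_auc),
        ("fold_range_cmax", summary.fold_range_cmax),
        ("ratio_meets_80pct", float(summary.ratio_meets_80pct)),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])
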