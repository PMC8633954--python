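"""Synthetic pharmacometabolomic cohort generator.

Produces, under one seed: (a) one-compartment oral-absorption plasma
concentration-time profiles on the study's 20-point sampling grid with
lognormal inter-individual variability and multiplicative assay noise,
censored at the LLOQ; (b) metabolomic feature tables (study samples,
pooled-QC replicates with injection drift, and a serial-dilution QC
series) in which a small planted subset of features is log-linearly
linked to each subject's drug clearance — and therefore to AUC and Cmax;
(c) weakly PK-correlated clinical covariates.

The one-compartment model

    C(t) = (D / (V/F)) * ka/(ka - ke) * (exp(-ke*t) - exp(-ka*t))

is the simplest generative stand-in whose non-compartmental readouts land
on the scale of a 20-mg oral statin study: median ka and ke chosen so
Tmax is near 4 h and t1/2 near 15 h, V/F so Cmax sits near 20 ng/ml, and
clearance variability wide enough for a seven- to eight-fold spread in
AUC and Cmax across 40 subjects.  Every generator returns the generating
truth alongside the data so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_qc import FeatureTable
from .nca import ConcentrationTimeProfile

__all__ = [
    "DEFAULT_SAMPLING_GRID",
    "CohortSpec",
    "FeatureLinkSpec",
    "simulate_pk_profiles",
    "simulate_feature_table",
    "simulate_clinical_features",
]

#: The study's 20-point blood-sampling grid (hours postdose).
DEFAULT_SAMPLING_GRID = (
    0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.33, 3.67, 4.0, 4.33,
    4.67, 5.0, 5.5, 6.0, 8.0, 10.0, 12.0, 24.0, 48.0, 72.0,
)


def _sigma_from_cv(cv: float) -> float:
    """Log-normal sigma with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


def _lognormal(rng: np.random.Generator, median: float, cv: float, size) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, _sigma_from_cv(cv), size=size))


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the simulated PK cohort.

    Rates are 1/h, volume is the apparent V/F in litres, dose in mg,
    concentrations in ng/ml.  Medians and CVs parameterize lognormal
    inter-individual distributions.
    """

    n_subjects: int = 40
    dose_mg: float = 20.0
    sampling_grid: tuple = DEFAULT_SAMPLING_GRID
    ka_median: float = 0.7
    ka_cv: float = 0.3
    ke_median: float = 0.0462
    ke_cv: float = 0.5
    vf_median_l: float = 850.0
    vf_cv: float = 0.3
    assay_noise_cv: float = 0.05
    lloq: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ka_median, self.ke_median, self.vf_median_l, self.dose_mg) <= 0:
            raise ValueError("rates, volume and dose must be positive")
        grid = np.asarray(self.sampling_grid, dtype=float)
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("sampling grid must start at 0 and strictly increase")


def one_compartment_concentration(
    t: np.ndarray, dose_mg: float, vf_l: float, ka: float, ke: float
) -> np.ndarray:
    """Noiseless plasma concentration (ng/ml) of the simulator model."""
    dose_ng = dose_mg * 1e6
    vf_ml = vf_l * 1e3
    return (dose_ng / vf_ml) * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def simulate_pk_profiles(
    spec: CohortSpec = CohortSpec(),
) -> tuple[list[ConcentrationTimeProfile], pd.DataFrame]:
    """Draw a cohort and sample its profiles on the grid.

    Returns ``(profiles, truth)``; ``truth`` carries the generating
    per-subject parameters (ka, ke, V/F, clearance, analytic Tmax/Cmax
    and AUC0-inf) for recovery checks.  Parameter draws with ka equal to
    ke (the flip-flop singularity) are redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.sampling_grid, dtype=float)
    profiles, rows = [], []
    n_redraws = 0
    for i in range(spec.n_subjects):
        while True:
            ka = float(_lognormal(rng, spec.ka_median, spec.ka_cv, None))
            ke = float(_lognormal(rng, spec.ke_median, spec.ke_cv, None))
            if abs(ka - ke) > 1e-8 * ke:
                break
            n_redraws += 1
        vf = float(_lognormal(rng, spec.vf_median_l, spec.vf_cv, None))
        clean = one_compartment_concentration(grid, spec.dose_mg, vf, ka, ke)
        if spec.assay_noise_cv > 0:
            noise = np.exp(rng.normal(0.0, _sigma_from_cv(spec.assay_noise_cv), grid.size))
        else:
            noise = 1.0
        observed = clean * noise
        blq = observed < spec.lloq
        subject_id = f"S{i + 1:02d}"
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=subject_id,
                times=grid,
                concentrations=observed,
                lloq=spec.lloq,
                blq=blq,
            )
        )
        cl_ml_h = vf * 1e3 * ke
        tmax = np.log(ka / ke) / (ka - ke)
        rows.append(
            {
                "subject_id": subject_id,
                "ka": ka,
                "ke": ke,
                "vf_l": vf,
                "cl_l_h": vf * ke,
                "tmax_true_h": tmax,
                "cmax_true_ng_ml": float(
                    one_compartment_concentration(np.array([tmax]), spec.dose_mg, vf, ka, ke)[0]
                ),
                "auc_inf_true_ng_h_ml": spec.dose_mg * 1e6 / cl_ml_h,
            }
        )
    truth = pd.DataFrame(rows).set_index("subject_id")
    truth.attrs["n_flip_flop_redraws"] = n_redraws
    return profiles, truth


@dataclass(frozen=True)
class FeatureLinkSpec:
    """Parameters of the simulated feature table and its PK link.

    ``n_planted`` features carry log-abundance = baseline +
    effect * standardized log-clearance + noise, with alternating effect
    sign; the rest are independent lognormal noise.  ``n_unstable``
    features get large pooled-QC injection noise (so the QC-RSD filter
    should remove them) and ``n_nondiluting`` features scale with, not
    against, the dilution factor (so the dilution-trend filter should
    remove them).
    """

    n_features: int = 2609
    mode: str = "positive"
    n_planted: int = 10
    effect_size: float = 1.0
    feature_noise_cv: float = 0.2
    n_qc_pools: int = 8
    qc_noise_cv: float = 0.05
    qc_drift: float = 0.002
    n_unstable: int = 0
    unstable_cv: float = 2.0
    n_nondiluting: int = 0
    dilution_levels: int = 5
    dilution_noise_cv: float = 0.05
    is_cv: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError("n_planted cannot exceed n_features")
        if self.n_planted + self.n_unstable + self.n_nondiluting > self.n_features:
            raise ValueError("planted + unstable + nondiluting exceed n_features")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")


def simulate_feature_table(
    link: FeatureLinkSpec, subject_truth: pd.DataFrame
) -> tuple[FeatureTable, dict]:
    """Simulate a feature table tied to the cohort's clearance truth.

    Returns ``(table, truth)`` where ``truth`` names the planted,
    unstable and non-diluting feature ids.
    """
    rng = np.random.default_rng(link.seed)
    subjects = list(subject_truth.index)
    n_sub = len(subjects)
    p = link.n_features

    # feature identities in the RT_m/z convention, plus a spiked IS feature
    rt = rng.uniform(0.3, 11.0, size=p)
    mz = rng.uniform(50.0, 1700.0, size=p)
    ids = [f"{rt[j]:.2f}_{mz[j]:.4f}" for j in range(p)]
    seen: dict[str, int] = {}
    for j, fid in enumerate(ids):  # de-duplicate pathological collisions
        if fid in seen:
            ids[j] = f"{fid}_{j}"
        seen[ids[j]] = j
    is_id = "2.50_230.0480_IS"

    roles = rng.permutation(p)
    planted_idx = roles[: link.n_planted]
    unstable_idx = roles[link.n_planted: link.n_planted + link.n_unstable]
    nondil_idx = roles[
        link.n_planted + link.n_unstable:
        link.n_planted + link.n_unstable + link.n_nondiluting
    ]

    z = np.log(subject_truth["cl_l_h"].to_numpy(float))
    z = (z - z.mean()) / z.std()

    log_base = rng.uniform(np.log(1e3), np.log(1e6), size=p)
    effects = np.zeros(p)
    effects[planted_idx] = link.effect_size * np.where(
        np.arange(link.n_planted) % 2 == 0, 1.0, -1.0
    )
    sigma_feat = _sigma_from_cv(link.feature_noise_cv)
    log_study = (
        log_base[None, :]
        + np.outer(z, effects)
        + rng.normal(0.0, sigma_feat, size=(n_sub, p))
    )
    study = np.exp(log_study)

    # pooled QC: feature-wise mean of study samples x injection drift x noise
    pool = study.mean(axis=0)
    n_qc = link.n_qc_pools
    # acquisition order: QC pools interleaved through the study run,
    # dilution series at the end of the batch
    qc_orders = np.linspace(0, n_sub + n_qc - 1, n_qc).round().astype(int)
    if np.unique(qc_orders).size < n_qc:  # rounding collision at tiny n
        qc_orders = np.arange(n_qc)
    qc = np.empty((n_qc, p))
    qc_sigma = np.full(p, _sigma_from_cv(link.qc_noise_cv))
    qc_sigma[unstable_idx] = _sigma_from_cv(link.unstable_cv)
    for q in range(n_qc):
        drift = (1.0 + link.qc_drift) ** qc_orders[q]
        qc[q] = pool * drift * np.exp(rng.normal(0.0, qc_sigma))

    # serial dilution of the pooled sample; non-diluting features track the
    # dilution factor instead (saturating background behaviour)
    factors = 2.0 ** np.arange(link.dilution_levels)
    dil = np.empty((link.dilution_levels, p))
    dil_sigma = _sigma_from_cv(link.dilution_noise_cv)
    for d, factor in enumerate(factors):
        scale = np.full(p, 1.0 / factor)
        scale[nondil_idx] = factor / factors.max()
        dil[d] = pool * scale * np.exp(rng.normal(0.0, dil_sigma, size=p))

    abundance = np.vstack([study, qc, dil])
    sample_ids = (
        subjects
        + [f"QC{q + 1}" for q in range(n_qc)]
        + [f"DIL{d + 1}" for d in range(link.dilution_levels)]
    )
    # spiked internal standard: constant per sample up to small CV
    is_area = 5e5 * np.exp(rng.normal(0.0, _sigma_from_cv(link.is_cv), len(sample_ids)))

    df = pd.DataFrame(abundance, index=sample_ids, columns=ids)
    df[is_id] = is_area

    study_orders = [o for o in range(n_sub + n_qc) if o not in set(qc_orders)]
    manifest = pd.DataFrame(
        {
            "role": ["study"] * n_sub + ["qc_pool"] * n_qc + ["dilution"] * link.dilution_levels,
            "dilution_factor": [np.nan] * (n_sub + n_qc) + list(factors),
            "order": study_orders
            + list(qc_orders)
            + list(range(n_sub + n_qc, n_sub + n_qc + link.dilution_levels)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata = pd.DataFrame(
        {
            "rt_min": list(rt) + [2.50],
            "mz": list(mz) + [230.0480],
            "mode": link.mode,
        },
        index=pd.Index(ids + [is_id], name="feature_id"),
    )
    table = FeatureTable(
        abundance=df,
        sample_manifest=manifest,
        feature_metadata=metadata,
        is_feature_id=is_id,
    )
    truth = {
        "planted_feature_ids": [ids[j] for j in planted_idx],
        "unstable_feature_ids": [ids[j] for j in unstable_idx],
        "nondiluting_feature_ids": [ids[j] for j in nondil_idx],
        "effects": {ids[j]: float(effects[j]) for j in planted_idx},
    }
    return table, truth


_CLINICAL_NAMES = ["age_y", "weight_kg", "height_cm", "bmi_kg_m2"]


def simulate_clinical_features(
    subject_truth: pd.DataFrame,
    n_features: int = 44,
    weak_effect: float = 0.25,
    seed: int = 2,
) -> pd.DataFrame:
    """Clinical/laboratory covariates weakly correlated with clearance.

    Each covariate has correlation about ``weak_effect`` (alternating
    sign) with the standardized log-clearance, so a clinical-only model
    performs far worse than the metabolomic one.
    """
    rng = np.random.default_rng(seed)
    z = np.log(subject_truth["cl_l_h"].to_numpy(float))
    z = (z - z.mean()) / z.std()
    n_sub = z.size
    w = float(np.clip(weak_effect, 0.0, 0.99))
    cols = {}
    for j in range(n_features):
        name = _CLINICAL_NAMES[j] if j < len(_CLINICAL_NAMES) else f"lab_{j - len(_CLINICAL_NAMES) + 1:02d}"
        sign = 1.0 if j % 2 == 0 else -1.0
        latent = sign * w * z + np.sqrt(1.0 - w**2) * rng.normal(size=n_sub)
        mu, sigma = 10.0 ** rng.uniform(0, 2), rng.uniform(0.05, 0.3)
        cols[name] = mu * np.exp(sigma * latent)  # lognormal lab-value scale
    return pd.DataFrame(cols, index=subject_truth.index)
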