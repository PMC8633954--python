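"""Metabolomic feature-table cleaning and normalization.

A :class:`FeatureTable` holds a samples x features abundance matrix, a
sample manifest (role: study / qc_pool / dilution, dilution factor,
acquisition order), feature metadata (retention time, m/z, ionization
mode), the internal-standard feature id, and an ordered processing log.

The standard preprocessing chain, in the order it is meant to run:

1. ``is_normalize``            - divide each sample by its internal-standard area
2. ``pool_reference_normalize``- probabilistic quotient normalization against
                                 the mean pooled-QC spectrum
3. ``qc_rsd_filter``           - drop features with pooled-QC RSD > 25%
4. ``dilution_trend_filter``   - keep features that track a serial-dilution series
5. ``cube_root_transform``     - x -> x^(1/3), variance taming
6. ``robust_scale``            - per-feature (x - median)/IQR on study samples

Every step returns a new table and appends exactly one log entry; a
processing log can be replayed on the raw table via :func:`replay` to
reproduce the processed table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "is_normalize",
    "pool_reference_normalize",
    "cube_root_transform",
    "robust_scale",
    "qc_rsd_filter",
    "dilution_trend_filter",
    "run_chain",
    "replay",
]

ROLES = ("study", "qc_pool", "dilution")


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features abundance matrix with manifest and metadata.

    ``abundance``: DataFrame indexed by sample_id, columns are feature ids
    (the conventional ``RT_m/z`` strings).  ``sample_manifest``: DataFrame
    indexed by sample_id with columns ``role``, ``dilution_factor``,
    ``order``.  ``feature_metadata``: DataFrame indexed by feature id with
    columns ``rt_min``, ``mz``, ``mode``.
    """

    abundance: pd.DataFrame
    sample_manifest: pd.DataFrame
    feature_metadata: pd.DataFrame
    is_feature_id: str | None = None
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.sample_manifest.index):
            raise ValueError("abundance rows and sample manifest are misaligned")
        if list(self.abundance.columns) != list(self.feature_metadata.index):
            raise ValueError("abundance columns and feature metadata are misaligned")
        bad_roles = set(self.sample_manifest["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        if self.is_feature_id is not None and self.is_feature_id not in self.abundance.columns:
            raise ValueError(f"internal-standard feature {self.is_feature_id!r} not in table")

    # -- convenience selectors -------------------------------------------
    def samples_with_role(self, role: str) -> pd.Index:
        return self.sample_manifest.index[self.sample_manifest["role"] == role]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    def _evolve(self, abundance: pd.DataFrame, entry: dict,
                drop_features: pd.Index | None = None) -> "FeatureTable":
        meta = self.feature_metadata
        if drop_features is not None and self.is_feature_id is not None:
            # the spiked internal standard is a known control, never filtered
            drop_features = drop_features.drop(self.is_feature_id, errors="ignore")
        if drop_features is not None and len(drop_features):
            abundance = abundance.drop(columns=drop_features)
            meta = meta.drop(index=drop_features)
        return replace(
            self,
            abundance=abundance,
            feature_metadata=meta,
            processing_log=self.processing_log + [entry],
        )


def _log_entry(step: str, params: dict, **info) -> dict:
    return {"step": step, "params": params, **info}


def is_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample by its internal-standard abundance.

    The IS feature becomes identically 1 and is retained, so downstream
    filters see it as a perfectly stable feature.
    """
    if table.is_feature_id is None:
        raise ValueError("table has no internal-standard feature id")
    is_col = table.abundance[table.is_feature_id]
    bad = is_col.index[(is_col <= 0) | is_col.isna()]
    if len(bad):
        raise ValueError(
            f"internal standard nonpositive/missing in samples: {list(bad[:5])}"
        )
    out = table.abundance.div(is_col, axis=0)
    return table._evolve(out, _log_entry("is_normalize", {}))


def pool_reference_normalize(table: FeatureTable) -> FeatureTable:
    """Probabilistic quotient normalization against the pooled-QC mean.

    Reference spectrum = feature-wise mean over qc_pool samples; each
    study/qc_pool sample is divided by the median over features (with
    positive reference values) of sample/reference.  Dilution-series
    samples pass through unchanged: their deliberate concentration trend
    is what the downstream dilution filter measures, and the quotient
    would cancel it exactly.
    """
    qc_ids = table.samples_with_role("qc_pool")
    if len(qc_ids) == 0:
        raise ValueError("quotient normalization needs at least one qc_pool sample")
    reference = table.abundance.loc[qc_ids].mean(axis=0)
    positive = reference > 0
    if not positive.any():
        raise ValueError("reference spectrum has no positive features")
    out = table.abundance.copy()
    norm_ids = table.sample_manifest.index[table.sample_manifest["role"] != "dilution"]
    quotients = (
        out.loc[norm_ids, positive.index[positive]]
        .div(reference[positive], axis=1)
        .median(axis=1)
    )
    if (quotients <= 0).any():
        bad = quotients.index[quotients <= 0]
        raise ValueError(f"nonpositive dilution quotient for samples: {list(bad[:5])}")
    out.loc[norm_ids] = out.loc[norm_ids].div(quotients, axis=0)
    return table._evolve(
        out,
        _log_entry("pool_reference_normalize", {},
                   n_reference_samples=int(len(qc_ids))),
    )


def cube_root_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise x -> x^(1/3); requires nonnegative abundances."""
    if (table.abundance.to_numpy() < 0).any():
        raise ValueError("cube-root transform requires nonnegative abundances")
    out = np.cbrt(table.abundance)
    return table._evolve(out, _log_entry("cube_root_transform", {}))


def robust_scale(table: FeatureTable) -> FeatureTable:
    """Per-feature (x - median) / IQR, statistics from study samples only.

    IQR = Q3 - Q1 with linear-interpolation quantiles.  Features with zero
    IQR are centered, left unscaled, and flagged in the log.
    """
    study_ids = table.samples_with_role("study")
    if len(study_ids) < 2:
        raise ValueError("robust scaling needs at least 2 study samples")
    study = table.abundance.loc[study_ids]
    median = study.median(axis=0)
    q1 = study.quantile(0.25, axis=0, interpolation="linear")
    q3 = study.quantile(0.75, axis=0, interpolation="linear")
    iqr = q3 - q1
    zero_iqr = iqr.index[iqr == 0]
    scale = iqr.replace(0, 1.0)
    out = table.abundance.sub(median, axis=1).div(scale, axis=1)
    return table._evolve(
        out,
        _log_entry("robust_scale", {}, zero_iqr_features=list(zero_iqr)),
    )


def qc_rsd_filter(table: FeatureTable, threshold_pct: float = 25.0) -> FeatureTable:
    """Drop features whose pooled-QC RSD exceeds ``threshold_pct``.

    RSD = 100*SD/mean (sample SD) across qc_pool samples on the current
    scale; the drop rule is a strict ``>``, so a feature at exactly the
    threshold is kept.  Features with zero QC mean are dropped and logged.
    """
    qc_ids = table.samples_with_role("qc_pool")
    if len(qc_ids) < 2:
        raise ValueError("QC-RSD filter needs at least 2 qc_pool samples")
    qc = table.abundance.loc[qc_ids]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    zero_mean = mean.index[mean == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        feature_rsd = 100.0 * sd / mean
    drop = feature_rsd.index[(feature_rsd > threshold_pct) | mean.eq(0)]
    entry = _log_entry(
        "qc_rsd_filter",
        {"threshold_pct": threshold_pct},
        n_dropped=int(len(drop)),
        n_zero_mean=int(len(zero_mean)),
    )
    return table._evolve(table.abundance, entry, drop_features=drop)


def dilution_trend_filter(table: FeatureTable, min_correlation: float = 0.8) -> FeatureTable:
    """Keep features correlated with the serial-dilution concentration.

    Pearson r between abundance across dilution samples and the relative
    concentration 1/dilution_factor; keep r >= ``min_correlation``.
    Constant features (undefined r) are dropped and logged.  With no
    dilution samples the step is skipped with a logged warning.
    """
    dil_ids = table.samples_with_role("dilution")
    if len(dil_ids) == 0:
        entry = _log_entry(
            "dilution_trend_filter",
            {"min_correlation": min_correlation},
            skipped=True,
            warning="no dilution samples acquired; filter skipped",
        )
        return table._evolve(table.abundance, entry)
    factors = table.sample_manifest.loc[dil_ids, "dilution_factor"].to_numpy(float)
    if np.unique(factors).size < 3:
        raise ValueError("dilution-trend filter needs >= 3 distinct dilution factors")
    rel_conc = 1.0 / factors
    dil = table.abundance.loc[dil_ids].to_numpy(float)
    centered = dil - dil.mean(axis=0)
    x = rel_conc - rel_conc.mean()
    denom = np.sqrt((centered**2).sum(axis=0) * (x**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered * x[:, None]).sum(axis=0) / denom
    keep = r >= min_correlation  # NaN (constant feature) compares False -> dropped
    n_undefined = int(np.isnan(r).sum())
    drop = table.abundance.columns[~keep]
    entry = _log_entry(
        "dilution_trend_filter",
        {"min_correlation": min_correlation},
        n_dropped=int(len(drop)),
        n_undefined_r=n_undefined,
    )
    return table._evolve(table.abundance, entry, drop_features=drop)


# ---------------------------------------------------------------------------
# chain orchestration and log replay
# ---------------------------------------------------------------------------

_STEPS = {
    "is_normalize": is_normalize,
    "pool_reference_normalize": pool_reference_normalize,
    "cube_root_transform": cube_root_transform,
    "robust_scale": robust_scale,
    "qc_rsd_filter": qc_rsd_filter,
    "dilution_trend_filter": dilution_trend_filter,
}


def run_chain(
    table: FeatureTable,
    qc_rsd_threshold_pct: float = 25.0,
    dilution_min_correlation: float = 0.8,
) -> FeatureTable:
    """Apply the full default preprocessing chain in canonical order."""
    table = is_normalize(table)
    table = pool_reference_normalize(table)
    table = qc_rsd_filter(table, threshold_pct=qc_rsd_threshold_pct)
    table = dilution_trend_filter(table, min_correlation=dilution_min_correlation)
    table = cube_root_transform(table)
    table = robust_scale(table)
    return table


def replay(raw_table: FeatureTable, processing_log: list) -> FeatureTable:
    """Re-apply a processing log to a raw table, reproducing the output."""
    table = raw_table
    for entry in processing_log:
        step = _STEPS.get(entry["step"])
        if step is None:
            raise ValueError(f"unknown processing step {entry['step']!r}")
        table = step(table, **entry["params"])
    return table


# ---------------------------------------------------------------------------
# delimited-text interfaces
# ---------------------------------------------------------------------------

def read_feature_table(
    abundance_csv, manifest_csv, metadata_csv, is_feature_id: str | None = None
) -> FeatureTable:
    """Load wide abundance CSV + manifest CSV + feature-metadata CSV."""
    abundance = pd.read_csv(abundance_csv, index_col=0)
    manifest = pd.read_csv(manifest_csv, index_col="sample_id")
    metadata = pd.read_csv(metadata_csv, index_col="feature_id")
    abundance = abundance.loc[manifest.index, metadata.index.astype(str)]
    return FeatureTable(
        abundance=abundance,
        sample_manifest=manifest,
        feature_metadata=metadata,
        is_feature_id=is_feature_id,
    )


def write_feature_table(table: FeatureTable, abundance_csv, log_json) -> None:
    """Write the processed matrix as CSV and the processing log as JSON."""
    import json

    table.abundance.to_csv(abundance_csv)
    with open(log_json, "w") as fh:
        json.dump(table.processing_log, fh, indent=2, default=str)
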