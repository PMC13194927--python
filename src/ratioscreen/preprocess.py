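"""Detection filtering, normalization and PCA for the abundance matrix.

Normalization methods:

``median_center``
    Subtract each sample's median of observed log2 values.

``quantile``
    Map each sample's observed values onto the mean order-statistic profile
    across samples (missing entries untouched, ties averaged via midranks).
    For complete samples this is classical quantile normalization: all
    sorted columns become identical.

``vsn_lite``
    A deliberately simplified variance-stabilizing transform: per-sample
    affine calibration (a_s, b_s) fitted by robust (Huber) regression of the
    sample's observed raw-intensity quantiles against a reference
    (column-median) quantile profile, followed by
    ``h(x) = arsinh((x − a_s)/b_s) / ln 2``.  It decouples the per-protein
    SD from the mean under multiplicative noise, like published VSN, but
    replaces the full maximum-likelihood fit with an explicit two-parameter
    robust regression.  It consumes raw intensities; log2-flagged input is
    inverse-transformed internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import (
    AbundanceMatrix,
    ConfigError,
    ValidationError,
    ceil_detection_threshold,
)

NORMALIZE_METHODS = ("median_center", "quantile", "vsn_lite")


@dataclass
class NormalizationReport:
    method: str
    #: per-sample affine parameters (offset, scale); NaN where not applicable
    params: pd.DataFrame
    #: |Spearman| correlation of per-protein SD vs mean, before/after
    trend_before: float
    trend_after: float


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples × components
    loadings: pd.DataFrame      # proteins × components
    explained_variance_fraction: np.ndarray


def filter_by_detection(
    matrix: AbundanceMatrix, min_fraction: float = 1.0 / 3.0
) -> AbundanceMatrix:
    """Retain proteins observed in ≥ ceil(min_fraction · n_samples) samples.

    Idempotent; preserves protein order.  An empty result is returned with a
    warning rather than raised.
    """
    threshold = ceil_detection_threshold(matrix.n_samples, min_fraction)
    keep = matrix.detection_counts() >= threshold
    if not keep.any():
        import warnings

        warnings.warn("detection filter removed every protein", stacklevel=2)
    return AbundanceMatrix(matrix.data.loc[keep].copy(), log2=matrix.log2)


def variance_mean_trend(values: np.ndarray) -> float:
    """|Spearman ρ| between per-protein SD and per-protein mean."""
    if values.shape[1] < 2:
        return float("nan")
    counts = np.sum(~np.isnan(values), axis=1)
    usable = counts >= 2
    if usable.sum() < 3:
        return float("nan")
    values = values[usable]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(values, axis=1)
        sds = np.nanstd(values, axis=1, ddof=1)
    ok = np.isfinite(means) & np.isfinite(sds)
    if ok.sum() < 3 or np.ptp(means[ok]) == 0 or np.ptp(sds[ok]) == 0:
        return float("nan")
    rho = stats.spearmanr(means[ok], sds[ok]).statistic
    return abs(float(rho))


def _median_center(vals: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    offsets = np.nanmedian(vals, axis=0)
    out = vals - offsets[None, :]
    params = pd.DataFrame({"offset": offsets, "scale": 1.0})
    return out, params


def _quantile_normalize(vals: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    n_prot, n_samp = vals.shape
    grid = (np.arange(n_prot) + 0.5) / n_prot
    profiles = np.empty((n_samp, n_prot))
    for s in range(n_samp):
        obs = np.sort(vals[~np.isnan(vals[:, s]), s])
        if obs.size < 2:
            raise ValidationError(f"sample column {s} has <2 observed values")
        probs = (np.arange(obs.size) + 0.5) / obs.size
        profiles[s] = np.interp(grid, probs, obs)
    reference = profiles.mean(axis=0)
    out = np.full_like(vals, np.nan)
    for s in range(n_samp):
        col = vals[:, s]
        obs_idx = np.flatnonzero(~np.isnan(col))
        ranks = stats.rankdata(col[obs_idx])  # midranks: ties share a value
        probs = (ranks - 0.5) / obs_idx.size
        out[obs_idx, s] = np.interp(probs, grid, reference)
    params = pd.DataFrame(
        {"offset": np.full(n_samp, np.nan), "scale": np.full(n_samp, np.nan)}
    )
    return out, params


def _vsn_lite(vals_raw: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Affine + arsinh calibration against the column-median profile."""
    n_prot, n_samp = vals_raw.shape
    reference = np.nanmedian(vals_raw, axis=1)
    offsets = np.empty(n_samp)
    scales = np.empty(n_samp)
    out = np.full_like(vals_raw, np.nan)
    for s in range(n_samp):
        col = vals_raw[:, s]
        obs = ~np.isnan(col) & ~np.isnan(reference)
        if obs.sum() < 3:
            raise ValidationError(
                f"sample column {s} has <3 observed values; cannot calibrate"
            )
        sample_q = np.sort(col[obs])
        ref_q = np.sort(reference[obs])
        design = sm.add_constant(ref_q)
        fit = sm.RLM(sample_q, design, M=sm.robust.norms.HuberT()).fit()
        a_s, b_s = float(fit.params[0]), float(fit.params[1])
        if b_s <= 0:
            raise ValidationError(f"sample column {s}: non-positive scale estimate")
        offsets[s] = a_s
        scales[s] = b_s
        col_obs = ~np.isnan(col)
        out[col_obs, s] = np.arcsinh((col[col_obs] - a_s) / b_s) / np.log(2.0)
    params = pd.DataFrame({"offset": offsets, "scale": scales})
    return out, params


def normalize(
    matrix: AbundanceMatrix, method: str
) -> tuple[AbundanceMatrix, NormalizationReport]:
    """Normalize; ``method`` may be a comma-chain applied left to right."""
    methods = [m.strip() for m in method.split(",") if m.strip()]
    if not methods:
        raise ConfigError("no normalization method given")
    for m in methods:
        if m not in NORMALIZE_METHODS:
            raise ConfigError(
                f"unknown normalization method {m!r}; choose from {NORMALIZE_METHODS}"
            )
    current = matrix
    report = None
    for m in methods:
        current, report = _normalize_one(current, m)
    return current, report


def _normalize_one(
    matrix: AbundanceMatrix, method: str
) -> tuple[AbundanceMatrix, NormalizationReport]:
    vals = matrix.values
    trend_before = variance_mean_trend(vals)
    if method == "median_center":
        if not matrix.log2:
            raise ConfigError("median_center expects log2-scale input")
        out, params = _median_center(vals)
        out_log2 = True
    elif method == "quantile":
        if not matrix.log2:
            raise ConfigError("quantile normalization expects log2-scale input")
        out, params = _quantile_normalize(vals)
        out_log2 = True
    elif method == "vsn_lite":
        vals_raw = np.power(2.0, vals) if matrix.log2 else vals
        trend_before = variance_mean_trend(vals_raw)
        out, params = _vsn_lite(vals_raw)
        out_log2 = True  # arsinh/ln2 is log2-like for large intensities
    else:  # pragma: no cover - guarded by normalize()
        raise ConfigError(method)
    params.index = pd.Index(matrix.sample_ids, name="sample_id")
    normed = AbundanceMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        log2=out_log2,
    )
    report = NormalizationReport(
        method=method,
        params=params,
        trend_before=trend_before,
        trend_after=variance_mean_trend(out),
    )
    return normed, report


def run_pca(
    matrix: AbundanceMatrix, impute: str = "half_min", n_components: int | None = None
) -> PcaResult:
    """PCA of samples on the log2 matrix (proteins are features).

    ``complete_proteins`` restricts to fully observed proteins;
    ``half_min`` imputes missing entries with half the protein's observed
    minimum (a standard low-abundance surrogate for left-censored LFQ data).
    Protein values are centered before the decomposition.  Scores are
    reproducible up to component sign.
    """
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs ≥2 samples")
    vals = matrix.values.copy()
    if impute == "complete_proteins":
        keep = ~np.isnan(vals).any(axis=1)
        if keep.sum() < 2:
            raise ValidationError(
                "fewer than 2 fully observed proteins; try impute='half_min'"
            )
        vals = vals[keep]
        protein_ids = [p for p, k in zip(matrix.protein_ids, keep) if k]
    elif impute == "half_min":
        mins = np.nanmin(vals, axis=1)
        empty = ~np.isfinite(mins)
        if empty.any():
            vals = vals[~empty]
            protein_ids = [p for p, e in zip(matrix.protein_ids, empty) if not e]
        else:
            protein_ids = matrix.protein_ids
        # half the minimum on the raw scale = minus 1 on the log2 scale
        fill = (np.nanmin(vals, axis=1) - 1.0) if matrix.log2 else np.nanmin(vals, axis=1) / 2.0
        idx = np.where(np.isnan(vals))
        vals[idx] = fill[idx[0]]
    else:
        raise ConfigError("impute must be 'complete_proteins' or 'half_min'")
    if vals.shape[0] < 2:
        raise ValidationError("PCA needs ≥2 usable proteins")

    x = (vals - vals.mean(axis=1, keepdims=True)).T  # samples × proteins, centered
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    explained = (s**2) / total if total > 0 else np.zeros_like(s)
    k = n_components or len(s)
    comps = [f"PC{i + 1}" for i in range(min(k, len(s)))]
    scores = pd.DataFrame(
        (u[:, : len(comps)] * s[: len(comps)]),
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=comps,
    )
    loadings = pd.DataFrame(
        vt[: len(comps)].T, index=pd.Index(protein_ids, name="protein_id"),
        columns=comps,
    )
    return PcaResult(scores, loadings, explained[: len(comps)])
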