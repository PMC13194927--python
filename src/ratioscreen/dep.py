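"""Covariate-adjusted differential expression with moderated t-statistics.

Per protein, an ordinary least-squares linear model is fitted on the
protein's complete-case samples with POTS status (one indicator) and disease
severity (two treatment-coded indicators, baseline = mild) as covariates.
Contrasts of interest are linear combinations of the coefficients:
POTS vs NoPOTS adjusted for severity, and the three pairwise severity
comparisons.

Residual variances are shrunk across proteins by empirical Bayes: the prior
(d0, s0²) of a scaled inverse-χ² hierarchy is estimated by the
method-of-moments on log s² (Smyth 2004), giving the posterior variance

    s̃²ᵢ = (d0·s0² + dᵢ·s²ᵢ) / (d0 + dᵢ)

and a moderated t with dᵢ + d0 degrees of freedom.  d0 = ∞ collapses every
s̃² to s0² (normal reference); d0 = 0 recovers the ordinary t.

Nominal DEP calling follows the volcano convention: raw p < 0.05 and linear
fold change > 1.5 (i.e. |log2FC| > log2 1.5), both strict.  BH adjustment is
applied within each contrast separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceMatrix, ConfigError, SampleInfo, ValidationError

#: contrast name -> coefficient combination over (pots, sev_moderate, sev_severe)
CONTRASTS: dict[str, dict[str, float]] = {
    "POTS_vs_NoPOTS": {"pots": 1.0},
    "Moderate_vs_Mild": {"sev_moderate": 1.0},
    "Severe_vs_Mild": {"sev_severe": 1.0},
    "Severe_vs_Moderate": {"sev_severe": 1.0, "sev_moderate": -1.0},
}

SEVERITY_CONTRASTS = ("Severe_vs_Moderate", "Severe_vs_Mild", "Moderate_vs_Mild")

MIN_RESIDUAL_DF = 3


@dataclass
class DesignSpec:
    contrasts: tuple[str, ...] = tuple(CONTRASTS)

    def __post_init__(self) -> None:
        unknown = [c for c in self.contrasts if c not in CONTRASTS]
        if unknown:
            raise ConfigError(f"unknown contrasts {unknown}; choose from {list(CONTRASTS)}")


@dataclass
class ProteinFit:
    protein_id: str
    coef: dict[str, float]
    cov_unscaled: pd.DataFrame  # (XᵀX)⁻¹ on the protein's complete cases
    s2: float
    df: int
    n_used: int


@dataclass
class ModerationParams:
    """Empirical-Bayes variance prior: d0 may be ``math.inf``."""

    d0: float
    s0_sq: float

    def posterior_s2(self, s2: float, df: float) -> float:
        if math.isinf(self.d0):
            return self.s0_sq
        if self.d0 == 0:
            return s2
        return (self.d0 * self.s0_sq + df * s2) / (self.d0 + df)


@dataclass
class FitResult:
    fits: list[ProteinFit]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (protein, reason)


def build_design(info: SampleInfo) -> pd.DataFrame:
    """Model matrix: intercept + POTS indicator + severity treatment coding.

    Covariate columns that are constant across the cohort (an absent severity
    level, or no POTS variation) are dropped so the design stays full rank;
    contrasts referencing a dropped column are unavailable for that cohort.
    """
    sev = info.severity
    x = pd.DataFrame(
        {
            "intercept": 1.0,
            "pots": info.pots.astype(float),
            "sev_moderate": (sev == "moderate").astype(float),
            "sev_severe": (sev == "severe").astype(float),
        },
        index=info.table.index,
    )
    drop = [c for c in x.columns[1:] if x[c].nunique() == 1]
    return x.drop(columns=drop)


def contrast_vector(name: str, columns: list[str]) -> np.ndarray:
    missing = [col for col in CONTRASTS[name] if col not in columns]
    if missing:
        raise ConfigError(
            f"contrast {name!r} needs design columns {missing} absent from this cohort"
        )
    c = np.zeros(len(columns))
    for col, w in CONTRASTS[name].items():
        c[columns.index(col)] = w
    return c


def fit_models(
    matrix: AbundanceMatrix, info: SampleInfo, design: DesignSpec | None = None
) -> FitResult:
    """Per-protein OLS on complete-case samples.

    Proteins whose complete-case design is rank deficient (e.g. an entire
    severity level unobserved) or whose residual df falls below
    ``MIN_RESIDUAL_DF`` are skipped with a reason.
    """
    design = design or DesignSpec()
    info = info.aligned_to(matrix)
    x_full = build_design(info)
    cols = list(x_full.columns)
    x_np = x_full.to_numpy()
    vals = matrix.values

    fits: list[ProteinFit] = []
    skipped: list[tuple[str, str]] = []
    for i, pid in enumerate(matrix.protein_ids):
        y = vals[i]
        obs = ~np.isnan(y)
        n_used = int(obs.sum())
        xp = x_np[obs]
        rank = np.linalg.matrix_rank(xp)
        if rank < xp.shape[1]:
            skipped.append((pid, "rank_deficient_design"))
            continue
        df = n_used - rank
        if df < MIN_RESIDUAL_DF:
            skipped.append((pid, f"residual_df<{MIN_RESIDUAL_DF}"))
            continue
        yp = y[obs]
        xtx_inv = np.linalg.inv(xp.T @ xp)
        beta = xtx_inv @ xp.T @ yp
        resid = yp - xp @ beta
        s2 = float(resid @ resid) / df
        fits.append(
            ProteinFit(
                protein_id=pid,
                coef=dict(zip(cols, beta)),
                cov_unscaled=pd.DataFrame(xtx_inv, index=cols, columns=cols),
                s2=s2,
                df=df,
                n_used=n_used,
            )
        )
    if not fits:
        raise ValidationError("every protein was skipped; cannot fit any model")
    return FitResult(fits=fits, skipped=skipped)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return y


def moderate(s2_list, df_list) -> ModerationParams:
    """Method-of-moments fit of the scaled inverse-χ² variance prior.

    Matches the moments of log s² against the log-F implied by the
    hierarchy; proteins with non-positive s² or df are excluded from the
    estimation (their posterior still shrinks towards s0²).  When the
    observed spread of log s² does not exceed the sampling noise, d0 = ∞.
    """
    s2 = np.asarray(s2_list, dtype=float)
    df = np.asarray(df_list, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValidationError("need ≥2 proteins with positive s² and df to moderate")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def test_contrasts(
    fit_result: FitResult,
    params: ModerationParams,
    design: DesignSpec | None = None,
) -> pd.DataFrame:
    """Moderated t-tests for every protein × contrast.

    Returns one row per protein and contrast with columns protein_id,
    contrast, n_used, log2fc, fc, s2, t_mod, df_total, p, p_adj.  BH is
    applied within each contrast.
    """
    design = design or DesignSpec()
    rows = []
    for fit in fit_result.fits:
        cols = list(fit.cov_unscaled.columns)
        cov = fit.cov_unscaled.to_numpy()
        beta = np.array([fit.coef[c] for c in cols])
        s_tilde2 = params.posterior_s2(fit.s2, fit.df)
        df_total = fit.df + params.d0
        for name in design.contrasts:
            c = contrast_vector(name, cols)
            est = float(c @ beta)
            se_unscaled = math.sqrt(float(c @ cov @ c))
            se = math.sqrt(s_tilde2) * se_unscaled
            if se == 0:
                t_mod = 0.0 if est == 0 else math.copysign(math.inf, est)
            else:
                t_mod = est / se
            if math.isinf(df_total):
                p = 2.0 * stats.norm.sf(abs(t_mod))
            else:
                p = 2.0 * stats.t.sf(abs(t_mod), df_total)
            rows.append(
                {
                    "protein_id": fit.protein_id,
                    "contrast": name,
                    "n_used": fit.n_used,
                    "log2fc": est,
                    "fc": 2.0 ** est,
                    "s2": fit.s2,
                    "t_mod": t_mod,
                    "df_total": df_total,
                    "p": min(p, 1.0),
                }
            )
    records = pd.DataFrame(rows)
    records["p_adj"] = np.nan
    for name in design.contrasts:
        sel = records["contrast"] == name
        records.loc[sel, "p_adj"] = bh_adjust(records.loc[sel, "p"].to_numpy())
    return records


def run_dep(
    matrix: AbundanceMatrix,
    info: SampleInfo,
    design: DesignSpec | None = None,
    params: ModerationParams | None = None,
) -> tuple[pd.DataFrame, ModerationParams, FitResult]:
    """Fit, moderate and test in one call; ``params`` overrides the prior."""
    design = design or DesignSpec()
    fit_result = fit_models(matrix, info, design)
    if params is None:
        params = moderate(
            [f.s2 for f in fit_result.fits], [f.df for f in fit_result.fits]
        )
    records = test_contrasts(fit_result, params, design)
    return records, params, fit_result


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving on indices."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nominal_dep_filter(
    records: pd.DataFrame,
    p_max: float = 0.05,
    fc_min: float = 1.5,
    fc_on_linear_scale: bool = True,
) -> tuple[dict[str, list[str]], list[str]]:
    """Nominal DEP calling: p < p_max and |FC| > fc_min, both strict.

    With ``fc_on_linear_scale`` (default) the fold-change gate is
    |log2fc| > log2(fc_min); the alternative reads fc_min directly on the
    log2 scale.  Returns per-contrast protein id lists (input order) and
    their de-duplicated union.
    """
    log2_thr = math.log2(fc_min) if fc_on_linear_scale else fc_min
    hits = records[(records["p"] < p_max) & (records["log2fc"].abs() > log2_thr)]
    per_contrast: dict[str, list[str]] = {}
    for name in records["contrast"].unique():
        per_contrast[name] = hits.loc[hits["contrast"] == name, "protein_id"].tolist()
    union: list[str] = []
    seen = set()
    for name in records["contrast"].unique():
        for pid in per_contrast[name]:
            if pid not in seen:
                seen.add(pid)
                union.append(pid)
    return per_contrast, union


def severity_dep_union(
    records: pd.DataFrame, p_max: float = 0.05, fc_min: float = 1.5
) -> list[str]:
    """Union of nominal DEPs over the three severity contrasts (screen input)."""
    sel = records[records["contrast"].isin(SEVERITY_CONTRASTS)]
    _, union = nominal_dep_filter(sel, p_max=p_max, fc_min=fc_min)
    return union
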