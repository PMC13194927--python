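"""All-pairs protein-ratio screening against ordinal disease severity.

For every unordered pair (A, B) of candidate proteins (typically the union
of nominal severity DEPs), the per-participant abundance ratio is formed as
the difference of log2 intensities — monotone-equivalent to the raw-scale
ratio for every rank statistic used here — restricted to participants with
both proteins quantified (complete-case).  Each ratio series is tested two
ways against severity encoded 1 = mild, 2 = moderate, 3 = severe:

* Spearman correlation with the ordinal score, with a 95% percentile
  bootstrap confidence interval over participant-level resamples;
* a Kruskal–Wallis test of ratio distributions across severity groups.

Multiplicity over all tested pairs is controlled with Storey q-values
(π0-adaptive FDR).  A pair is retained when q < 0.05 and |ρ| ≥ 0.75, and the
report is ranked by |ρ| descending (ties: smaller Kruskal–Wallis p, then
canonical pair name).  The unfiltered table is kept for audit, including a
Spearman-p-based q-value alongside the default Kruskal–Wallis-based one.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceMatrix, ConfigError, SampleInfo, ValidationError
from .dep import bh_adjust

SEVERITY_SCORE = {"mild": 1, "moderate": 2, "severe": 3}


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    reason: str | None  # None when defined; else "insufficient_n"/"constant_input"


class KruskalResult(NamedTuple):
    h: float
    df: int
    p: float
    reason: str | None


class BootstrapCI(NamedTuple):
    low: float
    high: float
    n_dropped: int
    unreliable: bool


@dataclass
class ScreenConfig:
    min_n: int = 8
    min_groups: int = 2
    n_boot: int = 1000
    ci_level: float = 0.95
    rho_min: float = 0.75
    q_max: float = 0.05
    q_on: str = "kw"  # q-values from "kw" or "spearman" p-values
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.q_max < 1:
            raise ConfigError("q_max must be in (0,1)")
        if not 0 < self.rho_min <= 1:
            raise ConfigError("rho_min must be in (0,1]")
        if self.q_on not in ("kw", "spearman"):
            raise ConfigError("q_on must be 'kw' or 'spearman'")
        if self.min_n < 3:
            raise ConfigError("min_n must be ≥3")


def severity_scores(info: SampleInfo) -> pd.Series:
    """Ordinal severity encoding, fixed mild→1, moderate→2, severe→3."""
    return info.severity.map(SEVERITY_SCORE).astype(int)


def enumerate_pairs(ids) -> list[tuple[str, str]]:
    """All unordered unique pairs in canonical (lexicographic) order."""
    unique = sorted(set(ids))
    if len(unique) < 2:
        raise ValidationError("need ≥2 protein ids to enumerate pairs")
    return list(itertools.combinations(unique, 2))


def pair_ratio_series(matrix: AbundanceMatrix, pair: tuple[str, str]) -> pd.Series:
    """Per-sample log2 ratio a − b; missing where either protein is missing."""
    a, b = pair
    for pid in pair:
        if pid not in matrix.data.index:
            raise ValidationError(f"protein {pid!r} not in matrix")
    return matrix.data.loc[a] - matrix.data.loc[b]


def spearman_rho(x, y) -> SpearmanResult:
    """Tie-aware Spearman correlation (Pearson on midranks) of complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return SpearmanResult(np.nan, np.nan, "insufficient_n")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(np.nan, np.nan, "constant_input")
    res = stats.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue), None)


def _batch_spearman(xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of pre-ranked matrices."""
    xc = xr - xr.mean(axis=1, keepdims=True)
    yc = yr - yr.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom


def bootstrap_ci(
    x, y, n_boot: int = 1000, level: float = 0.95, seed: int = 0,
    max_retry_rounds: int = 10,
) -> BootstrapCI:
    """Percentile bootstrap CI for Spearman ρ over participant resamples.

    Participants are resampled jointly (x, y together).  Degenerate
    resamples — constant x or y, or fewer than 3 distinct pairs — are
    redrawn up to ``max_retry_rounds`` passes, then dropped with a count;
    the CI is flagged unreliable when more than half the requested resamples
    are ultimately degenerate.  Deterministic under a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return BootstrapCI(np.nan, np.nan, n_boot, True)
    if n_boot <= 0:
        return BootstrapCI(np.nan, np.nan, 0, False)
    rng = np.random.default_rng(seed)

    def degenerate(idx: np.ndarray) -> np.ndarray:
        xs, ys = x[idx], y[idx]
        const = (np.ptp(xs, axis=1) == 0) | (np.ptp(ys, axis=1) == 0)
        distinct = np.array(
            [len({(a, b) for a, b in zip(xs[i], ys[i])}) for i in range(idx.shape[0])]
        )
        return const | (distinct < 3)

    idx = rng.integers(0, n, size=(n_boot, n))
    bad = degenerate(idx)
    for _ in range(max_retry_rounds):
        if not bad.any():
            break
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        idx[bad] = redraw
        bad_new = np.zeros_like(bad)
        bad_new[bad] = degenerate(redraw)
        bad = bad_new
    keep = ~bad
    n_dropped = int(bad.sum())
    if keep.sum() == 0:
        return BootstrapCI(np.nan, np.nan, n_dropped, True)
    xs, ys = x[idx[keep]], y[idx[keep]]
    rhos = _batch_spearman(
        stats.rankdata(xs, axis=1), stats.rankdata(ys, axis=1)
    )
    rhos = rhos[np.isfinite(rhos)]
    if rhos.size == 0:
        return BootstrapCI(np.nan, np.nan, n_dropped, True)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(rhos, [alpha, 1.0 - alpha])
    return BootstrapCI(float(low), float(high), n_dropped, n_dropped > n_boot / 2)


def kruskal_wallis(values, group_labels) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H with χ² p (df = non-empty groups − 1)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    groups = [values[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        return KruskalResult(np.nan, 0, np.nan, "fewer_than_2_groups")
    if values.size < 5:
        return KruskalResult(np.nan, len(groups) - 1, np.nan, "insufficient_n")
    if np.ptp(values) == 0:
        return KruskalResult(0.0, len(groups) - 1, 1.0, None)
    h, p = stats.kruskal(*groups)
    return KruskalResult(float(h), len(groups) - 1, float(p), None)


def estimate_pi0(p_values, lambdas=None) -> float:
    """Storey's smoother estimate of the null proportion π0.

    π0(λ) = #{p > λ} / (m(1−λ)) over λ = 0.05…0.95; a cubic least-squares
    smoother in λ is evaluated at λ = 0.95 and clipped to (0, 1].  Falls back
    to π0 = 1 (q ≡ BH) when too few p-values are available or the smoother
    is unstable.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m < 10:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    try:
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    except np.linalg.LinAlgError:
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def storey_qvalues(p_values, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values: π0 × BH step-up adjustment (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValidationError("pi0 must lie in (0, 1]")
    return pi0 * bh_adjust(p), pi0


def _pair_seed(seed: int, pair: tuple[str, str]) -> np.random.SeedSequence:
    """Per-pair child seed from the pipeline seed and the canonical pair name.

    Deterministic and independent of the order pairs are evaluated in.
    """
    tag = zlib.crc32(f"{pair[0]}|{pair[1]}".encode())
    return np.random.SeedSequence([seed, tag])


def screen(
    matrix: AbundanceMatrix,
    info: SampleInfo,
    dep_ids,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the all-pairs ratio screen.

    Returns ``(retained, audit)``: the ranked table of pairs passing
    q < q_max and |ρ| ≥ rho_min, and the full unfiltered audit table with
    reason codes for untested pairs and both q-value variants.
    """
    config = config or ScreenConfig()
    config.validate()
    # canonical (sorted) sample order: bootstrap resampling then gives
    # identical draws however the input columns were ordered
    matrix = AbundanceMatrix(
        matrix.data[sorted(matrix.sample_ids)], log2=matrix.log2
    )
    info = info.aligned_to(matrix)
    scores = severity_scores(info).to_numpy()
    severity = info.severity.to_numpy()
    pairs = enumerate_pairs(dep_ids)

    rows = []
    for pair in pairs:
        ratio = pair_ratio_series(matrix, pair).to_numpy()
        ok = ~np.isnan(ratio)
        n = int(ok.sum())
        groups_present = len(pd.unique(severity[ok]))
        row = {
            "protein_a": pair[0], "protein_b": pair[1], "n": n,
            "groups_present": groups_present, "rho": np.nan, "spearman_p": np.nan,
            "rho_ci_low": np.nan, "rho_ci_high": np.nan, "ci_unreliable": False,
            "kw_h": np.nan, "kw_df": 0, "kw_p": np.nan, "reason": "",
        }
        if n < config.min_n:
            row["reason"] = "n_below_min"
            rows.append(row)
            continue
        if groups_present < config.min_groups:
            row["reason"] = "too_few_severity_groups"
            rows.append(row)
            continue
        sp = spearman_rho(ratio, scores)
        if sp.reason is not None:
            row["reason"] = f"spearman_{sp.reason}"
            rows.append(row)
            continue
        row["rho"], row["spearman_p"] = sp.rho, sp.p
        kw = kruskal_wallis(ratio, severity)
        row["kw_h"], row["kw_df"], row["kw_p"] = kw.h, kw.df, kw.p
        if kw.reason is not None:
            row["reason"] = f"kw_{kw.reason}"
            rows.append(row)
            continue
        if config.n_boot > 0:
            child = _pair_seed(config.seed, pair)
            ci = bootstrap_ci(
                ratio, scores, n_boot=config.n_boot, level=config.ci_level,
                seed=child,
            )
            row["rho_ci_low"], row["rho_ci_high"] = ci.low, ci.high
            row["ci_unreliable"] = ci.unreliable
        rows.append(row)

    audit = pd.DataFrame(rows)
    if audit.empty:
        import warnings

        warnings.warn("zero testable pairs", stacklevel=2)
        return audit.copy(), audit

    # q-values over pairs with a defined test p-value (both variants for audit)
    audit["q"] = np.nan
    audit["q_spearman"] = np.nan
    for col, qcol in (("kw_p", "q"), ("spearman_p", "q_spearman")):
        defined = audit[col].notna()
        if defined.any():
            qvals, _ = storey_qvalues(audit.loc[defined, col].to_numpy())
            audit.loc[defined, qcol] = qvals
    gate_q = "q" if config.q_on == "kw" else "q_spearman"

    tested = audit[audit[gate_q].notna() & audit["rho"].notna()]
    retained = tested[
        (tested[gate_q] < config.q_max) & (tested["rho"].abs() >= config.rho_min)
    ].copy()
    retained = retained.sort_values(
        by=["rho", "kw_p", "protein_a", "protein_b"],
        key=lambda s: -s.abs() if s.name == "rho" else s,
    ).reset_index(drop=True)
    retained.insert(0, "rank", np.arange(1, len(retained) + 1))
    cols = ["rank", "protein_a", "protein_b", "n", "rho", "rho_ci_low",
            "rho_ci_high", "spearman_p", "kw_p", "q"]
    return retained[cols + [c for c in retained.columns if c not in cols]], audit


def named_ratio_trend(
    matrix: AbundanceMatrix, info: SampleInfo, pair: tuple[str, str]
) -> tuple[pd.Series, float]:
    """Group-wise median log2 ratios plus the Spearman ρ vs severity.

    Utility for single named ratios of interest (e.g. a YWHAG/NPTX2-style
    severity trend panel); ρ is NaN when undefined (constant ratio).
    """
    info = info.aligned_to(matrix)
    ratio = pair_ratio_series(matrix, pair)
    medians = ratio.groupby(info.severity).median()
    medians = medians.reindex([s for s in SEVERITY_SCORE if s in medians.index])
    sp = spearman_rho(ratio.to_numpy(), severity_scores(info).to_numpy())
    return medians, sp.rho
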