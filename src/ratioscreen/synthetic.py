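"""Synthetic label-free proteomics data with planted, recoverable signal.

Emulates the statistical structure of a small CSF LFQ cohort: 31 samples in
severity groups mild/moderate/severe of 3/21/7 with 9 POTS-positive
participants, ~900 proteins with protein-specific means and dispersions, and
abundance-dependent (left-censored, MNAR) missingness so that low-abundance
proteins fall below the detection filter while the bulk of the proteome stays
quantifiable in most samples.

Two kinds of signal can be planted, on disjoint protein sets:

* **DEP proteins** — shifted by a fixed log2 fold change in one severity
  contrast (default severe vs. mild baseline), exercising the moderated-t
  differential expression stage.
* **Ratio pairs** — protein pairs (A, B) whose per-participant log-ratio
  ``log2 A − log2 B`` is a monotone function of the ordinal severity score
  plus Gaussian noise.  The noise SD is calibrated by Monte Carlo so the
  Spearman correlation of the ratio with severity hits ``planted_pair_rho``
  in expectation.  Both proteins share a participant-level random effect, so
  the pair signal lives in the ratio, not (only) in the marginals.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AbundanceMatrix,
    ConfigError,
    SampleInfo,
    _header_line,
    read_matrix,
    read_metadata,
    write_matrix,
    write_metadata,
)

SEVERITY_ORDER = ("mild", "moderate", "severe")


@dataclass
class SimConfig:
    """Generator configuration; defaults mirror the study cohort shape."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"mild": 3, "moderate": 21, "severe": 7}
    )
    n_pots: int = 9
    n_proteins: int = 900
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.5
    protein_sd_range: tuple[float, float] = (0.25, 0.9)
    n_planted_deps: int = 0
    planted_log2fc: float = 0.7
    dep_contrast: str = "Severe_vs_Mild"
    n_planted_pairs: int = 0
    planted_pair_rho: float = 0.9
    pair_ratio_step: float = 1.0  # log2-ratio increment per severity level
    censor_quantile: float = 0.13
    censor_mode: str = "global"  # "global" (pooled intensity cutoff) or "per_protein"
    pots_severity_dependent: bool = False
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        if set(self.group_sizes) != set(SEVERITY_ORDER):
            raise ConfigError(f"group_sizes must key exactly {SEVERITY_ORDER}")
        if any(n < 0 for n in self.group_sizes.values()) or self.n_samples < 2:
            raise ConfigError("group sizes must be non-negative and sum to ≥2")
        if self.n_pots > self.n_samples:
            raise ConfigError("n_pots cannot exceed n_samples")
        if not 0 <= self.censor_quantile < 1:
            raise ConfigError("censor_quantile must be in [0, 1)")
        if self.censor_mode not in ("global", "per_protein"):
            raise ConfigError("censor_mode must be 'global' or 'per_protein'")
        if not 0 < self.planted_pair_rho <= 1:
            raise ConfigError("planted_pair_rho must be in (0, 1]")
        lo, hi = self.protein_sd_range
        if not 0 < lo <= hi:
            raise ConfigError("protein_sd_range must be 0 < low ≤ high")
        needed = self.n_planted_deps + 2 * self.n_planted_pairs
        if needed > self.n_proteins:
            raise ConfigError("not enough proteins for the requested planted signal")


@dataclass
class TruthTable:
    """Ground truth of planted signal for recovery tests.

    ``deps`` rows: protein_id, contrast, true_log2fc.
    ``pairs`` rows: protein_a, protein_b, rho_sign (±1), target_rho.
    """

    deps: pd.DataFrame
    pairs: pd.DataFrame

    @staticmethod
    def empty() -> "TruthTable":
        return TruthTable(
            deps=pd.DataFrame(columns=["protein_id", "contrast", "true_log2fc"]),
            pairs=pd.DataFrame(
                columns=["protein_a", "protein_b", "rho_sign", "target_rho"]
            ),
        )


def calibrate_pair_noise_sd(
    severity_scores: np.ndarray,
    target_rho: float,
    step: float,
    rng: np.random.Generator,
    n_reps: int = 400,
    tol: float = 0.01,
) -> float:
    """Noise SD for ``ratio = step·score + ε`` hitting a target Spearman ρ.

    Monte Carlo bisection on the SD: the expected Spearman correlation of the
    noisy ratio with the ordinal score decreases monotonically in the noise
    SD, from the tie-limited maximum at SD→0 down to 0.  Returns 0 when the
    target is at or above the tie-limited maximum (e.g. target_rho = 1 forces
    a noiseless, perfectly group-ordered ratio).
    """
    scores = np.asarray(severity_scores, dtype=float)

    def mean_rho(sd: float) -> float:
        noise = rng.normal(0.0, sd, size=(n_reps, scores.size))
        ratios = step * scores[None, :] + noise
        r_ranks = stats.rankdata(ratios, axis=1)
        s_ranks = stats.rankdata(np.broadcast_to(scores, ratios.shape), axis=1)
        rc = r_ranks - r_ranks.mean(axis=1, keepdims=True)
        sc = s_ranks - s_ranks.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc**2).sum(axis=1) * (sc**2).sum(axis=1))
        return float(np.mean((rc * sc).sum(axis=1) / denom))

    # with ties broken by infinitesimal noise the attainable maximum is <1 only
    # when scores repeat; Spearman of (score + tiny noise) vs score is what
    # sd→0 converges to from above ρ(target)=1 requires sd=0 exactly
    if target_rho >= 1.0:
        return 0.0
    lo, hi = 0.0, step * (scores.max() - scores.min() + 1.0)
    while mean_rho(hi) > target_rho:
        hi *= 2.0
        if hi > 1e3 * step:
            break
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mean_rho(mid) > target_rho:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(step, 1.0) / 10:
            break
    return 0.5 * (lo + hi)


def generate_dataset(
    config: SimConfig,
) -> tuple[AbundanceMatrix, SampleInfo, TruthTable]:
    """Generate (matrix, metadata, truth) per the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- samples ---
    sample_ids, severities = [], []
    for level in SEVERITY_ORDER:
        for k in range(config.group_sizes.get(level, 0)):
            sample_ids.append(f"S{len(sample_ids) + 1:02d}")
            severities.append(level)
    n = len(sample_ids)
    severity = np.array(severities)
    score = np.array([SEVERITY_ORDER.index(s) + 1 for s in severities], dtype=float)

    if config.pots_severity_dependent:
        # weight POTS towards more severe participants
        w = score / score.sum()
        pots_idx = rng.choice(n, size=config.n_pots, replace=False, p=w)
    else:
        pots_idx = rng.choice(n, size=config.n_pots, replace=False)
    pots = np.zeros(n, dtype=bool)
    pots[pots_idx] = True

    info = SampleInfo(
        pd.DataFrame(
            {"severity": severity, "pots": pots},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # --- proteins ---
    p = config.n_proteins
    protein_ids = np.array([f"P{i + 1:04d}" for i in range(p)])
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=p)
    lo, hi = config.protein_sd_range
    sd = rng.uniform(lo, hi, size=p)

    # planted signal is placed on well-quantified (above-median abundance)
    # proteins: real reported hits necessarily pass the detection filter,
    # and left-censoring must not silently delete the planted truth
    n_planted = config.n_planted_deps + 2 * config.n_planted_pairs
    eligible = np.flatnonzero(mu >= np.median(mu))
    if n_planted > eligible.size:
        raise ConfigError("not enough well-quantified proteins for planted signal")
    planted = rng.choice(eligible, size=n_planted, replace=False)
    dep_idx = planted[: config.n_planted_deps]
    pair_a = planted[config.n_planted_deps: config.n_planted_deps + config.n_planted_pairs]
    pair_b = planted[config.n_planted_deps + config.n_planted_pairs:]

    values = mu[:, None] + rng.normal(0.0, 1.0, size=(p, n)) * sd[:, None]

    # planted DEPs: shift the contrast's numerator group
    contrast_group = {"Severe_vs_Mild": "severe", "Severe_vs_Moderate": "severe",
                      "Moderate_vs_Mild": "moderate", "POTS_vs_NoPOTS": None}
    if config.dep_contrast not in contrast_group:
        raise ConfigError(f"unknown dep_contrast {config.dep_contrast!r}")
    if config.dep_contrast == "POTS_vs_NoPOTS":
        shift_cols = pots
    else:
        shift_cols = severity == contrast_group[config.dep_contrast]
    values[np.ix_(dep_idx, np.flatnonzero(shift_cols))] += config.planted_log2fc

    # planted ratio pairs: shared participant effect + ratio split A−B
    noise_sd = None
    if config.n_planted_pairs:
        noise_sd = calibrate_pair_noise_sd(
            score, config.planted_pair_rho, config.pair_ratio_step,
            np.random.default_rng(config.seed + 10_007),
        )
    for a, b in zip(pair_a, pair_b):
        shared = rng.normal(0.0, 0.4, size=n)
        ratio = config.pair_ratio_step * score + rng.normal(0.0, noise_sd, size=n)
        values[a] = mu[a] + shared + ratio / 2.0
        values[b] = mu[b] + shared - ratio / 2.0

    # --- left-censoring ---
    if config.censor_quantile > 0:
        if config.censor_mode == "global":
            thr = np.quantile(values, config.censor_quantile)
            censored = values < thr
        else:
            thr = mu + sd * stats.norm.ppf(config.censor_quantile)
            censored = values < thr[:, None]
        # planted-pair proteins are kept clear of censoring only via their
        # means; no special-casing, so per-pair complete-case n can vary
        values = values.astype(float)
        values[censored] = np.nan

    matrix = AbundanceMatrix(
        pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                     columns=sample_ids),
        log2=True,
    )

    truth = TruthTable(
        deps=pd.DataFrame(
            {
                "protein_id": protein_ids[dep_idx],
                "contrast": config.dep_contrast,
                "true_log2fc": config.planted_log2fc,
            }
        ),
        pairs=pd.DataFrame(
            {
                "protein_a": protein_ids[pair_a],
                "protein_b": protein_ids[pair_b],
                "rho_sign": 1,
                "target_rho": config.planted_pair_rho,
            }
        ),
    )
    return matrix, info, truth


def write_dataset(
    matrix: AbundanceMatrix,
    info: SampleInfo,
    truth: TruthTable,
    directory: str | Path,
) -> dict[str, Path]:
    """Write matrix/metadata/truth TSVs; round-trips through core_io readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": write_matrix(matrix, directory / "matrix.tsv"),
        "metadata": write_metadata(info, directory / "metadata.tsv"),
        "truth": directory / "truth.tsv",
    }
    rows = []
    for _, r in truth.deps.iterrows():
        rows.append({"kind": "dep", "id_a": r["protein_id"], "id_b": "",
                     "contrast": r["contrast"], "effect": r["true_log2fc"]})
    for _, r in truth.pairs.iterrows():
        rows.append({"kind": "pair", "id_a": r["protein_a"], "id_b": r["protein_b"],
                     "contrast": "", "effect": r["rho_sign"] * r["target_rho"]})
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(_header_line("truth") + "\n")
        pd.DataFrame(rows, columns=["kind", "id_a", "id_b", "contrast", "effect"]).to_csv(
            fh, sep="\t", index=False
        )
    return paths


def read_truth(path: str | Path) -> TruthTable:
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    deps = raw[raw["kind"] == "dep"]
    pairs = raw[raw["kind"] == "pair"]
    return TruthTable(
        deps=pd.DataFrame(
            {
                "protein_id": deps["id_a"].to_numpy(),
                "contrast": deps["contrast"].to_numpy(),
                "true_log2fc": deps["effect"].astype(float).to_numpy(),
            }
        ),
        pairs=pd.DataFrame(
            {
                "protein_a": pairs["id_a"].to_numpy(),
                "protein_b": pairs["id_b"].to_numpy(),
                "rho_sign": np.sign(pairs["effect"].astype(float)).astype(int).to_numpy(),
                "target_rho": pairs["effect"].astype(float).abs().to_numpy(),
            }
        ),
    )


def read_dataset(directory: str | Path) -> tuple[AbundanceMatrix, SampleInfo, TruthTable]:
    directory = Path(directory)
    return (
        read_matrix(directory / "matrix.tsv"),
        read_metadata(directory / "metadata.tsv"),
        read_truth(directory / "truth.tsv"),
    )
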