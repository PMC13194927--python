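"""End-to-end orchestration: simulate/load → preprocess → DEP → ratios → enrich.

Every stage writes its table under the output directory with a
write-then-rename discipline (no partially written final tables), and a JSON
manifest records the configuration echo, the global seed, per-stage row
counts and the skipped-protein log.  Re-running with an identical
configuration reproduces identical outputs: all randomness flows from the
single global seed via named substreams (synthetic generation, per-pair
bootstrap seeds).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    AbundanceMatrix,
    ConfigError,
    SampleInfo,
    log2_transform,
    read_gmt,
    read_matrix,
    read_metadata,
    write_matrix,
)
from .dep import DesignSpec, nominal_dep_filter, run_dep, severity_dep_union
from .enrichment import enrich
from .preprocess import filter_by_detection, normalize, run_pca
from .ratio_screen import ScreenConfig, screen
from .synthetic import SimConfig, generate_dataset, write_dataset

log = logging.getLogger("ratioscreen")


@dataclass
class RunConfig:
    out_dir: str = "ratioscreen_run"
    seed: int = 0
    # inputs: either paths or a synthetic config
    matrix_path: str | None = None
    metadata_path: str | None = None
    input_scale: str = "log2"  # or "raw": explicit, never auto-detected
    gmt_path: str | None = None
    synthetic: SimConfig | None = None
    # preprocessing
    min_fraction: float = 1.0 / 3.0
    normalize_chain: str = "vsn_lite"
    run_pca_stage: bool = True
    # DEP thresholds
    p_max: float = 0.05
    fc_min: float = 1.5
    # screen parameters
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    screen_input: str = "severity_union"  # or a single contrast name

    def validate(self) -> None:
        if not 0 < self.p_max < 1:
            raise ConfigError("p_max must be in (0,1)")
        if self.fc_min <= 1:
            raise ConfigError("fc_min must be > 1")
        self.screen.validate()
        if self.synthetic is None and (
            self.matrix_path is None or self.metadata_path is None
        ):
            raise ConfigError("provide matrix_path+metadata_path or a synthetic config")
        if self.input_scale not in ("log2", "raw"):
            raise ConfigError("input_scale must be 'log2' or 'raw'")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        screen_cfg = raw.pop("screen", None)
        config = RunConfig(**raw)
        if syn is not None:
            if "group_sizes" in syn:
                syn["group_sizes"] = dict(syn["group_sizes"])
            if "protein_sd_range" in syn:
                syn["protein_sd_range"] = tuple(syn["protein_sd_range"])
            config.synthetic = SimConfig(**syn)
        if screen_cfg is not None:
            config.screen = ScreenConfig(**screen_cfg)
        return config


def _atomic_write(frame: pd.DataFrame, path: Path, index: bool = False) -> int:
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, sep="\t", index=index, na_rep="")
    os.replace(tmp, path)
    return len(frame)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str, t0: float, rows_in: int, rows_out: int, **extra) -> None:
        rec = {"duration_s": round(time.time() - t0, 3),
               "rows_in": rows_in, "rows_out": rows_out, **extra}
        manifest["stages"][name] = rec
        log.info("stage=%s duration=%.3fs rows_in=%d rows_out=%d",
                 name, rec["duration_s"], rows_in, rows_out)

    try:
        # --- input ---
        t0 = time.time()
        if config.synthetic is not None:
            syn = config.synthetic
            syn.seed = config.seed  # single global seed feeds the generator
            matrix, info, truth = generate_dataset(syn)
            write_dataset(matrix, info, truth, out / "synthetic")
            manifest["truth_deps"] = len(truth.deps)
            manifest["truth_pairs"] = len(truth.pairs)
        else:
            matrix = read_matrix(config.matrix_path, log2=config.input_scale == "log2")
            if config.input_scale == "raw":
                matrix = log2_transform(matrix)
            info = read_metadata(config.metadata_path)
        info = info.aligned_to(matrix)
        stage("input", t0, matrix.n_proteins, matrix.n_proteins,
              n_samples=matrix.n_samples)

        # --- preprocess ---
        t0 = time.time()
        filtered = filter_by_detection(matrix, config.min_fraction)
        normed, report = normalize(filtered, config.normalize_chain)
        write_matrix(normed, out / "normalized.tsv")
        _atomic_write(
            report.params.assign(method=report.method,
                                 trend_before=report.trend_before,
                                 trend_after=report.trend_after),
            out / "norm_report.tsv", index=True,
        )
        stage("preprocess", t0, matrix.n_proteins, normed.n_proteins,
              normalization=config.normalize_chain)

        if config.run_pca_stage:
            t0 = time.time()
            pca = run_pca(normed)
            scores = pca.scores.copy()
            _atomic_write(scores, out / "pca_scores.tsv", index=True)
            stage("pca", t0, normed.n_proteins, len(scores),
                  explained_pc1=float(pca.explained_variance_fraction[0]))

        # --- differential expression ---
        t0 = time.time()
        records, params, fit_result = run_dep(normed, info, DesignSpec())
        _atomic_write(records, out / "dep.tsv")
        _atomic_write(
            pd.DataFrame(fit_result.skipped, columns=["protein_id", "reason"]),
            out / "dep_skipped.tsv",
        )
        per_contrast, union = nominal_dep_filter(records, config.p_max, config.fc_min)
        manifest["dep_counts"] = {k: len(v) for k, v in per_contrast.items()}
        manifest["dep_union"] = len(union)
        manifest["moderation"] = {"d0": params.d0 if np.isfinite(params.d0) else "inf",
                                  "s0_sq": params.s0_sq}
        stage("dep", t0, normed.n_proteins, len(records),
              skipped=len(fit_result.skipped))

        # --- ratio screen ---
        t0 = time.time()
        if config.screen_input == "severity_union":
            dep_ids = severity_dep_union(records, config.p_max, config.fc_min)
        else:
            dep_ids = per_contrast.get(config.screen_input, [])
        manifest["screen_input_size"] = len(dep_ids)
        config.screen.seed = config.seed
        if len(dep_ids) >= 2:
            retained, audit = screen(normed, info, dep_ids, config.screen)
            _atomic_write(retained, out / "ratios.tsv")
            _atomic_write(audit, out / "ratios_all.tsv")
            manifest["retained_pairs"] = len(retained)
            manifest["tested_pairs"] = int(audit["kw_p"].notna().sum()) if len(audit) else 0
            stage("ratios", t0, len(dep_ids), len(retained))
        else:
            manifest["retained_pairs"] = 0
            manifest["tested_pairs"] = 0
            stage("ratios", t0, len(dep_ids), 0, note="fewer than 2 DEP ids")

        # --- enrichment ---
        if config.gmt_path:
            t0 = time.time()
            collection = read_gmt(config.gmt_path)
            background = normed.protein_ids
            tables = []
            for contrast in DesignSpec().contrasts:
                table = enrich(records, contrast, collection, background,
                               config.p_max, config.fc_min)
                table.insert(0, "contrast", contrast)
                tables.append(table)
            enrich_table = pd.concat(tables, ignore_index=True)
            _atomic_write(enrich_table, out / "enrichment.tsv")
            stage("enrich", t0, len(collection), len(enrich_table))
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest["config"] = _config_echo(config)
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    os.replace(tmp, out / "manifest.json")
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    return echo
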