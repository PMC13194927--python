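"""Checks against the study's published supplementary tables, when available.

The article's "Supporting Data Values" workbook (VSN-normalized protein
matrix plus differential-expression result tables) is not redistributable
with this package.  A user who has it can export the sheets to the package's
TSV dialects (matrix: ``protein_id`` + one column per sample; DEP table:
``protein_id``, ``contrast``, ``log2fc``, ``p``) and point these helpers at
them to reproduce the published counts and ratio statistics:

* nominal DEP counts per contrast and the de-duplicated severity union;
* the ratio screen on the published matrix with the published DEP set,
  whose top pairs can be compared against the printed Spearman ρ values;
* the severity trend of a named ratio such as YWHAG/NPTX2.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .core_io import AbundanceMatrix, SampleInfo, ValidationError, read_matrix, read_metadata
from .dep import SEVERITY_CONTRASTS
from .ratio_screen import ScreenConfig, named_ratio_trend, screen

#: conventional location where a user drops the exported supplementary TSVs
DEFAULT_DIR = Path("data/supporting_data_values")


def load_supplementary(directory: str | Path = DEFAULT_DIR):
    """Load (vsn_matrix, metadata, dep_table) exported from the workbook."""
    directory = Path(directory)
    matrix_path = directory / "vsn_matrix.tsv"
    meta_path = directory / "metadata.tsv"
    dep_path = directory / "dep_results.tsv"
    for p in (matrix_path, meta_path, dep_path):
        if not p.exists():
            raise FileNotFoundError(
                f"supplementary export not found: {p} — export the published "
                "Supporting Data Values sheets to this layout to run the checks"
            )
    matrix = read_matrix(matrix_path)
    info = read_metadata(meta_path)
    dep_table = pd.read_csv(dep_path, sep="\t", comment="#")
    for col in ("protein_id", "contrast", "log2fc", "p"):
        if col not in dep_table.columns:
            raise ValidationError(f"dep_results.tsv missing column {col!r}")
    return matrix, info, dep_table


def published_dep_counts(
    dep_table: pd.DataFrame, p_max: float = 0.05, fc_min: float = 1.5
) -> dict[str, int]:
    """Nominal DEP counts per contrast and the severity union."""
    log2_thr = math.log2(fc_min)
    hits = dep_table[
        (dep_table["p"] < p_max) & (dep_table["log2fc"].abs() > log2_thr)
    ]
    counts = {
        c: int((hits["contrast"] == c).sum()) for c in dep_table["contrast"].unique()
    }
    sev = hits[hits["contrast"].isin(SEVERITY_CONTRASTS)]
    counts["severity_union"] = int(sev["protein_id"].nunique())
    return counts


def published_ratio_screen(
    matrix: AbundanceMatrix,
    info: SampleInfo,
    dep_table: pd.DataFrame,
    seed: int = 0,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Run the severity ratio screen on the published matrix and DEP set."""
    log2_thr = math.log2(1.5)
    hits = dep_table[
        (dep_table["p"] < 0.05)
        & (dep_table["log2fc"].abs() > log2_thr)
        & (dep_table["contrast"].isin(SEVERITY_CONTRASTS))
    ]
    dep_ids = [p for p in hits["protein_id"].unique() if p in matrix.data.index]
    retained, audit = screen(
        matrix, info, dep_ids, ScreenConfig(seed=seed, n_boot=n_boot)
    )
    return retained


def named_pair_rho(
    matrix: AbundanceMatrix, info: SampleInfo, pair: tuple[str, str]
) -> float:
    _, rho = named_ratio_trend(matrix, info, pair)
    return rho
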