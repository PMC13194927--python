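"""Data model and readers/writers shared by all pipeline stages.

The central object is :class:`AbundanceMatrix`, a proteins × samples table of
log2 label-free quantification (LFQ) intensities with explicit missingness
(``NaN`` internally; empty/``NA``/``NaN`` tokens on disk).  Sample metadata
carries the clinical annotations the models use: a three-level disease
severity label (mild/moderate/severe) and a binary POTS flag, plus arbitrary
extra covariates.

All tabular files are UTF-8 TSV (or CSV by extension) with a single comment
header line ``# ratioscreen v<version> schema=<name>``.  Readers reject
structurally invalid input (duplicate identifiers, non-numeric cells, unknown
severity labels) rather than silently coercing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = "0.1"

SEVERITY_LEVELS = ("mild", "moderate", "severe")

#: Tokens (case-insensitive) recognised as missing values on disk.  Nothing
#: else is treated as missing: any other non-numeric cell is a parse error.
MISSING_TOKENS = frozenset({"", "na", "nan"})


class RatioscreenError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(RatioscreenError):
    """Malformed input file (bad header, non-numeric cell, short line...)."""


class ValidationError(RatioscreenError):
    """Structurally valid file whose content violates a contract."""


class ConfigError(RatioscreenError):
    """Invalid configuration."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Proteins × samples abundance table with explicit missingness.

    Parameters
    ----------
    data:
        DataFrame indexed by protein id with one float column per sample.
        ``NaN`` marks a missing (undetected) measurement.
    log2:
        True when values are on the log2 intensity scale (the canonical
        internal scale).  Raw-intensity matrices are only ever held
        transiently (e.g. inside vsn-style calibration).
    """

    data: pd.DataFrame
    log2: bool = True

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise ValidationError("abundance matrix contains non-finite values")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def mask(self) -> np.ndarray:
        """Boolean missingness indicator, True where the value is undefined."""
        return self.data.isna().to_numpy()

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def detection_counts(self) -> pd.Series:
        """Number of samples in which each protein is observed."""
        return self.data.notna().sum(axis=1)

    def subset_proteins(self, ids: list[str]) -> "AbundanceMatrix":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise ValidationError(f"unknown protein ids: {missing[:5]}")
        return AbundanceMatrix(self.data.loc[ids].copy(), log2=self.log2)


@dataclass
class SampleInfo:
    """Per-sample clinical annotations.

    ``table`` is indexed by sample id with columns ``severity`` (one of
    mild/moderate/severe), ``pots`` (bool) and any extra covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        for col in ("severity", "pots"):
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        bad = set(self.table["severity"]) - set(SEVERITY_LEVELS)
        if bad:
            raise ValidationError(
                f"unknown severity labels {sorted(bad)}; allowed: {list(SEVERITY_LEVELS)}"
            )
        self.table = self.table.copy()
        self.table["pots"] = self.table["pots"].astype(bool)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def severity(self) -> pd.Series:
        return self.table["severity"]

    @property
    def pots(self) -> pd.Series:
        return self.table["pots"]

    def aligned_to(self, matrix: AbundanceMatrix) -> "SampleInfo":
        """Reorder metadata to the matrix column order; sets must match."""
        mat_ids, meta_ids = set(matrix.sample_ids), set(self.table.index)
        if mat_ids != meta_ids:
            missing = sorted(mat_ids - meta_ids)
            extra = sorted(meta_ids - mat_ids)
            raise ValidationError(
                f"sample ids disagree between matrix and metadata; "
                f"missing from metadata: {missing}; not in matrix: {extra}"
            )
        return SampleInfo(self.table.loc[matrix.sample_ids])


@dataclass
class GeneSetCollection:
    """Named gene/protein sets (GMT-style), e.g. pathway collections."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} has no members")
            if len(members) != len(set(members)):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _header_line(schema: str) -> str:
    return f"# ratioscreen v{SCHEMA_VERSION} schema={schema}"


def _read_table(path: Path) -> pd.DataFrame:
    """Read a TSV/CSV as strings, skipping ``#`` comment lines."""
    try:
        return pd.read_csv(
            path, sep=_sep_for(path), comment="#", dtype=str,
            keep_default_na=False, skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: {exc}") from exc


def read_matrix(path: str | Path, log2: bool = True) -> AbundanceMatrix:
    """Read a protein × sample abundance matrix.

    First column holds protein ids, remaining columns one sample each.
    Missing cells: empty string, ``NA`` or ``NaN`` (case-insensitive).
    """
    path = Path(path)
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: matrix needs an id column and ≥1 sample column")
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        raise ParseError(
            f"{path}: duplicate protein ids: {ids[ids.duplicated()].unique()[:5].tolist()}"
        )
    data = {}
    for col in raw.columns[1:]:
        parsed = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            token = cell.strip()
            if token.lower() in MISSING_TOKENS:
                parsed[i] = np.nan
                continue
            try:
                parsed[i] = float(token)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at protein {ids.iloc[i]!r}, "
                    f"sample {col!r}"
                ) from None
        data[col] = parsed
    frame = pd.DataFrame(data, index=pd.Index(ids, name="protein_id"))
    return AbundanceMatrix(frame, log2=log2)


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line("matrix") + "\n")
        out = matrix.data.copy()
        out.index.name = "protein_id"
        out.to_csv(fh, sep=sep, na_rep="", float_format="%.6f")
    return path


_TRUE_TOKENS = {"1", "true"}
_FALSE_TOKENS = {"0", "false"}


def read_metadata(path: str | Path) -> SampleInfo:
    """Read the sample metadata table (sample_id, severity, pots, extras)."""
    path = Path(path)
    raw = _read_table(path)
    cols = {c.lower(): c for c in raw.columns}
    for need in ("sample_id", "severity", "pots"):
        if need not in cols:
            raise ParseError(f"{path}: metadata missing required column {need!r}")
    ids = raw[cols["sample_id"]].astype(str)
    if ids.duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    severity = raw[cols["severity"]].str.strip().str.lower()
    bad = sorted(set(severity) - set(SEVERITY_LEVELS))
    if bad:
        raise ParseError(
            f"{path}: unknown severity labels {bad}; allowed: {list(SEVERITY_LEVELS)}"
        )
    pots = []
    for cell in raw[cols["pots"]]:
        token = str(cell).strip().lower()
        if token in _TRUE_TOKENS:
            pots.append(True)
        elif token in _FALSE_TOKENS:
            pots.append(False)
        else:
            raise ParseError(
                f"{path}: POTS value {cell!r} not in {{0,1,true,false}}"
            )
    table = pd.DataFrame(
        {"severity": severity.to_numpy(), "pots": pots},
        index=pd.Index(ids, name="sample_id"),
    )
    extra_cols = [c for c in raw.columns
                  if c not in {cols["sample_id"], cols["severity"], cols["pots"]}]
    for col in extra_cols:
        series = raw[col]
        try:
            table[col] = series.astype(float)
        except ValueError:
            table[col] = series.to_numpy()
    return SampleInfo(table)


def write_metadata(info: SampleInfo, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_line("metadata") + "\n")
        out = info.table.copy()
        out["pots"] = out["pots"].astype(int)
        out.index.name = "sample_id"
        out.to_csv(fh, sep=_sep_for(path))
    return path


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB member...

    Duplicate members within a line are stored once (first occurrence wins).
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs ≥3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (description, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, (description, members) in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
    return path


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Explicit raw-intensity → log2 transform (never auto-detected)."""
    if matrix.log2:
        raise ValidationError("matrix is already flagged log2; refusing to re-log")
    vals = matrix.data.to_numpy()
    if np.nanmin(vals) <= 0:
        raise ValidationError("raw intensities must be positive for log2 transform")
    return AbundanceMatrix(np.log2(matrix.data), log2=True)


def ceil_detection_threshold(n_samples: int, min_fraction: float) -> int:
    """Minimum number of observed samples implied by a detection fraction.

    Uses the ceiling so that for the 31-sample cohort a fraction of 1/3
    yields a threshold of 11 samples ("detected in at least eleven (33.3%)
    samples").
    """
    if not 0 < min_fraction <= 1:
        raise ConfigError("min_fraction must be in (0, 1]")
    return math.ceil(min_fraction * n_samples - 1e-9)
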