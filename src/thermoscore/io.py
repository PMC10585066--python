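"""Domain types, file readers/writers and configuration.

Expression values are log2-scale throughout; raw-intensity inputs must be
log2-transformed at ingestion. Missing expression values are carried as NaN
and dropped by group aggregates (an aggregate over fewer than two non-missing
replicates is an error in the analysis stages).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "ValidationError",
    "TREATMENTS",
    "SampleInfo",
    "ExpressionStudy",
    "PromoterSet",
    "Motif",
    "PipelineConfig",
    "get_logger",
    "read_expression_study",
    "write_expression_study",
    "read_promoters",
    "read_physio_table",
    "validate_physio_table",
    "write_table",
    "read_table",
]

#: Treatment vocabulary: 25 degC control, stepwise 40->50 degC ramp, acute 50 degC.
TREATMENTS = ("control_25", "stepwise_40_50", "acute_50")

#: Physiological parameters expected for every cultivar.
PHYSIO_PARAMETERS = (
    "fvfm_before",
    "fvfm_after",
    "root_wt_before_g",
    "root_wt_after_g",
    "shoot_wt_before_g",
    "shoot_wt_after_g",
    "lwi",
)

MISSING_MARKER = "NA"

_LOG_CONFIGURED = False


def get_logger(stage: str) -> logging.Logger:
    """Return a stage-tagged logger writing to standard error."""
    global _LOG_CONFIGURED
    root = logging.getLogger("thermoscore")
    if not _LOG_CONFIGURED:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
        _LOG_CONFIGURED = True
    return root.getChild(stage)


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates its contract."""


@dataclass(frozen=True)
class SampleInfo:
    """One microarray/qPCR sample: which cultivar, treatment, time and replicate."""

    sample_id: str
    cultivar: str
    treatment: str
    time_h: float
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown treatment {self.treatment!r}; "
                f"expected one of {TREATMENTS}"
            )
        if self.time_h < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative time_h")
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass
class ExpressionStudy:
    """A genes x samples matrix of log2 expression plus its sample annotations."""

    genes: list[str]
    samples: list[SampleInfo]
    values: np.ndarray  # genes x samples, float, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dup = _first_duplicate(self.genes)
            raise ValidationError(f"duplicate gene id {dup!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = _first_duplicate(ids)
            raise ValidationError(f"duplicate sample id {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def cultivars(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.cultivar, None)
        return list(seen)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def select(
        self,
        cultivar: str | None = None,
        treatment: str | None = None,
        time_h: float | None = None,
    ) -> list[int]:
        """Column indices of samples matching all given selectors."""
        out = []
        for j, s in enumerate(self.samples):
            if cultivar is not None and s.cultivar != cultivar:
                continue
            if treatment is not None and s.treatment != treatment:
                continue
            if time_h is not None and abs(s.time_h - time_h) > 1e-9:
                continue
            out.append(j)
        return out

    def replicate_values(
        self, cultivar: str, treatment: str, time_h: float | None = None
    ) -> np.ndarray:
        """genes x replicates slice for one (cultivar, treatment[, time]) cell.

        Errors when fewer than two replicate columns resolve, because every
        downstream aggregate needs a dispersion estimate.
        """
        cols = self.select(cultivar, treatment, time_h)
        if len(cols) < 2:
            raise ValidationError(
                f"selector (cultivar={cultivar!r}, treatment={treatment!r}, "
                f"time_h={time_h!r}) resolves to {len(cols)} replicate(s); need >= 2"
            )
        return self.values[:, cols]


#: gene id -> uppercase promoter sequence over {A,C,G,T,N}, 5'->3' toward the start site.
PromoterSet = dict


@dataclass(frozen=True)
class Motif:
    """A named cis-element as ordered degenerate modules (IUPAC subset N/R/K).

    Module strings are concatenated for matching; ``required_module_count``
    says how many leading modules (contiguous, in order) must match.
    """

    name: str
    modules: tuple[str, ...]
    required_module_count: int | None = None

    ALLOWED = frozenset("ACGTNRK")

    def __post_init__(self) -> None:
        if not self.modules or any(not m for m in self.modules):
            raise ValidationError(f"motif {self.name!r}: modules must be non-empty")
        for m in self.modules:
            bad = set(m.upper()) - self.ALLOWED
            if bad:
                raise ValidationError(
                    f"motif {self.name!r}: invalid IUPAC symbol(s) {sorted(bad)}"
                )
        k = self.required_module_count
        if k is not None and not (1 <= k <= len(self.modules)):
            raise ValidationError(
                f"motif {self.name!r}: required_module_count {k} out of range"
            )
        object.__setattr__(self, "modules", tuple(m.upper() for m in self.modules))

    @property
    def pattern(self) -> str:
        k = self.required_module_count or len(self.modules)
        return "".join(self.modules[:k])


@dataclass
class PipelineConfig:
    """Tunable thresholds and sizes for the whole pipeline.

    Thresholds are on the log2 scale; ``biomarker_*`` defaults are the printed
    selection criteria (induction > 6, tolerant/sensitive ratio > 1.4,
    absolute stress level > 12).
    """

    upstream_len: int = 1000
    top_n: int = 100
    null_set_size: int = 100
    null_reps: int = 1000
    rng_seed: int = 0
    fc_call_log2: float = 1.0
    call_alpha: float = 0.05
    diff_induction_log2: float = 1.0
    biomarker_induction_min_log2: float = 6.0
    biomarker_at_over_sf_min_log2: float = 1.4
    biomarker_level_min_log2: float = 12.0
    strand_mode: str = "forward"
    zscore_ddof: int = 1

    def __post_init__(self) -> None:
        if self.strand_mode not in ("forward", "both"):
            raise ValidationError(f"strand_mode must be forward|both, got {self.strand_mode!r}")
        if self.null_reps < 2 or self.null_set_size < 2:
            raise ValidationError("null_reps and null_set_size must both be >= 2")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValidationError(f"config field {f.name} is not finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_study(matrix_path: str | Path, sample_sheet_path: str | Path) -> ExpressionStudy:
    """Read a genes x samples log2 TSV and its sample sheet, reconciled by sample_id.

    The matrix header row carries sample ids and the first column gene ids.
    The sheet needs columns sample_id, cultivar, treatment, time_h, replicate.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in mat.index]
    dup = _first_duplicate(gene_ids)
    if dup:
        raise ValidationError(f"duplicate gene id {dup!r} in {matrix_path}")

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "cultivar", "treatment", "time_h", "replicate"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise ValidationError(f"sample sheet missing column(s): {sorted(missing_cols)}")

    sheet_ids = list(sheet["sample_id"])
    matrix_ids = [str(c) for c in mat.columns]
    only_matrix = set(matrix_ids) - set(sheet_ids)
    if only_matrix:
        raise ValidationError(
            f"sample(s) in matrix absent from sheet: {sorted(only_matrix)}"
        )
    only_sheet = set(sheet_ids) - set(matrix_ids)
    if only_sheet:
        raise ValidationError(
            f"sample(s) in sheet absent from matrix: {sorted(only_sheet)}"
        )

    samples = [
        SampleInfo(
            sample_id=row.sample_id,
            cultivar=row.cultivar,
            treatment=row.treatment,
            time_h=float(row.time_h),
            replicate=int(row.replicate),
        )
        for row in sheet.itertuples()
    ]
    # reorder matrix columns to the sheet's sample order
    mat = mat[[s.sample_id for s in samples]]

    values = np.empty(mat.shape, dtype=float)
    for j, col in enumerate(mat.columns):
        for i, cell in enumerate(mat[col]):
            if cell == MISSING_MARKER or (isinstance(cell, float) and np.isnan(cell)):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric cell {cell!r} at gene {gene_ids[i]!r}, sample {col!r}"
                ) from None
    return ExpressionStudy(genes=gene_ids, samples=samples, values=values)


def write_expression_study(study: ExpressionStudy, matrix_path: str | Path, sample_sheet_path: str | Path) -> None:
    """Inverse of :func:`read_expression_study` (NaN rendered as the missing marker)."""
    df = pd.DataFrame(study.values, index=study.genes, columns=study.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", na_rep=MISSING_MARKER, float_format="%.10g")
    sheet = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in study.samples],
            "cultivar": [s.cultivar for s in study.samples],
            "treatment": [s.treatment for s in study.samples],
            "time_h": [s.time_h for s in study.samples],
            "replicate": [s.replicate for s in study.samples],
        }
    )
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


_DNA_ALPHABET = frozenset("ACGTN")


def read_promoters(fasta_path: str | Path, upstream_len: int = 1000) -> PromoterSet:
    """Read 1-kb upstream promoter sequences from FASTA, keyed by record id.

    Records longer than ``upstream_len`` keep the 3' end (the bases nearest
    the start site); shorter records are kept with a warning.
    """
    log = get_logger("io")
    out: PromoterSet = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate promoter record id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"record {rec.id!r}: invalid character(s) {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )
        if len(seq) > upstream_len:
            seq = seq[-upstream_len:]
        elif len(seq) < upstream_len:
            log.warning(
                "promoter %s is %d bp, shorter than the configured %d bp",
                rec.id, len(seq), upstream_len,
            )
        out[rec.id] = seq
    return out


def read_physio_table(path: str | Path) -> pd.DataFrame:
    """Read a physiology TSV (cultivar, parameter, replicate, value) and validate it."""
    df = pd.read_csv(path, sep="\t")
    return validate_physio_table(df)


def validate_physio_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"cultivar", "parameter", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"physiology table missing column(s): {sorted(missing)}")
    bad_param = set(df["parameter"]) - set(PHYSIO_PARAMETERS)
    if bad_param:
        raise ValidationError(f"unknown physiology parameter(s): {sorted(bad_param)}")
    if (df["value"] < 0).any():
        raise ValidationError("physiology values must be non-negative")
    counts = df.groupby(["cultivar", "parameter"]).size()
    for cultivar in df["cultivar"].unique():
        have = set(df.loc[df["cultivar"] == cultivar, "parameter"])
        lacking = set(PHYSIO_PARAMETERS) - have
        if lacking:
            raise ValidationError(
                f"cultivar {cultivar!r} missing parameter(s): {sorted(lacking)}"
            )
    too_few = counts[counts < 3]
    if len(too_few):
        cultivar, parameter = too_few.index[0]
        raise ValidationError(
            f"cultivar {cultivar!r}, parameter {parameter!r}: "
            f"{too_few.iloc[0]} replicate(s); need >= 3"
        )
    return df


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with >= 6 significant digits on floats."""
    if rows is None or len(rows) == 0:
        raise ValidationError("refusing to write an empty table")
    rows.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep=MISSING_MARKER)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", na_values=[MISSING_MARKER], keep_default_na=False)
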