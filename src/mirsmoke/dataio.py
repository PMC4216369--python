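"""Input/output and cohort assembly.

Every stage of the pipeline consumes an :class:`ExpressionMatrix` (a
miRNA-by-sample grid of RPKM values), a list of :class:`SampleRecord`
clinical annotations, and, for network construction, a table of
miRNA-to-gene target predictions.  This module reads and writes those
tables, enforces the RPKM detection floor (values below 1 RPKM are
treated as not expressed), and assembles patient-matched tumor/normal
pairs grouped by smoking status (current / former / never smoker).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SMOKING_GROUPS = ("CS", "FS", "NS")
TISSUES = ("tumor", "normal")
NA = "NA"

#: Columns of the metadata TSV, in canonical order.
METADATA_COLUMNS = [
    "sample_id", "patient_id", "tissue", "smoking", "age", "sex", "stage",
    "ethnicity", "pack_years", "years_quit", "surv_time", "event", "cohort",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """miRNA x sample RPKM table.

    Thin wrapper around a :class:`pandas.DataFrame` (index = miRNA ids,
    columns = sample ids) that validates uniqueness and non-negativity
    on construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.rename("mirna_id")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate miRNA ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        vals = df.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if vals.size and (np.isnan(vals).any() or (vals < 0).any()):
            raise ValidationError("expression values must be non-negative reals")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_mirna(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleRecord:
    """Clinical annotation for one profiled tissue sample."""

    sample_id: str
    patient_id: str
    tissue: str                      # "tumor" | "normal"
    smoking: str                     # "CS" | "FS" | "NS"
    age: float | None = None
    sex: str = "unknown"             # "M" | "F" | "unknown"
    stage: str = "unknown"           # "I".."IV" | "unknown"
    ethnicity: str = "unknown"
    pack_years: float | None = None
    years_quit: float | None = None
    surv_time: float | None = None   # months
    event: bool | None = None
    cohort: str = ""                 # cohort-of-origin tag, set by merge_cohorts

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"{self.sample_id}: tissue must be one of {TISSUES}")
        if self.smoking not in SMOKING_GROUPS:
            raise ValidationError(
                f"{self.sample_id}: smoking must be one of {SMOKING_GROUPS}")
        if self.years_quit is not None and self.smoking != "FS":
            raise ValidationError(
                f"{self.sample_id}: years_quit only meaningful for former smokers")
        if self.pack_years == 0 and self.smoking != "NS":
            raise ValidationError(
                f"{self.sample_id}: zero pack-years implies never smoker")
        if (self.surv_time is None) != (self.event is None):
            raise ValidationError(
                f"{self.sample_id}: surv_time and event must be missing together")
        if self.surv_time is not None and self.surv_time < 0:
            raise ValidationError(f"{self.sample_id}: negative survival time")


@dataclass(frozen=True)
class PairedCohort:
    """Patient-matched tumor/normal sample pairs sharing one smoking group."""

    group: str
    pairs: tuple[tuple[str, str, str], ...]  # (patient_id, tumor_id, normal_id)

    def __post_init__(self) -> None:
        patients = [p for p, _, _ in self.pairs]
        if len(set(patients)) != len(patients):
            raise ValidationError("a patient appears in more than one pair")
        if self.group not in SMOKING_GROUPS:
            raise ValidationError(f"group must be one of {SMOKING_GROUPS}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def tumor_ids(self) -> list[str]:
        return [t for _, t, _ in self.pairs]

    @property
    def normal_ids(self) -> list[str]:
        return [n for _, _, n in self.pairs]


@dataclass(frozen=True)
class PairingResult:
    cohorts: Mapping[str, PairedCohort]
    unpaired: tuple[str, ...]  # sample_ids lacking a matched counterpart


# ---------------------------------------------------------------------------
# expression tables

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a miRNA-by-sample RPKM TSV (header row = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            out[col] = df[col].astype(float)
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValidationError(
                f"malformed numeric cell at row {bad!r}, column {col!r}") from None
    return ExpressionMatrix(out)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "mirna_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def filter_expressed(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Drop miRNAs never reaching the detection floor in any sample.

    A value below 1 RPKM counts as not expressed; a row whose maximum is
    strictly below ``floor`` is discarded (``== floor`` is kept).
    Row order and values of retained rows are preserved.
    """
    if m.n_samples == 0:
        return ExpressionMatrix(m.data.iloc[0:0])
    keep = (m.data.to_numpy() >= floor).any(axis=1)
    return ExpressionMatrix(m.data.loc[keep])


# ---------------------------------------------------------------------------
# metadata tables

def _parse_opt_float(v: str) -> float | None:
    return None if v == NA or v == "" else float(v)


def _parse_opt_bool(v: str) -> bool | None:
    if v == NA or v == "":
        return None
    if v in ("1", "True", "true"):
        return True
    if v in ("0", "False", "false"):
        return False
    raise ValidationError(f"unparseable event flag {v!r}")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read a sample metadata TSV; missing values use the literal ``NA``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = set(METADATA_COLUMNS) - {"cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(SampleRecord(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            tissue=row.tissue,
            smoking=row.smoking,
            age=_parse_opt_float(row.age),
            sex=row.sex,
            stage=row.stage,
            ethnicity=row.ethnicity,
            pack_years=_parse_opt_float(row.pack_years),
            years_quit=_parse_opt_float(row.years_quit),
            surv_time=_parse_opt_float(row.surv_time),
            event=_parse_opt_bool(row.event),
            cohort=getattr(row, "cohort", ""),
        ))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in metadata")
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for k, v in d.items():
            if v is None:
                d[k] = NA
            elif isinstance(v, bool):
                d[k] = "1" if v else "0"
        rows.append(d)
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def build_pairs(meta: Sequence[SampleRecord]) -> PairingResult:
    """Assemble patient-matched tumor/normal pairs per smoking group.

    Patients with a single tissue are reported in ``unpaired`` rather
    than silently dropped.  Two samples of the same tissue for one
    patient is an error.
    """
    by_patient: dict[str, dict[str, SampleRecord]] = {}
    for r in meta:
        slot = by_patient.setdefault(r.patient_id, {})
        if r.tissue in slot:
            raise ValidationError(
                f"patient {r.patient_id} has two {r.tissue} samples")
        slot[r.tissue] = r
    pairs_by_group: dict[str, list[tuple[str, str, str]]] = {g: [] for g in SMOKING_GROUPS}
    unpaired: list[str] = []
    for patient_id, slot in by_patient.items():
        if "tumor" in slot and "normal" in slot:
            t, n = slot["tumor"], slot["normal"]
            if t.smoking != n.smoking:
                raise ValidationError(
                    f"patient {patient_id}: tumor/normal smoking status disagree")
            pairs_by_group[t.smoking].append((patient_id, t.sample_id, n.sample_id))
        else:
            unpaired.extend(r.sample_id for r in slot.values())
    cohorts = {
        g: PairedCohort(group=g, pairs=tuple(pairs))
        for g, pairs in pairs_by_group.items()
    }
    return PairingResult(cohorts=cohorts, unpaired=tuple(unpaired))


def merge_cohorts(
    a: Sequence[SampleRecord],
    b: Sequence[SampleRecord],
    tags: tuple[str, str] = ("A", "B"),
) -> list[SampleRecord]:
    """Concatenate two cohorts, recording cohort of origin per sample.

    Sample and patient ids are prefixed ``<tag>:`` so the namespaces are
    disjoint; a collision after prefixing is an error.
    """
    if tags[0] == tags[1]:
        raise ValidationError("cohort tags must be distinct")
    merged: list[SampleRecord] = []
    for tag, cohort in zip(tags, (a, b)):
        for r in cohort:
            merged.append(dataclasses.replace(
                r,
                sample_id=f"{tag}:{r.sample_id}",
                patient_id=f"{tag}:{r.patient_id}",
                cohort=tag,
            ))
    ids = [r.sample_id for r in merged]
    if len(set(ids)) != len(ids):
        raise ValidationError("sample id collision after cohort prefixing")
    return merged


def group_counts(meta: Sequence[SampleRecord], tissue: str | None = None) -> dict[str, int]:
    """Number of distinct patients per smoking group (optionally one tissue)."""
    counts: dict[str, set[str]] = {g: set() for g in SMOKING_GROUPS}
    for r in meta:
        if tissue is None or r.tissue == tissue:
            counts[r.smoking].add(r.patient_id)
    return {g: len(s) for g, s in counts.items()}


# ---------------------------------------------------------------------------
# target predictions and gene lists

def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a miRNA->gene target-prediction TSV with source-support counts."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene": str,
                                            "support_count": int})
    required = {"mirna_id", "gene", "support_count"}
    if missing := required - set(df.columns):
        raise ValidationError(f"prediction table missing columns: {sorted(missing)}")
    if (df["support_count"] < 1).any():
        raise ValidationError("support_count must be >= 1")
    if df.duplicated(["mirna_id", "gene"]).any():
        raise ValidationError("duplicate (miRNA, gene) prediction pairs")
    return df


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    df[["mirna_id", "gene", "support_count"]].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line; ``#`` comments allowed."""
    genes: list[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym and sym not in seen:
            genes.append(sym)
            seen.add(sym)
    return genes
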