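"""Readers and writers for the flat-file dataset formats, plus validation.

All tabular files are UTF-8 TSV with "." as decimal separator. Sequences are
exchanged as plain FASTA, with the ASV id taken from the first
whitespace-delimited token of the header line.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    AMPLICON_WINDOWS,
    AsvRecord,
    AsvTable,
    FormatError,
    IsolationMethod,
    MockReference,
    SampleMeta,
    SampleType,
    SequencingMethod,
    UNCLASSIFIED,
    normalize_sequence,
)

# ---------------------------------------------------------------------------
# count table


def read_asv_table(path: str | Path) -> AsvTable:
    """Read a samples x ASVs count TSV (header = ASV ids, first column = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample ids {dups}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicated ASV ids in header")
    try:
        return AsvTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_asv_table(table: AsvTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, mask_ambiguous: bool = False) -> list[AsvRecord]:
    """Read ASV sequences from FASTA, normalizing to uppercase DNA (U -> T)."""
    records: list[AsvRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        asv_id = rec.id
        if asv_id in seen:
            raise FormatError(f"{path}: duplicate ASV id {asv_id!r}")
        seen.add(asv_id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {asv_id!r}")
        records.append(
            AsvRecord(asv_id=asv_id, sequence=normalize_sequence(seq, mask_ambiguous))
        )
    return records


def write_fasta(records: Sequence[AsvRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.asv_id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# taxonomy / metadata / mock reference


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV with columns asv_id, genus, species."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNCLASSIFIED)
    missing = {"asv_id", "genus", "species"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: taxonomy missing columns {sorted(missing)}")
    if df["asv_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate asv_id rows in taxonomy")
    return df.set_index("asv_id")


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    out = taxonomy.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV (columns named as the SampleMeta fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sample_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    metas: list[SampleMeta] = []
    for _, row in df.iterrows():
        family = row.get("family_id")
        family = None if (pd.isna(family) or family == "") else str(family)
        yield_raw = row.get("dna_yield_ng")
        dna_yield = (
            None if (yield_raw is None or pd.isna(yield_raw) or yield_raw == "")
            else float(yield_raw)
        )
        rep_raw = row.get("replicate")
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                sample_type=SampleType(row["sample_type"]),
                family_id=family,
                isolation_method=IsolationMethod(
                    row.get("isolation_method") or "NONE"
                ),
                sequencing_method=SequencingMethod(
                    row.get("sequencing_method") or "SHORT_16S"
                ),
                replicate=int(rep_raw) if rep_raw and not pd.isna(rep_raw) else 1,
                dna_yield_ng=dna_yield,
            )
        )
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample ids in metadata")
    return metas


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "sample_id": m.sample_id,
                "family_id": "" if m.family_id is None else m.family_id,
                "sample_type": m.sample_type.value,
                "isolation_method": m.isolation_method.value,
                "sequencing_method": m.sequencing_method.value,
                "replicate": m.replicate,
                "dna_yield_ng": "" if m.dna_yield_ng is None else m.dna_yield_ng,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_mock_reference(path: str | Path) -> MockReference:
    df = pd.read_csv(path, sep="\t")
    missing = {"genus", "expected_fraction"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: mock reference missing columns {sorted(missing)}")
    return MockReference(dict(zip(df["genus"], df["expected_fraction"].astype(float))))


def write_mock_reference(ref: MockReference, path: str | Path) -> None:
    ref.as_series().rename_axis("genus").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# dataset validation


@dataclass
class ValidationFinding:
    category: str
    subject: str
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    def add(self, category: str, subject: str, message: str) -> None:
        self.findings.append(ValidationFinding(category, subject, message))

    @property
    def ok(self) -> bool:
        return not self.findings

    def subjects(self, category: str) -> list[str]:
        return [f.subject for f in self.findings if f.category == category]

    def __str__(self) -> str:
        if self.ok:
            return "dataset valid: no findings"
        return "\n".join(
            f"[{f.category}] {f.subject}: {f.message}" for f in self.findings
        )


def validate_dataset(
    table: AsvTable,
    meta: Sequence[SampleMeta],
    records: Sequence[AsvRecord],
    taxonomy: pd.DataFrame,
    mode: str = "short",
    strict: bool = False,
) -> ValidationReport:
    """Cross-check the four dataset files against one another.

    Report-only by default: findings name every table sample without
    metadata, every ASV without sequence or taxonomy, and every ASV whose
    length falls outside the active amplicon window (400-431 bp for the
    short-read mode, 1900-3000 bp for the long-read mode). With
    ``strict=True`` any finding raises :class:`FormatError`.
    """
    if mode not in AMPLICON_WINDOWS:
        raise FormatError(f"unknown amplicon mode {mode!r}")
    lo, hi = AMPLICON_WINDOWS[mode]
    report = ValidationReport()

    meta_ids = {m.sample_id for m in meta}
    for sid in table.sample_ids:
        if sid not in meta_ids:
            report.add("sample_without_metadata", sid, "present in table, absent from metadata")
    table_ids = set(table.sample_ids)
    for m in meta:
        if m.sample_id not in table_ids:
            report.add("metadata_without_sample", m.sample_id, "metadata row has no table row")

    seq_by_id = {r.asv_id: r for r in records}
    for asv in table.asv_ids:
        rec = seq_by_id.get(asv)
        if rec is None:
            report.add("asv_without_sequence", asv, "no FASTA record")
        elif not (lo <= rec.length_bp <= hi):
            report.add(
                "asv_out_of_window",
                asv,
                f"length {rec.length_bp} bp outside {mode} window [{lo}, {hi}]",
            )
        if asv not in taxonomy.index:
            report.add("asv_without_taxonomy", asv, "no taxonomy row")

    if strict and not report.ok:
        raise FormatError(str(report))
    return report


# ---------------------------------------------------------------------------
# published-summary reconstruction


def reconstruct_replicate_values(
    median: float, lo: float, hi: float, n: int
) -> list[float]:
    """Reconstruct per-replicate values from a published "median (range)" summary.

    For ``n == 1`` the single value is the median; for ``n == 3`` the three
    values are the two range endpoints plus the median itself. For ``n == 2``
    the two values are the endpoints, and the published median must be their
    midpoint up to integer-rounding (checked to 0.5; a larger discrepancy
    triggers a warning because the reconstruction convention no longer
    explains the printed median). Returns the sorted multiset.
    """
    if n not in (1, 2, 3):
        raise ValueError(f"n={n} unsupported (need 1, 2 or 3 replicates)")
    if not (lo <= median <= hi):
        raise ValueError(f"ordering violated: need lo <= median <= hi, got {lo}, {median}, {hi}")
    if n == 1:
        if not (lo == median == hi):
            raise ValueError("n=1 requires lo == median == hi")
        return [median]
    if n == 2:
        mid = (lo + hi) / 2.0
        if abs(mid - median) > 0.5:
            warnings.warn(
                f"midpoint {mid} of range ({lo}, {hi}) differs from published "
                f"median {median} by more than 0.5; reconstruction is inexact",
                stacklevel=2,
            )
        return [lo, hi]
    return [lo, median, hi]


def pooled_median(values: Sequence[float]) -> float:
    """Median of pooled reconstructed values (plain sample median)."""
    return float(statistics.median(values))
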