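"""Core typed containers shared by every analysis stage.

The central objects mirror what a denoising pipeline hands downstream: an
integer ASV count matrix (samples x ASVs), the per-ASV sequences and taxonomy,
per-sample metadata describing the study design (family, body site, DNA
isolation kit, sequencing chemistry), and labelled distance matrices used for
both between-sample (Aitchison) and between-ASV (Hamming) geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class SampleType(str, Enum):
    MILK = "MILK"
    INFANT_ORAL = "INFANT_ORAL"
    INFANT_FAECES = "INFANT_FAECES"
    MATERNAL_FAECES = "MATERNAL_FAECES"
    NEG_ISOLATION = "NEG_ISOLATION"
    NEG_LIBPREP = "NEG_LIBPREP"
    MOCK = "MOCK"


class IsolationMethod(str, Enum):
    FS = "FS"
    MD = "MD"
    PS = "PS"
    MX = "MX"
    NONE = "NONE"


class SequencingMethod(str, Enum):
    SHORT_16S = "SHORT_16S"
    LONG_16S_ITS_23S = "LONG_16S_ITS_23S"


#: amplicon length windows (inclusive, bp) kept after denoising, per mode
AMPLICON_WINDOWS: dict[str, tuple[int, int]] = {
    "short": (400, 431),
    "long": (1900, 3000),
}

UNCLASSIFIED = "UNCLASSIFIED"

_VALID_BASES = frozenset("ACGT")
_VALID_BASES_MASKED = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file or container violates a format invariant."""


def normalize_sequence(seq: str, mask_ambiguous: bool = False) -> str:
    """Normalize a nucleotide string to uppercase DNA over {A,C,G,T}.

    RNA ``U`` is mapped to ``T``. Any other character (including IUPAC
    ambiguity codes) raises :class:`FormatError` unless ``mask_ambiguous``,
    in which case it is replaced by ``N``. Exact-identity sharing calls need
    an unambiguous alphabet, hence the strict default.
    """
    s = seq.strip().upper().replace("U", "T")
    if not s:
        raise FormatError("empty sequence")
    bad = set(s) - _VALID_BASES
    if bad:
        if mask_ambiguous:
            s = "".join(c if c in _VALID_BASES else "N" for c in s)
        else:
            raise FormatError(
                f"invalid characters {sorted(bad)} in sequence (use mask_ambiguous to mask to N)"
            )
    return s


@dataclass(frozen=True)
class AsvRecord:
    """One amplicon sequence variant with its normalized sequence and taxonomy."""

    asv_id: str
    sequence: str
    genus: str = UNCLASSIFIED
    species: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if not self.asv_id:
            raise FormatError("asv_id must be non-empty")
        if not self.sequence:
            raise FormatError(f"ASV {self.asv_id}: empty sequence")
        if not set(self.sequence) <= _VALID_BASES_MASKED:
            raise FormatError(
                f"ASV {self.asv_id}: sequence not normalized (call normalize_sequence)"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


class AsvTable:
    """Integer ASV count matrix with sample rows and ASV columns.

    Wraps a ``pandas.DataFrame`` whose index holds sample ids and whose
    columns hold ASV ids; every entry is a non-negative integer read count.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise FormatError("duplicate sample ids in count table")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate ASV ids in count table")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise FormatError("non-numeric entries in count table")
            if np.any(arr < 0):
                raise FormatError("negative counts in count table")
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("non-integer counts in count table")
        self.counts = counts.astype(np.int64)

    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray,
        sample_ids: Sequence[str],
        asv_ids: Sequence[str],
    ) -> "AsvTable":
        return cls(pd.DataFrame(counts, index=list(sample_ids), columns=list(asv_ids)))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)])

    def drop_empty_asvs(self) -> "AsvTable":
        keep = self.counts.columns[(self.counts > 0).any(axis=0)]
        return AsvTable(self.counts[keep])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AsvTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"AsvTable({n} samples x {m} ASVs)"


@dataclass(frozen=True)
class SampleMeta:
    """Design attributes of one sequenced sample.

    ``family_id`` is ``None`` for controls and mocks; ``dna_yield_ng`` is
    ``None`` when no measurement exists (distinct from 0.0, which the study
    design uses for yields below the detection limit).
    """

    sample_id: str
    sample_type: SampleType
    family_id: str | None = None
    isolation_method: IsolationMethod = IsolationMethod.NONE
    sequencing_method: SequencingMethod = SequencingMethod.SHORT_16S
    replicate: int = 1
    dna_yield_ng: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FormatError("sample_id must be non-empty")
        if self.replicate < 1:
            raise FormatError(f"{self.sample_id}: replicate must be >= 1")
        if self.sample_type in (
            SampleType.NEG_ISOLATION,
            SampleType.NEG_LIBPREP,
            SampleType.MOCK,
        ) and self.family_id is not None:
            raise FormatError(
                f"{self.sample_id}: control/mock samples must have no family_id"
            )
        if self.dna_yield_ng is not None and (
            math.isnan(self.dna_yield_ng) or self.dna_yield_ng < 0
        ):
            raise FormatError(f"{self.sample_id}: dna_yield_ng must be >= 0 or None")


def meta_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Tabulate a metadata list as a DataFrame indexed by sample id."""
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in metadata")
    return pd.DataFrame(
        {
            "family_id": [m.family_id for m in meta],
            "sample_type": [m.sample_type.value for m in meta],
            "isolation_method": [m.isolation_method.value for m in meta],
            "sequencing_method": [m.sequencing_method.value for m in meta],
            "replicate": [m.replicate for m in meta],
            "dna_yield_ng": [m.dna_yield_ng for m in meta],
        },
        index=pd.Index(ids, name="sample_id"),
    )


class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    def __init__(self, labels: Sequence[str], values: np.ndarray, atol: float = 1e-8):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate labels in distance matrix")
        n = len(labels)
        if values.shape != (n, n):
            raise FormatError(f"distance matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=atol):
            raise FormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=atol):
            raise FormatError("distance matrix diagonal is not zero")
        if np.any(values < -atol):
            raise FormatError("negative distances")
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        self.labels = labels
        self.values = values

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise FormatError("distance matrix rows and columns must carry same labels")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM

        return SkbioDM(self.values, ids=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={self.n})"


@dataclass(frozen=True)
class MockReference:
    """Expected genus-level composition of a mock community (fractions sum to 1)."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise FormatError("mock reference must list at least one genus")
        vals = np.array(list(self.fractions.values()), dtype=float)
        if np.any(vals < 0):
            raise FormatError("mock reference fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise FormatError(
                f"mock reference fractions sum to {vals.sum():.12f}, expected 1"
            )

    @property
    def genera(self) -> list[str]:
        return list(self.fractions)

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.fractions), name="expected_fraction")


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (read-count reporting convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
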