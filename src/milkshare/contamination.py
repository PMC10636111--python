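"""Negative-control-based contamination detection and accounting.

An ASV observed (count >= 1) in both a biological sample and a matched
negative control is a potential contaminant. The default matching policy
pools all isolation controls of the sample's DNA-isolation method and all
library-preparation controls globally. No reads are removed: the module
quantifies contamination (per-sample contaminated read fractions, source
attribution to isolation vs library preparation, yield correlation) and
reports it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import (
    AsvTable,
    IsolationMethod,
    SampleMeta,
    SampleType,
    round_half_away,
)


class NoMatchedControlError(ValueError):
    """Raised when a sample has no negative control under the matching policy."""


def _present(table: AsvTable, sample_id: str) -> set[str]:
    row = table.counts.loc[sample_id]
    return set(row.index[row > 0])


def matched_controls(
    sample: SampleMeta, meta: Sequence[SampleMeta], control_class: SampleType
) -> list[str]:
    """Control sample ids matched to a biological sample.

    Isolation controls match on the same isolation method; library-prep
    controls match globally (they sit downstream of isolation).
    """
    if control_class is SampleType.NEG_ISOLATION:
        return [
            m.sample_id
            for m in meta
            if m.sample_type is SampleType.NEG_ISOLATION
            and m.isolation_method is sample.isolation_method
        ]
    return [m.sample_id for m in meta if m.sample_type is SampleType.NEG_LIBPREP]


def detect_contaminants(
    table: AsvTable, sample_id: str, control_ids: Sequence[str]
) -> set[str]:
    """ASVs with count >= 1 in the sample and in at least one matched control."""
    if not control_ids:
        raise NoMatchedControlError(f"no matched negative control for {sample_id}")
    sample_asvs = _present(table, sample_id)
    control_asvs: set[str] = set()
    for cid in control_ids:
        control_asvs |= _present(table, cid)
    return sample_asvs & control_asvs


def contamination_fraction(
    table: AsvTable, sample_id: str, contaminants: set[str]
) -> tuple[float, int, int]:
    """(fraction, contaminated reads, total reads) for one sample.

    A zero-read sample has an undefined fraction, reported as NaN.
    """
    unknown = contaminants - set(table.asv_ids)
    if unknown:
        raise ValueError(f"contaminant ASVs not in table: {sorted(unknown)[:5]}")
    row = table.counts.loc[sample_id]
    total = int(row.sum())
    contaminated = int(row[list(contaminants)].sum()) if contaminants else 0
    if total == 0:
        warnings.warn(f"{sample_id}: zero reads, contamination fraction undefined", stacklevel=2)
        return math.nan, 0, 0
    return contaminated / total, contaminated, total


@dataclass
class ContaminationReport:
    """Per-sample contamination accounting against matched controls."""

    per_sample: pd.DataFrame
    # columns: sample_id, isolation_method, n_controls, contaminant_asvs,
    #          contaminated_reads, total_reads, fraction,
    #          isolation_fraction, libprep_fraction
    policy: str = "pool isolation controls per method; pool library-prep controls globally"

    def summary_by_method(self) -> pd.DataFrame:
        """Median (range) of the contaminated read percentage per isolation method."""
        rows = []
        for method, grp in self.per_sample.groupby("isolation_method"):
            f = grp["fraction"].dropna() * 100.0
            if f.empty:
                continue
            rows.append(
                {
                    "isolation_method": method,
                    "n_samples": len(grp),
                    "pct_median": round_half_away(float(f.median())),
                    "pct_min": float(f.min()),
                    "pct_max": float(f.max()),
                    "summary": f"{round_half_away(float(f.median()))}% "
                    f"({round_half_away(float(f.min()))}%-{round_half_away(float(f.max()))}%)",
                }
            )
        return pd.DataFrame(rows)


def contamination_report(
    table: AsvTable,
    meta: Sequence[SampleMeta],
    sample_types: tuple[SampleType, ...] = (SampleType.MILK,),
) -> ContaminationReport:
    """Quantify contamination for every biological sample of the given types.

    The headline ``fraction`` uses contaminants from both control classes
    combined; ``isolation_fraction`` and ``libprep_fraction`` attribute reads
    to each class separately (a read can count against both when the ASV
    occurs in both kinds of control). Missing control classes yield NaN in
    the corresponding column with a warning.
    """
    rows = []
    have_iso = any(m.sample_type is SampleType.NEG_ISOLATION for m in meta)
    have_lib = any(m.sample_type is SampleType.NEG_LIBPREP for m in meta)
    if not have_iso:
        warnings.warn("no isolation negative controls: isolation attribution MISSING", stacklevel=2)
    if not have_lib:
        warnings.warn("no library-prep negative controls: libprep attribution MISSING", stacklevel=2)
    for m in meta:
        if m.sample_type not in sample_types:
            continue
        iso_ids = matched_controls(m, meta, SampleType.NEG_ISOLATION)
        lib_ids = matched_controls(m, meta, SampleType.NEG_LIBPREP)
        all_ids = iso_ids + lib_ids
        contaminants = detect_contaminants(table, m.sample_id, all_ids)
        frac, n_cont, n_total = contamination_fraction(table, m.sample_id, contaminants)
        iso_frac = lib_frac = math.nan
        if iso_ids:
            iso_set = detect_contaminants(table, m.sample_id, iso_ids)
            iso_frac, _, _ = contamination_fraction(table, m.sample_id, iso_set)
        if lib_ids:
            lib_set = detect_contaminants(table, m.sample_id, lib_ids)
            lib_frac, _, _ = contamination_fraction(table, m.sample_id, lib_set)
        rows.append(
            {
                "sample_id": m.sample_id,
                "isolation_method": m.isolation_method.value,
                "n_controls": len(all_ids),
                "contaminant_asvs": ";".join(sorted(contaminants)),
                "contaminated_reads": n_cont,
                "total_reads": n_total,
                "fraction": frac,
                "isolation_fraction": iso_frac,
                "libprep_fraction": lib_frac,
            }
        )
    return ContaminationReport(per_sample=pd.DataFrame(rows))


def attribute_source(report: ContaminationReport) -> pd.DataFrame:
    """Min/max contaminated fraction per isolation method and control class."""
    rows = []
    for method, grp in report.per_sample.groupby("isolation_method"):
        for col, source in [
            ("isolation_fraction", "isolation"),
            ("libprep_fraction", "library_prep"),
        ]:
            vals = grp[col].dropna()
            if vals.empty:
                rows.append(
                    {"isolation_method": method, "source": source,
                     "min_fraction": math.nan, "max_fraction": math.nan}
                )
                continue
            rows.append(
                {
                    "isolation_method": method,
                    "source": source,
                    "min_fraction": float(vals.min()),
                    "max_fraction": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def yield_correlation(
    dna_yields: Sequence[float | None], fractions: Sequence[float]
) -> tuple[float, float, int]:
    """Spearman correlation between DNA yield and contaminated fraction.

    Pairs with a missing member are dropped (and counted); fewer than three
    complete pairs is an error; constant vectors make the rank correlation
    undefined (NaN, with a warning).
    """
    y = np.array([math.nan if v is None else float(v) for v in dna_yields])
    f = np.asarray(fractions, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(f))
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete (yield, fraction) pairs, have {n}")
    if np.unique(y[ok]).size < 2 or np.unique(f[ok]).size < 2:
        warnings.warn("degenerate ranks: Spearman rho undefined (MISSING)", stacklevel=2)
        return math.nan, math.nan, n
    rho, p = sps.spearmanr(y[ok], f[ok])
    return float(rho), float(p), n
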