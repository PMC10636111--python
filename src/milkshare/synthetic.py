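"""Synthetic mother-infant cohort generator with a machine-readable truth log.

The generator emulates the structure of a low-biomass milk amplicon study:
per-genus ASV pools derived from an ancestor sequence by point substitutions,
one sample per configured body site per family, planted ASV-sharing events
between related (same-family) sample pairs, kit-specific contaminant ASVs
that appear in negative controls and leak into biological samples, and mock
communities drawn around a known reference composition.

Sharing model
-------------
For every genus, each sample that carries the genus always carries its own
sample-private ASV. Related-pair sharing is planted per (family, genus,
body-site comparison) with probability ``p_share`` by placing one
family-specific ASV in both members of the pair. Background (unrelated)
sharing arises only through a single per-genus background ASV that each
carrying sample picks up independently with probability ``sqrt(p_bg)``, so
two carrying samples coincide on it with probability ~``p_bg``. At
``p_bg=0`` an identical ASV therefore occurs in a sample pair if and only if
a sharing event was planted there, which is what makes the truth log exact.

Every carried ASV is guaranteed at least one read (reads are multinomial
given the sample depth, then floored to 1 for carried ASVs), so presence and
sharing are deterministic given the carriage draws.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AMPLICON_WINDOWS,
    AsvRecord,
    AsvTable,
    DistanceMatrix,
    FormatError,
    IsolationMethod,
    MockReference,
    SampleMeta,
    SampleType,
    SequencingMethod,
    UNCLASSIFIED,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# role constants used to derive independent, order-insensitive RNG streams
_ROLE_POOL = 1
_ROLE_PRESENCE = 2
_ROLE_PLANT = 3
_ROLE_BACKGROUND = 4
_ROLE_COUNTS = 5
_ROLE_CONTROLS = 6
_ROLE_INJECT = 7
_ROLE_MOCK = 8


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def brute_force_hamming(sequences: Sequence[str]) -> np.ndarray:
    """Reference pairwise Hamming distances by direct character comparison."""
    n = len(sequences)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[i], sequences[j]
            if len(a) != len(b):
                raise ValueError("brute_force_hamming requires equal-length sequences")
            d[i, j] = d[j, i] = sum(x != y for x, y in zip(a, b))
    return d


# ---------------------------------------------------------------------------
# genus pools


@dataclass
class GenusPool:
    """ASVs of one genus, derived from a shared ancestor by point substitutions."""

    genus: str
    ancestor: str
    records: list[AsvRecord]
    distances: DistanceMatrix

    @property
    def asv_ids(self) -> list[str]:
        return [r.asv_id for r in self.records]


def generate_genus_pool(
    genus: str,
    n_asvs: int,
    length_bp: int,
    substitution_rate: float,
    seed: int,
    mode: str = "short",
    id_prefix: str | None = None,
) -> GenusPool:
    """Generate ``n_asvs`` distinct same-length ASVs for one genus.

    The first ASV is the ancestor itself; each further ASV carries
    ``max(1, Binomial(L, substitution_rate))`` point substitutions relative
    to the ancestor, re-drawn until distinct from all earlier pool members.
    Pairwise Hamming distances are recorded from the generated sequences.
    Deterministic for a given seed.
    """
    lo, hi = AMPLICON_WINDOWS[mode]
    if not (lo <= length_bp <= hi):
        raise ValueError(
            f"length {length_bp} bp outside {mode} amplicon window [{lo}, {hi}]"
        )
    if not (0 <= substitution_rate < 1):
        raise ValueError("substitution_rate must be in [0, 1)")
    if n_asvs < 1:
        raise ValueError("n_asvs must be >= 1")
    prefix = id_prefix if id_prefix is not None else genus
    rng = _rng(seed, _ROLE_POOL, _stable_key(prefix))
    ancestor = rng.choice(_BASES, size=length_bp)
    seqs = [ancestor.copy()]
    seen = {ancestor.tobytes()}
    attempts_cap = 200
    for _ in range(1, n_asvs):
        for attempt in range(attempts_cap):
            k = max(1, rng.binomial(length_bp, substitution_rate))
            if k > length_bp:
                k = length_bp
            pos = rng.choice(length_bp, size=k, replace=False)
            var = ancestor.copy()
            # substitute with a base different from the ancestor's
            shifts = rng.integers(1, 4, size=k)
            idx = np.searchsorted(_BASES, ancestor[pos])
            var[pos] = _BASES[(idx + shifts) % 4]
            key = var.tobytes()
            if key not in seen:
                seen.add(key)
                seqs.append(var)
                break
        else:
            raise ValueError(
                f"could not generate {n_asvs} distinct ASVs for {genus} "
                f"(capacity exhausted after {attempts_cap} attempts)"
            )
    records = [
        AsvRecord(f"{prefix}_asv{i:03d}", _array_to_seq(s), genus=genus)
        for i, s in enumerate(seqs)
    ]
    arr = np.stack(seqs)
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return GenusPool(
        genus=genus,
        ancestor=_array_to_seq(ancestor),
        records=records,
        distances=DistanceMatrix([r.asv_id for r in records], d.astype(float)),
    )


def _stable_key(name: str) -> int:
    import zlib

    return zlib.crc32(name.encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GenusSpec:
    """Generative parameters for one genus in the cohort."""

    name: str
    prevalence: float = 0.6          # per-sample probability of carrying the genus
    log_mean: float = 0.0            # log-normal relative-abundance location
    log_sd: float = 1.0              # log-normal relative-abundance scale
    p_share: float = 0.5             # per related pair: probability of a planted event
    p_bg: float = 0.02               # approximate unrelated-pair background sharing

    def __post_init__(self) -> None:
        for p, label in ((self.prevalence, "prevalence"), (self.p_share, "p_share"), (self.p_bg, "p_bg")):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.name}: {label} must be in [0, 1]")


@dataclass(frozen=True)
class ContaminantSpec:
    """Kit-specific contaminant pool for one isolation method."""

    method: IsolationMethod
    genera: tuple[str, ...] = (
        "Cutibacterium",
        "Enhydrobacter",
        "Escherichia-Shigella",
        "Pelomonas",
    )
    injection_rate: float = 0.5      # per (biological sample, contaminant ASV)
    injection_log_mean: float = 2.0  # log of typical injected read count
    injection_log_sd: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort; deterministic under seed."""

    seed: int = 0
    n_families: int = 14
    sample_types: tuple[SampleType, ...] = (
        SampleType.MILK,
        SampleType.INFANT_ORAL,
        SampleType.INFANT_FAECES,
        SampleType.MATERNAL_FAECES,
    )
    genera: tuple[GenusSpec, ...] = (
        GenusSpec("Staphylococcus", prevalence=0.9, log_mean=1.5),
        GenusSpec("Streptococcus", prevalence=0.9, log_mean=1.0),
        GenusSpec("Gemella", prevalence=0.7),
        GenusSpec("Rothia", prevalence=0.6),
        GenusSpec("Veillonella", prevalence=0.5),
    )
    mode: str = "short"
    length_bp: int | None = None          # default: 420 (short) / 2200 (long)
    substitution_rate: float = 0.02
    depth_mean: int = 20000               # biological sample depth (log-normal)
    depth_log_sd: float = 0.3
    isolation_method: IsolationMethod = IsolationMethod.PS
    contaminants: tuple[ContaminantSpec, ...] = (
        ContaminantSpec(IsolationMethod.PS),
    )
    libprep_contaminant_genera: tuple[str, ...] = ("Ralstonia", "Sphingomonas")
    libprep_injection_rate: float = 0.05
    n_controls_per_method: int = 2
    control_depth_range: tuple[int, int] = (0, 5000)
    libprep_control_depth_range: tuple[int, int] = (50, 500)
    mock_reference: MockReference | None = None
    n_mock: int = 1
    mock_depth: int = 100000
    mock_dispersion: float = 0.3
    sequencing_method: SequencingMethod = SequencingMethod.SHORT_16S

    def __post_init__(self) -> None:
        if not self.genera:
            raise ValueError("SimConfig needs at least one genus")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.mode not in AMPLICON_WINDOWS:
            raise ValueError(f"unknown amplicon mode {self.mode!r}")
        if SampleType.MILK not in self.sample_types:
            raise ValueError("sample_types must include MILK (pairing anchor)")

    @property
    def effective_length(self) -> int:
        if self.length_bp is not None:
            return self.length_bp
        return 420 if self.mode == "short" else 2200


# ---------------------------------------------------------------------------
# truth log


@dataclass(frozen=True)
class SharingEvent:
    family_id: str
    genus: str
    comparison: str          # e.g. "MILK_vs_INFANT_ORAL"
    asv_id: str
    sample_a: str
    sample_b: str


@dataclass(frozen=True)
class ContaminantEvent:
    sample_id: str
    asv_id: str
    source: str              # isolation method name or "LIBPREP"
    count: int


@dataclass
class TruthLog:
    sharing: list[SharingEvent] = field(default_factory=list)
    contaminants: list[ContaminantEvent] = field(default_factory=list)

    def planted_families(self, genus: str, comparison: str) -> set[str]:
        return {
            e.family_id
            for e in self.sharing
            if e.genus == genus and e.comparison == comparison
        }

    def contaminant_ids(self, sample_id: str) -> set[str]:
        return {e.asv_id for e in self.contaminants if e.sample_id == sample_id}

    def sharing_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.sharing])

    def contaminant_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.contaminants])

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.sharing_frame().to_csv(directory / "truth_sharing.tsv", sep="\t", index=False)
        self.contaminant_frame().to_csv(
            directory / "truth_contaminants.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# mock communities


def simulate_mock_sample(
    reference: MockReference,
    depth: int,
    dispersion: float,
    seed: int,
    length_bp: int = 420,
    mode: str = "short",
    sample_id: str = "MOCK_1",
) -> tuple[pd.Series, list[AsvRecord]]:
    """Draw one mock-community column around a reference composition.

    Expected fractions are the reference perturbed by multiplicative
    log-normal noise and renormalized (softmax-like closure); counts are
    multinomial at the given depth. ``dispersion=0`` leaves the expected
    fractions exactly at the reference.
    """
    rng = _rng(seed, _ROLE_MOCK, _stable_key(sample_id))
    genera = reference.genera
    records = []
    for g in genera:
        pool = generate_genus_pool(
            g, 1, length_bp, 0.0, seed, mode=mode, id_prefix=f"{g}_mock"
        )
        records.append(pool.records[0])
    p = np.array([reference.fractions[g] for g in genera], dtype=float)
    if dispersion > 0:
        p = p * np.exp(rng.normal(0.0, dispersion, size=len(p)))
    if p.sum() == 0:
        raise ValueError("degenerate perturbed reference (all zero)")
    p = p / p.sum()
    if depth == 0:
        warnings.warn(f"{sample_id}: depth 0 gives an all-zero mock column", stacklevel=2)
        counts = np.zeros(len(p), dtype=int)
    else:
        counts = rng.multinomial(depth, p)
    col = pd.Series(counts, index=[r.asv_id for r in records], name=sample_id)
    return col, records


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortData:
    """One simulated dataset plus its ground truth and the config that made it."""

    table: AsvTable
    meta: list[SampleMeta]
    records: list[AsvRecord]
    taxonomy: pd.DataFrame
    truth: TruthLog
    config: SimConfig

    def write(self, directory: str | Path) -> None:
        from . import io as msio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        msio.write_asv_table(self.table, directory / "counts.tsv")
        msio.write_sample_meta(self.meta, directory / "metadata.tsv")
        msio.write_fasta(self.records, directory / "asvs.fasta")
        msio.write_taxonomy(self.taxonomy, directory / "taxonomy.tsv")
        self.truth.write(directory)


def _bio_sample_id(family: int, stype: SampleType) -> str:
    return f"F{family:02d}_{stype.value}"


def simulate_cohort(config: SimConfig) -> CohortData:
    """Simulate a full cohort (biological samples, controls, mocks) with truth."""
    seed = config.seed
    L = config.effective_length
    n_fam = config.n_families
    stypes = list(config.sample_types)
    bio_samples = [
        (_bio_sample_id(f, t), f, t) for f in range(1, n_fam + 1) for t in stypes
    ]
    n_bio = len(bio_samples)
    sample_index = {sid: k for k, (sid, _, _) in enumerate(bio_samples)}

    # --- genus pools: background + per-family + per-sample-private ASVs
    pool_size = 1 + n_fam + n_bio
    pools: dict[str, GenusPool] = {}
    for spec in config.genera:
        pools[spec.name] = generate_genus_pool(
            spec.name, pool_size, L, config.substitution_rate, seed, mode=config.mode
        )

    truth = TruthLog()
    # carriage[sample_id] -> {genus -> set of asv_ids}
    carriage: dict[str, dict[str, set[str]]] = {sid: {} for sid, _, _ in bio_samples}

    other_types = [t for t in stypes if t is not SampleType.MILK]
    for spec in config.genera:
        g = spec.name
        pool = pools[g]
        bg_asv = pool.records[0].asv_id
        fam_asv = {f: pool.records[f].asv_id for f in range(1, n_fam + 1)}
        rng_presence = _rng(seed, _ROLE_PRESENCE, _stable_key(g))
        rng_plant = _rng(seed, _ROLE_PLANT, _stable_key(g))
        rng_bg = _rng(seed, _ROLE_BACKGROUND, _stable_key(g))

        present = rng_presence.random(n_bio) < spec.prevalence
        carriers = {sid for k, (sid, _, _) in enumerate(bio_samples) if present[k]}

        for f in range(1, n_fam + 1):
            milk_id = _bio_sample_id(f, SampleType.MILK)
            for t in other_types:
                other_id = _bio_sample_id(f, t)
                if rng_plant.random() < spec.p_share:
                    carriers.add(milk_id)
                    carriers.add(other_id)
                    carriage[milk_id].setdefault(g, set()).add(fam_asv[f])
                    carriage[other_id].setdefault(g, set()).add(fam_asv[f])
                    truth.sharing.append(
                        SharingEvent(
                            family_id=f"F{f:02d}",
                            genus=g,
                            comparison=f"MILK_vs_{t.value}",
                            asv_id=fam_asv[f],
                            sample_a=milk_id,
                            sample_b=other_id,
                        )
                    )

        q_bg = float(np.sqrt(spec.p_bg))
        for sid, _, _ in bio_samples:
            if sid not in carriers:
                continue
            carried = carriage[sid].setdefault(g, set())
            carried.add(f"{g}_asv{1 + n_fam + sample_index[sid]:03d}")  # private ASV
            if q_bg > 0 and rng_bg.random() < q_bg:
                carried.add(bg_asv)

    # --- contaminant pools
    contaminant_pools: dict[str, list[AsvRecord]] = {}
    for cspec in config.contaminants:
        recs: list[AsvRecord] = []
        for gname in cspec.genera:
            p = generate_genus_pool(
                gname,
                1,
                L,
                0.0,
                seed,
                mode=config.mode,
                id_prefix=f"{gname}_{cspec.method.value}",
            )
            recs.extend(p.records)
        contaminant_pools[cspec.method.value] = recs
    libprep_pool: list[AsvRecord] = []
    for gname in config.libprep_contaminant_genera:
        p = generate_genus_pool(
            gname, 1, L, 0.0, seed, mode=config.mode, id_prefix=f"{gname}_LIBPREP"
        )
        libprep_pool.extend(p.records)

    # --- per-sample read counts
    all_records: dict[str, AsvRecord] = {}
    for pool in pools.values():
        for r in pool.records:
            all_records[r.asv_id] = r
    for recs in contaminant_pools.values():
        for r in recs:
            all_records[r.asv_id] = r
    for r in libprep_pool:
        all_records[r.asv_id] = r

    columns: dict[str, dict[str, int]] = {}
    meta: list[SampleMeta] = []
    log_sd_by_genus = {s.name: (s.log_mean, s.log_sd) for s in config.genera}

    for sid, fam, stype in bio_samples:
        rng_s = _rng(seed, _ROLE_COUNTS, sample_index[sid])
        depth = int(
            np.round(
                rng_s.lognormal(np.log(config.depth_mean), config.depth_log_sd)
            )
        )
        carried_genera = [g for g in carriage[sid] if carriage[sid][g]]
        cell_ids: list[str] = []
        cell_p: list[float] = []
        if carried_genera:
            gw = np.array(
                [
                    rng_s.lognormal(*log_sd_by_genus[g])
                    for g in carried_genera
                ]
            )
            gw = gw / gw.sum()
            for g, w in zip(carried_genera, gw):
                asvs = sorted(carriage[sid][g])
                within = rng_s.dirichlet(np.ones(len(asvs)))
                cell_ids.extend(asvs)
                cell_p.extend(w * within)
        col: dict[str, int] = {}
        if cell_ids:
            counts = rng_s.multinomial(depth, np.array(cell_p) / np.sum(cell_p))
            counts = np.maximum(counts, 1)  # carried ASVs always detectable
            col = dict(zip(cell_ids, counts.astype(int)))
        columns[sid] = col
        meta.append(
            SampleMeta(
                sample_id=sid,
                sample_type=stype,
                family_id=f"F{fam:02d}",
                isolation_method=config.isolation_method,
                sequencing_method=config.sequencing_method,
                dna_yield_ng=float(np.round(rng_s.lognormal(3.0, 1.0), 2)),
            )
        )

    # --- contaminant injection into biological samples
    rng_inject = _rng(seed, _ROLE_INJECT)
    for cspec in config.contaminants:
        pool_recs = contaminant_pools[cspec.method.value]
        for sid, fam, stype in bio_samples:
            if config.isolation_method != cspec.method:
                continue
            for rec in pool_recs:
                if rng_inject.random() < cspec.injection_rate:
                    cnt = max(
                        1,
                        int(
                            np.round(
                                rng_inject.lognormal(
                                    cspec.injection_log_mean, cspec.injection_log_sd
                                )
                            )
                        ),
                    )
                    columns[sid][rec.asv_id] = columns[sid].get(rec.asv_id, 0) + cnt
                    truth.contaminants.append(
                        ContaminantEvent(sid, rec.asv_id, cspec.method.value, cnt)
                    )
    for sid, fam, stype in bio_samples:
        for rec in libprep_pool:
            if rng_inject.random() < config.libprep_injection_rate:
                cnt = max(1, int(np.round(rng_inject.lognormal(1.0, 0.5))))
                columns[sid][rec.asv_id] = columns[sid].get(rec.asv_id, 0) + cnt
                truth.contaminants.append(
                    ContaminantEvent(sid, rec.asv_id, "LIBPREP", cnt)
                )

    # --- negative controls
    rng_ctrl = _rng(seed, _ROLE_CONTROLS)
    for cspec in config.contaminants:
        pool_recs = contaminant_pools[cspec.method.value]
        for r in range(1, config.n_controls_per_method + 1):
            cid = f"NEG_{cspec.method.value}_{r}"
            lo, hi = config.control_depth_range
            depth = int(rng_ctrl.integers(lo, hi + 1))
            col: dict[str, int] = {}
            if depth > 0 and pool_recs:
                w = rng_ctrl.dirichlet(np.ones(len(pool_recs)))
                counts = rng_ctrl.multinomial(depth, w)
                if depth >= len(pool_recs):
                    counts = np.maximum(counts, 1)  # every pool ASV detectable
                col = {
                    rec.asv_id: int(c) for rec, c in zip(pool_recs, counts) if c > 0
                }
            columns[cid] = col
            meta.append(
                SampleMeta(
                    sample_id=cid,
                    sample_type=SampleType.NEG_ISOLATION,
                    isolation_method=cspec.method,
                    sequencing_method=config.sequencing_method,
                    replicate=r,
                    dna_yield_ng=0.0,
                )
            )
    # library-prep control
    cid = "NEG_LIBPREP_1"
    lo, hi = config.libprep_control_depth_range
    depth = int(rng_ctrl.integers(lo, hi + 1))
    col = {}
    if depth > 0 and libprep_pool:
        w = rng_ctrl.dirichlet(np.ones(len(libprep_pool)))
        counts = rng_ctrl.multinomial(depth, w)
        if depth >= len(libprep_pool):
            counts = np.maximum(counts, 1)
        col = {rec.asv_id: int(c) for rec, c in zip(libprep_pool, counts) if c > 0}
    columns[cid] = col
    meta.append(
        SampleMeta(
            sample_id=cid,
            sample_type=SampleType.NEG_LIBPREP,
            sequencing_method=config.sequencing_method,
            dna_yield_ng=0.0,
        )
    )

    # --- mock communities
    if config.mock_reference is not None:
        for i in range(1, config.n_mock + 1):
            mid = f"MOCK_{i}"
            mcol, mrecs = simulate_mock_sample(
                config.mock_reference,
                config.mock_depth,
                config.mock_dispersion,
                seed,
                length_bp=L,
                mode=config.mode,
                sample_id=mid,
            )
            for r in mrecs:
                all_records[r.asv_id] = r
            columns[mid] = {a: int(c) for a, c in mcol.items() if c > 0}
            meta.append(
                SampleMeta(
                    sample_id=mid,
                    sample_type=SampleType.MOCK,
                    isolation_method=config.isolation_method,
                    sequencing_method=config.sequencing_method,
                    replicate=i,
                    dna_yield_ng=None,
                )
            )

    # --- assemble table over ASVs observed at least once
    sample_ids = [m.sample_id for m in meta]
    observed = sorted({a for col in columns.values() for a in col})
    mat = np.zeros((len(sample_ids), len(observed)), dtype=np.int64)
    col_index = {a: j for j, a in enumerate(observed)}
    for i, sid in enumerate(sample_ids):
        for a, c in columns[sid].items():
            mat[i, col_index[a]] = c
    table = AsvTable.from_arrays(mat, sample_ids, observed)

    records = [all_records[a] for a in observed]
    taxonomy = pd.DataFrame(
        {
            "genus": [r.genus for r in records],
            "species": [r.species for r in records],
        },
        index=pd.Index(observed, name="asv_id"),
    )
    return CohortData(table, meta, records, taxonomy, truth, config)


def simulate_negative_controls(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[SampleMeta], list[ContaminantEvent]]:
    """Standalone view of the negative-control columns of a simulated cohort."""
    cohort = simulate_cohort(config)
    ctrl_meta = [
        m
        for m in cohort.meta
        if m.sample_type in (SampleType.NEG_ISOLATION, SampleType.NEG_LIBPREP)
    ]
    ids = [m.sample_id for m in ctrl_meta]
    return cohort.table.counts.loc[ids], ctrl_meta, list(cohort.truth.contaminants)
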