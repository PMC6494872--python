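"""Data model and I/O for rCRS-aligned mitochondrial population transects.

All coordinates are 1-based rCRS positions; windows are closed on both
ends ("between np X and Y" is inclusive).  Sequences are fixed-length
strings of length 16,569 over the alphabet ``{A, C, G, T, N, -}`` where
``N`` and ``-`` both denote missing data for identity checks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOME_LENGTH = 16569
ALPHABET = frozenset("ACGTN-")


class MalformedRecordError(ValueError):
    """A FASTA record violates the fixed-length rCRS contract."""


class PileupError(ValueError):
    """A pileup row is internally inconsistent."""


class Era(str, Enum):
    """Chronological strata, ordered oldest to youngest."""

    HG = "HG"
    EN = "EN"
    MN = "MN"
    LN = "LN"
    EBA = "EBA"
    IA = "IA"
    MODERN = "MODERN"

    @property
    def rank(self) -> int:
        return ERA_ORDER.index(self)


ERA_ORDER: tuple[Era, ...] = (
    Era.HG, Era.EN, Era.MN, Era.LN, Era.EBA, Era.IA, Era.MODERN,
)


@dataclass(frozen=True)
class HvsWindow:
    """Closed 1-based rCRS coordinate window."""

    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= GENOME_LENGTH):
            raise ValueError(
                f"window {self.name!r} ({self.start}, {self.end}) outside 1..{GENOME_LENGTH}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Canonical hypervariable-segment windows used throughout the analyses.
WINDOWS: dict[str, HvsWindow] = {
    "HVS-I-diversity": HvsWindow(16033, 16365, "HVS-I-diversity"),
    "HVS-II": HvsWindow(73, 340, "HVS-II"),
    "HVS-I-pi": HvsWindow(16000, 16410, "HVS-I-pi"),
    "HVS-I-distance": HvsWindow(16064, 16400, "HVS-I-distance"),
}


@dataclass(frozen=True)
class MtSequence:
    """One individual's full rCRS-coordinate mitochondrial sequence."""

    sample_id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if len(self.bases) != GENOME_LENGTH:
            raise MalformedRecordError(
                f"record {self.sample_id!r} has length {len(self.bases)}, expected {GENOME_LENGTH}"
            )
        bad = set(self.bases) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.sample_id!r} contains illegal characters {sorted(bad)!r}"
            )

    def window(self, window: HvsWindow) -> str:
        return extract_window(self, window)


def extract_window(seq: MtSequence, window: HvsWindow) -> str:
    """Substring covering rCRS positions ``start..end`` inclusive."""
    return seq.bases[window.start - 1 : window.end]


def read_fasta(path: str | Path) -> list[MtSequence]:
    """Read fixed-length rCRS-aligned records; bases are uppercased."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper()
        if len(bases) != GENOME_LENGTH:
            raise MalformedRecordError(
                f"record {rec.id!r} has length {len(bases)}, expected {GENOME_LENGTH}"
            )
        out.append(MtSequence(sample_id=rec.id, bases=bases))
    return out


def write_fasta(seqs: Iterable[MtSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.sample_id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


class Sex(str, Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


@dataclass
class Individual:
    sample_id: str
    population: str
    era: Era
    haplogroup_label: str = ""
    sequence: MtSequence | None = None
    anthropological_sex: Sex = Sex.UNKNOWN


@dataclass
class TransectDataset:
    """Populations x individuals with era tags — the unit every stage consumes."""

    individuals: list[Individual]
    populations: dict[str, Era]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.sample_id in seen:
                raise ValueError(f"duplicate sample_id {ind.sample_id!r}")
            seen.add(ind.sample_id)
            if ind.population not in self.populations:
                raise ValueError(
                    f"individual {ind.sample_id!r} in unknown population {ind.population!r}"
                )

    def get(self, sample_id: str) -> Individual:
        for ind in self.individuals:
            if ind.sample_id == sample_id:
                return ind
        raise KeyError(sample_id)

    def members(self, population: str) -> list[Individual]:
        if population not in self.populations:
            raise KeyError(population)
        return [i for i in self.individuals if i.population == population]

    def subset(self, populations: Iterable[str]) -> "TransectDataset":
        pops = list(populations)
        return TransectDataset(
            individuals=[i for i in self.individuals if i.population in pops],
            populations={p: self.populations[p] for p in pops},
            provenance=self.provenance,
        )

    def sequences(self, population: str, window: HvsWindow | None = None) -> list[str]:
        """Window strings (or full genomes) for one population, erroring on absent sequences."""
        out = []
        for ind in self.members(population):
            if ind.sequence is None:
                raise ValueError(f"sample {ind.sample_id!r} has no sequence")
            out.append(
                extract_window(ind.sequence, window) if window else ind.sequence.bases
            )
        return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Metadata CSV with columns sample_id,population,era,haplogroup,anthro_sex."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "population", "era", "haplogroup"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    return df


def write_metadata(dataset: TransectDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "population", "era", "haplogroup", "anthro_sex"])
        for ind in dataset.individuals:
            w.writerow(
                [
                    ind.sample_id,
                    ind.population,
                    ind.era.value,
                    ind.haplogroup_label,
                    ind.anthropological_sex.value,
                ]
            )


def dataset_from_metadata(
    df: pd.DataFrame,
    sequences: Mapping[str, MtSequence] | None = None,
    provenance: str = "",
) -> TransectDataset:
    sequences = sequences or {}
    individuals = []
    populations: dict[str, Era] = {}
    for row in df.itertuples(index=False):
        era = Era(row.era)
        populations.setdefault(row.population, era)
        sex = Sex(row.anthro_sex) if getattr(row, "anthro_sex", "") in ("F", "M") else Sex.UNKNOWN
        individuals.append(
            Individual(
                sample_id=row.sample_id,
                population=row.population,
                era=era,
                haplogroup_label=row.haplogroup,
                sequence=sequences.get(row.sample_id),
                anthropological_sex=sex,
            )
        )
    return TransectDataset(individuals, populations, provenance)


# ---------------------------------------------------------------------------
# Consensus calling from per-site pileup summaries
# ---------------------------------------------------------------------------

@dataclass
class SitePileup:
    """Per-site read support for one sample: rows of (pos, depth, A, C, G, T)."""

    sample_id: str
    rows: list[tuple[int, int, int, int, int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pos, depth, a, c, g, t in self.rows:
            if not (1 <= pos <= GENOME_LENGTH):
                raise PileupError(f"{self.sample_id}: position {pos} outside genome")
            if pos in seen:
                raise PileupError(f"{self.sample_id}: duplicate position {pos}")
            seen.add(pos)
            if depth != a + c + g + t:
                raise PileupError(
                    f"{self.sample_id}: depth {depth} != base-count sum at position {pos}"
                )


def read_pileup(path: str | Path) -> list[SitePileup]:
    """TSV with columns sample_id,pos,depth,A,C,G,T; one SitePileup per sample."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        rows = [
            (int(r.pos), int(r.depth), int(r.A), int(r.C), int(r.G), int(r.T))
            for r in grp.itertuples(index=False)
        ]
        out.append(SitePileup(sample_id=str(sid), rows=rows))
    return out


@dataclass
class QcReport:
    sample_id: str
    n_missing: int
    missing_fraction: float
    fail_missingness: bool
    fail_hvs1: bool

    @property
    def passed(self) -> bool:
        return not (self.fail_missingness or self.fail_hvs1)


# Consensus call rules: depth >= 3 and a 3/5 read majority; a whole-genome
# missing fraction >= 5% or any N inside the HVS-I window fails QC.
MIN_DEPTH = 3
MAJORITY = 3 / 5
MAX_MISSING_FRACTION = 0.05


def consensus_from_pileup(
    pileup: SitePileup, genome_length: int = GENOME_LENGTH
) -> tuple[MtSequence, QcReport]:
    calls = ["N"] * genome_length
    for pos, depth, a, c, g, t in pileup.rows:
        if depth < MIN_DEPTH:
            continue
        for base, count in zip("ACGT", (a, c, g, t)):
            if count / depth >= MAJORITY:
                calls[pos - 1] = base
                break
    bases = "".join(calls)
    n_missing = bases.count("N")
    frac = n_missing / genome_length
    hvs1 = WINDOWS["HVS-I-diversity"]
    fail_hvs1 = "N" in bases[hvs1.start - 1 : hvs1.end]
    seq = MtSequence(sample_id=pileup.sample_id, bases=bases)
    report = QcReport(
        sample_id=pileup.sample_id,
        n_missing=n_missing,
        missing_fraction=frac,
        fail_missingness=frac >= MAX_MISSING_FRACTION,
        fail_hvs1=fail_hvs1,
    )
    return seq, report


# ---------------------------------------------------------------------------
# Duplicate-individual handling
# ---------------------------------------------------------------------------

def _identity_key(seq: MtSequence, window: HvsWindow | None) -> str:
    s = extract_window(seq, window) if window else seq.bases
    return s.replace("-", "N")


def find_identical_pairs(
    dataset: TransectDataset, window: HvsWindow | None = None
) -> list[tuple[str, str]]:
    """All unordered pairs with character-identical sequences over the range.

    Gaps and Ns are both treated as missing and compared as equal.  Output is
    sorted lexicographically (within and between pairs) so it is independent
    of input order.
    """
    by_key: dict[str, list[str]] = {}
    for ind in dataset.individuals:
        if ind.sequence is None:
            raise ValueError(f"sample {ind.sample_id!r} has no sequence")
        by_key.setdefault(_identity_key(ind.sequence, window), []).append(ind.sample_id)
    pairs = []
    for ids in by_key.values():
        ids = sorted(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j]))
    return sorted(pairs)


def deduplicate(
    dataset: TransectDataset,
    pairs: Sequence[tuple[str, str]],
    remove: Iterable[str] | None = None,
) -> TransectDataset:
    """Drop one member of each identical pair.

    The default policy removes the lexicographically later sample_id of each
    pair; an explicit ``remove`` list overrides it.
    """
    ids = {i.sample_id for i in dataset.individuals}
    for a, b in pairs:
        for sid in (a, b):
            if sid not in ids:
                raise ValueError(f"pair member {sid!r} not in dataset")
    if remove is not None:
        to_drop = set(remove)
        missing = to_drop - ids
        if missing:
            raise ValueError(f"removal list names absent samples {sorted(missing)}")
    else:
        to_drop = {max(a, b) for a, b in pairs}
    return TransectDataset(
        individuals=[i for i in dataset.individuals if i.sample_id not in to_drop],
        populations=dict(dataset.populations),
        provenance=dataset.provenance,
    )
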