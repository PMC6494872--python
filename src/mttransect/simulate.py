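"""Founder-graph synthetic population transects with known ground truth.

The generator plants exactly the structures the downstream analyses
measure — haplogroup-bin frequencies, HVS divergence, haplotype sharing
along an era-ordered founder graph, group structure for the molecular
variance analyses, and sex-chromosome read counts — with analytically
known truth, rather than simulating a coalescent.  Every dataset is
deterministic under its seed.

Sequences are built on a seeded synthetic 16,569-base backbone (the
coordinate system and window arithmetic are the same as for real
rCRS-aligned data; the backbone itself is synthetic).  Founders are
defined by private variant motifs at dedicated sites, so pairwise
differences between founder haplotypes are sums of their motif sizes and
planted diversity values are exact.  Individual-level private mutations
(rate ``mu`` per site) never hit motif sites, keeping haplogroup labels
and founder identity truthful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    GENOME_LENGTH,
    Era,
    Individual,
    MtSequence,
    Sex,
    TransectDataset,
    WINDOWS,
    dataset_from_metadata,
    read_fasta,
    read_metadata,
    write_fasta,
    write_metadata,
)

_BACKBONE_SEED = 20_210_417  # fixed: the coordinate backbone never varies


def synthetic_backbone(length: int = GENOME_LENGTH) -> str:
    """Deterministic synthetic reference sequence (not the real rCRS)."""
    rng = np.random.default_rng(_BACKBONE_SEED)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


_SUBSTITUTE = {"A": "G", "C": "T", "G": "A", "T": "C"}


def _apply_sites(backbone: list[str], sites: dict[int, str]) -> str:
    seq = backbone.copy()
    for pos, base in sites.items():
        seq[pos - 1] = base
    return "".join(seq)


@dataclass(frozen=True)
class FounderSpec:
    name: str
    haplogroup: str
    era: Era                      # era of first appearance
    sites: dict[int, str] = field(default_factory=dict, hash=False)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    era: Era
    n: int
    #: haplogroup-bin (or label) target frequencies; sampled per individual
    bin_freqs: dict[str, float] = field(default_factory=dict, hash=False)
    #: founder names this population may draw from
    founder_pool: tuple[str, ...] = ()


@dataclass
class GeneratorConfig:
    populations: list[PopulationSpec]
    founders: list[FounderSpec]
    mu: float = 0.0               # private mutations per site per individual
    mutation_window: tuple[int, int] = (16000, 16410)
    planted_partition: dict[str, int] | None = None
    emit_sequences: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 0.05):
            raise ValueError("mu must lie in [0, 0.05]")
        for pop in self.populations:
            total = sum(pop.bin_freqs.values())
            if pop.bin_freqs and abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"population {pop.name!r} bin frequencies sum to {total}"
                )
        names = [f.name for f in self.founders]
        if len(names) != len(set(names)):
            raise ValueError("founder names must be unique")


class ConfigError(ValueError):
    pass


@dataclass
class GroundTruthManifest:
    founder_of: dict[str, str]            # sample_id -> founder name
    founder_era: dict[str, str]           # founder name -> era of first appearance
    founder_haplogroup: dict[str, str]
    planted_partition: dict[str, int] | None = None
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    expected_pi: dict[str, float] = field(default_factory=dict)
    true_sexes: dict[str, str] = field(default_factory=dict)
    expected_attribution: dict[str, float] = field(default_factory=dict)
    expected_sharing: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "founder_of": self.founder_of,
            "founder_era": self.founder_era,
            "founder_haplogroup": self.founder_haplogroup,
            "planted_partition": self.planted_partition,
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "expected_pi": self.expected_pi,
            "true_sexes": self.true_sexes,
            "expected_attribution": self.expected_attribution,
            "expected_sharing": self.expected_sharing,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(
            founder_of=d["founder_of"],
            founder_era=d["founder_era"],
            founder_haplogroup=d["founder_haplogroup"],
            planted_partition=d["planted_partition"],
            duplicate_pairs=[tuple(p) for p in d["duplicate_pairs"]],
            expected_pi=d["expected_pi"],
            true_sexes=d["true_sexes"],
            expected_attribution=d["expected_attribution"],
            expected_sharing=d["expected_sharing"],
        )


def simulate_transect(
    config: GeneratorConfig, seed: int | None = 0
) -> tuple[TransectDataset, GroundTruthManifest]:
    """Draw a transect: founder per mixture, then Poisson private mutations."""
    rng = np.random.default_rng(seed)
    founders = {f.name: f for f in config.founders}
    motif_sites = {p for f in config.founders for p in f.sites}
    lo, hi = config.mutation_window
    free_sites = np.array(
        sorted(set(range(lo, hi + 1)) - motif_sites), dtype=int
    )
    backbone = list(synthetic_backbone())

    individuals: list[Individual] = []
    populations: dict[str, Era] = {}
    founder_of: dict[str, str] = {}
    for pop in config.populations:
        populations[pop.name] = pop.era
        pool = [founders[n] for n in pop.founder_pool]
        by_bin: dict[str, list[FounderSpec]] = {}
        for f in pool:
            by_bin.setdefault(f.haplogroup, []).append(f)
        bins = sorted(pop.bin_freqs) if pop.bin_freqs else []
        for b in bins:
            if pop.bin_freqs[b] > 0 and b not in by_bin:
                raise ConfigError(
                    f"population {pop.name!r}: no founder available for bin {b!r}"
                )
        for i in range(pop.n):
            if bins:
                probs = np.array([pop.bin_freqs[b] for b in bins])
                chosen_bin = bins[rng.choice(len(bins), p=probs)]
                cands = by_bin[chosen_bin]
            else:
                cands = pool
            if not cands:
                raise ConfigError(f"population {pop.name!r} has an empty founder pool")
            founder = cands[int(rng.integers(len(cands)))]
            sid = f"{pop.name}{i + 1:03d}"
            founder_of[sid] = founder.name
            seq = None
            if config.emit_sequences:
                sites = dict(founder.sites)
                n_mut = rng.poisson(config.mu * (hi - lo + 1))
                if n_mut > 0:
                    for pos in rng.choice(free_sites, size=min(n_mut, len(free_sites)), replace=False):
                        ref = backbone[pos - 1]
                        alts = [b for b in "ACGT" if b != ref]
                        sites[int(pos)] = alts[int(rng.integers(3))]
                seq = MtSequence(sid, _apply_sites(backbone, sites))
            individuals.append(
                Individual(
                    sample_id=sid,
                    population=pop.name,
                    era=pop.era,
                    haplogroup_label=founder.haplogroup,
                    sequence=seq,
                )
            )

    dataset = TransectDataset(
        individuals=individuals,
        populations=populations,
        provenance="synthetic founder-graph transect",
    )
    manifest = GroundTruthManifest(
        founder_of=founder_of,
        founder_era={f.name: f.era.value for f in config.founders},
        founder_haplogroup={f.name: f.haplogroup for f in config.founders},
        planted_partition=config.planted_partition,
    )
    return dataset, manifest


# ---------------------------------------------------------------------------
# Curated demo transect emulating the study conditions
# ---------------------------------------------------------------------------

#: focal founder design: (name, haplogroup, attributed era, carrier reference
#: populations, motif size k).  The focal Iron Age population carries one
#: individual per founder plus two whole-genome duplicates, giving 27
#: individuals, 25 distinct haplotypes, and exact planted attribution and
#: sharing fractions (EN 44%, MN 20%, LN 12%, EBA 8%, HG 16%; 20/25 present
#: in >=1 LN/EBA population, 7/25 in all of CWC+BBC+UC, 5/25 absent).
_FOCAL_FOUNDERS: list[tuple[str, str, Era, tuple[str, ...], int]] = [
    ("F01", "U3a1a",    Era.EN,  ("STA", "CWC", "BBC", "UC"), 3),
    ("F02", "HV0f",     Era.EN,  ("LBK", "CWC", "BBC", "UC"), 3),
    ("F03", "J1c3",     Era.EN,  ("RSC", "CWC", "BBC", "UC"), 3),
    ("F04", "U5a1b3",   Era.EN,  ("STA", "CWC", "BBC", "UC"), 3),
    ("F05", "H16",      Era.EN,  ("LBK", "BEC"), 3),
    ("F06", "T1a9",     Era.EN,  ("RSC", "BEC", "CWC"), 3),
    ("F07", "H11a1",    Era.EN,  ("STA", "BBC"), 3),
    ("F08", "U4c1",     Era.EN,  ("LBK", "UC"), 3),
    ("F09", "T2a1a",    Era.EN,  ("STA",), 3),
    ("F10", "H1e2",     Era.EN,  ("LBK",), 3),
    ("F11", "H1cg",     Era.EN,  ("RSC",), 3),
    ("F12", "U5a2b3",   Era.MN,  ("BAC", "CWC", "BBC", "UC"), 3),
    ("F13", "K1c1",     Era.MN,  ("SMC", "CWC", "BBC", "UC"), 3),
    ("F14", "H2a1a",    Era.MN,  ("BAC", "BEC"), 3),
    ("F15", "H1a3",     Era.MN,  ("SMC", "UC"), 3),
    ("F16", "U5a2a1",   Era.MN,  ("BAC",), 3),
    ("F17", "T2b",      Era.LN,  ("CWC", "BBC", "UC"), 4),
    ("F18", "U5a1b1e",  Era.LN,  ("BEC",), 4),
    ("F19", "T2b23",    Era.LN,  ("BBC",), 4),
    ("F20", "K1a27",    Era.EBA, ("UC",), 4),
    ("F21", "H5e1b",    Era.EBA, ("UC",), 4),
    ("F22", "N1a1a1a2", Era.HG,  ("HGC", "BEC"), 4),
    ("F23", "T2b2b",    Era.HG,  ("HGC", "CWC"), 4),
    ("F24", "V",        Era.HG,  ("HGC", "UC"), 4),
    ("F25", "H7a1a",    Era.HG,  ("HGC",), 4),
]

_REFERENCE_ERAS: dict[str, Era] = {
    "HGC": Era.HG,
    "STA": Era.EN, "LBK": Era.EN, "RSC": Era.EN,
    "BAC": Era.MN, "SMC": Era.MN,
    "BEC": Era.LN, "CWC": Era.LN, "BBC": Era.LN,
    "UC": Era.EBA,
}

#: LN/EBA populations used in the sharing summary; the "all three" triple.
LNBA_POPULATIONS = ("BEC", "CWC", "BBC", "UC")
LNBA_TRIPLE = ("CWC", "BBC", "UC")

#: two private (unshared) founders per reference population
_PRIVATE_LABELS: dict[str, tuple[str, str]] = {
    "HGC": ("U5b1", "U2e1"),
    "STA": ("N1a1a", "T2c1"),
    "LBK": ("N1a1b", "K1a2"),
    "RSC": ("H1j", "J1c2"),
    "BAC": ("H3b", "T2e1"),
    "SMC": ("U5b2a", "W1c"),
    "BEC": ("J2b1a", "X2b"),
    "CWC": ("U4a2", "I1a"),
    "BBC": ("H1b1", "W5a"),
    "UC": ("U5a1a", "I4a"),
}

FOCAL_POPULATION = "MAS"


def mas_like_transect(seed: int = 0) -> tuple[TransectDataset, GroundTruthManifest]:
    """The demo transect: a 27-individual Iron Age focal cohort with two
    planted whole-genome duplicate pairs, plus ten era-tagged reference
    populations sharing founder haplotypes along the era order.

    Planted quantities (exact by construction, from the disjoint-motif
    design): focal HD on the deduplicated 25 distinct haplotypes is 1.0;
    focal nucleotide diversity over np 16000-16410 on the deduplicated set
    is 2 * 84 / (25 * 411) = 0.016350; attribution and LN/EBA sharing
    fractions follow the founder table.
    """
    rng = np.random.default_rng(seed)
    backbone = list(synthetic_backbone())

    # dedicated motif sites inside np 16070..16360 (within every HVS window)
    site_pool = list(rng.permutation(np.arange(16070, 16361)))

    def take(k: int) -> dict[int, str]:
        sites = {}
        for _ in range(k):
            pos = int(site_pool.pop())
            sites[pos] = _SUBSTITUTE[backbone[pos - 1]]
        return sites

    founders: dict[str, FounderSpec] = {}
    carriers: dict[str, list[str]] = {p: [] for p in _REFERENCE_ERAS}
    for name, hg, era, pops, k in _FOCAL_FOUNDERS:
        founders[name] = FounderSpec(name=name, haplogroup=hg, era=era, sites=take(k))
        for p in pops:
            carriers[p].append(name)
    for pop, (lab1, lab2) in _PRIVATE_LABELS.items():
        era = _REFERENCE_ERAS[pop]
        for j, lab in enumerate((lab1, lab2), start=1):
            name = f"P{pop}{j}"
            founders[name] = FounderSpec(name=name, haplogroup=lab, era=era, sites=take(3))
            carriers[pop].append(name)

    individuals: list[Individual] = []
    founder_of: dict[str, str] = {}

    def add(pop: str, era: Era, founder: FounderSpec, sid: str) -> None:
        seq = MtSequence(sid, _apply_sites(backbone, founder.sites))
        individuals.append(
            Individual(
                sample_id=sid, population=pop, era=era,
                haplogroup_label=founder.haplogroup, sequence=seq,
            )
        )
        founder_of[sid] = founder.name

    # focal cohort: one individual per founder + duplicates of F01 and F02
    focal_names = [f[0] for f in _FOCAL_FOUNDERS]
    for i, fname in enumerate(focal_names, start=1):
        add(FOCAL_POPULATION, Era.IA, founders[fname], f"MAS{i:03d}")
    add(FOCAL_POPULATION, Era.IA, founders["F01"], "MAS026")
    add(FOCAL_POPULATION, Era.IA, founders["F02"], "MAS027")

    # Reference populations: one carrier per shared founder, and three
    # carriers per private background founder (background homogeneity gives
    # the transect non-degenerate between-population distances without
    # touching the focal cohort or the planted sharing sets).
    for pop, era in _REFERENCE_ERAS.items():
        i = 0
        for fname in sorted(carriers[pop]):
            copies = 3 if fname.startswith("P") else 1
            for _ in range(copies):
                i += 1
                add(pop, era, founders[fname], f"{pop}{i:03d}")

    populations = {FOCAL_POPULATION: Era.IA, **_REFERENCE_ERAS}
    dataset = TransectDataset(
        individuals=individuals,
        populations=populations,
        provenance="synthetic founder-graph transect emulating the focal study conditions",
    )

    sum_k = sum(k for *_x, k in _FOCAL_FOUNDERS)
    pi_window = WINDOWS["HVS-I-pi"].length
    manifest = GroundTruthManifest(
        founder_of=founder_of,
        founder_era={f.name: f.era.value for f in founders.values()},
        founder_haplogroup={f.name: f.haplogroup for f in founders.values()},
        duplicate_pairs=[("MAS001", "MAS026"), ("MAS002", "MAS027")],
        expected_pi={FOCAL_POPULATION: 2.0 * sum_k / len(_FOCAL_FOUNDERS) / pi_window},
        expected_attribution={
            "HG": 16.0, "EN": 44.0, "MN": 20.0, "LN": 12.0, "EBA": 8.0,
        },
        expected_sharing={
            "pct_inherited_in_any": 80.0,
            "pct_inherited_in_all": 28.0,
            "pct_absent": 20.0,
        },
    )
    return dataset, manifest


def planted_amova_transect(
    seed: int = 0, pops_per_group: int = 2, n_per_pop: int = 8
) -> tuple[TransectDataset, GroundTruthManifest]:
    """Three planted groups of populations with group-defining motifs.

    Populations within a group share a founder pool; groups differ at six
    dedicated sites, so the true 3-way partition maximizes Fct.
    """
    rng = np.random.default_rng(seed)
    backbone = synthetic_backbone()
    site_pool = list(rng.permutation(np.arange(16070, 16361)))

    def take(k: int) -> dict[int, str]:
        return {
            (pos := int(site_pool.pop())): _SUBSTITUTE[backbone[pos - 1]]
            for _ in range(k)
        }

    labels = ("H1", "U5a1", "T2b")
    founders: list[FounderSpec] = []
    pops: list[PopulationSpec] = []
    partition: dict[str, int] = {}
    for g in range(3):
        group_sites = take(6)
        pool = []
        for j in range(2):
            f = FounderSpec(
                name=f"G{g}F{j}",
                haplogroup=labels[g],
                era=Era.LN,
                sites={**group_sites, **take(1)},
            )
            founders.append(f)
            pool.append(f.name)
        for p in range(pops_per_group):
            name = f"G{g}P{p}"
            pops.append(
                PopulationSpec(
                    name=name, era=Era.LN, n=n_per_pop, founder_pool=tuple(pool)
                )
            )
            partition[name] = g
    config = GeneratorConfig(
        populations=pops,
        founders=founders,
        mu=0.0,
        planted_partition=partition,
    )
    return simulate_transect(config, seed=int(rng.integers(2**31 - 1)))


# ---------------------------------------------------------------------------
# Sex-chromosome read counts
# ---------------------------------------------------------------------------

#: typical Ry centers: females show a small noise floor, males ~0.09
FEMALE_RY = 0.001
MALE_RY = 0.09


@dataclass(frozen=True)
class SexCohortMember:
    sample_id: str
    true_sex: str  # "F" | "M"
    depth: int


def simulate_sex_counts(
    cohort: list[SexCohortMember],
    seed: int | None = 0,
    female_ry: float = FEMALE_RY,
    male_ry: float = MALE_RY,
):
    """Binomial X/Y read counts for individuals of known sex."""
    from .sexing import SexReadCounts

    rng = np.random.default_rng(seed)
    out = []
    for member in cohort:
        if member.depth < 0:
            raise ValueError("depths must be >= 0")
        r = male_ry if member.true_sex == "M" else female_ry
        n_y = int(rng.binomial(member.depth, r)) if member.depth > 0 else 0
        out.append(
            SexReadCounts(sample_id=member.sample_id, n_y=n_y, n_x=member.depth - n_y)
        )
    return out


def default_sex_cohort(n: int = 27, depth: int = 10_000, seed: int = 0):
    rng = np.random.default_rng(seed)
    return [
        SexCohortMember(
            sample_id=f"SX{i:04d}",
            true_sex="M" if rng.random() < 0.5 else "F",
            depth=depth,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Round-trip persistence
# ---------------------------------------------------------------------------

def save_bundle(
    dataset: TransectDataset, manifest: GroundTruthManifest, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [i.sequence for i in dataset.individuals if i.sequence is not None],
        outdir / "sequences.fasta",
    )
    write_metadata(dataset, outdir / "metadata.csv")
    (outdir / "manifest.json").write_text(manifest.to_json())


def load_bundle(outdir: str | Path) -> tuple[TransectDataset, GroundTruthManifest]:
    outdir = Path(outdir)
    seqs = {s.sample_id: s for s in read_fasta(outdir / "sequences.fasta")}
    df = read_metadata(outdir / "metadata.csv")
    dataset = dataset_from_metadata(df, sequences=seqs, provenance="reloaded bundle")
    manifest = GroundTruthManifest.from_json((outdir / "manifest.json").read_text())
    return dataset, manifest


def verify_manifest(dataset: TransectDataset, manifest: GroundTruthManifest) -> None:
    """Exact consistency checks between a dataset and its manifest."""
    ids = {i.sample_id for i in dataset.individuals}
    if set(manifest.founder_of) != ids:
        raise ValueError("manifest individuals do not match dataset")
    for ind in dataset.individuals:
        fname = manifest.founder_of[ind.sample_id]
        if manifest.founder_haplogroup[fname] != ind.haplogroup_label:
            raise ValueError(f"haplogroup mismatch for {ind.sample_id}")
    for a, b in manifest.duplicate_pairs:
        sa, sb = dataset.get(a).sequence, dataset.get(b).sequence
        if sa is None or sb is None or sa.bases != sb.bases:
            raise ValueError(f"planted duplicate pair ({a}, {b}) not identical")
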