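"""Shared-haplotype matrices and earliest-era lineage attribution.

Haplotype identity is exact string match over a window (default the
cross-population comparison window, np 16064-16400).  A focal haplotype is
attributed to the earliest chronological stratum (HG < EN < MN < LN < EBA
< IA) in which an identical haplotype occurs among the reference
populations; haplotypes matching no reference are "novel".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ERA_ORDER, Era, HvsWindow, TransectDataset, WINDOWS, extract_window

MISSING = frozenset("N-")


def _haplotype_sets(
    dataset: TransectDataset, window: HvsWindow, populations: Sequence[str]
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for pop in populations:
        haps = set()
        bad = []
        for ind in dataset.members(pop):
            if ind.sequence is None:
                raise ValueError(f"sample {ind.sample_id!r} has no sequence")
            hap = extract_window(ind.sequence, window)
            if set(hap) & MISSING:
                bad.append(ind.sample_id)
            else:
                haps.add(hap)
        if bad:
            raise ValueError(f"missing data within window for {bad}")
        out[pop] = haps
    return out


@dataclass
class SharingMatrix:
    populations: list[str]
    shared: pd.DataFrame       # counts of shared distinct haplotypes
    unique_pair: pd.DataFrame  # haplotypes present in exactly that pair


def shared_haplotypes(
    dataset: TransectDataset,
    window: HvsWindow,
    focal: str,
    references: Sequence[str],
) -> SharingMatrix:
    """Counts of distinct window haplotypes shared between population pairs.

    The diagonal holds each population's distinct haplotype count; the
    ``unique_pair`` matrix counts haplotypes present in exactly that pair of
    populations (among the populations considered here).
    """
    pops = [focal] + [p for p in references if p != focal]
    sets = _haplotype_sets(dataset, window, pops)
    k = len(pops)
    shared = np.zeros((k, k), dtype=int)
    unique = np.zeros((k, k), dtype=int)
    for i in range(k):
        shared[i, i] = len(sets[pops[i]])
    for i, j in combinations(range(k), 2):
        inter = sets[pops[i]] & sets[pops[j]]
        shared[i, j] = shared[j, i] = len(inter)
        n_unique = sum(
            1
            for h in inter
            if all(h not in sets[pops[m]] for m in range(k) if m not in (i, j))
        )
        unique[i, j] = unique[j, i] = n_unique
    return SharingMatrix(
        populations=pops,
        shared=pd.DataFrame(shared, index=pops, columns=pops),
        unique_pair=pd.DataFrame(unique, index=pops, columns=pops),
    )


@dataclass
class HaplotypeAttribution:
    haplotype: str
    carriers: list[str]        # focal sample ids carrying it
    earliest_era: str          # era value or "novel"
    earliest_populations: list[str]  # reference pops of that earliest era
    carrier_populations: list[str]   # every reference pop containing it


@dataclass
class LineageAttribution:
    focal: str
    references: list[str]
    records: list[HaplotypeAttribution]
    percentages: dict[str, float]  # category -> percent of focal haplotypes

    @property
    def n_haplotypes(self) -> int:
        return len(self.records)


def attribute_lineages(
    dataset: TransectDataset,
    window: HvsWindow,
    focal: str,
    references: Sequence[str],
    era_order: Sequence[Era] = ERA_ORDER,
) -> LineageAttribution:
    """Earliest-era attribution of every distinct focal haplotype."""
    if not references:
        raise ValueError("empty reference set")
    sets = _haplotype_sets(dataset, window, list(references))
    pop_era = {p: dataset.populations[p] for p in references}
    rank = {era: i for i, era in enumerate(era_order)}

    focal_haps: dict[str, list[str]] = {}
    for ind in dataset.members(focal):
        hap = extract_window(ind.sequence, window)
        if set(hap) & MISSING:
            raise ValueError(f"missing data within window for [{ind.sample_id!r}]")
        focal_haps.setdefault(hap, []).append(ind.sample_id)

    records = []
    for hap in sorted(focal_haps):
        carrier_pops = sorted(p for p in references if hap in sets[p])
        if not carrier_pops:
            era_label, earliest_pops = "novel", []
        else:
            best = min(rank[pop_era[p]] for p in carrier_pops)
            era_label = era_order[best].value
            earliest_pops = [p for p in carrier_pops if rank[pop_era[p]] == best]
        records.append(
            HaplotypeAttribution(
                haplotype=hap,
                carriers=sorted(focal_haps[hap]),
                earliest_era=era_label,
                earliest_populations=earliest_pops,
                carrier_populations=carrier_pops,
            )
        )

    n = len(records)
    categories = [e.value for e in era_order] + ["novel"]
    percentages = {
        cat: 100.0 * sum(1 for r in records if r.earliest_era == cat) / n
        for cat in categories
        if any(r.earliest_era == cat for r in records)
    }
    return LineageAttribution(
        focal=focal, references=list(references), records=records,
        percentages=percentages,
    )


@dataclass
class LnbaPresenceSummary:
    pct_inherited_in_any: float   # of inherited haplotypes, % in >= 1 LN/EBA pop
    pct_inherited_in_all: float   # of inherited haplotypes, % in every pop of the triple
    pct_absent: float             # of all focal haplotypes, % absent from every LN/EBA pop
    n_inherited: int
    n_focal: int


def lnba_presence_summary(
    attribution: LineageAttribution,
    lnba_pops: Iterable[str],
    all_of: Iterable[str] | None = None,
    era_order: Sequence[Era] = ERA_ORDER,
) -> LnbaPresenceSummary:
    """Presence of inherited focal haplotypes among named LN/EBA populations.

    "Inherited" means attributed to LN/EBA or any earlier stratum.  The
    ``all_of`` triple defaults to the LN/EBA set itself.
    """
    lnba = set(lnba_pops)
    if not lnba:
        raise ValueError("empty LN/EBA population set")
    unknown = lnba - set(attribution.references)
    if unknown:
        raise ValueError(f"unknown population name(s) {sorted(unknown)}")
    if all_of is None:
        all_of = lnba
    all_of = set(all_of)

    rank = {era.value: i for i, era in enumerate(era_order)}
    cutoff = rank[Era.EBA.value]
    inherited = [
        r
        for r in attribution.records
        if r.earliest_era != "novel" and rank[r.earliest_era] <= cutoff
    ]
    n_inherited = len(inherited)
    n_focal = len(attribution.records)
    in_any = sum(1 for r in inherited if lnba & set(r.carrier_populations))
    in_all = sum(1 for r in inherited if all_of <= set(r.carrier_populations))
    absent = sum(
        1 for r in attribution.records if not (lnba & set(r.carrier_populations))
    )
    return LnbaPresenceSummary(
        pct_inherited_in_any=100.0 * in_any / n_inherited if n_inherited else 0.0,
        pct_inherited_in_all=100.0 * in_all / n_inherited if n_inherited else 0.0,
        pct_absent=100.0 * absent / n_focal,
        n_inherited=n_inherited,
        n_focal=n_focal,
    )
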