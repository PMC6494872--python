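"""Haplotype diversity and nucleotide diversity over HVS windows.

HD follows Nei's unbiased estimator with his sampling variance; the
nucleotide-diversity standard deviation uses Tajima's total variance
approximation (the estimator behind the customary printed "+/-" values).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .io import HvsWindow, TransectDataset, extract_window

MISSING = frozenset("N-")


@dataclass
class HaplotypeTable:
    windows: list[HvsWindow]
    counts: dict[str, int]  # haplotype string -> multiplicity

    def __post_init__(self) -> None:
        lengths = {len(h) for h in self.counts}
        if len(lengths) > 1:
            raise ValueError("haplotype strings of unequal length")
        for h in self.counts:
            if set(h) & MISSING:
                raise ValueError("haplotype table requires complete windows")

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def haplotype_table(
    dataset: TransectDataset, population: str, windows: Sequence[HvsWindow]
) -> HaplotypeTable:
    """Concatenated window haplotypes with multiplicities for one population."""
    counts: Counter[str] = Counter()
    for ind in dataset.members(population):
        if ind.sequence is None:
            raise ValueError(f"sample {ind.sample_id!r} has no sequence")
        hap = "".join(extract_window(ind.sequence, w) for w in windows)
        if set(hap) & MISSING:
            raise ValueError(
                f"sample {ind.sample_id!r} has missing data within the window(s)"
            )
        counts[hap] += 1
    return HaplotypeTable(windows=list(windows), counts=dict(counts))


@dataclass
class DiversityEstimate:
    statistic: str  # "HD" or "PI"
    value: float
    sd: float
    n: int


def haplotype_diversity(table: HaplotypeTable) -> DiversityEstimate:
    """Nei's unbiased haplotype (gene) diversity with its sampling s.d.

    HD = n/(n-1) (1 - sum p_i^2); the variance is Nei's (1987) formula
    V = 2/(n(n-1)) * [2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2].
    """
    n = table.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = np.array(list(table.counts.values())) / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum2)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return DiversityEstimate("HD", hd, float(np.sqrt(max(var, 0.0))), n)


def nucleotide_diversity(
    seqs: Sequence[str], per_site: bool = True, ids: Sequence[str] | None = None
) -> DiversityEstimate:
    """Mean pairwise difference (per site by default), pairwise-deleting missing.

    The s.d. is Tajima's (1983) total variance of pi,
    V = (n+1)/(3(n-1)) * pi/L + 2(n^2+n+3)/(9n(n-1)) * pi^2,
    with L the mean number of compared sites.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity requires >= 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, -1)
    present = (arr != b"N") & (arr != b"-")
    total = 0.0
    sites = []
    for i, j in combinations(range(n), 2):
        ok = present[i] & present[j]
        c = int(ok.sum())
        if c == 0:
            a = ids[i] if ids else str(i)
            b = ids[j] if ids else str(j)
            raise ValueError(f"no comparable sites between {a!r} and {b!r}")
        d = int((arr[i, ok] != arr[j, ok]).sum())
        sites.append(c)
        total += d / c if per_site else d
    n_pairs = n * (n - 1) // 2
    pi = total / n_pairs
    L = float(np.mean(sites))
    pi_site = pi if per_site else pi / L
    var_site = (n + 1) / (3 * (n - 1)) * pi_site / L + (
        2 * (n**2 + n + 3) / (9 * n * (n - 1))
    ) * pi_site**2
    sd = float(np.sqrt(max(var_site, 0.0)))
    if not per_site:
        sd *= L
    return DiversityEstimate("PI", pi, sd, n)


def population_diversity(
    dataset: TransectDataset,
    population: str,
    hd_windows: Sequence[HvsWindow],
    pi_window: HvsWindow,
) -> dict[str, DiversityEstimate]:
    """Both statistics for one population over the configured windows."""
    table = haplotype_table(dataset, population, hd_windows)
    members = dataset.members(population)
    seqs = [extract_window(i.sequence, pi_window) for i in members]
    return {
        "HD": haplotype_diversity(table),
        "PI": nucleotide_diversity(seqs, ids=[i.sample_id for i in members]),
    }
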