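"""Three-level AMOVA and the exhaustive grouping-optimality search.

The molecular variance of squared pairwise model distances is partitioned
among groups (sigma2_a), among populations within groups (sigma2_b) and
within populations (sigma2_c), with unequal-sample-size coefficients.
Phi-statistics:

    Fct = sigma2_a / sigma2_total
    Fsc = sigma2_b / (sigma2_b + sigma2_c)
    Fst = (sigma2_a + sigma2_b) / sigma2_total

Permutation null distributions follow the customary schemes: individuals
among populations (Fst), individuals among populations within groups
(Fsc), and whole populations among groups (Fct); p = (1+x)/(N+1).

A grouping is considered optimal when Fct is maximal and Fsc minimal; as
no single scalar combines the two, the search reports the Pareto front
over (max Fct, min Fsc) and ranks nondominated candidates by Fct with
Fsc as tie-break.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .distance import SubstitutionModel, _phist_from_d2, _ss, distance_matrix
from .io import HvsWindow, TransectDataset


@dataclass
class GroupingScheme:
    partition: dict[str, int]  # population -> group id
    locked_blocks: list[frozenset] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(set(self.partition.values()))

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pop, gid in self.partition.items():
            out.setdefault(gid, []).append(pop)
        return out

    def validate(self) -> None:
        for block in self.locked_blocks:
            gids = {self.partition[p] for p in block if p in self.partition}
            missing = [p for p in block if p not in self.partition]
            if missing:
                raise ValueError(f"locked block member(s) {missing} unassigned")
            if len(gids) > 1:
                raise ValueError(f"locked block {sorted(block)} split across groups")


@dataclass
class AmovaResult:
    sigma_a: float
    sigma_b: float
    sigma_c: float
    fct: float
    fsc: float
    fst: float
    fct_raw: float
    fsc_raw: float
    fst_raw: float
    p_fct: float | None = None
    p_fsc: float | None = None
    p_fst: float | None = None
    n_perm: int = 0

    @property
    def sigma_total(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c


def _components(
    d2: np.ndarray, groups: list[list[np.ndarray]]
) -> tuple[float, float, float]:
    """Variance components (a, b, c) for populations nested in groups."""
    pops = [p for g in groups for p in g]
    sizes = np.array([len(p) for p in pops], dtype=float)
    N = float(sizes.sum())
    P = len(pops)
    G = len(groups)
    if G < 2:
        raise ValueError("Fct undefined: need >= 2 groups")

    group_idx = [np.concatenate(g) for g in groups]
    Ng = np.array([len(gi) for gi in group_idx], dtype=float)
    all_idx = np.concatenate(group_idx)

    ss_total = _ss(d2, all_idx)
    ss_wp = sum(_ss(d2, p) for p in pops)
    ss_groups = sum(_ss(d2, gi) for gi in group_idx)
    ss_ag = ss_total - ss_groups
    ss_apwg = ss_groups - ss_wp

    df_wp = N - P
    df_apwg = P - G
    df_ag = G - 1

    # Unequal-n coefficients (Excoffier-style nested design)
    sum_n2_over_Ng = sum(
        sum(len(p) ** 2 for p in g) / len(gi)
        for g, gi in zip(groups, group_idx)
    )
    sum_n2_over_N = float(np.sum(sizes**2)) / N
    sum_Ng2_over_N = float(np.sum(Ng**2)) / N
    n1 = (N - sum_n2_over_Ng) / df_apwg if df_apwg > 0 else 1.0
    n2 = (sum_n2_over_Ng - sum_n2_over_N) / df_ag
    n3 = (N - sum_Ng2_over_N) / df_ag

    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    ms_apwg = ss_apwg / df_apwg if df_apwg > 0 else ms_wp
    ms_ag = ss_ag / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_apwg - sigma_c) / n1 if df_apwg > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def _phis(sigma_a: float, sigma_b: float, sigma_c: float) -> tuple[float, float, float]:
    total = sigma_a + sigma_b + sigma_c
    fct = sigma_a / total if total != 0 else 0.0
    fsc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0
    fst = (sigma_a + sigma_b) / total if total != 0 else 0.0
    return fct, fsc, fst


def amova3(
    dataset: TransectDataset,
    scheme: GroupingScheme,
    model: SubstitutionModel,
    window: HvsWindow | None = None,
    n_perm: int = 0,
    seed: int | None = None,
    d2: np.ndarray | None = None,
    pop_indices: dict[str, np.ndarray] | None = None,
) -> AmovaResult:
    """Three-level AMOVA of a grouped transect.

    A precomputed squared-distance matrix and per-population index arrays
    may be supplied so a grouping search reuses them across candidates.
    """
    scheme.validate()
    grouping = scheme.groups()
    if d2 is None or pop_indices is None:
        seqs: list[str] = []
        pop_indices = {}
        for pop in scheme.partition:
            member_seqs = dataset.sequences(pop, window)
            if len(member_seqs) < 2:
                raise ValueError(f"population {pop!r} needs >= 2 individuals")
            start = len(seqs)
            seqs.extend(member_seqs)
            pop_indices[pop] = np.arange(start, len(seqs))
        d2 = distance_matrix(seqs, model) ** 2

    groups = [
        [pop_indices[p] for p in sorted(pops)] for _, pops in sorted(grouping.items())
    ]
    sigma_a, sigma_b, sigma_c = _components(d2, groups)
    fct_raw, fsc_raw, fst_raw = _phis(sigma_a, sigma_b, sigma_c)
    result = AmovaResult(
        sigma_a=sigma_a, sigma_b=sigma_b, sigma_c=sigma_c,
        fct=max(fct_raw, 0.0), fsc=max(fsc_raw, 0.0), fst=max(fst_raw, 0.0),
        fct_raw=fct_raw, fsc_raw=fsc_raw, fst_raw=fst_raw,
        n_perm=n_perm,
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        result.p_fst = _perm_p_fst(d2, groups, fst_raw, n_perm, rng)
        result.p_fsc = _perm_p_fsc(d2, groups, fsc_raw, n_perm, rng)
        result.p_fct = _perm_p_fct(d2, groups, fct_raw, n_perm, rng)
    return result


def _perm_p_fst(d2, groups, observed, n_perm, rng) -> float:
    sizes = [len(p) for g in groups for p in g]
    group_sizes = [len(g) for g in groups]
    all_idx = np.concatenate([p for g in groups for p in g])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        pops, start = [], 0
        for s in sizes:
            pops.append(perm[start : start + s])
            start += s
        regrouped, k = [], 0
        for gs in group_sizes:
            regrouped.append(pops[k : k + gs])
            k += gs
        _, _, fst = _phis(*_components(d2, regrouped))
        if fst >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _perm_p_fsc(d2, groups, observed, n_perm, rng) -> float:
    hits = 0
    for _ in range(n_perm):
        shuffled = []
        for g in groups:
            idx = np.concatenate(g)
            perm = rng.permutation(idx)
            pops, start = [], 0
            for p in g:
                pops.append(perm[start : start + len(p)])
                start += len(p)
            shuffled.append(pops)
        _, fsc, _ = _phis(*_components(d2, shuffled))
        if fsc >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _perm_p_fct(d2, groups, observed, n_perm, rng) -> float:
    pops = [p for g in groups for p in g]
    group_sizes = [len(g) for g in groups]
    hits = 0
    for _ in range(n_perm):
        order = rng.permutation(len(pops))
        regrouped, k = [], 0
        for gs in group_sizes:
            regrouped.append([pops[i] for i in order[k : k + gs]])
            k += gs
        fct, _, _ = _phis(*_components(d2, regrouped))
        if fct >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Candidate partitions and the optimality search
# ---------------------------------------------------------------------------

def parse_candidates(lines: Iterable[str]) -> list[GroupingScheme]:
    """Parse one partition per line: groups separated by '+', populations by
    commas, optionally parenthesised, e.g. ``(STA, LBK) + (CWC, UC)``."""
    schemes = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        partition: dict[str, int] = {}
        for gid, chunk in enumerate(line.split("+")):
            for pop in re.split(r"[,\s]+", chunk.strip().strip("()")):
                if pop:
                    partition[pop.strip()] = gid
        schemes.append(GroupingScheme(partition=partition))
    return schemes


def read_candidates(path: str | Path) -> list[GroupingScheme]:
    return parse_candidates(Path(path).read_text().splitlines())


def enumerate_partitions(
    populations: Sequence[str],
    locked_blocks: Sequence[Iterable[str]] = (),
    max_groups: int | None = None,
    max_candidates: int = 10000,
) -> list[GroupingScheme]:
    """All set partitions of the populations (locked blocks kept together)."""
    blocks: list[frozenset] = [frozenset(b) for b in locked_blocks]
    locked = set().union(*blocks) if blocks else set()
    units: list[frozenset] = blocks + [
        frozenset([p]) for p in populations if p not in locked
    ]

    def rec(i: int, groups: list[list[frozenset]]):
        if i == len(units):
            yield [g[:] for g in groups]
            return
        for g in groups:
            g.append(units[i])
            yield from rec(i + 1, groups)
            g.pop()
        if max_groups is None or len(groups) < max_groups:
            groups.append([units[i]])
            yield from rec(i + 1, groups)
            groups.pop()

    out = []
    for grouping in rec(0, []):
        partition = {
            pop: gid for gid, units_in_g in enumerate(grouping)
            for u in units_in_g for pop in u
        }
        out.append(GroupingScheme(partition=partition, locked_blocks=list(blocks)))
        if len(out) >= max_candidates:
            break
    return out


@dataclass
class SearchEntry:
    scheme: GroupingScheme
    result: AmovaResult | None
    pareto: bool = False
    rank: int | None = None
    rejected: str | None = None


@dataclass
class GroupingSearchReport:
    entries: list[SearchEntry]

    @property
    def best(self) -> SearchEntry:
        ranked = [e for e in self.entries if e.rank is not None]
        return min(ranked, key=lambda e: e.rank)

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.entries:
            groups = " + ".join(
                "(" + ",".join(sorted(pops)) + ")"
                for _, pops in sorted(e.scheme.groups().items())
            )
            rows.append(
                {
                    "partition": groups,
                    "n_groups": e.scheme.n_groups,
                    "fct": e.result.fct_raw if e.result else np.nan,
                    "fsc": e.result.fsc_raw if e.result else np.nan,
                    "fst": e.result.fst_raw if e.result else np.nan,
                    "p_fct": e.result.p_fct if e.result else np.nan,
                    "pareto": e.pareto,
                    "rank": e.rank,
                    "rejected": e.rejected or "",
                }
            )
        return pd.DataFrame(rows)


def grouping_search(
    dataset: TransectDataset,
    candidates: Sequence[GroupingScheme],
    model: SubstitutionModel,
    window: HvsWindow | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> GroupingSearchReport:
    """Evaluate amova3 for every candidate partition and rank them.

    The squared-distance matrix is computed once and shared by all
    candidates.  Single-group candidates and candidates violating their
    locked blocks are recorded as rejected, not silently dropped.
    """
    pops = sorted({p for c in candidates for p in c.partition})
    seqs: list[str] = []
    pop_indices: dict[str, np.ndarray] = {}
    for pop in pops:
        member_seqs = dataset.sequences(pop, window)
        if len(member_seqs) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 individuals")
        start = len(seqs)
        seqs.extend(member_seqs)
        pop_indices[pop] = np.arange(start, len(seqs))
    d2 = distance_matrix(seqs, model) ** 2

    entries = []
    for i, cand in enumerate(candidates):
        if cand.n_groups < 2:
            entries.append(
                SearchEntry(cand, None, rejected="Fct undefined for a single group")
            )
            continue
        try:
            cand.validate()
        except ValueError as exc:
            entries.append(SearchEntry(cand, None, rejected=str(exc)))
            continue
        res = amova3(
            dataset, cand, model, window=window, n_perm=n_perm,
            seed=None if seed is None else seed + i,
            d2=d2, pop_indices=pop_indices,
        )
        entries.append(SearchEntry(cand, res))

    evaluated = [e for e in entries if e.result is not None]
    for e in evaluated:
        e.pareto = not any(
            (o.result.fct_raw >= e.result.fct_raw and o.result.fsc_raw <= e.result.fsc_raw)
            and (o.result.fct_raw > e.result.fct_raw or o.result.fsc_raw < e.result.fsc_raw)
            for o in evaluated
        )
    front = [e for e in evaluated if e.pareto]
    front.sort(key=lambda e: (-e.result.fct_raw, e.result.fsc_raw))
    for r, e in enumerate(front):
        e.rank = r
    return GroupingSearchReport(entries=entries)
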