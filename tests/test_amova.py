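"""Three-level molecular variance analysis and the grouping search."""

import numpy as np
import pytest
from scipy.stats import kstest

from mttransect.amova import (
    GroupingScheme,
    amova3,
    enumerate_partitions,
    grouping_search,
    parse_candidates,
)
from mttransect.distance import SubstitutionModel, pairwise_distance, pairwise_fst
from mttransect.io import Era, WINDOWS
from mttransect.simulate import planted_amova_transect

from conftest import toy_dataset, variant

P = SubstitutionModel(model="P_DIST")
WIN = WINDOWS["HVS-I-distance"]


def _pos(i):
    return 16100 + i


def build_dataset(groups: dict[int, dict[str, list[dict[int, str]]]]):
    """groups: {gid: {pop: [site-dict per individual]}} -> dataset + scheme."""
    spec = {}
    partition = {}
    for gid, pops in groups.items():
        for pop, members in pops.items():
            spec[pop] = (
                Era.LN,
                {f"{pop}_{k}": sites for k, sites in enumerate(members)},
            )
            partition[pop] = gid
    return toy_dataset(spec), GroupingScheme(partition=partition)


def amova3_oracle(dataset, scheme, model, window):
    """Independent nested sums-of-squares decomposition with plain loops."""
    groups = {}
    for pop, gid in scheme.partition.items():
        groups.setdefault(gid, []).append(pop)
    seq_of = {}
    for pop in scheme.partition:
        for ind in dataset.members(pop):
            seq_of[ind.sample_id] = (
                pop,
                gid := scheme.partition[pop],
                ind.sequence.window(window),
            )

    ids = sorted(seq_of)

    def ss(members):
        n = len(members)
        tot = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                tot += pairwise_distance(
                    seq_of[members[i]][2], seq_of[members[j]][2], model
                ) ** 2
        return tot / n

    pops = sorted(scheme.partition)
    pop_members = {p: [i for i in ids if seq_of[i][0] == p] for p in pops}
    group_members = {
        g: [i for i in ids if seq_of[i][1] == g] for g in groups
    }
    N, Pn, G = len(ids), len(pops), len(groups)
    ss_total = ss(ids)
    ss_wp = sum(ss(pop_members[p]) for p in pops)
    ss_groups = sum(ss(group_members[g]) for g in groups)

    ms_wp = (ss_wp) / (N - Pn)
    ms_apwg = (ss_groups - ss_wp) / (Pn - G) if Pn > G else 0.0
    ms_ag = (ss_total - ss_groups) / (G - 1)

    sum_n2_over_Ng = sum(
        sum(len(pop_members[p]) ** 2 for p in groups[g]) / len(group_members[g])
        for g in groups
    )
    n1 = (N - sum_n2_over_Ng) / (Pn - G) if Pn > G else 1.0
    n2 = (sum_n2_over_Ng - sum(len(pop_members[p]) ** 2 for p in pops) / N) / (G - 1)
    n3 = (N - sum(len(group_members[g]) ** 2 for g in groups) / N) / (G - 1)

    sc = ms_wp
    sb = (ms_apwg - sc) / n1 if Pn > G else 0.0
    sa = (ms_ag - sc - n2 * sb) / n3
    return sa, sb, sc


class TestAmova3:
    def test_all_identical_individuals_give_zero_components(self):
        ds, scheme = build_dataset({
            0: {"p1": [{}, {}], "p2": [{}, {}]},
            1: {"p3": [{}, {}], "p4": [{}, {}]},
        })
        res = amova3(ds, scheme, P, window=WIN)
        assert res.sigma_total == pytest.approx(0.0)
        assert res.fct == res.fsc == res.fst == 0.0

    def test_pure_between_group_difference_gives_fct_one(self):
        v = {_pos(0): variant(_pos(0))}
        ds, scheme = build_dataset({
            0: {"p1": [{}, {}], "p2": [{}, {}]},
            1: {"p3": [v, v], "p4": [v, v]},
        })
        res = amova3(ds, scheme, P, window=WIN)
        assert res.fct_raw == pytest.approx(1.0)
        assert res.sigma_b == pytest.approx(0.0)
        assert res.sigma_c == pytest.approx(0.0)

    def test_matches_independent_oracle_on_random_unbalanced_toys(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            groups = {}
            for g in range(2):
                pops = {}
                for p in range(2 + g):  # unbalanced: 2 and 3 populations
                    members = []
                    for _ in range(int(rng.integers(2, 5))):
                        sites = {
                            _pos(i): variant(_pos(i))
                            for i in rng.choice(12, size=rng.integers(0, 5), replace=False)
                        }
                        members.append(sites)
                    pops[f"g{g}p{p}"] = members
                groups[g] = pops
            ds, scheme = build_dataset(groups)
            res = amova3(ds, scheme, P, window=WIN)
            sa, sb, sc = amova3_oracle(ds, scheme, P, WIN)
            assert res.sigma_a == pytest.approx(sa, abs=1e-12)
            assert res.sigma_b == pytest.approx(sb, abs=1e-12)
            assert res.sigma_c == pytest.approx(sc, abs=1e-12)

    def test_degenerate_two_population_design_reproduces_pairwise_phist(self):
        rng = np.random.default_rng(23)
        mk = lambda: {
            _pos(i): variant(_pos(i))
            for i in rng.choice(10, size=rng.integers(1, 4), replace=False)
        }
        ds, scheme = build_dataset({
            0: {"pa": [mk(), mk(), mk()]},
            1: {"pb": [mk(), mk(), mk()]},
        })
        res = amova3(ds, scheme, P, window=WIN)
        seqs_a = ds.sequences("pa", WIN)
        seqs_b = ds.sequences("pb", WIN)
        two_level = pairwise_fst(seqs_a, seqs_b, P)
        assert res.fst_raw == pytest.approx(two_level.fst_raw, abs=1e-12)

    def test_group_relabeling_leaves_statistics_unchanged(self):
        v = {_pos(0): variant(_pos(0))}
        ds, scheme = build_dataset({
            0: {"p1": [{}, v], "p2": [{}, {}]},
            1: {"p3": [v, v], "p4": [v, {}]},
        })
        res1 = amova3(ds, scheme, P, window=WIN)
        relabeled = GroupingScheme(
            partition={p: 9 - g for p, g in scheme.partition.items()}
        )
        res2 = amova3(ds, relabeled, P, window=WIN)
        assert res1.fct_raw == pytest.approx(res2.fct_raw)
        assert res1.fsc_raw == pytest.approx(res2.fsc_raw)

    def test_single_group_rejected(self):
        ds, _ = build_dataset({0: {"p1": [{}, {}], "p2": [{}, {}]}})
        scheme = GroupingScheme(partition={"p1": 0, "p2": 0})
        with pytest.raises(ValueError, match="Fct undefined"):
            amova3(ds, scheme, P, window=WIN)

    def test_permutation_p_reproducible_and_bounded(self):
        v = {_pos(0): variant(_pos(0))}
        ds, scheme = build_dataset({
            0: {"p1": [{}, {}, v], "p2": [{}, v, {}]},
            1: {"p3": [v, v, {}], "p4": [v, {}, v]},
        })
        r1 = amova3(ds, scheme, P, window=WIN, n_perm=99, seed=3)
        r2 = amova3(ds, scheme, P, window=WIN, n_perm=99, seed=3)
        for a, b in [(r1.p_fct, r2.p_fct), (r1.p_fsc, r2.p_fsc), (r1.p_fst, r2.p_fst)]:
            assert a == b
            assert 1 / 100 <= a <= 1.0

    def test_null_fct_permutation_p_is_uniform(self):
        # 8 populations drawn from one pool, grouped 4+4: p should be uniform
        rng = np.random.default_rng(31)
        pvals = []
        for _ in range(200):
            groups = {0: {}, 1: {}}
            for p in range(8):
                members = []
                for _ in range(4):
                    sites = {
                        _pos(i): variant(_pos(i))
                        for i in rng.choice(10, size=rng.integers(0, 4), replace=False)
                    }
                    members.append(sites)
                groups[p % 2][f"p{p}"] = members
            ds, scheme = build_dataset(groups)
            res = amova3(
                ds, scheme, P, window=WIN, n_perm=49,
                seed=int(rng.integers(2**31 - 1)),
            )
            pvals.append(res.p_fct)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestGroupingSearch:
    def test_candidate_file_round_trip(self):
        lines = [
            "(STA, LBK, RSC) + (CWC, UC) + (BEC, BBC)",
            "STA,LBK,RSC + CWC,UC,BEC,BBC",
        ]
        cands = parse_candidates(lines)
        assert len(cands) == 2
        assert cands[0].n_groups == 3
        assert cands[1].partition["BBC"] == cands[1].partition["CWC"]

    def test_41_candidates_all_evaluated(self):
        ds, _ = planted_amova_transect(seed=5)
        pops = sorted(ds.populations)
        all_cands = enumerate_partitions(pops, max_groups=3)
        cands = all_cands[:41]
        report = grouping_search(ds, cands, P, window=WIN)
        assert len(report.entries) == 41

    def test_planted_three_group_partition_ranks_first(self):
        ds, manifest = planted_amova_transect(seed=5)
        cands = enumerate_partitions(sorted(ds.populations), max_groups=3)
        report = grouping_search(ds, cands, P, window=WIN)
        best = report.best
        truth = manifest.planted_partition
        # compare as set-partitions (group ids are arbitrary)
        blocks = lambda part: {
            frozenset(p for p in part if part[p] == g) for g in set(part.values())
        }
        assert blocks(best.scheme.partition) == blocks(truth)
        assert best.result.fct_raw > 0.9

    def test_single_group_candidate_excluded_with_message(self):
        ds, _ = planted_amova_transect(seed=5)
        pops = sorted(ds.populations)
        single = parse_candidates([",".join(pops)])
        report = grouping_search(ds, single, P, window=WIN)
        assert report.entries[0].rejected is not None
        assert "Fct undefined" in report.entries[0].rejected

    def test_locked_block_violation_rejected(self):
        ds, _ = planted_amova_transect(seed=5)
        pops = sorted(ds.populations)
        cand = GroupingScheme(
            partition={p: i % 2 for i, p in enumerate(pops)},
            locked_blocks=[frozenset(pops[:2])],
        )
        report = grouping_search(ds, [cand], P, window=WIN)
        assert report.entries[0].rejected is not None
        assert "locked" in report.entries[0].rejected

    def test_enumerate_partitions_respects_locked_blocks(self):
        cands = enumerate_partitions(
            ["a", "b", "c", "d"], locked_blocks=[["a", "b"]], max_groups=2
        )
        for cand in cands:
            assert cand.partition["a"] == cand.partition["b"]

    def test_pareto_front_flags_are_nondominated(self):
        ds, _ = planted_amova_transect(seed=5)
        cands = enumerate_partitions(sorted(ds.populations), max_groups=3)[:20]
        report = grouping_search(ds, cands, P, window=WIN)
        evaluated = [e for e in report.entries if e.result is not None]
        for e in evaluated:
            if e.pareto:
                assert not any(
                    o.result.fct_raw > e.result.fct_raw
                    and o.result.fsc_raw < e.result.fsc_raw
                    for o in evaluated
                )
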