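"""End-to-end orchestration of the analysis sequence.

Stages run in the published order: consensus QC -> duplicate removal ->
diversity -> median-joining network -> haplogroup profiles / clustering /
PCA -> Phi-st + MDS -> AMOVA grouping search -> lineage attribution ->
sexing.  Every stage is a pure function of the run configuration and the
upstream stage outputs, and all randomness flows from the configured
seeds, so a repeated run is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diversity as div
from . import haplogroups as hg
from .amova import GroupingScheme, grouping_search
from .distance import SubstitutionModel, fst_matrix, nmds
from .io import WINDOWS, TransectDataset, deduplicate, find_identical_pairs
from .lineages import attribute_lineages, lnba_presence_summary, shared_haplotypes
from .mjn import build_mjn
from .sexing import SexingThresholds, sex_table
from .simulate import (
    FOCAL_POPULATION,
    LNBA_POPULATIONS,
    LNBA_TRIPLE,
    default_sex_cohort,
    load_bundle,
    mas_like_transect,
    planted_amova_transect,
    simulate_sex_counts,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    With ``input_dir`` unset the demo transect is generated from ``seed``;
    otherwise a saved bundle (FASTA + metadata CSV + manifest JSON) is
    loaded from disk.
    """

    outdir: str
    seed: int = 0
    input_dir: str | None = None
    focal: str = FOCAL_POPULATION
    scheme: str = "CEPT23"
    metric: str = "euclidean"
    model: str = "P_DIST"
    gamma_alpha: float | None = None
    n_perm: int = 99
    n_boot: int = 200
    dedup_remove: list[str] | None = None
    candidate_lines: list[str] = field(default_factory=list)
    fst_populations: list[str] | None = None
    run_sexing: bool = True
    sex_depth: int = 10_000

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        if cfg.input_dir is not None and not Path(cfg.input_dir).exists():
            raise FileNotFoundError(f"input_dir {cfg.input_dir!r} does not exist")
        return cfg


def _round(x, nd=10):
    if isinstance(x, bool):
        return x
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_all(config: RunConfig) -> dict:
    """Execute all stages, writing tables plus a JSON summary; returns the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "focal": config.focal}

    # --- input -----------------------------------------------------------
    if config.input_dir is not None:
        dataset, manifest = load_bundle(config.input_dir)
    else:
        dataset, manifest = mas_like_transect(seed=config.seed)
    summary["n_individuals"] = len(dataset.individuals)
    summary["n_populations"] = len(dataset.populations)

    model = SubstitutionModel(model=config.model, gamma_alpha=config.gamma_alpha)
    win_dist = WINDOWS["HVS-I-distance"]

    # --- duplicates (within the focal cohort) ----------------------------
    try:
        pairs = find_identical_pairs(dataset.subset([config.focal]))
        deduped = deduplicate(dataset, pairs, remove=config.dedup_remove)
        summary["identical_pairs"] = [list(p) for p in pairs]
        summary["n_after_dedup"] = len(deduped.members(config.focal))
    except Exception as exc:  # noqa: BLE001 - stage-named halt
        raise StageError("dedup", exc)

    # --- diversity -------------------------------------------------------
    try:
        ests = div.population_diversity(
            deduped, config.focal,
            hd_windows=[WINDOWS["HVS-I-diversity"], WINDOWS["HVS-II"]],
            pi_window=WINDOWS["HVS-I-pi"],
        )
        ests_all = div.population_diversity(
            dataset, config.focal,
            hd_windows=[WINDOWS["HVS-I-diversity"], WINDOWS["HVS-II"]],
            pi_window=WINDOWS["HVS-I-pi"],
        )
        summary["diversity"] = {
            "deduplicated": {
                k: {"value": e.value, "sd": e.sd, "n": e.n} for k, e in ests.items()
            },
            "all": {
                k: {"value": e.value, "sd": e.sd, "n": e.n}
                for k, e in ests_all.items()
            },
        }
    except Exception as exc:
        raise StageError("diversity", exc)

    # --- median-joining network -----------------------------------------
    try:
        focal_seqs = {
            i.sample_id: i.sequence.bases for i in dataset.members(config.focal)
        }
        net = build_mjn(focal_seqs)
        net.node_table().to_csv(outdir / "mjn_nodes.tsv", sep="\t", index=False)
        (outdir / "mjn.dot").write_text(net.to_dot())
        summary["mjn"] = {
            "n_observed": len(net.observed_nodes),
            "n_median": len(net.median_nodes),
            "n_edges": net.graph.number_of_edges(),
        }
    except Exception as exc:
        raise StageError("mjn", exc)

    # --- profiles, clustering, PCA --------------------------------------
    try:
        scheme = hg.SCHEMES[config.scheme]
        profiles = [
            hg.profile(dataset, p, scheme) for p in sorted(dataset.populations)
        ]
        hg.profiles_frame(profiles).to_csv(outdir / "profiles.tsv", sep="\t")
        dendro = hg.ward_cluster(
            profiles, metric=config.metric, n_boot=config.n_boot, seed=config.seed
        )
        (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        pca_res = hg.pca(profiles)
        summary["profiles"] = {
            "scheme": scheme.name,
            "pca_variance_pc1_pc2_pct": 100.0
            * float(np.sum(pca_res.variance_explained[:2])),
            "top_clade_support": max(
                (s for s in dendro.supports.values() if s is not None), default=None
            ),
        }
    except Exception as exc:
        raise StageError("profiles", exc)

    # --- Phi-st and MDS --------------------------------------------------
    try:
        fst_pops = config.fst_populations or sorted(dataset.populations)
        seqs_by_pop = {p: dataset.sequences(p, win_dist) for p in fst_pops}
        fst_df, slatkin_df, p_df = fst_matrix(
            seqs_by_pop, model, n_perm=config.n_perm, seed=config.seed
        )
        fst_df.to_csv(outdir / "fst.tsv", sep="\t")
        slatkin_df.to_csv(outdir / "slatkin.tsv", sep="\t")
        p_df.to_csv(outdir / "fst_p.tsv", sep="\t")
        emb = nmds(
            slatkin_df.to_numpy(), k=2, n_starts=4, seed=config.seed,
            labels=list(fst_df.index),
        )
        focal_row = fst_df.loc[config.focal].drop(config.focal)
        summary["fst"] = {
            "closest_to_focal": focal_row.idxmin(),
            "closest_fst": float(focal_row.min()),
            "mds_stress": emb.stress,
        }
    except Exception as exc:
        raise StageError("fst", exc)

    # --- AMOVA grouping search ------------------------------------------
    try:
        amova_data, amova_manifest = planted_amova_transect(seed=config.seed)
        if config.candidate_lines:
            from .amova import parse_candidates

            candidates = parse_candidates(config.candidate_lines)
        else:
            from .amova import enumerate_partitions

            candidates = enumerate_partitions(
                sorted(amova_data.populations), max_groups=3
            )
        report = grouping_search(
            amova_data, candidates, model, window=win_dist,
            n_perm=0, seed=config.seed,
        )
        report.to_frame().to_csv(outdir / "amova_search.tsv", sep="\t", index=False)
        best = report.best
        truth = amova_manifest.planted_partition
        recovered = _same_partition(best.scheme.partition, truth)
        summary["amova"] = {
            "n_candidates": len(report.entries),
            "best_fct": best.result.fct_raw,
            "best_fsc": best.result.fsc_raw,
            "planted_partition_recovered": bool(recovered),
        }
    except Exception as exc:
        raise StageError("amova", exc)

    # --- lineages --------------------------------------------------------
    try:
        refs = [p for p in sorted(dataset.populations) if p != config.focal]
        sharing = shared_haplotypes(dataset, win_dist, config.focal, refs)
        sharing.shared.to_csv(outdir / "sharing.tsv", sep="\t")
        attribution = attribute_lineages(dataset, win_dist, config.focal, refs)
        lnba = lnba_presence_summary(
            attribution, LNBA_POPULATIONS, all_of=LNBA_TRIPLE
        )
        summary["lineages"] = {
            "percentages": attribution.percentages,
            "lnba_in_any_pct": lnba.pct_inherited_in_any,
            "lnba_in_all_triple_pct": lnba.pct_inherited_in_all,
            "lnba_absent_pct": lnba.pct_absent,
        }
    except Exception as exc:
        raise StageError("lineages", exc)

    # --- sexing ----------------------------------------------------------
    if config.run_sexing:
        try:
            cohort = default_sex_cohort(
                n=len(dataset.members(config.focal)),
                depth=config.sex_depth,
                seed=config.seed,
            )
            counts = simulate_sex_counts(cohort, seed=config.seed + 1)
            table = sex_table(counts, SexingThresholds())
            table.to_csv(outdir / "sex_calls.tsv", sep="\t", index=False)
            truth = {m.sample_id: m.true_sex for m in cohort}
            called = table[table["call"].isin(["F", "M"])]
            concordance = float(
                np.mean([truth[r.sample_id] == r.call for r in called.itertuples()])
            )
            summary["sexing"] = {
                "n_called": int(len(called)),
                "concordance": concordance,
            }
        except Exception as exc:
            raise StageError("sexing", exc)
    else:
        summary["sexing"] = None

    summary = _round(summary)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary


def _same_partition(a: dict[str, int], b: dict[str, int] | None) -> bool:
    if b is None or set(a) != set(b):
        return False
    seen: dict[int, int] = {}
    for pop in a:
        if a[pop] in seen:
            if seen[a[pop]] != b[pop]:
                return False
        else:
            if b[pop] in seen.values():
                return False
            seen[a[pop]] = b[pop]
    return True


STAGE_SECTIONS = (
    "diversity", "mjn", "profiles", "fst", "amova", "lineages", "sexing",
    "identical_pairs",
)


def make_report(summary: dict) -> str:
    """Human-readable digest of a run summary."""
    lines = ["# Matrilineal transect analysis report", ""]
    missing = [s for s in STAGE_SECTIONS if s not in summary]
    if missing:
        lines.append("Incomplete bundle; missing stages: " + ", ".join(missing))

    def sec(title: str) -> None:
        lines.append(f"## {title}")

    if "identical_pairs" in summary:
        sec("Duplicate individuals")
        pairs = summary["identical_pairs"]
        lines.append(
            f"{len(pairs)} identical pair(s): "
            + "; ".join("-".join(p) for p in pairs)
        )
    if "diversity" in summary:
        sec("Diversity")
        d = summary["diversity"]["deduplicated"]
        lines.append(
            f"HD = {d['HD']['value']:.4f} +/- {d['HD']['sd']:.4f} (n={d['HD']['n']}); "
            f"pi = {d['PI']['value']:.6f} +/- {d['PI']['sd']:.6f}"
        )
    if "mjn" in summary:
        sec("Median-joining network")
        m = summary["mjn"]
        lines.append(
            f"{m['n_observed']} observed haplotype nodes, {m['n_median']} median "
            f"nodes, {m['n_edges']} edges"
        )
    if "profiles" in summary:
        sec("Haplogroup profiles")
        p = summary["profiles"]
        lines.append(
            f"scheme {p['scheme']}; PC1+PC2 variance "
            f"{p['pca_variance_pc1_pc2_pct']:.1f}%; top clade support "
            f"{p['top_clade_support']}"
        )
    if "fst" in summary:
        sec("Genetic distances")
        f = summary["fst"]
        lines.append(
            f"focal population closest to {f['closest_to_focal']} "
            f"(Fst = {f['closest_fst']:.4f}); MDS stress {f['mds_stress']:.4g}"
        )
    if "amova" in summary:
        sec("AMOVA grouping search")
        a = summary["amova"]
        lines.append(
            f"{a['n_candidates']} candidates; best Fct = {a['best_fct']:.4f}, "
            f"Fsc = {a['best_fsc']:.4f}; planted partition recovered: "
            f"{a['planted_partition_recovered']}"
        )
    if "lineages" in summary:
        sec("Lineage attribution")
        pct = summary["lineages"]["percentages"]
        lines.append(
            "; ".join(f"{k}: {v:.1f}%" for k, v in sorted(pct.items()))
            + f" (sum {sum(pct.values()):.1f}%)"
        )
        lines.append(
            f"inherited haplotypes in >=1 LN/EBA population: "
            f"{summary['lineages']['lnba_in_any_pct']:.1f}%; in all of the triple: "
            f"{summary['lineages']['lnba_in_all_triple_pct']:.1f}%; absent: "
            f"{summary['lineages']['lnba_absent_pct']:.1f}%"
        )
    sec("Sexing")
    if summary.get("sexing"):
        s = summary["sexing"]
        lines.append(
            f"{s['n_called']} confident calls; concordance with truth "
            f"{100 * s['concordance']:.1f}%"
        )
    else:
        lines.append("skipped")
    return "\n".join(lines) + "\n"
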