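"""Model-corrected sequence distances, pairwise Phi-st, permutation tests,
Slatkin's linearization and non-metric MDS.

Distances: p-distance, JC69, K2P and TN93, each with an optional gamma
rate-heterogeneity correction (shape ``alpha``).  Missing data (``N``, and
gaps under the default gap mode) are removed pairwise; under
``fifth_state`` the gap character is scored as an ordinary fifth state,
which is only meaningful for the uncorrected p-distance.

Phi-st between two populations is obtained from a two-level analysis of
molecular variance on squared model distances with unequal-sample-size
coefficients; its permutation p-value reshuffles individuals between the
populations keeping sizes fixed, with the (1+x)/(N+1) estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.manifold import MDS

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Observed divergence exceeds the model's invertible domain."""


@dataclass(frozen=True)
class SubstitutionModel:
    model: str = "TN93"  # P_DIST | JC69 | K2P | TN93
    gamma_alpha: float | None = None
    gap_mode: str = "missing"  # missing | fifth_state
    base_freqs: tuple[float, float, float, float] | None = None  # A, C, G, T

    def __post_init__(self) -> None:
        if self.model not in ("P_DIST", "JC69", "K2P", "TN93"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be positive")
        if self.gap_mode not in ("missing", "fifth_state"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")
        if self.gap_mode == "fifth_state" and self.model != "P_DIST":
            raise ValueError("fifth_state gaps are only supported with P_DIST")


def _ln_term(w: float, alpha: float | None) -> float:
    """-ln(w), or its gamma-corrected counterpart alpha*(w^(-1/alpha) - 1)."""
    if w <= 0:
        raise SaturationError("distance saturated (log argument <= 0)")
    if alpha is None:
        return -math.log(w)
    return alpha * (w ** (-1.0 / alpha) - 1.0)


def pairwise_distance(a: str, b: str, model: SubstitutionModel) -> float:
    """Model-corrected distance between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    missing = {"N"} if model.gap_mode == "fifth_state" else {"N", "-"}
    pairs = [
        (x, y) for x, y in zip(a, b) if x not in missing and y not in missing
    ]
    L = len(pairs)
    if L == 0:
        raise ValueError("no comparable sites")
    mismatches = sum(1 for x, y in pairs if x != y)
    p = mismatches / L
    alpha = model.gamma_alpha

    if model.model == "P_DIST":
        return p
    if model.model == "JC69":
        return 0.75 * _ln_term(1.0 - 4.0 * p / 3.0, alpha)

    # transition/transversion split
    P1 = sum(1 for x, y in pairs if x != y and {x, y} <= PURINES) / L
    P2 = sum(1 for x, y in pairs if x != y and {x, y} <= PYRIMIDINES) / L
    Q = p - P1 - P2

    if model.model == "K2P":
        P = P1 + P2
        return 0.5 * _ln_term(1.0 - 2.0 * P - Q, alpha) + 0.25 * _ln_term(
            1.0 - 2.0 * Q, alpha
        )

    # TN93
    if model.base_freqs is not None:
        fA, fC, fG, fT = model.base_freqs
    else:
        counts = {c: 0 for c in "ACGT"}
        for x, y in pairs:
            counts[x] += 1
            counts[y] += 1
        tot = sum(counts.values())
        fA, fC, fG, fT = (counts[c] / tot for c in "ACGT")
    gR, gY = fA + fG, fC + fT
    if min(fA, fC, fG, fT) <= 0:
        raise SaturationError("TN93 undefined with a zero base frequency")
    k1 = 2.0 * fA * fG / gR
    k2 = 2.0 * fC * fT / gY
    k3 = 2.0 * (gR * gY - fA * fG * gY / gR - fC * fT * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    return (
        k1 * _ln_term(w1, alpha)
        + k2 * _ln_term(w2, alpha)
        + k3 * _ln_term(w3, alpha)
    )


def distance_matrix(seqs: Sequence[str], model: SubstitutionModel) -> np.ndarray:
    """Square symmetric matrix of pairwise model distances."""
    n = len(seqs)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        D[i, j] = D[j, i] = pairwise_distance(seqs[i], seqs[j], model)
    return D


# ---------------------------------------------------------------------------
# Phi-st from two-level molecular variance
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    pair: tuple[str, str]
    fst: float       # truncated at 0 for reporting
    fst_raw: float
    slatkin_d: float | None = None
    p_value: float | None = None
    n_perm: int = 0


def _ss(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squares of a set: (1/n) * sum over unordered pairs of d^2."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum()) / (2.0 * len(idx))


def _phist_from_d2(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    """Phi-st from squared distances for >= 2 populations, unequal n."""
    sizes = np.array([len(g) for g in groups])
    N = int(sizes.sum())
    P = len(groups)
    all_idx = np.concatenate(groups)
    ss_total = _ss(d2, all_idx)
    ss_within = sum(_ss(d2, g) for g in groups)
    ss_among = ss_total - ss_within
    df_within = N - P
    df_among = P - 1
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among
    n_c = (N - float(np.sum(sizes**2)) / N) / df_among
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_c
    total = sigma_a + sigma_w
    if total == 0:
        return 0.0
    return sigma_a / total


def pairwise_fst(
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    model: SubstitutionModel,
    names: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Phi-st between two populations of window sequences (no p-value)."""
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs >= 2 sequences")
    seqs = list(pop_a) + list(pop_b)
    d2 = distance_matrix(seqs, model) ** 2
    groups = [np.arange(len(pop_a)), np.arange(len(pop_a), len(seqs))]
    raw = _phist_from_d2(d2, groups)
    fst = max(raw, 0.0)
    return FstResult(pair=names, fst=fst, fst_raw=raw, slatkin_d=slatkin_linearize(fst))


def fst_permutation_p(
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    model: SubstitutionModel,
    n_perm: int,
    seed: int | None = None,
) -> float:
    """Permutation p for Phi-st, shuffling individuals between populations.

    p = (1 + #{permuted Phi-st >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seqs = list(pop_a) + list(pop_b)
    na = len(pop_a)
    d2 = distance_matrix(seqs, model) ** 2
    idx = np.arange(len(seqs))
    observed = _phist_from_d2(d2, [idx[:na], idx[na:]])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        if _phist_from_d2(d2, [perm[:na], perm[na:]]) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def slatkin_linearize(fst: float) -> float:
    """Slatkin's linearized distance d = Fst / (1 - Fst)."""
    if fst >= 1.0:
        return math.inf
    return fst / (1.0 - fst)


def fst_matrix(
    populations: dict[str, Sequence[str]],
    model: SubstitutionModel,
    n_perm: int = 0,
    seed: int | None = None,
):
    """All pairwise Phi-st (and optional permutation p) as DataFrames."""
    import pandas as pd

    names = list(populations)
    k = len(names)
    fst = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    for i, j in combinations(range(k), 2):
        res = pairwise_fst(
            populations[names[i]], populations[names[j]], model, (names[i], names[j])
        )
        fst[i, j] = fst[j, i] = res.fst
        if n_perm > 0:
            p = fst_permutation_p(
                populations[names[i]], populations[names[j]], model, n_perm,
                seed=None if seed is None else seed + 1000 * i + j,
            )
            pval[i, j] = pval[j, i] = p
    fst_df = pd.DataFrame(fst, index=names, columns=names)
    slatkin = fst_df.map(slatkin_linearize)
    p_df = pd.DataFrame(pval, index=names, columns=names)
    return fst_df, slatkin, p_df


# ---------------------------------------------------------------------------
# Non-metric MDS
# ---------------------------------------------------------------------------

@dataclass
class MdsEmbedding:
    coordinates: np.ndarray  # populations x k
    stress: float            # Kruskal stress-1
    seed: int | None
    n_starts: int
    labels: list[str] | None = None


def nmds(
    dist_matrix: np.ndarray,
    k: int = 2,
    n_starts: int = 4,
    seed: int | None = 0,
    labels: Sequence[str] | None = None,
    max_iter: int = 1000,
) -> MdsEmbedding:
    """Non-metric MDS minimizing Kruskal stress-1.

    The best configuration over a classical-scaling start plus
    ``n_starts - 1`` random starts is retained; results are deterministic
    under a fixed seed.
    """
    D = np.asarray(dist_matrix, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("negative distances (truncate upstream)")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if np.allclose(D, 0):
        # all populations coincide; the embedding is a single point
        return MdsEmbedding(
            coordinates=np.zeros((D.shape[0], k)), stress=0.0, seed=seed,
            n_starts=n_starts, labels=list(labels) if labels is not None else None,
        )

    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    # one classical-scaling start, then random restarts
    inits = ["classical_mds"] + ["random"] * (n_starts - 1)
    for init in inits:
        mds = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=1e-12,
            normalized_stress=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        coords = mds.fit_transform(D)
        if mds.stress_ < best_stress:
            best_stress, best_coords = float(mds.stress_), coords
    return MdsEmbedding(
        coordinates=best_coords,
        stress=best_stress,
        seed=seed,
        n_starts=n_starts,
        labels=list(labels) if labels is not None else None,
    )
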