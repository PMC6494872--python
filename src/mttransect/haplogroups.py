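"""Haplogroup binning schemes, frequency profiles, Ward clustering and PCA.

Three coarse binning schemes are provided, matching the published frequency
analyses:

* ``CEPT23`` — 23 bins used for the Central European transect.
* ``EPT24`` — 24 bins used for the pan-European ancient transect, with an
  "Asian" macro-bin (A/C/D/F/G/Z lineages) and a merged "V/HV0" bin.
* ``MODERN23`` — 23 bins used against extant worldwide populations, adding
  an "African" macro-bin (L lineages).

Binning is longest-matching-prefix over phylotree-style labels; anything
unmatched falls into the terminal "other" bin, so binning is a total
function of the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import TransectDataset


@dataclass(frozen=True)
class BinningScheme:
    name: str
    bins: tuple[str, ...]
    #: prefix -> bin; longest matching prefix wins
    rules: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if "other" not in self.bins:
            raise ValueError("scheme must contain a terminal 'other' bin")
        for _, b in self.rules:
            if b not in self.bins:
                raise ValueError(f"rule targets unknown bin {b!r}")


def _scheme(name: str, spec: list[tuple[str, list[str]]]) -> BinningScheme:
    bins = tuple(b for b, _ in spec) + ("other",)
    rules = tuple((p, b) for b, prefixes in spec for p in prefixes)
    return BinningScheme(name=name, bins=bins, rules=rules)


CEPT23 = _scheme(
    "CEPT23",
    [
        ("H", ["H"]), ("H5", ["H5"]), ("HV", ["HV"]), ("HV0", ["HV0"]),
        ("V", ["V"]), ("I", ["I"]), ("J", ["J"]), ("K", ["K"]),
        ("N", ["N"]), ("N1a", ["N1a"]), ("R", ["R"]), ("T1", ["T1"]),
        ("T2", ["T2"]), ("U", ["U"]), ("U2", ["U2"]), ("U3", ["U3"]),
        ("U4", ["U4"]), ("U5a", ["U5a"]), ("U5b", ["U5b"]), ("U8", ["U8"]),
        ("W", ["W"]), ("X", ["X"]),
    ],
)

EPT24 = _scheme(
    "EPT24",
    [
        ("Asian", ["A", "C", "D", "F", "G", "Z"]),
        ("N", ["N"]), ("N1a", ["N1a"]), ("I", ["I"]), ("J", ["J"]),
        ("W", ["W"]), ("X", ["X"]), ("R", ["R"]), ("HV", ["HV"]),
        ("V/HV0", ["V", "HV0"]), ("H", ["H"]), ("H5", ["H5"]),
        ("T", ["T"]), ("T1", ["T1"]), ("T2", ["T2"]),
        ("U", ["U"]), ("U2", ["U2"]), ("U3", ["U3"]), ("U4", ["U4"]),
        ("U5a", ["U5a"]), ("U5b", ["U5b"]), ("U8", ["U8"]), ("K", ["K"]),
    ],
)

MODERN23 = _scheme(
    "MODERN23",
    [
        ("Asian", ["A", "C", "D", "F", "G", "Z"]),
        ("African", ["L"]),
        ("N1a", ["N1a"]), ("I", ["I"]), ("I1", ["I1"]), ("W", ["W"]),
        ("X", ["X"]), ("HV", ["HV"]), ("V/HV0", ["V", "HV0"]),
        ("H", ["H"]), ("H5", ["H5"]), ("T1", ["T1"]), ("T2", ["T2"]),
        ("J", ["J"]), ("U", ["U"]), ("U2", ["U2"]), ("U3", ["U3"]),
        ("U4", ["U4"]), ("U5a", ["U5a"]), ("U5b", ["U5b"]), ("U8", ["U8"]),
        ("K", ["K"]),
    ],
)

SCHEMES: dict[str, BinningScheme] = {s.name: s for s in (CEPT23, EPT24, MODERN23)}


def bin_haplogroup(label: str, scheme: BinningScheme) -> str:
    """Coarse bin of a phylotree-style label; unmatched labels go to "other"."""
    best: str | None = None
    best_len = -1
    for prefix, b in scheme.rules:
        if label.startswith(prefix) and len(prefix) > best_len:
            best, best_len = b, len(prefix)
    return best if best is not None else "other"


@dataclass
class HaplogroupProfile:
    population: str
    scheme: str
    frequencies: np.ndarray  # over scheme bins, sums to 1
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("profile requires n >= 1")
        total = float(np.sum(self.frequencies))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")


def profile(
    dataset: TransectDataset, population: str, scheme: BinningScheme
) -> HaplogroupProfile:
    members = dataset.members(population)
    if not members:
        raise ValueError(f"population {population!r} is empty")
    counts = np.zeros(len(scheme.bins))
    index = {b: i for i, b in enumerate(scheme.bins)}
    for ind in members:
        if not ind.haplogroup_label:
            raise ValueError(f"sample {ind.sample_id!r} has no haplogroup label")
        counts[index[bin_haplogroup(ind.haplogroup_label, scheme)]] += 1
    return HaplogroupProfile(
        population=population,
        scheme=scheme.name,
        frequencies=counts / counts.sum(),
        n=len(members),
    )


def profiles_frame(profiles: list[HaplogroupProfile]):
    """Population x bin frequency table as a DataFrame."""
    import pandas as pd

    scheme = SCHEMES[profiles[0].scheme]
    return pd.DataFrame(
        [p.frequencies for p in profiles],
        index=[p.population for p in profiles],
        columns=list(scheme.bins),
    )


# ---------------------------------------------------------------------------
# Ward clustering with bootstrap clade support
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree over populations.

    ``linkage_matrix`` is in scipy format; ``supports`` maps each internal
    node's leaf set to its bootstrap support in percent (None when no
    bootstrap was run).
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    supports: dict[frozenset, float | None] = field(default_factory=dict)

    def clades(self) -> list[frozenset]:
        """Leaf-label sets of all internal nodes, smallest first."""
        n = len(self.labels)
        sets: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for k, (a, b, _h, _c) in enumerate(self.linkage_matrix):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        n = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        sets: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (a, b, h, _c) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            merged = sets[a] | sets[b]
            support = self.supports.get(merged)
            tag = "" if support is None else f"{support:g}"
            nodes[n + k] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g}){tag}"
            heights[n + k] = h
            sets[n + k] = merged
        return nodes[n + len(self.linkage_matrix) - 1] + ";"


def _ward_linkage(matrix: np.ndarray, metric: str) -> np.ndarray:
    # Euclidean Ward is exact; for other metrics the Lance-Williams Ward
    # update is applied to the given dissimilarities (a documented heuristic).
    if metric == "euclidean":
        return linkage(matrix, method="ward")
    return linkage(pdist(matrix, metric=metric), method="ward")


def ward_cluster(
    profiles: list[HaplogroupProfile],
    metric: str = "euclidean",
    n_boot: int = 0,
    seed: int | None = None,
) -> Dendrogram:
    """Ward clustering of frequency profiles with bootstrap clade support.

    Support for an internal node is the percentage of bootstrap replicates
    (individuals resampled with replacement within each population, profiles
    recomputed, tree rebuilt) in which the node's leaf set recurs as a clade.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    schemes = {p.scheme for p in profiles}
    if len(schemes) != 1:
        raise ValueError(f"profiles on mismatched schemes {sorted(schemes)}")
    if metric not in ("euclidean", "cityblock", "manhattan"):
        raise ValueError(f"unsupported metric {metric!r}")
    if metric == "manhattan":
        metric = "cityblock"

    labels = [p.population for p in profiles]
    X = np.array([p.frequencies for p in profiles])
    Z = _ward_linkage(X, metric)
    dendro = Dendrogram(labels=labels, linkage_matrix=Z)
    clades = dendro.clades()
    if n_boot <= 0:
        dendro.supports = {c: None for c in clades}
        return dendro

    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in clades}
    ns = np.array([p.n for p in profiles])
    for _ in range(n_boot):
        # Resampling individuals with replacement within a population is a
        # multinomial redraw of its bin counts.
        Xb = np.array(
            [rng.multinomial(n, p.frequencies) / n for n, p in zip(ns, profiles)]
        )
        Zb = _ward_linkage(Xb, metric)
        boot = set(Dendrogram(labels=labels, linkage_matrix=Zb).clades())
        for c in clades:
            if c in boot:
                hits[c] += 1
    dendro.supports = {c: 100.0 * hits[c] / n_boot for c in clades}
    return dendro


# ---------------------------------------------------------------------------
# PCA of haplogroup frequencies
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray            # populations x components
    loadings: np.ndarray          # bins x components
    variance_explained: np.ndarray  # fraction per component
    labels: list[str]
    bins: list[str]


def pca(profiles: list[HaplogroupProfile]) -> PcaResult:
    """Centered (unscaled) PCA on the population x bin frequency matrix.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are deterministic.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles")
    X = np.array([p.frequencies for p in profiles])
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("degenerate input: all profiles identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = int(np.sum(s > 1e-12 * s[0]))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    n = X.shape[0]
    var = s**2 / (n - 1)
    total = np.sum(Xc**2) / (n - 1)
    scheme = SCHEMES[profiles[0].scheme]
    return PcaResult(
        scores=U * s,
        loadings=Vt.T,
        variance_explained=var / total,
        labels=[p.population for p in profiles],
        bins=list(scheme.bins),
    )
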