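"""Shared fixtures: the demo founder-graph transect and sequence builders."""

from __future__ import annotations

import pytest

from mttransect.io import Era, GENOME_LENGTH, Individual, MtSequence, TransectDataset
from mttransect.simulate import mas_like_transect, synthetic_backbone

BACKBONE = synthetic_backbone()


def variant(pos: int) -> str:
    """A base guaranteed to differ from the backbone at a 1-based position."""
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[BACKBONE[pos - 1]]


def seq_with(sample_id: str, sites: dict[int, str]) -> MtSequence:
    """Full-length sequence: the synthetic backbone with substitutions at
    1-based positions."""
    bases = list(BACKBONE)
    for pos, b in sites.items():
        bases[pos - 1] = b
    return MtSequence(sample_id, "".join(bases))


def toy_dataset(spec: dict[str, tuple[Era, dict[str, dict[int, str]]]]) -> TransectDataset:
    """Build a TransectDataset from {pop: (era, {sample_id: {pos: base}})}."""
    individuals = []
    populations = {}
    for pop, (era, members) in spec.items():
        populations[pop] = era
        for sid, sites in members.items():
            individuals.append(
                Individual(
                    sample_id=sid,
                    population=pop,
                    era=era,
                    haplogroup_label="H",
                    sequence=seq_with(sid, sites),
                )
            )
    return TransectDataset(individuals, populations)


@pytest.fixture(scope="session")
def demo_transect():
    """The seeded demo transect with its ground-truth manifest."""
    return mas_like_transect(seed=1)


@pytest.fixture(scope="session")
def backbone():
    assert len(BACKBONE) == GENOME_LENGTH
    return BACKBONE
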