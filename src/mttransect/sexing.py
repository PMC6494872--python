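"""Genetic sex assignment from sex-chromosome read counts (the Ry statistic).

Ry = nY / (nX + nY) over reads mapped to the sex chromosomes (mapping
quality filtering happens upstream; counts are inputs).  Samples with
fewer than 3,000 sex-chromosome reads are not called.  By default the
95% interval Ry +/- 1.96*SE must lie entirely above the male threshold
(0.075) or below the female threshold (0.016); overlapping calls are
reported as ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class SexReadCounts:
    sample_id: str
    n_y: int
    n_x: int

    def __post_init__(self) -> None:
        if self.n_y < 0 or self.n_x < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class SexingThresholds:
    min_reads: int = 3000
    female_max: float = 0.016
    male_min: float = 0.075
    z: float = 1.96
    use_interval: bool = True  # False: gate on the point estimate


@dataclass
class SexCall:
    sample_id: str
    ry: float | None
    se: float | None
    call: str  # F | M | undetermined-low-coverage | undetermined-ambiguous


def assign_sex(
    counts: SexReadCounts, thresholds: SexingThresholds = SexingThresholds()
) -> SexCall:
    total = counts.n_x + counts.n_y
    if total < thresholds.min_reads:
        return SexCall(counts.sample_id, None, None, "undetermined-low-coverage")
    ry = counts.n_y / total
    se = math.sqrt(ry * (1.0 - ry) / total)
    if thresholds.use_interval:
        lo, hi = ry - thresholds.z * se, ry + thresholds.z * se
    else:
        lo = hi = ry
    if lo > thresholds.male_min:
        call = "M"
    elif hi < thresholds.female_max:
        call = "F"
    else:
        call = "undetermined-ambiguous"
    return SexCall(counts.sample_id, ry, se, call)


def read_sex_counts(path: str | Path) -> list[SexReadCounts]:
    """TSV with columns sample_id, n_X, n_Y."""
    df = pd.read_csv(path, sep="\t")
    return [
        SexReadCounts(sample_id=str(r.sample_id), n_y=int(r.n_Y), n_x=int(r.n_X))
        for r in df.itertuples(index=False)
    ]


def sex_table(
    counts: list[SexReadCounts], thresholds: SexingThresholds = SexingThresholds()
) -> pd.DataFrame:
    calls = [assign_sex(c, thresholds) for c in counts]
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "ry": [c.ry for c in calls],
            "se": [c.se for c in calls],
            "call": [c.call for c in calls],
        }
    )
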