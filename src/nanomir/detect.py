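"""Detection calling against the Low LOD and the group detection partition.

A probe is called detected in a sample when its *raw* count strictly exceeds
the Low LOD (detection is defined against raw background, since the LOD is
itself derived from raw negative-control counts). A probe counts as
detectable in a sample set when it is called in at least 15% of those
samples (ceil rule); the group partition classifies probes as exclusive to
either group or shared, as in a two-set Venn diagram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .qc import LodThresholds
from .rcc_io import CountMatrix

DEFAULT_PREVALENCE = 0.15


@dataclass
class DetectionCalls:
    """Boolean probes x samples detection matrix plus the LOD used."""

    calls: pd.DataFrame
    lod_used: LodThresholds
    prevalence_threshold: float = DEFAULT_PREVALENCE

    def __post_init__(self):
        if not 0 < self.prevalence_threshold <= 1:
            raise ValueError("prevalence threshold must be in (0, 1]")


@dataclass
class DetectionPartition:
    """Venn partition of detected probes between two groups."""

    exclusive_a: list[str]
    exclusive_b: list[str]
    shared: list[str]
    total_a: int = field(init=False)
    total_b: int = field(init=False)

    def __post_init__(self):
        sets = (set(self.exclusive_a), set(self.exclusive_b), set(self.shared))
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("partition sets must be pairwise disjoint")
        self.total_a = len(self.exclusive_a) + len(self.shared)
        self.total_b = len(self.exclusive_b) + len(self.shared)

    @property
    def total_detected(self) -> int:
        return len(self.exclusive_a) + len(self.exclusive_b) + len(self.shared)

    def to_dict(self) -> dict:
        return {
            "exclusive_a": list(self.exclusive_a),
            "exclusive_b": list(self.exclusive_b),
            "shared": list(self.shared),
            "total_a": self.total_a,
            "total_b": self.total_b,
        }


def call_detection(
    matrix: CountMatrix,
    lod: LodThresholds,
    prevalence_threshold: float = DEFAULT_PREVALENCE,
) -> DetectionCalls:
    """Boolean detection calls: raw count strictly above the Low LOD."""
    if matrix.stage != "raw":
        raise ValueError("detection is defined on raw counts")
    calls = matrix.counts > lod.low
    return DetectionCalls(
        calls=calls, lod_used=lod, prevalence_threshold=prevalence_threshold
    )


def _min_count(threshold: float, n: int) -> int:
    # smallest integer k with k >= threshold*n; guard binary-float excess
    # (0.15*20 == 3.0000000000000004 must still give 3)
    return max(1, math.ceil(threshold * n - 1e-9))


def prevalence_filter(
    calls: DetectionCalls,
    within: Sequence[str] | None = None,
    rule: str = "ceil",
) -> list[str]:
    """Probes detected in at least the threshold fraction of ``within`` samples.

    ``rule="ceil"`` keeps a probe when its detected-sample count is at least
    ceil(threshold * n); ``rule="fraction"`` compares the detected fraction
    with the threshold directly (identical except at non-integer boundaries).
    """
    samples = list(within) if within is not None else list(calls.calls.columns)
    if len(samples) == 0:
        raise ValueError("sample subset is empty")
    sub = calls.calls[samples]
    ndet = sub.sum(axis=1)
    if rule == "ceil":
        keep = ndet >= _min_count(calls.prevalence_threshold, len(samples))
    elif rule == "fraction":
        keep = (ndet / len(samples)) >= calls.prevalence_threshold
    else:
        raise ValueError(f"unknown prevalence rule {rule!r}")
    return list(sub.index[keep])


def detection_partition(
    calls: DetectionCalls,
    group_a: Sequence[str],
    group_b: Sequence[str],
    rule: str = "ceil",
) -> DetectionPartition:
    """Partition probes into exclusive-A / exclusive-B / shared detection sets.

    The prevalence filter is applied within each group separately.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    det_a = set(prevalence_filter(calls, within=group_a, rule=rule))
    det_b = set(prevalence_filter(calls, within=group_b, rule=rule))
    part = DetectionPartition(
        exclusive_a=sorted(det_a - det_b),
        exclusive_b=sorted(det_b - det_a),
        shared=sorted(det_a & det_b),
    )
    # conservation identity: every detected probe lands in exactly one set
    assert part.total_detected == len(det_a | det_b)
    return part
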