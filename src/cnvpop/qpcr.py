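"""Relative copy number from qPCR Ct values by the 2^-ddCt method.

ddCt = (Ct_target - Ct_reference)_test - (Ct_target - Ct_reference)_calibrator;
relative copy number = 2^-ddCt.  Replicate wells are aggregated to a mean
Ct before the quad is formed — the quad itself is explicit, never implied.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True)
class CtQuad:
    """The four cycle-threshold values entering one ddCt computation."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_calibrator: float
    ct_ref_calibrator: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_test",
            "ct_ref_test",
            "ct_target_calibrator",
            "ct_ref_calibrator",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


def delta_delta_ct(q: CtQuad) -> float:
    return (q.ct_target_test - q.ct_ref_test) - (
        q.ct_target_calibrator - q.ct_ref_calibrator
    )


def relative_copy_number(q: CtQuad) -> float:
    """2^-ddCt relative quantity (1.0 = same copy number as calibrator)."""
    return 2.0 ** (-delta_delta_ct(q))


def mean_ct(replicates: Iterable[float]) -> float:
    """Arithmetic mean Ct over replicate wells."""
    reps = list(replicates)
    if not reps:
        raise ValueError("no replicate Ct values")
    if not all(math.isfinite(r) for r in reps):
        raise ValueError("non-finite Ct value among replicates")
    return statistics.fmean(reps)


def read_ct_tsv(path: str) -> dict[tuple[str, str, str], float]:
    """Read (sample, target, role) -> mean Ct from a replicate-level TSV.

    Columns: sample, target, role (test|calibrator), ct.  Replicate rows
    of the same (sample, target, role) are averaged.
    """
    wells: dict[tuple[str, str, str], list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["sample"], row["target"], row["role"])
            wells.setdefault(key, []).append(float(row["ct"]))
    return {k: mean_ct(v) for k, v in wells.items()}


def write_relative_cn_tsv(path: str, results: dict[str, float]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "relative_cn"])
        for sample, rcn in sorted(results.items()):
            writer.writerow([sample, f"{rcn:.6g}"])
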