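"""Per-locus Weir–Cockerham FST and empirical outlier scans.

The estimator is the moment-based theta of Weir & Cockerham (1984) for a
biallelic locus observed in r populations.  With per-population diploid
sample size n_i, alt-allele frequency p_i and observed heterozygote
proportion h_i:

    n_bar = sum(n_i) / r
    n_c   = (sum(n_i) - sum(n_i^2)/sum(n_i)) / (r - 1)
    p_bar = sum(n_i p_i) / sum(n_i)
    s2    = sum(n_i (p_i - p_bar)^2) / ((r - 1) n_bar)
    h_bar = sum(n_i h_i) / sum(n_i)

    a = (n_bar/n_c) [ s2 - (1/(n_bar-1)) ( p_bar(1-p_bar)
                        - ((r-1)/r) s2 - h_bar/4 ) ]
    b = (n_bar/(n_bar-1)) [ p_bar(1-p_bar) - ((r-1)/r) s2
                        - ((2 n_bar - 1)/(4 n_bar)) h_bar ]
    c = h_bar / 2

    theta = a / (a + b + c)

a, b, c estimate the among-population, among-individual-within-population
and within-individual variance components.  theta is undefined when
a + b + c = 0 (a locus monomorphic across all populations) or when
n_bar = 1; negative estimates are reported as computed, not clamped,
so genome-wide means and medians keep the estimator's convention.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "FstComponents",
    "ScanResult",
    "wc_fst_locus",
    "wc_fst_dosages",
    "fst_scan",
    "ratio_of_sums_fst",
    "subsample_group",
    "write_scan_tsv",
]


@dataclass(frozen=True)
class FstComponents:
    """Variance components and theta for one locus between r populations."""

    locus_id: str
    n_i: tuple[int, ...]
    p_i: tuple[float, ...]
    h_i: tuple[float, ...]
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float
    a: float
    b: float
    c: float
    theta: Optional[float]  # None when undefined

    @property
    def r(self) -> int:
        return len(self.n_i)


def _group_stats(dosages: np.ndarray) -> tuple[int, float, float]:
    """(n, p, h) of one group: non-missing count, alt freq, het proportion."""
    ok = ~np.isnan(dosages)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("group has no non-missing genotypes")
    d = dosages[ok]
    p = float(d.sum()) / (2 * n)
    h = float((d == 1).sum()) / n
    return n, p, h


def wc_fst_locus(
    n_i: Sequence[int],
    p_i: Sequence[float],
    h_i: Sequence[float],
    locus_id: str = "",
) -> FstComponents:
    """Weir–Cockerham components from per-population summary statistics."""
    r = len(n_i)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = tuple(int(n) for n in n_i)
    p_i = tuple(float(p) for p in p_i)
    h_i = tuple(float(h) for h in h_i)
    n_sum = sum(n_i)
    n_bar = n_sum / r
    n_c = (n_sum - sum(n * n for n in n_i) / n_sum) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / n_sum
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / n_sum
    if n_bar <= 1 or n_c == 0:
        return FstComponents(
            locus_id, n_i, p_i, h_i, n_bar, n_c, p_bar, s2, h_bar,
            math.nan, math.nan, math.nan, None,
        )
    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else None
    return FstComponents(
        locus_id, n_i, p_i, h_i, n_bar, n_c, p_bar, s2, h_bar, a, b, c, theta
    )


def wc_fst_dosages(
    group1: Sequence[float], group2: Sequence[float], locus_id: str = ""
) -> FstComponents:
    """Two-group theta directly from diploid dosage vectors (NaN = missing)."""
    n1, p1, h1 = _group_stats(np.asarray(group1, dtype=float))
    n2, p2, h2 = _group_stats(np.asarray(group2, dtype=float))
    return wc_fst_locus((n1, n2), (p1, p2), (h1, h2), locus_id)


@dataclass
class ScanResult:
    """Genome-wide FST scan output."""

    components: list[FstComponents]
    table: pd.DataFrame  # per-locus rows, scan order (chrom, start)
    mean_theta: float
    median_theta: float
    tail_threshold: float
    outlier_ids: list[str]
    n_defined: int


def _tail_threshold(thetas: np.ndarray, tail: float) -> tuple[float, int]:
    """Nearest-rank rule: threshold = min of the top ceil(tail * L) values."""
    L = len(thetas)
    k = math.ceil(tail * L)
    top = np.sort(thetas)[::-1][:k]
    return float(top[-1]), k


def fst_scan(
    matrix: GenotypeMatrix,
    group_assignment: Mapping[str, str],
    tail: float = 0.05,
) -> ScanResult:
    """Per-locus two-group theta scan with empirical top-tail outliers.

    ``group_assignment`` maps sample_id to "group1"/"group2"; samples not
    mapped are excluded.  Undefined-theta loci (monomorphic across both
    groups) are excluded from summaries and from the tail count L; the
    threshold is the smallest theta among the top ``ceil(tail * L)``
    defined loci, and outliers are all loci with theta >= threshold.
    """
    g1 = [s for s in matrix.samples["sample_id"] if group_assignment.get(s) == "group1"]
    g2 = [s for s in matrix.samples["sample_id"] if group_assignment.get(s) == "group2"]
    if not g1 or not g2:
        raise ValueError("both groups must contain at least one sample")
    c1 = matrix.sample_columns(g1)
    c2 = matrix.sample_columns(g2)
    order = matrix.loci.sort_values(
        ["chrom", "start0", "end0"], kind="mergesort"
    ).index
    comps: list[FstComponents] = []
    rows = []
    for i in order:
        li = matrix.loci.loc[i]
        comp = wc_fst_dosages(
            matrix.dosage[i, c1], matrix.dosage[i, c2], locus_id=li["locus_id"]
        )
        comps.append(comp)
        rows.append(
            {
                "locus_id": li["locus_id"],
                "chrom": li["chrom"],
                "start1": li["start0"] + 1,
                "end1": li["end0"],
                "svtype": li["svtype"],
                "n1": comp.n_i[0],
                "n2": comp.n_i[1],
                "p1": comp.p_i[0],
                "p2": comp.p_i[1],
                "a": comp.a,
                "b": comp.b,
                "c": comp.c,
                "theta": math.nan if comp.theta is None else comp.theta,
            }
        )
    table = pd.DataFrame(rows)
    defined = table["theta"].dropna().to_numpy()
    if defined.size == 0:
        raise ValueError("no locus with defined theta")
    threshold, _ = _tail_threshold(defined, tail)
    table["outlier"] = (table["theta"] >= threshold).fillna(False)
    outliers = list(table.loc[table["outlier"], "locus_id"])
    return ScanResult(
        components=comps,
        table=table,
        mean_theta=float(defined.mean()),
        median_theta=float(np.median(defined)),
        tail_threshold=threshold,
        outlier_ids=outliers,
        n_defined=int(defined.size),
    )


def ratio_of_sums_fst(components: Sequence[FstComponents]) -> float:
    """Multi-locus estimator sum(a) / sum(a+b+c) over defined-component loci."""
    num = sum(c.a for c in components if not math.isnan(c.a))
    den = sum(c.a + c.b + c.c for c in components if not math.isnan(c.a))
    return num / den


def subsample_group(
    samples: Sequence[str],
    populations: Mapping[str, str],
    keep: Optional[Sequence[str]] = None,
    per_population: Optional[int] = None,
    seed: int = 0,
) -> list[str]:
    """Deterministic sample subsetting.

    Either an explicit ``keep`` list (order preserved, unknown samples are
    an error) or ``per_population`` random draws per population under a
    fixed seed.  With neither, returns all samples.
    """
    if keep is not None:
        unknown = [s for s in keep if s not in set(samples)]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        return list(keep)
    if per_population is None:
        return list(samples)
    rng = np.random.default_rng(seed)
    out: list[str] = []
    pops: dict[str, list[str]] = {}
    for s in samples:
        pops.setdefault(populations[s], []).append(s)
    for pop in sorted(pops):
        members = sorted(pops[pop])
        k = min(per_population, len(members))
        idx = rng.choice(len(members), size=k, replace=False)
        out.extend(members[i] for i in sorted(idx))
    return out


def write_scan_tsv(path: str, result: ScanResult) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["locus_id", "chrom", "start1", "end1", "svtype", "n1", "n2",
             "p1", "p2", "a", "b", "c", "theta", "outlier_flag"]
        )
        for row in result.table.itertuples(index=False):
            writer.writerow(
                [row.locus_id, row.chrom, row.start1, row.end1, row.svtype,
                 row.n1, row.n2, f"{row.p1:.6g}", f"{row.p2:.6g}",
                 f"{row.a:.6g}", f"{row.b:.6g}", f"{row.c:.6g}",
                 "NA" if math.isnan(row.theta) else f"{row.theta:.6g}",
                 int(row.outlier)]
            )
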