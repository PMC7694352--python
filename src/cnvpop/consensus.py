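"""Two-caller consensus CNVs, CNVR construction, and read-depth unification.

The quality-control chain mirrors a three-step multi-caller design:

1. Per sample, a split-read call and a paired-end call that share a
   chromosome and SV type and reciprocally overlap by at least 50% of the
   smaller call are collapsed into one consensus CNV whose coordinates are
   the overlapped sequence.
2. Consensus CNVs are merged across individuals into CNVRs whenever they
   share at least one base; CNVRs supported by a single CNV are discarded.
   Merging runs both within each population and over the whole cohort
   ("meta" level).
3. CNVRs are kept only when confirmed by an independent read-depth CNVR
   track (>= 50% of the shorter region shared); regions supported by a
   single approach are removed.

CNVRs containing only deletions are "deletion" CNVRs, only duplications
"duplication", and mixed membership "complex".
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .callsets import CnvCall, RdCnvr
from .intervals import (
    GenomicInterval,
    cluster_by_overlap,
    overlap_fraction,
    overlap_length,
    union_length,
)

logger = logging.getLogger(__name__)

APPROACH_PE_SR = "pairedend_splitread"
APPROACH_RD = "read_depth"


@dataclass(frozen=True)
class ConsensusCnv:
    """A per-sample CNV supported by both callers; interval = the overlap."""

    sample_id: str
    interval: GenomicInterval
    svtype: str
    source_pair: tuple[CnvCall, CnvCall]  # (delly-style, pindel-style)


@dataclass(frozen=True)
class Cnvr:
    """A merged copy-number-variable region."""

    interval: GenomicInterval  # envelope
    members: tuple[ConsensusCnv, ...]
    approaches: frozenset[str]
    cnvr_class: str  # deletion | duplication | complex
    level: str  # population | meta
    population: Optional[str] = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def sample_ids(self) -> set[str]:
        return {m.sample_id for m in self.members}


def classify_cnvr(member_svtypes: Sequence[str]) -> str:
    """deletion / duplication / complex from the member SV types."""
    types = set(member_svtypes)
    if not types:
        raise ValueError("cannot classify a CNVR with no members")
    if types == {"DEL"}:
        return "deletion"
    if types == {"DUP"}:
        return "duplication"
    return "complex"


def intersect_callsets(
    delly: Sequence[CnvCall],
    pindel: Sequence[CnvCall],
    min_frac: float = 0.5,
    denominator: str = "smaller",
) -> list[ConsensusCnv]:
    """One sample's two-caller consensus.

    Candidate pairs share chromosome and SV type and overlap by
    ``>= min_frac`` of the ``denominator`` call length (default: the
    smaller call).  Matching is one-to-one: pairs are accepted greedily by
    decreasing overlap length, ties broken by leftmost coordinates, and a
    call joins at most one consensus.  The consensus interval is the
    intersection of the pair.
    """
    samples = {c.sample_id for c in delly} | {c.sample_id for c in pindel}
    if len(samples) > 1:
        raise ValueError(f"intersect_callsets is per-sample; got {sorted(samples)}")
    candidates = []
    for i, d in enumerate(delly):
        for j, p in enumerate(pindel):
            if d.svtype != p.svtype or d.interval.chrom != p.interval.chrom:
                continue
            ov = overlap_length(d.interval, p.interval)
            if ov <= 0:
                continue
            if overlap_fraction(d.interval, p.interval, denominator) >= min_frac:
                candidates.append((ov, d.interval, p.interval, i, j))
    # best overlap first; ties resolved toward leftmost partners
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_d: set[int] = set()
    used_p: set[int] = set()
    out: list[ConsensusCnv] = []
    for ov, div, piv, i, j in candidates:
        if i in used_d or j in used_p:
            continue
        used_d.add(i)
        used_p.add(j)
        inter = GenomicInterval(
            div.chrom, max(div.start, piv.start), min(div.end, piv.end)
        )
        out.append(
            ConsensusCnv(
                sample_id=delly[i].sample_id,
                interval=inter,
                svtype=delly[i].svtype,
                source_pair=(delly[i], pindel[j]),
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return out


def build_cnvrs(
    consensus: Sequence[ConsensusCnv],
    populations: Mapping[str, str],
    level: str = "meta",
) -> list[Cnvr]:
    """Merge consensus CNVs (>= 1 bp shared) into CNVRs; drop singletons.

    ``level="population"`` merges within each population separately;
    ``level="meta"`` merges over all samples.  Merging ignores SV type so
    mixed clusters become "complex" CNVRs.
    """
    if level not in ("population", "meta"):
        raise ValueError(f"unknown level {level!r}")
    unmapped = sorted({c.sample_id for c in consensus} - set(populations))
    if unmapped:
        raise ValueError(f"samples without population label: {unmapped}")
    if level == "meta":
        groups = {None: list(consensus)}
    else:
        groups = {}
        for c in consensus:
            groups.setdefault(populations[c.sample_id], []).append(c)
    out: list[Cnvr] = []
    for pop in sorted(groups, key=lambda p: (p is not None, p)):
        cnvs = groups[pop]
        by_interval: dict[GenomicInterval, list[ConsensusCnv]] = {}
        for c in cnvs:
            by_interval.setdefault(c.interval, []).append(c)
        for cl in cluster_by_overlap(list(by_interval), min_overlap_bp=1):
            members = tuple(
                m
                for iv in cl.members
                for m in sorted(by_interval[iv], key=lambda c: c.sample_id)
            )
            if len(members) < 2:  # discard CNVRs with a single CNV
                continue
            out.append(
                Cnvr(
                    interval=cl.envelope,
                    members=members,
                    approaches=frozenset({APPROACH_PE_SR}),
                    cnvr_class=classify_cnvr([m.svtype for m in members]),
                    level=level,
                    population=pop,
                )
            )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    logger.info("build_cnvrs(level=%s): %d CNVRs from %d consensus CNVs",
                level, len(out), len(consensus))
    return out


def unify_with_read_depth(
    track_a: Sequence[Cnvr],
    track_rd: Sequence[RdCnvr],
    min_frac_shortest: float = 0.5,
) -> list[Cnvr]:
    """Keep CNVRs confirmed by the read-depth track; drop single-approach regions.

    A CNVR survives iff it overlaps at least one read-depth region by
    >= ``min_frac_shortest`` of the shorter of the two.  The unified
    envelope is the union span of the CNVR and every qualifying read-depth
    region; surviving CNVRs carry both approaches.  Read-depth regions
    with no qualifying partner contribute nothing to the output.
    """
    out: list[Cnvr] = []
    for r in track_a:
        partners = [
            rd.interval
            for rd in track_rd
            if overlap_length(r.interval, rd.interval) > 0
            and overlap_fraction(r.interval, rd.interval, "shortest")
            >= min_frac_shortest
        ]
        if not partners:
            continue
        start = min([r.interval.start] + [p.start for p in partners])
        end = max([r.interval.end] + [p.end for p in partners])
        out.append(
            Cnvr(
                interval=GenomicInterval(r.interval.chrom, start, end),
                members=r.members,
                approaches=frozenset({APPROACH_PE_SR, APPROACH_RD}),
                cnvr_class=r.cnvr_class,
                level=r.level,
                population=r.population,
            )
        )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    logger.info("unify_with_read_depth: retained %d/%d CNVRs", len(out), len(track_a))
    return out


@dataclass
class Summary:
    """Cohort summary of CNVRs or raw calls."""

    n_total: int
    total_length_bp: int
    union_span_bp: int
    coverage_percent: float
    mean_size_bp: float
    median_size_bp: float
    counts_by_chrom: dict[str, int] = field(default_factory=dict)
    counts_by_class: dict[str, int] = field(default_factory=dict)
    counts_by_sample: dict[str, int] = field(default_factory=dict)
    span_by_sample: dict[str, int] = field(default_factory=dict)


def summarize(
    items: Sequence[Union[Cnvr, CnvCall, ConsensusCnv]], genome_length_bp: int
) -> Summary:
    """Counts, size statistics, and genome coverage of CNVRs or calls.

    Coverage is ``100 * union-of-spans / genome_length_bp`` — overlapping
    items are not double-counted.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    intervals = [it.interval for it in items]
    lengths = [iv.length for iv in intervals]
    counts_by_chrom: dict[str, int] = {}
    for iv in intervals:
        counts_by_chrom[iv.chrom] = counts_by_chrom.get(iv.chrom, 0) + 1
    counts_by_class: dict[str, int] = {}
    counts_by_sample: dict[str, int] = {}
    span_by_sample: dict[str, int] = {}
    for it in items:
        if isinstance(it, Cnvr):
            counts_by_class[it.cnvr_class] = counts_by_class.get(it.cnvr_class, 0) + 1
        else:
            sid = it.sample_id
            counts_by_sample[sid] = counts_by_sample.get(sid, 0) + 1
            span_by_sample[sid] = span_by_sample.get(sid, 0) + it.interval.length
    union_bp = union_length(intervals) if intervals else 0
    return Summary(
        n_total=len(items),
        total_length_bp=sum(lengths),
        union_span_bp=union_bp,
        coverage_percent=100.0 * union_bp / genome_length_bp,
        mean_size_bp=statistics.fmean(lengths) if lengths else 0.0,
        median_size_bp=statistics.median(lengths) if lengths else 0.0,
        counts_by_chrom=dict(sorted(counts_by_chrom.items())),
        counts_by_class=dict(sorted(counts_by_class.items())),
        counts_by_sample=dict(sorted(counts_by_sample.items())),
        span_by_sample=dict(sorted(span_by_sample.items())),
    )


CNVR_TSV_COLUMNS = [
    "chrom",
    "start1",
    "end1",
    "length",
    "class",
    "n_members",
    "n_samples",
    "approaches",
    "level",
]


def write_cnvr_tsv(path: str, cnvrs: Iterable[Cnvr]) -> None:
    """CNVR table with 1-based inclusive coordinates."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CNVR_TSV_COLUMNS)
        for r in cnvrs:
            writer.writerow(
                [
                    r.interval.chrom,
                    r.interval.start + 1,
                    r.interval.end,
                    r.interval.length,
                    r.cnvr_class,
                    r.n_members,
                    len(r.sample_ids),
                    ",".join(sorted(r.approaches)),
                    r.level,
                ]
            )


def write_cnvr_bed(path: str, cnvrs: Iterable[Cnvr]) -> None:
    """BED6 export; the CNVR class goes in the name field."""
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.cnvr_class}\t{r.n_members}\t.\n"
            )
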