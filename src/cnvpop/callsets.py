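"""Per-sample CNV call sets and caller-specific raw-call filters.

Raw deletion/duplication calls from a split-read caller (Pindel-style) and
a paired-end caller (DELLY-style) are normalised into :class:`CnvCall`
records and filtered with the caller-appropriate quality thresholds before
any consensus step:

* DELLY-style: length > 50 bp and FILTER == "PASS".
* Pindel-style: length > 50 bp, variant allele frequency > 0.2, and
  supporting read count >= 3.

Only DEL and DUP records are admitted; other SV types (INV, INS, BND, ...)
are tallied and skipped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "start0",
    "end0",
    "svtype",
    "caller",
    "filter",
    "vaf",
    "support_reads",
]

DELLY_MIN_LENGTH = 50
PINDEL_MIN_LENGTH = 50
PINDEL_MIN_VAF = 0.2
PINDEL_MIN_SUPPORT = 3


@dataclass(frozen=True)
class CnvCall:
    """One caller-emitted CNV event on one sample."""

    sample_id: str
    interval: GenomicInterval
    svtype: str  # DEL or DUP
    caller: str  # delly, pindel, other
    filter_status: str = "PASS"
    vaf: Optional[float] = None
    support_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "DUP"):
            raise ValueError(f"svtype must be DEL or DUP, got {self.svtype!r}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.support_reads is not None and self.support_reads < 0:
            raise ValueError("support_reads must be >= 0")


@dataclass(frozen=True)
class RdCnvr:
    """A population-level CNVR from a read-depth caller."""

    interval: GenomicInterval
    svtype_hint: str = "unknown"  # DEL, DUP, mixed, unknown


class CallValidationError(ValueError):
    """A caller record violates the filter's input contract."""


def filter_delly(calls: Sequence[CnvCall]) -> list[CnvCall]:
    """Keep DELLY-style calls with length > 50 bp and FILTER == PASS."""
    for c in calls:
        if c.caller != "delly":
            raise CallValidationError(
                f"filter_delly received a {c.caller!r} call (mixed call set)"
            )
    kept = [
        c
        for c in calls
        if c.interval.length > DELLY_MIN_LENGTH and c.filter_status == "PASS"
    ]
    logger.info("filter_delly: kept %d/%d calls", len(kept), len(calls))
    return kept


def filter_pindel(calls: Sequence[CnvCall]) -> list[CnvCall]:
    """Keep Pindel-style calls with length > 50 bp, VAF > 0.2 and >= 3 reads."""
    for c in calls:
        if c.caller != "pindel":
            raise CallValidationError(
                f"filter_pindel received a {c.caller!r} call (mixed call set)"
            )
        if c.vaf is None:
            raise CallValidationError(f"call {c.sample_id} {c.interval}: missing vaf")
        if c.support_reads is None:
            raise CallValidationError(
                f"call {c.sample_id} {c.interval}: missing support_reads"
            )
    kept = [
        c
        for c in calls
        if c.interval.length > PINDEL_MIN_LENGTH
        and c.vaf > PINDEL_MIN_VAF
        and c.support_reads >= PINDEL_MIN_SUPPORT
    ]
    logger.info("filter_pindel: kept %d/%d calls", len(kept), len(calls))
    return kept


def _parse_optional_float(s: str) -> Optional[float]:
    return None if s == "." else float(s)


def _parse_optional_int(s: str) -> Optional[int]:
    return None if s == "." else int(s)


def read_calls_tsv(path: str) -> list[CnvCall]:
    """Read the caller-call TSV dialect (header required, "." for absent)."""
    calls: list[CnvCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CallValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            start, end = int(row["start0"]), int(row["end0"])
            if end <= start:
                raise CallValidationError(
                    f"{path}:{i}: non-positive length interval {start}-{end}"
                )
            calls.append(
                CnvCall(
                    sample_id=row["sample_id"],
                    interval=GenomicInterval(row["chrom"], start, end),
                    svtype=row["svtype"],
                    caller=row["caller"],
                    filter_status=row["filter"],
                    vaf=_parse_optional_float(row["vaf"]),
                    support_reads=_parse_optional_int(row["support_reads"]),
                )
            )
    return calls


def write_calls_tsv(path: str, calls: Iterable[CnvCall]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.interval.chrom,
                    c.interval.start,
                    c.interval.end,
                    c.svtype,
                    c.caller,
                    c.filter_status,
                    "." if c.vaf is None else f"{c.vaf:.6g}",
                    "." if c.support_reads is None else c.support_reads,
                ]
            )


def read_sv_vcf(path: str, sample_id: str, caller: str) -> list[CnvCall]:
    """Read SV records (SVTYPE=DEL/DUP with END) from a single-sample VCF.

    POS is 1-based; the variant interval is taken as ``[POS, END]`` in
    1-based inclusive coordinates, i.e. ``[POS-1, END)`` internally.  When
    no explicit allele-frequency field exists, Pindel-style VAF is derived
    from AD counts as ``alt / (ref + alt)``.  Non-DEL/DUP records are
    counted and skipped.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    calls: list[CnvCall] = []
    skipped = 0
    vcf = VCF(path)
    for rec in vcf:
        svtype = rec.INFO.get("SVTYPE")
        if svtype not in ("DEL", "DUP"):
            skipped += 1
            continue
        end = rec.INFO.get("END", rec.end)
        vaf = None
        support = None
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            ref, alt = int(ad[0][0]), int(ad[0][1])
            support = alt
            if ref + alt > 0:
                vaf = alt / (ref + alt)
        dv = rec.format("DV") if "DV" in (rec.FORMAT or "") else None
        if dv is not None:
            support = int(dv[0][0])
        calls.append(
            CnvCall(
                sample_id=sample_id,
                interval=GenomicInterval(rec.CHROM, rec.POS - 1, int(end)),
                svtype=svtype,
                caller=caller,
                filter_status=rec.FILTER or "PASS",
                vaf=vaf,
                support_reads=support,
            )
        )
    if skipped:
        logger.info("read_sv_vcf: skipped %d non-DEL/DUP records", skipped)
    return calls


def read_rd_track(path: str) -> list[RdCnvr]:
    """Read a read-depth CNVR track from BED3+ (col 4, if present, is a type hint)."""
    out: list[RdCnvr] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            hint = f[3] if len(f) > 3 and f[3] in ("DEL", "DUP", "mixed") else "unknown"
            out.append(RdCnvr(GenomicInterval(f[0], int(f[1]), int(f[2])), hint))
    return out


def write_rd_track(path: str, track: Iterable[RdCnvr]) -> None:
    with open(path, "w") as fh:
        for r in track:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.svtype_hint}\n"
            )
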