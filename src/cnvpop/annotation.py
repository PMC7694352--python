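"""CNVR–gene overlap and multi-dataset gene-set comparison."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .consensus import Cnvr
from .intervals import GenomicInterval, overlap_length

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    interval: GenomicInterval
    symbol: Optional[str] = None

    @property
    def label(self) -> str:
        return self.symbol or self.gene_id


def read_gff3_genes(path: str) -> list[GeneFeature]:
    """Genes (feature type "gene" only) from a GFF3 file.

    GFF3 coordinates are 1-based inclusive.  gene_id comes from the ID
    attribute (``gene:`` prefix stripped), the symbol from Name if present.
    """
    genes: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{f[0]}:{f[3]}").removeprefix("gene:")
            if gid in seen:
                raise ValueError(f"duplicate gene_id {gid!r} in {path}")
            seen.add(gid)
            genes.append(
                GeneFeature(
                    gene_id=gid,
                    interval=GenomicInterval(f[0], int(f[3]) - 1, int(f[4])),
                    symbol=attrs.get("Name"),
                )
            )
    return genes


def read_bed_genes(path: str) -> list[GeneFeature]:
    """Genes from BED4+ (name field = gene_id)."""
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            genes.append(
                GeneFeature(
                    gene_id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                )
            )
    return genes


def overlap_genes(
    cnvrs: Sequence[Cnvr], genes: Sequence[GeneFeature]
) -> tuple[dict[int, list[GeneFeature]], list[GeneFeature]]:
    """Genes overlapping (>= 1 bp) each CNVR envelope.

    Returns ``(per_cnvr, union)``: a mapping from the CNVR's index in the
    input to its overlapping genes sorted by coordinate, and the union
    gene set deduplicated by gene_id in coordinate order.
    """
    trees: dict[str, IntervalTree] = {}
    for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )
    per_cnvr: dict[int, list[GeneFeature]] = {}
    union: dict[str, GeneFeature] = {}
    for i, r in enumerate(cnvrs):
        iv = r.interval
        hits = []
        if iv.chrom in trees:
            hits = [h.data for h in trees[iv.chrom].overlap(iv.start, iv.end)]
        hits.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
        per_cnvr[i] = hits
        for g in hits:
            union.setdefault(g.gene_id, g)
    union_list = sorted(
        union.values(), key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id)
    )
    return per_cnvr, union_list


def compare_gene_sets(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str]
) -> dict[str, int]:
    """Three-set membership counts (the seven exclusive regions + margins).

    Gene identity is case-insensitive on symbols; collisions that differ
    only by case are logged.  Keys ``a_only .. abc`` partition the union;
    ``ab, ac, bc`` and ``a, b, c`` are the (non-exclusive) intersection and
    set sizes.
    """

    def norm(items: Iterable[str]) -> set[str]:
        seen: dict[str, str] = {}
        for s in items:
            key = s.casefold()
            if key in seen and seen[key] != s:
                logger.warning("case collision: %r vs %r", seen[key], s)
            seen.setdefault(key, s)
        return set(seen)

    a, b, c = norm(set_a), norm(set_b), norm(set_c)
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(a & b & c),
        "ab": len(a & b),
        "ac": len(a & c),
        "bc": len(b & c),
        "a": len(a),
        "b": len(b),
        "c": len(c),
        "union": len(a | b | c),
    }


def write_gene_overlap_tsv(
    path: str, cnvrs: Sequence[Cnvr], per_cnvr: Mapping[int, list[GeneFeature]]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cnvr_id", "gene_id", "symbol", "overlap_bp"])
        for i, r in enumerate(cnvrs):
            for g in per_cnvr.get(i, []):
                writer.writerow(
                    [
                        str(r.interval),
                        g.gene_id,
                        g.symbol or ".",
                        overlap_length(r.interval, g.interval),
                    ]
                )
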