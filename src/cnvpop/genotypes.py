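"""CNV genotype matrices: parsing, frequencies, locus filters, and spectra.

Genotypes are biallelic per locus (reference vs SV allele), stored as
alt-allele dosage 0/1/2 with NaN for missing — the form emitted by
genotypers that write 0/0, 0/1, 1/1, ./. GT fields for merged SV sites.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval

MISSING = np.nan

LOCI_COLUMNS = ["locus_id", "chrom", "start0", "end0", "svtype"]


class AllMissingError(ValueError):
    """Every genotype at the locus is missing; frequency is undefined."""


@dataclass
class GenotypeMatrix:
    """Loci x samples alt-allele dosages with population labels.

    Attributes
    ----------
    loci : pd.DataFrame
        Columns ``locus_id, chrom, start0, end0, svtype``; one row per locus.
    samples : pd.DataFrame
        Columns ``sample_id, population``; one row per sample.
    dosage : np.ndarray
        float array of shape (n_loci, n_samples); values 0, 1, 2 or NaN.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosage values must be 0, 1, 2 or NaN")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def locus_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(row.chrom, row.start0, row.end0)
            for row in self.loci.itertuples()
        ]

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given sample ids (error on unknown)."""
        pos = {s: i for i, s in enumerate(self.samples["sample_id"])}
        unknown = [s for s in sample_ids if s not in pos]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.loci.loc[np.asarray(mask)], self.samples, self.dosage[np.asarray(mask)]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = self.sample_columns(sample_ids)
        return GenotypeMatrix(self.loci, self.samples.iloc[cols], self.dosage[:, cols])


def allele_frequency(dosages: Sequence[float]) -> tuple[float, float, float]:
    """Alt-allele frequency, MAF and call rate of one locus.

    Missing genotypes (NaN) are excluded from the frequency denominator.
    Raises :class:`AllMissingError` when no genotype is observed.
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n == 0:
        raise AllMissingError("all genotypes missing at locus")
    alt = float(d[ok].sum()) / (2 * n)
    return alt, min(alt, 1.0 - alt), n / d.size


def filter_loci(
    matrix: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.10
) -> GenotypeMatrix:
    """Drop loci with MAF below ``maf_min`` or missingness above ``max_missing``.

    Both thresholds are inclusive on the kept side (MAF >= maf_min,
    missing fraction <= max_missing), computed over all samples; loci with
    no observed genotype are dropped.
    """
    if matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    keep = np.zeros(matrix.n_loci, dtype=bool)
    for i in range(matrix.n_loci):
        row = matrix.dosage[i]
        miss = float(np.isnan(row).mean())
        if miss > max_missing:
            continue
        try:
            _, maf, _ = allele_frequency(row)
        except AllMissingError:
            continue
        keep[i] = maf >= maf_min
    return matrix.subset_loci(keep)


def extract_cnvr_loci(matrix: GenotypeMatrix, cnvrs: Sequence) -> GenotypeMatrix:
    """Keep loci overlapping (>= 1 bp) any CNVR envelope."""
    trees: dict[str, IntervalTree] = {}
    for r in cnvrs:
        iv = r.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    keep = np.array(
        [
            row.chrom in trees and bool(trees[row.chrom].overlap(row.start0, row.end0))
            for row in matrix.loci.itertuples()
        ],
        dtype=bool,
    )
    return matrix.subset_loci(keep)


def site_frequency_spectrum(
    matrix: GenotypeMatrix,
    svtype: Optional[str] = None,
    bin_width: float = 0.05,
    max_missing: float = 0.10,
) -> pd.DataFrame:
    """Folded site-frequency spectrum over MAF.

    Bins are left-open/right-closed: (0, w], (w, 2w], ..., (0.5-w, 0.5],
    so the rare class "MAF <= w" coincides with the first bin.  Loci with
    missing-genotype rate above ``max_missing`` are excluded; monomorphic
    loci (MAF = 0) are reported as a separate zero class and excluded from
    the fractions, which sum to 1 over polymorphic loci.

    Returns a DataFrame with columns ``bin_low, bin_high, n_loci, fraction``
    plus one leading zero-class row (bin_low = bin_high = 0).
    """
    n_bins = round(0.5 / bin_width)
    if abs(n_bins * bin_width - 0.5) > 1e-9:
        raise ValueError("bin_width must divide 0.5")
    mafs = []
    for i in range(matrix.n_loci):
        if svtype is not None and matrix.loci["svtype"].iat[i] != svtype:
            continue
        row = matrix.dosage[i]
        if float(np.isnan(row).mean()) > max_missing:
            continue
        try:
            _, maf, _ = allele_frequency(row)
        except AllMissingError:
            continue
        mafs.append(maf)
    if not mafs:
        raise ValueError("no loci left after exclusions")
    mafs = np.asarray(mafs)
    n_zero = int((mafs == 0).sum())
    poly = mafs[mafs > 0]
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    # right-closed bins: count maf in (edges[k], edges[k+1]]
    counts = [
        int(((poly > edges[k]) & (poly <= edges[k + 1] + 1e-12)).sum())
        for k in range(n_bins)
    ]
    total = len(poly)
    rows = [{"bin_low": 0.0, "bin_high": 0.0, "n_loci": n_zero, "fraction": np.nan}]
    for k in range(n_bins):
        rows.append(
            {
                "bin_low": edges[k],
                "bin_high": edges[k + 1],
                "n_loci": counts[k],
                "fraction": counts[k] / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _gt_to_dosage(gt: str) -> float:
    alleles = gt.replace("|", "/").split("/")
    if "." in alleles:
        return MISSING
    return float(sum(int(a) > 0 for a in alleles))


def read_genotype_vcf_text(path: str, populations: dict[str, str]) -> GenotypeMatrix:
    """Read a multi-sample SV genotype VCF (plain text) into a matrix.

    Uses POS/INFO:END for locus intervals and INFO:SVTYPE for the type;
    GT is the first colon-separated FORMAT subfield.
    """
    loci_rows = []
    dosages = []
    sample_ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            f = line.split("\t")
            chrom, pos, vid, info = f[0], int(f[1]), f[2], f[7]
            info_d = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            end = int(info_d.get("END", pos))
            svtype = info_d.get("SVTYPE", "DEL")
            loci_rows.append(
                {
                    "locus_id": vid if vid != "." else f"{chrom}:{pos}",
                    "chrom": chrom,
                    "start0": pos - 1,
                    "end0": end,
                    "svtype": svtype,
                }
            )
            dosages.append([_gt_to_dosage(s.split(":")[0]) for s in f[9:]])
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": [populations.get(s, "NA") for s in sample_ids],
        }
    )
    return GenotypeMatrix(
        pd.DataFrame(loci_rows, columns=LOCI_COLUMNS),
        samples,
        np.array(dosages, dtype=float).reshape(len(loci_rows), len(sample_ids)),
    )


def read_population_map(path: str) -> dict[str, str]:
    """Sample -> population TSV (two columns, optional header)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            if sample == "sample_id":
                continue
            out[sample] = pop
    return out


def write_dosage_tsv(path: str, matrix: GenotypeMatrix) -> None:
    """Loci x samples dosage table for external PCA/ADMIXTURE tooling."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(LOCI_COLUMNS + list(matrix.samples["sample_id"]))
        for i, row in enumerate(matrix.loci.itertuples()):
            dos = [
                "." if np.isnan(v) else str(int(v)) for v in matrix.dosage[i]
            ]
            writer.writerow(
                [row.locus_id, row.chrom, row.start0, row.end0, row.svtype] + dos
            )
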