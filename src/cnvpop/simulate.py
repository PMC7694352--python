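"""Synthetic cohorts with the statistical structure the pipeline assumes.

Populations are differentiated under the Balding–Nichols model: each locus
has an ancestral alt-allele frequency p drawn uniformly from a configured
range, and each subpopulation draws its own frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), where F is the target differentiation.
Diploid genotypes are Binomial(2, p_subpop), independent across loci
(no linkage).

Caller outputs are emulated per carrier (dosage >= 1): each caller emits
the true interval with independently Gaussian-jittered endpoints, drops it
with a false-negative probability, and decorates it with caller-specific
QC fields (FILTER for the paired-end caller; VAF and supporting reads for
the split-read caller).  Background false positives land uniformly on the
genome at a configurable rate per Mb.  A population-level read-depth CNVR
track is derived from the true CNVR set with its own jitter, and a
multi-sample genotype VCF encodes the true dosages with a configurable
missing rate.

All randomness flows from the single config seed through named
``numpy.random.SeedSequence`` child streams, so reruns are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .callsets import CnvCall, RdCnvr, write_calls_tsv, write_rd_track
from .genotypes import LOCI_COLUMNS, GenotypeMatrix
from .intervals import GenomicInterval, cluster_by_overlap

# study-cohort layout: four Chinese breeds, two Moroccan breeds, and
# wild Bezoar ibexes
DEFAULT_POPULATIONS = {
    "CB": 15,  # Chengdu Brown
    "JT": 9,   # Jintang Black
    "TC": 14,  # Tibetan Cashmere
    "SC": 4,   # Shaanbei Cashmere
    "MD": 14,  # Moroccan Draa
    "MN": 8,   # Moroccan Northern
    "BI": 21,  # Bezoar ibex
}

# a reserved suffix of the first chromosome keeps spike-in calls clear of
# simulated loci
SPIKE_REGION_BP = 50_000


@dataclass(frozen=True)
class CallerNoise:
    """Noise model of one emulated caller."""

    fn_rate: float = 0.05
    fp_per_mb: float = 0.05
    boundary_jitter_sd: float = 10.0
    pass_prob: float = 0.95  # paired-end caller FILTER
    vaf_sd: float = 0.08     # split-read caller VAF spread around 0.5 / 0.95
    support_reads_mean: float = 10.0

    def validate(self) -> None:
        for name in ("fn_rate", "pass_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")
        if self.fp_per_mb < 0:
            raise ValueError("fp_per_mb must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort, genome, and caller-noise parameters of one simulation."""

    populations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS)
    )
    n_loci: int = 2000
    differentiation_f: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
        ("chr3", 10_000_000),
        ("chr4", 10_000_000),
        ("chr5", 10_000_000),
    )
    # log-normal CNV lengths: median exp(mu) ~= 179 bp with a heavy right
    # tail, clipped to [51, 50_000] bp so every event passes size filters
    cnv_length_log_mean: float = 5.187  # ln(179)
    cnv_length_log_sd: float = 1.5
    cnv_length_min: int = 51
    cnv_length_max: int = 50_000
    del_fraction: float = 0.9
    delly_noise: CallerNoise = CallerNoise()
    pindel_noise: CallerNoise = CallerNoise(pass_prob=1.0)
    rd_jitter_sd: float = 20.0
    missing_rate: float = 0.02
    spike_known_fail: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.populations or any(n < 1 for n in self.populations.values()):
            raise ValueError("every population needs >= 1 sample")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 < self.differentiation_f < 1.0:
            raise ValueError("differentiation_f must be in (0,1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0,1]")
        self.delly_noise.validate()
        self.pindel_noise.validate()

    def sample_ids(self) -> list[str]:
        return [
            f"{pop}_{i + 1:02d}"
            for pop, n in self.populations.items()
            for i in range(n)
        ]

    def population_map(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids()}

    def zero_noise(self) -> "SimulationConfig":
        """Copy with all caller noise, jitter and missingness off."""
        quiet = CallerNoise(
            fn_rate=0.0, fp_per_mb=0.0, boundary_jitter_sd=0.0, pass_prob=1.0
        )
        return replace(
            self,
            delly_noise=quiet,
            pindel_noise=quiet,
            rd_jitter_sd=0.0,
            missing_rate=0.0,
        )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["loci", "freqs", "genotypes", "delly", "pindel", "rd", "missing"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _place_loci(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping locus intervals placed uniformly on the toy genome."""
    lengths = np.exp(
        rng.normal(config.cnv_length_log_mean, config.cnv_length_log_sd, config.n_loci)
    )
    lengths = np.clip(np.round(lengths), config.cnv_length_min, config.cnv_length_max)
    lengths = lengths.astype(int)
    usable = []
    for i, (chrom, size) in enumerate(config.genome):
        reserve = SPIKE_REGION_BP if i == 0 else 0
        usable.append((chrom, size - reserve))
    total = sum(u for _, u in usable)
    # spread loci over chromosomes proportionally to usable length
    counts = np.floor(config.n_loci * np.array([u for _, u in usable]) / total).astype(int)
    for i in range(config.n_loci - counts.sum()):
        counts[i % len(counts)] += 1
    rows = []
    pos = 0
    for (chrom, u), k in zip(usable, counts):
        ls = lengths[pos : pos + k]
        pos += k
        free = u - int(ls.sum())
        if free < k:
            raise ValueError(
                f"genome too small: cannot place {k} loci "
                f"({int(ls.sum())} bp) on {chrom} ({u} bp usable)"
            )
        gaps = np.sort(rng.integers(0, free, size=k))
        starts = gaps + np.concatenate(([0], np.cumsum(ls[:-1])))
        for s, l in zip(starts, ls):
            rows.append({"chrom": chrom, "start0": int(s), "end0": int(s + l)})
    rows.sort(key=lambda r: (r["chrom"], r["start0"]))
    df = pd.DataFrame(rows)
    df.insert(0, "locus_id", [f"cnv_{i:05d}" for i in range(len(df))])
    df["svtype"] = np.where(
        rng.random(len(df)) < config.del_fraction, "DEL", "DUP"
    )
    return df


def simulate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Draw the true locus table and true diploid dosages.

    Returns ``(locus_table, truth)`` where the locus table carries the
    ancestral frequency and one ``freq_<pop>`` column per population, and
    ``truth`` is the noise-free genotype matrix.
    """
    config.validate()
    rngs = _streams(config.seed)
    loci = _place_loci(config, rngs["loci"])
    L = len(loci)
    F = config.differentiation_f
    lo, hi = config.ancestral_freq_range
    p_anc = rngs["freqs"].uniform(lo, hi, L)
    loci["p_ancestral"] = p_anc
    pops = list(config.populations)
    subfreqs = {}
    for pop in pops:
        alpha = p_anc * (1 - F) / F
        beta = (1 - p_anc) * (1 - F) / F
        subfreqs[pop] = rngs["freqs"].beta(alpha, beta)
        loci[f"freq_{pop}"] = subfreqs[pop]
    sample_ids = config.sample_ids()
    pop_of = config.population_map()
    dosage = np.empty((L, len(sample_ids)), dtype=float)
    for j, s in enumerate(sample_ids):
        dosage[:, j] = rngs["genotypes"].binomial(2, subfreqs[pop_of[s]])
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "population": [pop_of[s] for s in sample_ids]}
    )
    truth = GenotypeMatrix(loci[LOCI_COLUMNS].copy(), samples, dosage)
    return loci, truth


def true_cnvrs(
    locus_table: pd.DataFrame, truth: GenotypeMatrix, min_carriers: int = 2
) -> list[GenomicInterval]:
    """The simulation's ground-truth CNVR set.

    A locus is a true CNVR when at least ``min_carriers`` individuals carry
    it (the pipeline's singleton-removal rule); overlapping true loci are
    merged.  Loci are placed non-overlapping, so in practice each true
    CNVR is one locus interval.
    """
    carriers = np.nansum(truth.dosage >= 1, axis=1)
    ivs = [
        GenomicInterval(row.chrom, row.start0, row.end0)
        for row, k in zip(locus_table.itertuples(), carriers)
        if k >= min_carriers
    ]
    return [cl.envelope for cl in cluster_by_overlap(ivs, 1)]


def _jitter_interval(
    iv: GenomicInterval,
    sd: float,
    chrom_len: int,
    rng: np.random.Generator,
) -> GenomicInterval:
    if sd == 0:
        return iv
    for _ in range(100):  # resample degenerate draws
        s = int(round(iv.start + rng.normal(0, sd)))
        e = int(round(iv.end + rng.normal(0, sd)))
        s = max(0, s)
        e = min(chrom_len, e)
        if e > s:
            return GenomicInterval(iv.chrom, s, e)
    return iv


def _spike_calls(config: SimulationConfig) -> tuple[list[CnvCall], list[CnvCall]]:
    """Deterministic known-fail calls, one per filter rule, in the reserved
    suffix of the first chromosome."""
    chrom, size = config.genome[0]
    base = size - SPIKE_REGION_BP + 1000
    sample = config.sample_ids()[0]

    def iv(off: int, length: int) -> GenomicInterval:
        return GenomicInterval(chrom, base + off, base + off + length)

    delly = [
        # at the length boundary: 50 bp is not > 50 bp
        CnvCall(sample, iv(0, 50), "DEL", "delly", "PASS"),
        CnvCall(sample, iv(2000, 500), "DEL", "delly", "LowQual"),
    ]
    pindel = [
        CnvCall(sample, iv(4000, 50), "DEL", "pindel", "PASS", vaf=0.5, support_reads=10),
        # at the VAF boundary: 0.2 is not > 0.2
        CnvCall(sample, iv(6000, 500), "DEL", "pindel", "PASS", vaf=0.2, support_reads=10),
        CnvCall(sample, iv(8000, 500), "DEL", "pindel", "PASS", vaf=0.5, support_reads=2),
    ]
    return delly, pindel


@dataclass
class CallSetBundle:
    """Everything one simulation emits for the pipeline to consume."""

    delly_calls: list[CnvCall]
    pindel_calls: list[CnvCall]
    rd_track: list[RdCnvr]
    observed: GenotypeMatrix  # true dosages with missingness applied
    spiked_delly: list[CnvCall]
    spiked_pindel: list[CnvCall]

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "delly": os.path.join(outdir, "delly_calls.tsv"),
            "pindel": os.path.join(outdir, "pindel_calls.tsv"),
            "rd_track": os.path.join(outdir, "rd_track.bed"),
            "genotypes": os.path.join(outdir, "genotypes.vcf"),
            "populations": os.path.join(outdir, "populations.tsv"),
        }
        write_calls_tsv(paths["delly"], self.delly_calls)
        write_calls_tsv(paths["pindel"], self.pindel_calls)
        write_rd_track(paths["rd_track"], self.rd_track)
        write_genotype_vcf(paths["genotypes"], self.observed)
        with open(paths["populations"], "w") as fh:
            fh.write("sample_id\tpopulation\n")
            for row in self.observed.samples.itertuples():
                fh.write(f"{row.sample_id}\t{row.population}\n")
        return paths


def _caller_calls(
    caller: str,
    noise: CallerNoise,
    locus_table: pd.DataFrame,
    truth: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[CnvCall]:
    chrom_len = dict(config.genome)
    calls: list[CnvCall] = []
    sample_ids = list(truth.samples["sample_id"])
    for i, row in enumerate(locus_table.itertuples()):
        iv0 = GenomicInterval(row.chrom, row.start0, row.end0)
        for j, sid in enumerate(sample_ids):
            dos = truth.dosage[i, j]
            if not dos >= 1:
                continue
            if rng.random() < noise.fn_rate:
                continue
            iv = _jitter_interval(iv0, noise.boundary_jitter_sd, chrom_len[row.chrom], rng)
            calls.append(_decorate(caller, noise, sid, iv, row.svtype, dos, rng))
    # background false positives, uniform on the genome
    genome_mb = sum(l for _, l in config.genome) / 1e6
    for sid in sample_ids:
        n_fp = rng.poisson(noise.fp_per_mb * genome_mb)
        for _ in range(n_fp):
            chrom, clen = config.genome[rng.integers(len(config.genome))]
            length = int(
                np.clip(
                    round(np.exp(rng.normal(config.cnv_length_log_mean,
                                            config.cnv_length_log_sd))),
                    config.cnv_length_min,
                    config.cnv_length_max,
                )
            )
            start = int(rng.integers(0, max(1, clen - length)))
            svtype = "DEL" if rng.random() < config.del_fraction else "DUP"
            fp_iv = GenomicInterval(chrom, start, start + length)
            dos = 1.0 if rng.random() < 0.8 else 2.0
            calls.append(_decorate(caller, noise, sid, fp_iv, svtype, dos, rng))
    calls.sort(key=lambda c: (c.sample_id, c.interval.chrom, c.interval.start, c.interval.end))
    return calls


def _decorate(
    caller: str,
    noise: CallerNoise,
    sample_id: str,
    iv: GenomicInterval,
    svtype: str,
    dosage: float,
    rng: np.random.Generator,
) -> CnvCall:
    if caller == "delly":
        status = "PASS" if rng.random() < noise.pass_prob else "LowQual"
        return CnvCall(sample_id, iv, svtype, "delly", status)
    center = 0.5 if dosage == 1 else 0.95
    vaf = (
        center
        if noise.vaf_sd == 0
        else float(np.clip(rng.normal(center, noise.vaf_sd), 0.01, 1.0))
    )
    reads = max(3, int(rng.poisson(noise.support_reads_mean)))
    return CnvCall(sample_id, iv, svtype, "pindel", "PASS", vaf=vaf, support_reads=reads)


def simulate_callsets(
    locus_table: pd.DataFrame,
    truth: GenotypeMatrix,
    config: SimulationConfig,
) -> CallSetBundle:
    """Emit noisy caller outputs, the read-depth track, and observed genotypes."""
    config.validate()
    rngs = _streams(config.seed)
    delly = _caller_calls("delly", config.delly_noise, locus_table, truth, config, rngs["delly"])
    pindel = _caller_calls("pindel", config.pindel_noise, locus_table, truth, config, rngs["pindel"])
    spiked_d: list[CnvCall] = []
    spiked_p: list[CnvCall] = []
    if config.spike_known_fail:
        spiked_d, spiked_p = _spike_calls(config)
        delly = delly + spiked_d
        pindel = pindel + spiked_p
    chrom_len = dict(config.genome)
    rd_track = [
        RdCnvr(_jitter_interval(iv, config.rd_jitter_sd, chrom_len[iv.chrom], rngs["rd"]))
        for iv in true_cnvrs(locus_table, truth)
    ]
    dosage = truth.dosage.copy()
    if config.missing_rate > 0:
        mask = rngs["missing"].random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    observed = GenotypeMatrix(truth.loci.copy(), truth.samples.copy(), dosage)
    return CallSetBundle(delly, pindel, rd_track, observed, spiked_d, spiked_p)


def write_genotype_vcf(path: str, matrix: GenotypeMatrix) -> None:
    """Minimal multi-sample SV VCF with SVTYPE/END INFO and GT genotypes."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples["sample_id"])
            + "\n"
        )
        for i, row in enumerate(matrix.loci.itertuples()):
            gts = [
                "./." if np.isnan(v) else gt_of[v] for v in matrix.dosage[i]
            ]
            fh.write(
                f"{row.chrom}\t{row.start0 + 1}\t{row.locus_id}\tN\t<{row.svtype}>\t.\tPASS\t"
                f"SVTYPE={row.svtype};END={row.end0}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_truth_tsv(path: str, locus_table: pd.DataFrame, truth: GenotypeMatrix) -> None:
    """Locus table with per-population frequencies and the true dosage matrix."""
    df = locus_table.copy()
    for j, sid in enumerate(truth.samples["sample_id"]):
        df[f"dosage_{sid}"] = truth.dosage[:, j].astype(int)
    df.to_csv(path, sep="\t", index=False)
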