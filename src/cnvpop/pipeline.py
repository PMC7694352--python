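"""End-to-end orchestration: filter -> consensus -> CNVR -> unify ->
genotypes -> locus filters -> SFS -> FST scan -> gene annotation.

Every stage writes its table into the run directory and logs its
retained/dropped record counts, so the filtering narrative is auditable.
Reruns with the same inputs and config are byte-identical apart from the
timestamp in the log header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional

from . import annotation, callsets, consensus, fst, genotypes


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run.

    Thresholds default to the workflow's standard values: 50% reciprocal
    overlap for consensus and unification, MAF >= 0.05,
    missingness <= 10%, and a 5% empirical outlier tail.
    """

    delly_calls: str = ""
    pindel_calls: str = ""
    rd_track: str = ""
    genotype_vcf: str = ""
    populations: str = ""
    genes: str = ""  # optional GFF3 or BED
    outdir: str = "cnvpop_run"
    min_frac: float = 0.5
    min_frac_shortest: float = 0.5
    maf_min: float = 0.05
    max_missing: float = 0.10
    tail: float = 0.05
    level: str = "meta"
    group1: tuple[str, ...] = ()  # population names
    group2: tuple[str, ...] = ()
    genome_length: int = 50_000_000
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_frac", "min_frac_shortest", "maf_min", "max_missing", "tail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("delly_calls", "pindel_calls", "rd_track", "genotype_vcf",
                     "populations"):
            path = getattr(self, name)
            if not path:
                raise ValueError(f"required path {name} is unset")
            if not os.path.exists(path):
                raise ValueError(f"{name}: no such file {path}")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        """Read a key=value config file; later keys win; kwargs override."""
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                kwargs[key] = value
        kwargs.update(overrides)
        return cls(**_coerce(kwargs))

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for key, value in vars(self).items():
                if isinstance(value, tuple):
                    value = ",".join(value)
                fh.write(f"{key}={value}\n")


def _coerce(kwargs: dict) -> dict:
    import dataclasses

    types = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    out = {}
    for key, value in kwargs.items():
        if key not in types:
            raise ValueError(f"unknown config key {key!r}")
        if not isinstance(value, str):
            out[key] = value
            continue
        t = types[key]
        if t == "float":
            out[key] = float(value)
        elif t == "int":
            out[key] = int(value)
        elif t.startswith("tuple"):
            out[key] = tuple(v for v in value.split(",") if v)
        else:
            out[key] = value
    return out


@dataclass
class PipelineResult:
    """Handles to everything a run produced."""

    config: PipelineConfig
    cnvrs_population: list
    cnvrs_meta: list
    cnvrs_final: list
    matrix_filtered: genotypes.GenotypeMatrix
    scan: Optional[fst.ScanResult]
    summary: consensus.Summary
    counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    log_lines = [
        f"# cnvpop pipeline run {datetime.now(timezone.utc).isoformat()}"
    ]
    counts: dict[str, int] = {}

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    def stage(name: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            log(name, f"FAILED: {exc}")
            _write_log(out("run.log"), log_lines)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    pop_map = stage("populations", genotypes.read_population_map, config.populations)

    # --- caller filters -------------------------------------------------
    delly_raw = stage("read_delly", callsets.read_calls_tsv, config.delly_calls)
    pindel_raw = stage("read_pindel", callsets.read_calls_tsv, config.pindel_calls)
    delly_kept = stage("filter_delly", callsets.filter_delly, delly_raw)
    pindel_kept = stage("filter_pindel", callsets.filter_pindel, pindel_raw)
    counts["delly_raw"], counts["delly_kept"] = len(delly_raw), len(delly_kept)
    counts["pindel_raw"], counts["pindel_kept"] = len(pindel_raw), len(pindel_kept)
    log("filter_delly", f"kept {len(delly_kept)}/{len(delly_raw)}")
    log("filter_pindel", f"kept {len(pindel_kept)}/{len(pindel_raw)}")
    callsets.write_calls_tsv(out("delly_filtered.tsv"), delly_kept)
    callsets.write_calls_tsv(out("pindel_filtered.tsv"), pindel_kept)

    # --- per-sample two-caller consensus --------------------------------
    by_sample_d: dict[str, list] = {}
    by_sample_p: dict[str, list] = {}
    for c in delly_kept:
        by_sample_d.setdefault(c.sample_id, []).append(c)
    for c in pindel_kept:
        by_sample_p.setdefault(c.sample_id, []).append(c)
    cons = []
    for sid in sorted(set(by_sample_d) | set(by_sample_p)):
        cons.extend(
            stage(
                "consensus",
                consensus.intersect_callsets,
                by_sample_d.get(sid, []),
                by_sample_p.get(sid, []),
                config.min_frac,
            )
        )
    counts["consensus"] = len(cons)
    log("consensus", f"{len(cons)} consensus CNVs")

    # --- CNVR merging, both levels --------------------------------------
    cnvrs_pop = stage("cnvr", consensus.build_cnvrs, cons, pop_map, "population")
    cnvrs_meta = stage("cnvr", consensus.build_cnvrs, cons, pop_map, "meta")
    counts["cnvr_population"] = len(cnvrs_pop)
    counts["cnvr_meta"] = len(cnvrs_meta)
    log("cnvr", f"{len(cnvrs_pop)} population-level, {len(cnvrs_meta)} meta-level")
    consensus.write_cnvr_tsv(out("cnvrs_population.tsv"), cnvrs_pop)
    consensus.write_cnvr_tsv(out("cnvrs_meta.tsv"), cnvrs_meta)

    # --- unification with the read-depth track --------------------------
    track = cnvrs_pop if config.level == "population" else cnvrs_meta
    rd = stage("read_rd", callsets.read_rd_track, config.rd_track)
    final = stage(
        "unify", consensus.unify_with_read_depth, track, rd, config.min_frac_shortest
    )
    counts["rd_track"] = len(rd)
    counts["cnvr_final"] = len(final)
    log("unify", f"retained {len(final)}/{len(track)} CNVRs against {len(rd)} RD regions")
    consensus.write_cnvr_tsv(out("cnvrs_final.tsv"), final)
    consensus.write_cnvr_bed(out("cnvrs_final.bed"), final)

    # --- genotypes ------------------------------------------------------
    matrix = stage(
        "genotypes", genotypes.read_genotype_vcf_text, config.genotype_vcf, pop_map
    )
    in_cnvr = stage("extract_loci", genotypes.extract_cnvr_loci, matrix, final)
    filtered = stage(
        "filter_loci", genotypes.filter_loci, in_cnvr, config.maf_min, config.max_missing
    )
    counts["loci_total"] = matrix.n_loci
    counts["loci_in_cnvr"] = in_cnvr.n_loci
    counts["loci_filtered"] = filtered.n_loci
    log("genotypes", f"{matrix.n_loci} loci read")
    log("extract_loci", f"{in_cnvr.n_loci} loci inside final CNVRs")
    log("filter_loci", f"{filtered.n_loci} loci pass MAF/missingness")
    genotypes.write_dosage_tsv(out("dosages_filtered.tsv"), filtered)

    # --- site frequency spectra -----------------------------------------
    for svtype in ("DEL", "DUP"):
        try:
            sfs = genotypes.site_frequency_spectrum(
                in_cnvr, svtype=svtype, max_missing=config.max_missing
            )
            sfs.to_csv(out(f"sfs_{svtype.lower()}.tsv"), sep="\t", index=False)
            log("sfs", f"{svtype}: {int(sfs['n_loci'].sum())} loci binned")
        except ValueError as exc:
            log("sfs", f"{svtype}: skipped ({exc})")

    # --- FST scan --------------------------------------------------------
    scan = None
    if config.group1 and config.group2:
        assign = {}
        for row in filtered.samples.itertuples():
            if row.population in config.group1:
                assign[row.sample_id] = "group1"
            elif row.population in config.group2:
                assign[row.sample_id] = "group2"
        scan = stage("fst", fst.fst_scan, filtered, assign, config.tail)
        fst.write_scan_tsv(out("fst_scan.tsv"), scan)
        counts["fst_defined"] = scan.n_defined
        counts["fst_outliers"] = len(scan.outlier_ids)
        log(
            "fst",
            f"mean={scan.mean_theta:.4f} median={scan.median_theta:.4f} "
            f"threshold={scan.tail_threshold:.4f} outliers={len(scan.outlier_ids)}",
        )

    # --- gene annotation -------------------------------------------------
    if config.genes:
        reader = (
            annotation.read_gff3_genes
            if config.genes.endswith((".gff", ".gff3"))
            else annotation.read_bed_genes
        )
        genes = stage("annotate", reader, config.genes)
        per_cnvr, union = stage("annotate", annotation.overlap_genes, final, genes)
        annotation.write_gene_overlap_tsv(out("cnvr_genes.tsv"), final, per_cnvr)
        counts["cnv_genes"] = len(union)
        log("annotate", f"{len(union)} genes overlap final CNVRs")

    # --- summary ---------------------------------------------------------
    summary = consensus.summarize(final, config.genome_length)
    with open(out("summary.tsv"), "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_cnvr\t{summary.n_total}\n")
        for cls, n in summary.counts_by_class.items():
            fh.write(f"n_{cls}\t{n}\n")
        fh.write(f"union_span_bp\t{summary.union_span_bp}\n")
        fh.write(f"coverage_percent\t{summary.coverage_percent:.2f}\n")
        fh.write(f"mean_size_bp\t{summary.mean_size_bp:.1f}\n")
        fh.write(f"median_size_bp\t{summary.median_size_bp:.1f}\n")
    log("summarize", f"coverage {summary.coverage_percent:.2f}% of {config.genome_length} bp")

    config.to_file(out("config.effective.txt"))
    _write_log(out("run.log"), log_lines)
    return PipelineResult(
        config=config,
        cnvrs_population=cnvrs_pop,
        cnvrs_meta=cnvrs_meta,
        cnvrs_final=final,
        matrix_filtered=filtered,
        scan=scan,
        summary=summary,
        counts=counts,
    )


def _write_log(path: str, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
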