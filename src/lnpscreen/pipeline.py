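"""End-to-end orchestration: design → simulate → count → quantify → enrich.

Each stage reads its predecessor's files from the run directory and writes
its own, so stages can be re-run independently; a manifest with the config
hash and the output list is written per stage, and every table carries the
config hash in a leading comment line. All randomness derives from the
single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import barcodes, counting, enrichment, library, quantify, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; loadable from a flat YAML mapping."""

    seed: int = 7
    outdir: str = "lnpscreen_run"
    primer_table: str | None = None        # packaged panel when None

    # library design
    lipids: Sequence[str] = library.DEFAULT_LIPIDS
    cholesterols: Sequence[str] = library.DEFAULT_CHOLESTEROLS
    pegs: Sequence[str] = library.DEFAULT_PEGS
    helper: str = library.DEFAULT_HELPER
    ratios: Sequence[Sequence[float]] = library.DEFAULT_RATIOS

    # barcode design
    barcode_length: int = 8
    min_hamming: int = 3
    diversity_ceiling: float = 0.75

    # QC gate
    d_min_nm: float = 20.0
    d_max_nm: float = 200.0
    pdi_max: float = 0.3
    qc_table: str | None = None            # synthetic when None
    qc_n_pass: int | None = 65             # designated passes for synthetic QC

    # pool
    total_dose_mg_per_kg: float = 1.5
    mrna_to_barcode_mass_ratio: float = 10.0

    # simulation
    cell_types: Sequence[str] = ("kupffer", "spleen_macrophage", "spleen_dc")
    n_mice: int = 3
    depth: int = 20_000
    input_depth: int = 100_000
    propensity_sdlog: float = 1.0
    control_factor: float = 0.1
    pcr_bias_sd: float = 0.5
    error_rate: float = 0.005
    reads_per_molecule: float = 10.0

    # counting
    anchor_max_mismatch: int = 1
    barcode_max_mismatch: int = 1

    # quantification / enrichment
    pseudocount: float = 0.5
    decile_fraction: float = 0.10
    n_boot: int = 0                        # 0 disables bootstrap intervals

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lipids"] = list(self.lipids)
        d["cholesterols"] = list(self.cholesterols)
        d["pegs"] = list(self.pegs)
        d["ratios"] = [list(r) for r in self.ratios]
        d["cell_types"] = list(self.cell_types)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # where results land does not change what they are
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_params(self) -> synthetic.SimParams:
        return synthetic.SimParams(
            propensity_sdlog=self.propensity_sdlog,
            control_factor=self.control_factor,
            pcr_bias_sd=self.pcr_bias_sd,
            error_rate=self.error_rate,
            reads_per_molecule=self.reads_per_molecule,
        )

    def count_params(self) -> counting.CountParams:
        return counting.CountParams(
            anchor_max_mismatch=self.anchor_max_mismatch,
            barcode_max_mismatch=self.barcode_max_mismatch,
        )


def validate_config(config: RunConfig) -> list[str]:
    """Collect every problem before failing; an empty list means valid."""
    errors: list[str] = []
    for name in ("lipids", "cholesterols", "pegs", "cell_types"):
        if not getattr(config, name):
            errors.append(f"{name} is empty")
    for i, ratio in enumerate(config.ratios):
        try:
            library._validate_ratio(ratio)
        except ValueError as exc:
            errors.append(f"ratios[{i}]: {exc}")
    if config.seed is None or int(config.seed) != config.seed:
        errors.append("seed must be an explicit integer")
    if not (0 < config.d_min_nm < config.d_max_nm):
        errors.append("QC bounds must satisfy 0 < d_min_nm < d_max_nm")
    if config.barcode_length < 1:
        errors.append("barcode_length must be >= 1")
    if not (1 <= config.min_hamming <= config.barcode_length):
        errors.append("min_hamming must be in [1, barcode_length]")
    if config.total_dose_mg_per_kg <= 0:
        errors.append("total_dose_mg_per_kg must be positive")
    if config.depth < 0 or config.input_depth < 0:
        errors.append("sequencing depths must be >= 0")
    if config.n_mice < 1:
        errors.append("n_mice must be >= 1")
    if not (0 < config.decile_fraction <= 0.5):
        errors.append("decile_fraction must be in (0, 0.5]")
    if config.pseudocount < 0:
        errors.append("pseudocount must be >= 0")
    if config.n_boot and config.n_boot < 100:
        errors.append("n_boot must be 0 (off) or >= 100")
    try:
        config.sim_params()
    except ValueError as exc:
        errors.append(f"simulation parameters: {exc}")
    for name in ("primer_table", "qc_table"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            errors.append(f"{name} path does not exist: {path}")
    n = (len(config.lipids) * len(config.cholesterols) * len(config.pegs)
         * len(config.ratios))
    if config.qc_n_pass is not None and not 0 < config.qc_n_pass <= n:
        errors.append(f"qc_n_pass must be in (0, {n}]")
    return errors


def _stage_seed(config: RunConfig, *key: int) -> int:
    ss = np.random.SeedSequence([int(config.seed), *key])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig,
                 index: bool = False, extra_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        for key, value in (extra_meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_manifest(stage: str, outdir: Path, config: RunConfig,
                    outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": sorted(str(p.relative_to(outdir)) for p in outputs),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_design(config: RunConfig) -> Path:
    """Barcode set + scaffolds + formulation library + QC + pool tables."""
    outdir = Path(config.outdir)
    design_dir = outdir / "design"
    design_dir.mkdir(parents=True, exist_ok=True)
    primer_set = barcodes.load_primer_set(config.primer_table)

    n_formulations = (len(config.lipids) * len(config.cholesterols)
                      * len(config.pegs) * len(config.ratios))
    bset = barcodes.generate_barcode_set(
        n=n_formulations + 1,                 # +1 naked control barcode
        length=config.barcode_length,
        min_hamming=config.min_hamming,
        seed=_stage_seed(config, 1),
        diversity_ceiling=config.diversity_ceiling,
    )
    barcodes.write_barcode_fasta(bset, design_dir / "barcodes.fasta")

    formulations = library.enumerate_formulations(
        config.lipids, config.cholesterols, config.pegs, config.helper,
        config.ratios, barcode_ids=bset.ids[:n_formulations],
    )
    _write_table(library.formulations_to_frame(formulations),
                 design_dir / "formulations.tsv", config)

    if config.qc_table is not None:
        qc_records = library.read_qc(config.qc_table)
    else:
        qc_records = synthetic.simulate_qc_table(
            formulations, seed=_stage_seed(config, 2), n_pass=config.qc_n_pass
        )
    _write_table(library.qc_to_frame(qc_records), design_dir / "qc.tsv", config)

    passed, _failed = library.apply_qc(
        formulations, qc_records, config.d_min_nm, config.d_max_nm, config.pdi_max
    )
    pool = library.build_pool(
        passed,
        control_barcode_id=bset.ids[n_formulations],
        total_dose_mg_per_kg=config.total_dose_mg_per_kg,
        mrna_to_barcode_mass_ratio=config.mrna_to_barcode_mass_ratio,
    )
    pool_df = library.pool_to_frame(pool)
    _write_table(
        pool_df, design_dir / "pool.tsv", config,
        extra_meta={
            "total_dose_mg_per_kg": pool.total_dose_mg_per_kg,
            "mrna_to_barcode_mass_ratio": pool.mrna_to_barcode_mass_ratio,
        },
    )
    _write_manifest("design", outdir, config, [
        design_dir / "barcodes.fasta", design_dir / "formulations.tsv",
        design_dir / "qc.tsv", design_dir / "pool.tsv",
    ])
    logger.info("design: %d formulations, %d pooled, per-particle dose %.3f mg/kg",
                n_formulations, len(pool.members), pool.per_particle_dose_mg_per_kg)
    return design_dir


def _load_design(config: RunConfig):
    design_dir = Path(config.outdir) / "design"
    bset = barcodes.read_barcode_fasta(design_dir / "barcodes.fasta")
    formulations = library.read_formulations(design_dir / "formulations.tsv")
    pool = library.read_pool(design_dir / "pool.tsv")
    primer_set = barcodes.load_primer_set(config.primer_table)
    return bset, formulations, pool, primer_set


def run_simulate(config: RunConfig) -> Path:
    """Ground truth + FASTQ per sorted-cell sample + the input pool sample."""
    outdir = Path(config.outdir)
    bset, formulations, pool, primer_set = _load_design(config)
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(parents=True, exist_ok=True)
    scaffolds = barcodes.assemble_scaffolds(bset, primer_set)

    truth = synthetic.simulate_ground_truth(
        pool, config.cell_types, config.sim_params(),
        seed=_stage_seed(config, 3),
        n_mice=config.n_mice, depth=config.depth, library=formulations,
    )
    outputs = []
    fastq_paths = {}
    truth_reads = []
    for i, sample in enumerate(truth.samples):
        reads = synthetic.simulate_sample_reads(
            truth, sample, scaffolds, primer_set, seed=_stage_seed(config, 4, i)
        )
        path = reads.write_fastq(fastq_dir / f"{sample.sample_id}.fastq.gz")
        fastq_paths[sample.sample_id] = str(path.relative_to(outdir))
        mols = reads.molecules.copy()
        mols.insert(0, "sample_id", sample.sample_id)
        truth_reads.append(mols)
        outputs.append(path)
    input_reads = synthetic.simulate_input_sample(
        pool, scaffolds, primer_set, depth=config.input_depth,
        seed=_stage_seed(config, 5), params=config.sim_params(),
    )
    input_path = input_reads.write_fastq(fastq_dir / "input.fastq.gz")
    outputs.append(input_path)

    sheet = synthetic.samples_to_frame(truth.samples, fastq_paths)
    _write_table(sheet, outdir / "sample_sheet.tsv", config)
    _write_table(
        truth.propensity.rename_axis("barcode_id"),
        outdir / "truth_propensity.tsv", config, index=True,
        extra_meta={"control": ",".join(f"{k}:{v:.6g}" for k, v in
                                        truth.control_propensity.items())},
    )
    _write_table(pd.concat(truth_reads, ignore_index=True),
                 outdir / "truth_molecules.tsv", config)
    outputs += [outdir / "sample_sheet.tsv", outdir / "truth_propensity.tsv",
                outdir / "truth_molecules.tsv"]
    _write_manifest("simulate", outdir, config, outputs)
    return fastq_dir


def run_count(config: RunConfig) -> Path:
    """Barcode/UMI counting for every sample in the sheet plus the input."""
    outdir = Path(config.outdir)
    bset, _formulations, _pool, primer_set = _load_design(config)
    sheet = pd.read_csv(outdir / "sample_sheet.tsv", sep="\t", comment="#")
    counts_dir = outdir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    params = config.count_params()
    tables = []
    outputs = []
    for row in sheet.itertuples():
        fastq = outdir / row.fastq
        if not fastq.exists():
            raise FileNotFoundError(
                f"sample {row.sample_id!r} in the sheet has no FASTQ at {fastq}"
            )
        table = counting.count_sample(
            fastq, bset, primer_set, params=params, sample_id=row.sample_id
        )
        path = counts_dir / f"{row.sample_id}.tsv"
        table.write_tsv(path, extra_meta={"config_hash": config.config_hash()})
        tables.append(table)
        outputs.append(path)
        logger.info("counted %s: %d reads, %.1f%% assigned",
                    row.sample_id, table.total_reads,
                    100 * table.assigned_fraction)
    input_table = counting.count_sample(
        outdir / "fastq" / "input.fastq.gz", bset, primer_set,
        params=params, sample_id="input",
    )
    input_table.write_tsv(counts_dir / "input.tsv",
                          extra_meta={"config_hash": config.config_hash()})
    tables.append(input_table)
    outputs.append(counts_dir / "input.tsv")
    _write_table(counting.qc_summary(tables), outdir / "counts_qc.tsv", config)
    outputs.append(outdir / "counts_qc.tsv")
    _write_manifest("count", outdir, config, outputs)
    return counts_dir


def run_quantify(config: RunConfig) -> Path:
    """Normalized delivery matrix, aggregates, ranks, and the control check."""
    outdir = Path(config.outdir)
    _bset, _formulations, pool, _primer_set = _load_design(config)
    sheet = pd.read_csv(outdir / "sample_sheet.tsv", sep="\t", comment="#")
    counts_dir = outdir / "counts"
    sample_tables = [
        counting.CountsTable.read_tsv(counts_dir / f"{sid}.tsv")
        for sid in sheet.sample_id
    ]
    input_table = counting.CountsTable.read_tsv(counts_dir / "input.tsv")

    pool_barcodes = list(pool.barcode_ids)
    for t in sample_tables + [input_table]:
        t.counts = t.counts.loc[pool_barcodes]
        t.unassigned_reads = t.total_reads - int(t.counts["raw_reads"].sum())
    matrix = quantify.build_delivery_matrix(
        sample_tables, input_table, pseudocount=config.pseudocount
    )
    grouping = {sid: "all" for sid in matrix.samples}
    grouping_ct = {row.sample_id: row.cell_type for row in sheet.itertuples()}
    aggregates, ranks = quantify.aggregate_and_rank(matrix, grouping)
    agg_ct, ranks_ct = quantify.aggregate_and_rank(matrix, grouping_ct)
    aggregates = aggregates.join(agg_ct)
    ranks = ranks.join(ranks_ct)
    report = quantify.control_check(aggregates, pool.control_barcode_id)

    matrix_path = outdir / "delivery_matrix.tsv"
    _write_table(matrix.values.rename_axis("barcode_id"), matrix_path,
                 config, index=True)
    _write_table(aggregates.rename_axis("barcode_id"),
                 outdir / "delivery_aggregates.tsv", config, index=True)
    _write_table(ranks.rename_axis("barcode_id"),
                 outdir / "delivery_ranks.tsv", config, index=True)
    _write_table(report, outdir / "control_report.tsv", config)
    _write_manifest("quantify", outdir, config, [
        matrix_path, outdir / "delivery_aggregates.tsv",
        outdir / "delivery_ranks.tsv", outdir / "control_report.tsv",
    ])
    if not report.loc[report.group == "all", "is_lowest"].all():
        logger.warning("negative-control check FAILED in the all-samples group")
    return matrix_path


def run_enrich(config: RunConfig) -> Path:
    """Top/bottom-decile fold enrichment per component axis."""
    outdir = Path(config.outdir)
    _bset, formulations, pool, _primer_set = _load_design(config)
    ranks = pd.read_csv(outdir / "delivery_ranks.tsv", sep="\t", comment="#",
                        index_col="barcode_id")
    values = pd.read_csv(outdir / "delivery_matrix.tsv", sep="\t", comment="#",
                         index_col="barcode_id")
    screened = [f for f in formulations if f.barcode_id in pool.member_barcodes]
    member_ranks = ranks.loc[[f.barcode_id for f in screened], "all"]
    # re-rank within the screened set (control excluded)
    member_ranks = member_ranks.rank(method="first").astype(int)
    table = enrichment.enrichment_table(
        member_ranks, screened, fraction=config.decile_fraction
    )
    if config.n_boot:
        ci_frames = []
        member_values = values.loc[[f.barcode_id for f in screened]]
        for axis in library.COMPONENT_AXES:
            ci_frames.append(
                enrichment.bootstrap_enrichment(
                    member_values, screened, axis, n_boot=config.n_boot,
                    seed=_stage_seed(config, 6), fraction=config.decile_fraction,
                )
            )
        ci = pd.concat(ci_frames, ignore_index=True)
        table = table.merge(ci[["axis", "level", "direction", "ci_low", "ci_high"]],
                            on=["axis", "level", "direction"], how="left")
    path = outdir / "enrichment.tsv"
    _write_table(table, path, config)
    _write_manifest("enrich", outdir, config, [path])
    return path


def run_all(config: RunConfig) -> Path:
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    run_design(config)
    run_simulate(config)
    run_count(config)
    run_quantify(config)
    run_enrich(config)
    return Path(config.outdir)
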