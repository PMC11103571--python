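"""End-to-end pipeline: read -> identification filter -> normalize -> log2 ->
QC -> imputation -> differential expression -> evaluation.

Every stage writes its output into the run directory and appends a count
line to ``stages.tsv`` (in = out + removed reconciles by construction).
All randomness flows from a single top-level seed through named substreams,
so single-stage reruns are stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scpquant import de_stats, evaluation, imputation, io_tables, normalization, qc
from scpquant.matrix import QuantMatrix

logger = logging.getLogger(__name__)


_STAGE_IDS = {"imputation": 1, "kmeans": 2, "synthesis": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the top-level seed (named substreams)."""
    sid = _STAGE_IDS.get(stage)
    if sid is None:
        raise KeyError(f"unknown stage {stage!r}")
    return int(np.random.SeedSequence([seed, sid]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    psm_paths: list[str]
    annotation_path: str
    protein_groups_path: str | None = None
    out_dir: str = "run"
    ratio_mode: str = "reference"
    weight_exponent: float = 0.75
    thresholds: qc.FilterThresholds = field(default_factory=qc.FilterThresholds)
    imputation: imputation.ImputationParams = field(
        default_factory=lambda: imputation.ImputationParams(down_shift=1.0)
    )
    q_cutoff: float = 0.05
    group_by: str = "cell_type"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = qc.FilterThresholds(**raw.pop("thresholds", {}))
        imp = imputation.ImputationParams(**raw.pop("imputation", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=thresholds, imputation=imp, **raw)


@dataclass
class PipelineResult:
    out_dir: Path
    stages: pd.DataFrame
    de_table: pd.DataFrame
    matrix_final: QuantMatrix
    warnings: list[str]


class _StageLog:
    def __init__(self) -> None:
        self.rows: list[dict] = []

    def add(self, stage: str, proteins_in: int, proteins_out: int,
            samples_in: int, samples_out: int, note: str = "") -> None:
        self.rows.append(
            {
                "stage": stage,
                "proteins_in": proteins_in, "proteins_out": proteins_out,
                "proteins_removed": proteins_in - proteins_out,
                "samples_in": samples_in, "samples_out": samples_out,
                "samples_removed": samples_in - samples_out,
                "note": note,
            }
        )
        logger.info("stage %-22s proteins %d->%d, samples %d->%d %s",
                    stage, proteins_in, proteins_out, samples_in, samples_out, note)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _StageLog()
    warnings: list[str] = []

    # 1. read
    psms = []
    for p in config.psm_paths:
        psms.extend(io_tables.read_psm_table(p))
    annotation = io_tables.read_annotation(config.annotation_path)
    if config.protein_groups_path:
        protein_groups = io_tables.read_protein_groups(config.protein_groups_path)
    else:
        protein_groups = []
    n_prot_in = len({p.protein_id for p in psms})
    log.add("read", n_prot_in, n_prot_in, 0, 0, f"{len(psms)} PSMs")

    # 2. identification filter
    psms, protein_groups = io_tables.filter_identifications(psms, protein_groups)
    n_prot = len({p.protein_id for p in psms})
    log.add("identification_filter", n_prot_in, n_prot, 0, 0)

    # 3. PSM normalization + 4. log2
    matrix = normalization.normalize_protein_table(
        psms, annotation, mode=config.ratio_mode,
        weight_exponent=config.weight_exponent, keep_control_channels=True,
    )
    io_tables.write_quant_matrix(matrix, out_dir / "03_normalized.tsv")
    log.add("normalize", n_prot, matrix.n_proteins, matrix.n_samples, matrix.n_samples)
    matrix = normalization.log2_transform(matrix)
    io_tables.write_quant_matrix(matrix, out_dir / "04_log2.tsv")
    log.add("log2", matrix.n_proteins, matrix.n_proteins, matrix.n_samples, matrix.n_samples)

    # 5. missingness profile (pre-filter)
    profile = qc.missingness_profile(matrix, annotation)
    profile.to_csv(out_dir / "05_missingness.tsv", sep="\t")
    log.add("missingness_profile", matrix.n_proteins, matrix.n_proteins,
            matrix.n_samples, matrix.n_samples,
            f"{int(profile['above_cutoff'].sum())} samples above cutoff")

    # 6. cell filter
    after_cells = qc.cell_filter(matrix, config.thresholds.min_valid_within_cell)
    io_tables.write_quant_matrix(after_cells, out_dir / "06_cell_filtered.tsv")
    log.add("cell_filter", matrix.n_proteins, after_cells.n_proteins,
            matrix.n_samples, after_cells.n_samples)

    # 7. protein filter
    after_prot = qc.protein_filter(after_cells, config.thresholds.min_valid_across_samples)
    io_tables.write_quant_matrix(after_prot, out_dir / "07_protein_filtered.tsv")
    log.add("protein_filter", after_cells.n_proteins, after_prot.n_proteins,
            after_cells.n_samples, after_prot.n_samples)

    # 8. min-PSM filter (drop control/empty channels before DE too)
    counts = qc.psm_counts_from_records(psms)
    after_psm = qc.min_psm_filter(after_prot, counts, config.thresholds.min_psm_count)
    if after_psm.sample_meta is not None:
        keep = after_psm.sample_meta["role"] == "single_cell"
        after_psm = after_psm.subset(samples=after_psm.samples[keep.to_numpy()])
    io_tables.write_quant_matrix(after_psm, out_dir / "08_min_psm_filtered.tsv")
    log.add("min_psm_filter", after_prot.n_proteins, after_psm.n_proteins,
            after_prot.n_samples, after_psm.n_samples)

    # 9. imputation
    imp_params = imputation.ImputationParams(
        down_shift=config.imputation.down_shift, width=config.imputation.width,
        scope=config.imputation.scope, seed=stage_seed(config.seed, "imputation"),
    )
    complete, imputed_mask = imputation.downshift_impute(after_psm, imp_params)
    io_tables.write_quant_matrix(complete, out_dir / "09_imputed.tsv")
    report = imputation.distribution_report(complete, imputed_mask)
    note = "bimodal imputed distribution" if report.bimodal else ""
    if report.bimodal:
        warnings.append(
            f"imputed values form a separate mode (gap {report.mode_gap_sd:.2f} SD); "
            f"consider lowering --down-shift below 1.0"
        )
    log.add("imputation", complete.n_proteins, complete.n_proteins,
            complete.n_samples, complete.n_samples, note)

    # 10. DE + volcano + evaluation
    labels = complete.sample_meta[config.group_by]
    results = de_stats.moderated_t_test(complete, labels, q_cutoff=config.q_cutoff)
    volcano = de_stats.volcano_table(results, q_cutoff=config.q_cutoff)
    volcano.to_csv(out_dir / "10_de_volcano.tsv", sep="\t")
    log.add("de", complete.n_proteins, complete.n_proteins,
            complete.n_samples, complete.n_samples,
            f"{int(volcano['significant'].sum())} significant at q<={config.q_cutoff}")

    embedding = evaluation.pca_embed(complete, labels=labels)
    coords = embedding.coordinates.copy()
    coords["label"] = embedding.labels
    coords.to_csv(out_dir / "11_pca.tsv", sep="\t")
    accuracy = evaluation.cluster_accuracy(embedding, seed=stage_seed(config.seed, "kmeans"))
    log.add("evaluate", complete.n_proteins, complete.n_proteins,
            complete.n_samples, complete.n_samples, f"cluster accuracy {accuracy:.3f}")

    stages = log.frame()
    stages.to_csv(out_dir / "stages.tsv", sep="\t", index=False)
    if warnings:
        (out_dir / "warnings.txt").write_text("\n".join(warnings) + "\n")
    return PipelineResult(out_dir, stages, volcano, complete, warnings)
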