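"""Synthetic multiplexed single-cell proteomics data.

Emits PSM tables in the evidence-table dialect read by
:mod:`scpquant.io_tables`, together with a channel annotation table, a
protein-group table and a ground-truth record. The design mirrors a
TMT-style single-cell experiment: each batch carries one carrier channel
(boosted signal), one pooled reference channel (the ratio denominator), one
cell-free control channel, and the remaining channels hold single cells of
two types.

Missingness is missing-not-at-random: the probability that a reporter value
is detected is logistic in its true log2 intensity, with the location
parameter calibrated by Monte Carlo so single-cell channels hit a target
missing rate. A configurable subset of cells is "low quality" with a higher
missing rate, and a subset of proteins carries planted log2 fold-changes
between the two cell types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from scpquant.io_tables import AnnotationSet, ChannelAnnotation

EVIDENCE_COLUMNS_PREFIX = ["Raw file", "Leading razor protein"]


@dataclass
class SynthConfig:
    n_batches: int = 8
    channels_per_batch: int = 18
    n_proteins: int = 1000
    carrier_boost: float = 100.0     # carrier signal multiple of the reference
    reference_boost: float = 5.0     # pooled reference loading vs one cell
    psm_lambda: float = 2.0          # PSMs per protein-batch = 1 + Poisson(lambda)
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    fraction_dep: float = 0.2
    dep_log2fc_choices: tuple[float, ...] = (0.5, 1.0, 2.0)  # magnitude; sign random
    batch_shift_sd: float = 0.5      # log2-scale batch intensity shift
    psm_noise_sd: float = 0.3        # log2-scale per-PSM-channel noise
    missing_target: float = 0.40     # single-cell channel missing rate
    logistic_slope: float = 1.0      # detection-probability slope per log2 unit
    low_quality_fraction: float = 0.1
    low_quality_missing_target: float = 0.70
    control_log2_offset: float = -8.0  # control channel signal vs one cell
    cell_types: tuple[str, str] = ("melanoma", "monocyte")
    n_decoys: int = 10
    n_contaminants: int = 5

    def __post_init__(self) -> None:
        for p in (self.fraction_dep, self.missing_target, self.low_quality_fraction,
                  self.low_quality_missing_target):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.missing_target > 0.99 or self.low_quality_missing_target > 0.99:
            raise ValueError("missingness target above 0.99 is infeasible")
        if self.carrier_boost < 1:
            raise ValueError("carrier_boost must be >= 1")
        if self.channels_per_batch < 5:
            raise ValueError("need at least 5 channels (carrier/reference/control + 2 cells)")


@dataclass
class GroundTruth:
    cell_type: dict[str, str]            # sample_id -> cell type
    dep_log2fc: dict[str, float]         # protein -> planted log2 FC (type2 - type1)
    low_quality_cells: list[str]
    batch_shift: dict[str, float]
    detection_location: float
    detection_location_low_quality: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class SynthDataset:
    psm_tables: dict[str, pd.DataFrame]  # batch id -> evidence-dialect table
    protein_groups: pd.DataFrame
    annotation: AnnotationSet
    ground_truth: GroundTruth
    config: SynthConfig

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for batch, df in self.psm_tables.items():
            df.to_csv(out_dir / f"{batch}.evidence.tsv", sep="\t", index=False)
        self.protein_groups.to_csv(out_dir / "proteinGroups.tsv", sep="\t", index=False)
        self.annotation.to_frame().to_csv(out_dir / "annotation.tsv", sep="\t", index=False)
        (out_dir / "ground_truth.json").write_text(self.ground_truth.to_json())


def _calibrate_location(log2_values: np.ndarray, slope: float, missing_target: float) -> float:
    """Find gamma with mean(1 - sigmoid(slope * (L - gamma))) == missing_target."""
    if missing_target <= 0:
        return float(log2_values.min() - 50.0)

    def missing_rate(gamma: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(np.clip(slope * (log2_values - gamma), -500, 500)))))

    lo, hi = float(log2_values.min() - 60), float(log2_values.max() + 60)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if missing_rate(mid) < missing_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _batch_layout(config: SynthConfig, batch: str) -> list[ChannelAnnotation]:
    """Channel 0 carrier, 1 reference, 2 control, the rest single cells (alternating types)."""
    anns = [
        ChannelAnnotation(batch, 0, "carrier"),
        ChannelAnnotation(batch, 1, "reference"),
        ChannelAnnotation(batch, 2, "control"),
    ]
    for c in range(3, config.channels_per_batch):
        anns.append(ChannelAnnotation(batch, c, "single_cell",
                                      config.cell_types[(c - 3) % 2]))
    return anns


def generate_dataset(config: SynthConfig | None = None, seed: int = 0) -> SynthDataset:
    """Generate a full synthetic experiment; identical (config, seed) -> identical output."""
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(seed)
    batches = [f"batch{b + 1:02d}" for b in range(config.n_batches)]
    proteins = [f"PROT{p + 1:04d}" for p in range(config.n_proteins)]

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=config.n_proteins)
    n_dep = int(round(config.fraction_dep * config.n_proteins))
    dep_idx = rng.choice(config.n_proteins, size=n_dep, replace=False)
    magnitudes = rng.choice(config.dep_log2fc_choices, size=n_dep)
    signs = rng.choice([-1.0, 1.0], size=n_dep)
    fc = np.zeros(config.n_proteins)
    fc[dep_idx] = magnitudes * signs
    batch_shift = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)

    annotations: list[ChannelAnnotation] = []
    for batch in batches:
        annotations.extend(_batch_layout(config, batch))
    annotation = AnnotationSet(annotations)

    single_cells = [a for a in annotation if a.role == "single_cell"]
    n_lq = int(round(config.low_quality_fraction * len(single_cells)))
    lq_pick = rng.choice(len(single_cells), size=n_lq, replace=False)
    low_quality = {single_cells[i].sample_id for i in lq_pick}

    type_effect = {config.cell_types[0]: 0.0, config.cell_types[1]: 1.0}
    log2_ref_boost = np.log2(config.reference_boost)
    log2_carrier = np.log2(config.carrier_boost)

    # true log2 signal per (batch, protein, channel), before noise/censoring
    def channel_signal(ann: ChannelAnnotation, b: int, p: np.ndarray) -> np.ndarray:
        if ann.role == "single_cell":
            return base[p] + fc[p] * type_effect[ann.cell_type] + batch_shift[b]
        if ann.role == "reference":
            return base[p] + 0.5 * fc[p] + log2_ref_boost + batch_shift[b]
        if ann.role == "carrier":
            return base[p] + 0.5 * fc[p] + log2_ref_boost + log2_carrier + batch_shift[b]
        if ann.role == "control":
            return base[p] + config.control_log2_offset + batch_shift[b]
        return np.full(len(p), -np.inf)  # unused/empty: no signal

    # PSM counts drawn once so the calibration pass sees the real design
    psm_counts = 1 + rng.poisson(config.psm_lambda, size=(config.n_batches, config.n_proteins))

    # calibration sample of single-cell true log2 values (noise included);
    # batch shifts are excluded here and added back to the per-batch detection
    # location, so every batch hits the same target missing rate
    calib = []
    for b in range(config.n_batches):
        reps = np.repeat(np.arange(config.n_proteins), psm_counts[b])
        calib.append(base[reps])
        calib.append(base[reps] + fc[reps])
    calib_values = np.concatenate(calib) + rng.normal(0.0, config.psm_noise_sd, size=sum(len(c) for c in calib))
    gamma = _calibrate_location(calib_values, config.logistic_slope, config.missing_target)
    gamma_lq = _calibrate_location(calib_values, config.logistic_slope, config.low_quality_missing_target)

    psm_tables: dict[str, pd.DataFrame] = {}
    reporter_cols = [f"Reporter intensity corrected {c + 1}" for c in range(config.channels_per_batch)]
    all_protein_ids = list(proteins)
    decoys = [f"REV__DECOY{p + 1:03d}" for p in range(config.n_decoys)]
    contaminants = [f"CON__CONTAM{p + 1:03d}" for p in range(config.n_contaminants)]

    total_counts: dict[str, int] = {pid: 0 for pid in all_protein_ids + decoys + contaminants}

    for b, batch in enumerate(batches):
        anns = annotation.channels(batch)
        n_psms = int(psm_counts[b].sum())
        protein_of_psm = np.repeat(np.arange(config.n_proteins), psm_counts[b])
        signal = np.empty((n_psms, config.channels_per_batch))
        for ann in anns:
            signal[:, ann.channel_index] = channel_signal(ann, b, protein_of_psm)
        signal += rng.normal(0.0, config.psm_noise_sd, size=signal.shape)

        # MNAR censoring: detection is logistic in the true log2 intensity;
        # the location follows the batch shift so missingness is batch-uniform
        locations = np.full(config.channels_per_batch, gamma + batch_shift[b])
        for ann in anns:
            if ann.sample_id in low_quality:
                locations[ann.channel_index] = gamma_lq + batch_shift[b]
        with np.errstate(over="ignore"):
            p_detect = 1.0 / (1.0 + np.exp(-config.logistic_slope * (signal - locations[None, :])))
        detected = rng.random(size=signal.shape) < p_detect

        intensity = np.power(2.0, signal)
        intensity[~detected] = 0.0  # evidence dialect: 0 encodes non-detection

        precursor = np.power(2.0, base[protein_of_psm] + batch_shift[b] + rng.normal(0, 1, size=n_psms)) * 50.0
        fill_time = rng.uniform(5.0, 50.0, size=n_psms)

        rows = {
            "Raw file": [batch] * n_psms,
            "Leading razor protein": [proteins[p] for p in protein_of_psm],
        }
        for c, col in enumerate(reporter_cols):
            rows[col] = intensity[:, c]
        rows["Intensity"] = precursor
        rows["Ion injection time"] = fill_time
        rows["Reverse"] = [""] * n_psms
        rows["Potential contaminant"] = [""] * n_psms
        df = pd.DataFrame(rows)

        # a handful of decoy/contaminant PSMs to exercise identification filtering
        extra_rows = []
        for pid, flag in [(d, "Reverse") for d in decoys] + [(c, "Potential contaminant") for c in contaminants]:
            if rng.random() < 0.5:
                continue
            vals = np.power(2.0, rng.normal(config.base_log2_mean, config.base_log2_sd,
                                            size=config.channels_per_batch))
            row = {"Raw file": batch, "Leading razor protein": pid,
                   "Intensity": float(np.power(2.0, rng.normal(config.base_log2_mean, 1.0)) * 50),
                   "Ion injection time": float(rng.uniform(5, 50)),
                   "Reverse": "+" if flag == "Reverse" else "",
                   "Potential contaminant": "+" if flag == "Potential contaminant" else ""}
            for c, col in enumerate(reporter_cols):
                row[col] = vals[c]
            extra_rows.append(row)
            total_counts[pid] += 1
        if extra_rows:
            df = pd.concat([df, pd.DataFrame(extra_rows)], ignore_index=True)

        for p, count in zip(*np.unique(protein_of_psm, return_counts=True)):
            total_counts[proteins[p]] += int(count)
        psm_tables[batch] = df

    pg_rows = []
    for pid in all_protein_ids + decoys + contaminants:
        pg_rows.append(
            {
                "Protein IDs": pid,
                "Gene names": pid.replace("PROT", "GENE"),
                "Reverse": "+" if pid.startswith("REV__") else "",
                "Potential contaminant": "+" if pid.startswith("CON__") else "",
                "Only identified by site": "",
                "MS/MS count": total_counts[pid],
            }
        )
    protein_groups = pd.DataFrame(pg_rows)

    truth = GroundTruth(
        cell_type={a.sample_id: a.cell_type for a in single_cells},
        dep_log2fc={proteins[i]: float(fc[i]) for i in sorted(dep_idx)},
        low_quality_cells=sorted(low_quality),
        batch_shift={batches[b]: float(batch_shift[b]) for b in range(config.n_batches)},
        detection_location=float(gamma),
        detection_location_low_quality=float(gamma_lq),
    )
    return SynthDataset(psm_tables, protein_groups, annotation, truth, config)


def emulate_mbr_off(
    psm_tables: dict[str, pd.DataFrame], dropout_rate: float, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Drop whole protein-batch blocks with the given probability.

    Models a peptide never selected for MS/MS in a run when cross-run
    identification transfer is unavailable, which raises cross-batch
    missingness without touching surviving blocks.
    """
    if not 0 <= dropout_rate <= 1:
        raise ValueError(f"dropout_rate out of [0, 1]: {dropout_rate}")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for batch in psm_tables:
        df = psm_tables[batch]
        proteins = df["Leading razor protein"].unique()
        dropped = set(proteins[rng.random(len(proteins)) < dropout_rate])
        out[batch] = df[~df["Leading razor protein"].isin(dropped)].reset_index(drop=True)
    return out
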