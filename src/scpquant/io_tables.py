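"""Readers/writers for PSM tables, protein-group tables and channel annotations.

The default column dialect follows the MaxQuant ``evidence.txt`` /
``proteinGroups.txt`` conventions, but every column name is configuration
data (:class:`Dialect`), so other search engines can be accommodated without
code changes.

Reporter intensities of 0 or blank are recorded as *missing*, never as a
true zero: an isobaric reporter signal of 0 indicates non-detection
(left-censoring), not absence of protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from scpquant.matrix import QuantMatrix

logger = logging.getLogger(__name__)

CHANNEL_ROLES = frozenset(
    {"carrier", "reference", "control", "unused", "empty", "single_cell"}
)

#: roles removed from quantification output columns unconditionally
NON_SAMPLE_ROLES = frozenset({"carrier", "reference", "unused"})


class TableFormatError(ValueError):
    """Malformed input table (bad value, duplicate key, unknown role...)."""


class DialectError(ValueError):
    """The configured column dialect does not match the file."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a PSM (evidence-style) table.

    ``reporter_pattern`` is formatted with the 1-based channel number; the
    reader probes consecutive numbers starting at ``reporter_start`` to
    discover the channel count.
    """

    reporter_pattern: str = "Reporter intensity corrected {}"
    reporter_start: int = 1
    precursor_column: str = "Intensity"
    fill_time_column: str = "Ion injection time"
    protein_column: str = "Leading razor protein"
    batch_column: str = "Raw file"
    reverse_column: str = "Reverse"
    contaminant_column: str = "Potential contaminant"
    flag_true: str = "+"


#: raw reporter intensities instead of impurity-corrected ones
RAW_REPORTER_DIALECT = Dialect(reporter_pattern="Reporter intensity {}")


@dataclass(frozen=True)
class ProteinGroupDialect:
    """Column mapping for a proteinGroups-style table."""

    protein_column: str = "Protein IDs"
    gene_column: str = "Gene names"
    reverse_column: str = "Reverse"
    contaminant_column: str = "Potential contaminant"
    site_only_column: str = "Only identified by site"
    psm_count_column: str = "MS/MS count"
    flag_true: str = "+"


@dataclass
class PSMRecord:
    """One PSM row: per-channel reporter intensities plus weighting metadata.

    ``reporter_intensity`` holds NaN for missing channels (0/blank on disk).
    """

    psm_id: str
    protein_id: str
    batch_id: str
    reporter_intensity: np.ndarray
    precursor_intensity: float
    fill_time: float
    is_reverse: bool = False
    is_contaminant: bool = False
    is_site_only: bool = False

    @property
    def n_channels(self) -> int:
        return len(self.reporter_intensity)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.reporter_intensity)


@dataclass(frozen=True)
class ChannelAnnotation:
    """Role and cell type of one (batch, channel) slot."""

    batch_id: str
    channel_index: int
    role: str
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise TableFormatError(
                f"unknown channel role {self.role!r}; expected one of {sorted(CHANNEL_ROLES)}"
            )
        if self.role == "single_cell" and not self.cell_type:
            raise TableFormatError(
                f"single_cell channel ({self.batch_id}, {self.channel_index}) lacks a cell_type"
            )

    @property
    def sample_id(self) -> str:
        return f"{self.batch_id}:{self.channel_index}"


@dataclass
class ProteinGroupRecord:
    protein_id: str
    gene_name: str = ""
    is_reverse: bool = False
    is_contaminant: bool = False
    is_site_only: bool = False
    psm_count: int = 0

    @property
    def flagged(self) -> bool:
        return self.is_reverse or self.is_contaminant or self.is_site_only


class AnnotationSet:
    """Validated set of channel annotations, indexed by (batch, channel)."""

    def __init__(self, annotations: list[ChannelAnnotation]):
        seen: dict[tuple[str, int], ChannelAnnotation] = {}
        refs: dict[str, int] = {}
        for ann in annotations:
            key = (ann.batch_id, ann.channel_index)
            if key in seen:
                raise TableFormatError(f"duplicate annotation for (batch, channel) {key}")
            seen[key] = ann
            if ann.role == "reference":
                refs[ann.batch_id] = refs.get(ann.batch_id, 0) + 1
        for batch, count in refs.items():
            if count > 1:
                raise TableFormatError(
                    f"batch {batch!r} has {count} reference channels (at most 1 allowed)"
                )
        self._by_key = seen

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def __getitem__(self, key: tuple[str, int]) -> ChannelAnnotation:
        return self._by_key[key]

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._by_key

    @property
    def batches(self) -> list[str]:
        out: list[str] = []
        for ann in self._by_key.values():
            if ann.batch_id not in out:
                out.append(ann.batch_id)
        return out

    def channels(self, batch_id: str, role: str | None = None) -> list[ChannelAnnotation]:
        anns = [a for a in self._by_key.values() if a.batch_id == batch_id]
        if role is not None:
            anns = [a for a in anns if a.role == role]
        return sorted(anns, key=lambda a: a.channel_index)

    def reference_channel(self, batch_id: str) -> int | None:
        refs = self.channels(batch_id, "reference")
        return refs[0].channel_index if refs else None

    def sample_channels(self, batch_id: str, keep_control: bool = True) -> list[ChannelAnnotation]:
        """Channels that become output columns: single cells, optionally controls/empties."""
        keep = {"single_cell"} | ({"control", "empty"} if keep_control else set())
        return [a for a in self.channels(batch_id) if a.role in keep]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "batch": a.batch_id,
                "channel": a.channel_index,
                "role": a.role,
                "cell_type": a.cell_type if a.cell_type is not None else "",
            }
            for a in self
        ]
        return pd.DataFrame(rows)


def _parse_flag(value, true_token: str) -> bool:
    if pd.isna(value):
        return False
    return str(value).strip() == true_token


def _discover_reporter_columns(columns: list[str], dialect: Dialect) -> list[str]:
    found = []
    i = dialect.reporter_start
    while dialect.reporter_pattern.format(i) in columns:
        found.append(dialect.reporter_pattern.format(i))
        i += 1
    return found


def read_psm_table(
    path: str | Path,
    dialect: Dialect = Dialect(),
    batch_id: str | None = None,
) -> list[PSMRecord]:
    """Read a tab-delimited PSM (evidence-style) table.

    Reporter values of 0 or blank are marked missing (NaN). If the table has
    no batch column and ``batch_id`` is not given, the file name stem is used.
    Missing fill-time values are kept as NaN; the weighting stage falls back
    to precursor intensity alone for those PSMs.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    reporter_cols = _discover_reporter_columns(list(df.columns), dialect)
    if not reporter_cols:
        raise DialectError(
            f"no reporter columns matching {dialect.reporter_pattern!r} in {path.name}"
        )
    for col in (dialect.precursor_column, dialect.fill_time_column, dialect.protein_column):
        if col not in df.columns:
            raise DialectError(f"mandatory column {col!r} missing from {path.name}")

    def _num(series: pd.Series, col: str) -> np.ndarray:
        out = pd.to_numeric(series, errors="coerce")
        bad = out.isna() & series.notna() & (series.str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"non-numeric value {series.iloc[row]!r} in column {col!r}, row {row + 2} of {path.name}"
            )
        return out.to_numpy(dtype=float)

    reporters = np.column_stack([_num(df[c], c) for c in reporter_cols])
    reporters[reporters == 0.0] = np.nan  # 0 == non-detection, not true zero
    precursor = _num(df[dialect.precursor_column], dialect.precursor_column)
    fill_time = _num(df[dialect.fill_time_column], dialect.fill_time_column)

    if dialect.batch_column in df.columns:
        batches = df[dialect.batch_column].fillna("").astype(str)
    else:
        batches = pd.Series([batch_id or path.stem] * len(df))

    rev = df[dialect.reverse_column] if dialect.reverse_column in df.columns else pd.Series([None] * len(df))
    con = (
        df[dialect.contaminant_column]
        if dialect.contaminant_column in df.columns
        else pd.Series([None] * len(df))
    )

    records = []
    for i in range(len(df)):
        records.append(
            PSMRecord(
                psm_id=f"{path.stem}:{i}",
                protein_id=str(df[dialect.protein_column].iloc[i]),
                batch_id=str(batches.iloc[i]),
                reporter_intensity=reporters[i].copy(),
                precursor_intensity=float(precursor[i]) if np.isfinite(precursor[i]) else np.nan,
                fill_time=float(fill_time[i]) if np.isfinite(fill_time[i]) else np.nan,
                is_reverse=_parse_flag(rev.iloc[i], dialect.flag_true),
                is_contaminant=_parse_flag(con.iloc[i], dialect.flag_true),
            )
        )
    logger.info("read %d PSMs (%d channels) from %s", len(records), len(reporter_cols), path.name)
    return records


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read a channel annotation table (columns: batch, channel, role, cell_type)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("batch", "channel", "role"):
        if col not in df.columns:
            raise DialectError(f"annotation table lacks mandatory column {col!r}")
    annotations = []
    for _, row in df.iterrows():
        cell_type = row.get("cell_type")
        if pd.isna(cell_type) or str(cell_type).strip() == "":
            cell_type = None
        annotations.append(
            ChannelAnnotation(
                batch_id=str(row["batch"]).strip(),
                channel_index=int(row["channel"]),
                role=str(row["role"]).strip(),
                cell_type=cell_type,
            )
        )
    return AnnotationSet(annotations)


def write_annotation(annotations: AnnotationSet, path: str | Path) -> None:
    annotations.to_frame().to_csv(path, sep="\t", index=False)


def read_protein_groups(
    path: str | Path, dialect: ProteinGroupDialect = ProteinGroupDialect()
) -> list[ProteinGroupRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect.protein_column not in df.columns:
        raise DialectError(f"mandatory column {dialect.protein_column!r} missing from {path.name}")

    def flag(col: str) -> pd.Series:
        if col in df.columns:
            return df[col].map(lambda v: _parse_flag(v, dialect.flag_true))
        return pd.Series([False] * len(df))

    counts = (
        pd.to_numeric(df[dialect.psm_count_column], errors="coerce").fillna(0).astype(int)
        if dialect.psm_count_column in df.columns
        else pd.Series([0] * len(df))
    )
    gene = df[dialect.gene_column] if dialect.gene_column in df.columns else pd.Series([""] * len(df))
    rev, con, site = flag(dialect.reverse_column), flag(dialect.contaminant_column), flag(dialect.site_only_column)
    return [
        ProteinGroupRecord(
            protein_id=str(df[dialect.protein_column].iloc[i]),
            gene_name="" if pd.isna(gene.iloc[i]) else str(gene.iloc[i]),
            is_reverse=bool(rev.iloc[i]),
            is_contaminant=bool(con.iloc[i]),
            is_site_only=bool(site.iloc[i]),
            psm_count=int(counts.iloc[i]),
        )
        for i in range(len(df))
    ]


def filter_identifications(
    psms: list[PSMRecord], protein_groups: list[ProteinGroupRecord]
) -> tuple[list[PSMRecord], list[ProteinGroupRecord]]:
    """Drop reverse / contaminant / site-only proteins and their PSMs.

    Also drops PSMs carrying their own reverse/contaminant flags. Idempotent.
    """
    removed = {pg.protein_id for pg in protein_groups if pg.flagged}
    kept_groups = [pg for pg in protein_groups if not pg.flagged]
    kept_psms = [
        p
        for p in psms
        if p.protein_id not in removed and not (p.is_reverse or p.is_contaminant or p.is_site_only)
    ]
    logger.info(
        "identification filter: %d/%d protein groups kept, %d/%d PSMs kept",
        len(kept_groups), len(protein_groups), len(kept_psms), len(psms),
    )
    return kept_psms, kept_groups


def write_quant_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    """Write a proteins x samples TSV with "NA" for missing; scale in a header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep="\t", na_rep="NA", index_label="protein_id")


def read_quant_matrix(path: str | Path) -> QuantMatrix:
    """Read a matrix written by :func:`write_quant_matrix` (lossless round-trip)."""
    path = Path(path)
    scale = "linear"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# scale="):
            scale = first.strip().split("=", 1)[1]
            skip = 1
        else:
            skip = 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, na_values=["NA"], index_col="protein_id")
    df.index = df.index.astype(str)
    return QuantMatrix(df, scale=scale)
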