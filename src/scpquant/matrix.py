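"""Protein-by-sample quantification matrix with an explicit missing mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("linear", "log2")


@dataclass
class QuantMatrix:
    """Proteins x samples matrix.

    Missing values are carried as NaN in ``data``; ``mask`` exposes them as a
    boolean DataFrame (True = missing). ``scale`` records whether the values
    are linear-scale ratios/intensities or log2-transformed.
    """

    data: pd.DataFrame
    scale: str = "linear"
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        self.data = self.data.astype(float)
        if self.sample_meta is not None:
            missing = [c for c in self.data.columns if c not in self.sample_meta.index]
            if missing:
                raise ValueError(f"sample_meta lacks entries for columns: {missing[:5]}")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value mask (True where missing)."""
        return self.data.isna()

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def valid_fraction_per_sample(self) -> pd.Series:
        """Fraction of non-missing entries per column."""
        return self.data.notna().mean(axis=0)

    def valid_fraction_per_protein(self) -> pd.Series:
        """Fraction of non-missing entries per row."""
        return self.data.notna().mean(axis=1)

    def subset(self, proteins=None, samples=None) -> "QuantMatrix":
        data = self.data
        if proteins is not None:
            data = data.loc[proteins]
        if samples is not None:
            data = data[samples]
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[data.columns]
        return QuantMatrix(data.copy(), scale=self.scale, sample_meta=meta)

    def copy(self) -> "QuantMatrix":
        meta = self.sample_meta.copy() if self.sample_meta is not None else None
        return QuantMatrix(self.data.copy(), scale=self.scale, sample_meta=meta)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuantMatrix):
            return NotImplemented
        if self.scale != other.scale:
            return False
        if not self.data.index.equals(other.data.index):
            return False
        if not self.data.columns.equals(other.data.columns):
            return False
        a, b = self.data.to_numpy(), other.data.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        return bool(np.all(both_nan | np.isclose(a, b, rtol=1e-12, atol=0, equal_nan=False)))
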