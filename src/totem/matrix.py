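"""The samples x markers interchange table (MFC / n_informative / coverage).

``MarkerMatrix`` is the hand-off object between quantification, marker
selection, scoring, and CSO classification.  Internally it keeps three
aligned wide DataFrames (samples x markers); ``mfr`` is derived.  The
on-disk form is the long TSV emitted by :mod:`totem.fragments`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError

__all__ = ["MarkerMatrix", "CANCER_CLASSES", "HEALTHY_LABEL", "read_sample_sheet"]

CANCER_CLASSES = ("BRCA", "COREAD", "ESCA", "LIHC", "NSCLC", "PAAD", "STAD")
HEALTHY_LABEL = "healthy"
STAGES = ("I", "II", "III", "IV")


@dataclass
class MarkerMatrix:
    """Aligned wide tables of fragment-level marker statistics."""

    mfc: pd.DataFrame
    n_informative: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("n_informative", "coverage"):
            other = getattr(self, name)
            if not other.index.equals(self.mfc.index) or not other.columns.equals(
                self.mfc.columns
            ):
                raise InvalidInputError(f"{name} not aligned with mfc table")
        if (self.mfc.to_numpy() > self.n_informative.to_numpy()).any():
            raise InvalidInputError("mfc exceeds n_informative")
        if (self.n_informative.to_numpy() > self.coverage.to_numpy()).any():
            raise InvalidInputError("n_informative exceeds coverage")

    @property
    def samples(self) -> pd.Index:
        return self.mfc.index

    @property
    def markers(self) -> pd.Index:
        return self.mfc.columns

    @property
    def mfr(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.mfc / self.n_informative
        return out

    def subset_samples(self, sample_ids: Sequence[str]) -> "MarkerMatrix":
        ids = pd.Index(sample_ids)
        missing = ids.difference(self.samples)
        if len(missing):
            raise InvalidInputError(f"unknown samples: {list(missing)[:5]}")
        return MarkerMatrix(
            self.mfc.loc[ids], self.n_informative.loc[ids], self.coverage.loc[ids]
        )

    def subset_markers(self, marker_ids: Sequence[str]) -> "MarkerMatrix":
        ids = pd.Index(marker_ids)
        missing = ids.difference(self.markers)
        if len(missing):
            raise SchemaError(f"unknown markers: {list(missing)[:5]}")
        return MarkerMatrix(
            self.mfc[ids], self.n_informative[ids], self.coverage[ids]
        )

    # -- long-form round trip ------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        frames = {
            "mfc": self.mfc,
            "n_informative": self.n_informative,
            "coverage": self.coverage,
        }
        long = pd.concat(
            {k: v.stack() for k, v in frames.items()}, axis=1
        ).reset_index()
        long.columns = ["sample_id", "mcb_id", "mfc", "n_informative", "coverage"]
        with np.errstate(invalid="ignore", divide="ignore"):
            long["mfr"] = long["mfc"] / long["n_informative"]
        return long[["sample_id", "mcb_id", "mfc", "n_informative", "mfr", "coverage"]]

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "MarkerMatrix":
        required = {"sample_id", "mcb_id", "mfc", "n_informative", "coverage"}
        if not required <= set(long.columns):
            raise SchemaError(f"marker table missing {required - set(long.columns)}")
        def pivot(col: str) -> pd.DataFrame:
            wide = long.pivot(index="sample_id", columns="mcb_id", values=col)
            if wide.isna().any().any():
                raise SchemaError("marker table has missing (sample, marker) cells")
            return wide.astype(int)
        return cls(pivot("mfc"), pivot("n_informative"), pivot("coverage"))

    def to_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerMatrix":
        return cls.from_long(pd.read_csv(path, sep="\t", na_values=["NA"]))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, label, stage, split."""
    sheet = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "label", "split"}
    if not required <= set(sheet.columns):
        raise SchemaError(f"sample sheet missing {required - set(sheet.columns)}")
    bad = set(sheet["label"]) - set(CANCER_CLASSES) - {HEALTHY_LABEL}
    if bad:
        raise SchemaError(f"unknown labels in sample sheet: {sorted(bad)}")
    return sheet
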