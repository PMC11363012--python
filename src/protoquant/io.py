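"""Readers, writers and validation for the pipeline's tabular interchange formats.

Everything is plain CSV (UTF-8, ``.`` decimal, header row required).  A
feature table is stored wide: one row per feature with ``feature_id``,
``mz`` (Da), ``rt`` (seconds) followed by one area column per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CompoundRecord",
    "QC_POOL_LABEL",
    "read_feature_table",
    "write_feature_table",
    "read_cell_metadata",
    "write_cell_metadata",
    "read_compound_library",
    "write_compound_library",
    "make_qc_pool",
]

QC_POOL_LABEL = "QC_POOL"

_FEATURE_COLS = ["feature_id", "mz", "rt"]
_METADATA_COLS = ["cell_id", "well", "diameter", "fluorescent", "colored", "tissue"]
_LIBRARY_COLS = [
    "name",
    "neutral_formula",
    "adduct",
    "charge",
    "expected_rt",
    "compound_class",
    "quantifiable",
]

COMPOUND_CLASSES = ("iridoid", "alkaloid", "flavonoid", "anthocyanin", "internal_standard")


@dataclass
class FeatureTable:
    """LC-MS features (m/z, RT) crossed with per-sample peak areas.

    Attributes
    ----------
    features : DataFrame with columns ``feature_id``, ``mz``, ``rt``.
    areas : DataFrame indexed by ``feature_id`` with one column per sample;
        entries are nonnegative peak areas.
    """

    features: pd.DataFrame
    areas: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = self.features.reset_index(drop=True)
        missing = [c for c in _FEATURE_COLS if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        ids = self.features["feature_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate feature ids: {sorted(set(dup))}")
        if (self.features["mz"] <= 0).any():
            bad = self.features.index[self.features["mz"] <= 0][0]
            raise ValueError(f"nonpositive m/z in feature row {bad}")
        if (self.features["rt"] < 0).any():
            bad = self.features.index[self.features["rt"] < 0][0]
            raise ValueError(f"negative RT in feature row {bad}")
        if not self.areas.index.equals(pd.Index(ids, name=self.areas.index.name)):
            self.areas = self.areas.reindex(ids)
            if self.areas.isna().any().any():
                raise ValueError("area matrix rows do not match feature ids")
        neg = self.areas.lt(0)
        if neg.any().any():
            row = self.areas.index[neg.any(axis=1)][0]
            raise ValueError(f"negative area for feature {row!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.areas.copy())


@dataclass(frozen=True)
class CompoundRecord:
    """A library metabolite: identity, ionization, and chromatographic position."""

    name: str
    neutral_formula: str
    adduct: str
    charge: int
    expected_rt: float  # seconds
    compound_class: str
    quantifiable: bool = True

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"{self.name}: charge must be >= 1")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"{self.name}: unknown class {self.compound_class!r}; "
                f"expected one of {COMPOUND_CLASSES}"
            )


def write_feature_table(table: FeatureTable, path: str | Path, comment: str | None = None) -> None:
    wide = pd.concat(
        [table.features.set_index("feature_id"), table.areas], axis=1
    ).reset_index()
    with open(path, "w", encoding="utf-8", newline="") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        wide.to_csv(handle, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _FEATURE_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    features = frame[_FEATURE_COLS].copy()
    features["feature_id"] = features["feature_id"].astype(str)
    sample_cols = [c for c in frame.columns if c not in _FEATURE_COLS]
    areas = frame[sample_cols].copy()
    areas.index = pd.Index(features["feature_id"], name="feature_id")
    for col in sample_cols:
        bad = areas.index[areas[col] < 0]
        if len(bad):
            raise ValueError(f"{path}: negative area in row {bad[0]!r}, column {col!r}")
    return FeatureTable(features, areas)


def write_cell_metadata(metadata: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    _validate_metadata(metadata)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        metadata[_METADATA_COLS].to_csv(handle, index=False)


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    _validate_metadata(frame, origin=str(path))
    frame["cell_id"] = frame["cell_id"].astype(str)
    return frame[_METADATA_COLS]


def _validate_metadata(frame: pd.DataFrame, origin: str = "metadata") -> None:
    missing = [c for c in _METADATA_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{origin}: missing columns {missing}")
    if len(frame):
        if (frame["diameter"] <= 0).any():
            bad = frame.index[frame["diameter"] <= 0][0]
            raise ValueError(f"{origin}: nonpositive diameter in row {bad}")
        dup = frame["cell_id"][frame["cell_id"].duplicated()]
        if len(dup):
            raise ValueError(f"{origin}: duplicate cell ids {sorted(set(dup))}")


def write_compound_library(library: list[CompoundRecord], path: str | Path) -> None:
    frame = pd.DataFrame([vars(c) for c in library])
    frame[_LIBRARY_COLS].to_csv(path, index=False)


def read_compound_library(path: str | Path) -> list[CompoundRecord]:
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _LIBRARY_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = [
        CompoundRecord(
            name=row.name_,
            neutral_formula=row.neutral_formula,
            adduct=row.adduct,
            charge=int(row.charge),
            expected_rt=float(row.expected_rt),
            compound_class=row.compound_class,
            quantifiable=bool(row.quantifiable),
        )
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    names = [c.name for c in records]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate compound names {dup}")
    return records


def make_qc_pool(
    table: FeatureTable,
    aliquot: float = 2.0,
    extract_volume: float = 12.0,
    label: str = QC_POOL_LABEL,
) -> FeatureTable:
    """Append a pooled quality-control sample built from equal aliquots.

    Pooling a fixed aliquot from every extract preserves each extract's
    concentration (an intensive quantity), so the pooled feature area is the
    plain mean of the per-sample areas.
    """
    if not 0 < aliquot < extract_volume:
        raise ValueError(
            f"aliquot must satisfy 0 < aliquot < extract_volume, "
            f"got {aliquot} / {extract_volume}"
        )
    if label in table.samples:
        raise ValueError(f"reserved sample label {label!r} already present")
    out = table.copy()
    out.areas[label] = out.areas.mean(axis=1) if len(table.samples) else np.nan
    return out
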