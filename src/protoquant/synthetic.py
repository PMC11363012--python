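"""Synthetic protoplast populations and simulated single-cell LC-MS measurements.

The generator emulates the cell populations the analysis chain is built
for: Catharanthus roseus protoplasts from leaf, root and petal tissue in
which a small number of specialized cell types (alkaloid-rich idioblasts,
loganic-acid IPAP cells, secologanin-rich epidermis, flavonoid/anthocyanin
cells) accumulate natural products at millimolar levels.  Every cell
carries its ground-truth type and concentrations, so the downstream
quantification and partitioning stages can be validated end to end.

Concentration model: given presence, a compound's in-cell concentration is
drawn log-uniformly between the population's low/high bounds (in mM) —
populations span orders of magnitude.  Diameters are uniform on each
type's range; the tissue-wide span is 16–45 μm.

Measurement model: the cell's entire content ends up in a 12 μL extract
(6 μL aqueous lysis + 6 μL methanolic internal standard); the peak area of
a compound is ``response_factor × amount-in-well``, perturbed by a
per-feature multiplicative log-normal error (``noise_cv``) and a shared
per-sample response factor (``sample_cv``) that the internal standard
tracks.  Censoring below the LOQ is applied downstream, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .formula import ion_mz
from .io import CompoundRecord, FeatureTable
from .library import INTERNAL_STANDARD, default_compound_library

__all__ = [
    "CellTypeSpec",
    "PopulationConfig",
    "CellRecord",
    "InstrumentConfig",
    "PRESETS",
    "DEFAULT_CALIBRATION_LEVELS",
    "build_preset",
    "generate_population",
    "simulate_measurement",
    "simulate_calibration_series",
    "calibration_sample_label",
    "parse_calibration_sample_label",
]

# mM * pL -> pmol conversion: 1 mM × 1 pL = 1e-3 mol/L × 1e-12 L = 1 fmol
_MM_PL_TO_PMOL = 1e-3
# nM extract concentration × μL extract volume -> pmol
_NM_UL_TO_PMOL = 1e-3

#: Default external-calibration levels, as extract concentrations in nM.
#: Seven decade-spaced levels; the lowest corresponds to 0.12 fmol in a
#: 12 μL extract, below the smallest single-cell amounts of interest.
DEFAULT_CALIBRATION_LEVELS: tuple[float, ...] = (
    1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3, 1e4,
)


@dataclass(frozen=True)
class CellTypeSpec:
    """Generative description of one cell type within a tissue.

    ``profile`` maps compound name -> (presence probability, (low, high))
    with concentration bounds in mM; given presence the concentration is
    log-uniform on [low, high].
    """

    name: str
    proportion: float
    diameter_range: tuple[float, float]  # μm
    profile: Mapping[str, tuple[float, tuple[float, float]]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"{self.name}: proportion must be in [0, 1]")
        lo, hi = self.diameter_range
        if not 0 < lo <= hi:
            raise ValueError(f"{self.name}: bad diameter range ({lo}, {hi})")
        for compound, (presence, (clo, chi)) in self.profile.items():
            if not 0.0 <= presence <= 1.0:
                raise ValueError(f"{self.name}/{compound}: presence not in [0, 1]")
            if not 0 < clo <= chi:
                raise ValueError(f"{self.name}/{compound}: bad bounds ({clo}, {chi})")


@dataclass(frozen=True)
class PopulationConfig:
    """A tissue's cell-type mixture plus sampling parameters."""

    tissue: str
    cultivar: str
    cell_types: tuple[CellTypeSpec, ...]
    n_cells: int
    cross_contamination_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(t.proportion for t in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell-type proportions sum to {total}, not 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.cross_contamination_rate <= 1.0:
            raise ValueError("cross_contamination_rate must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "cultivar": self.cultivar,
            "n_cells": self.n_cells,
            "cross_contamination_rate": self.cross_contamination_rate,
            "seed": self.seed,
            "cell_types": [
                {
                    "name": t.name,
                    "proportion": t.proportion,
                    "diameter_range": list(t.diameter_range),
                    "profile": {
                        c: {"presence": p, "range_mM": list(bounds)}
                        for c, (p, bounds) in t.profile.items()
                    },
                }
                for t in self.cell_types
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PopulationConfig":
        types = tuple(
            CellTypeSpec(
                name=t["name"],
                proportion=float(t["proportion"]),
                diameter_range=tuple(t["diameter_range"]),
                profile={
                    c: (float(v["presence"]), tuple(v["range_mM"]))
                    for c, v in t["profile"].items()
                },
            )
            for t in data["cell_types"]
        )
        return cls(
            tissue=data["tissue"],
            cultivar=data["cultivar"],
            cell_types=types,
            n_cells=int(data["n_cells"]),
            cross_contamination_rate=float(data.get("cross_contamination_rate", 0.0)),
            seed=int(data.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle))


@dataclass(frozen=True)
class CellRecord:
    """One generated protoplast with its ground truth."""

    cell_id: str
    tissue: str
    true_type: str
    diameter: float  # μm
    true_concentrations: Mapping[str, float]  # compound -> mM

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"{self.cell_id}: diameter must be positive")
        for compound, conc in self.true_concentrations.items():
            if conc < 0:
                raise ValueError(f"{self.cell_id}/{compound}: negative concentration")


def _default_response_factors() -> dict[str, float]:
    # area counts per pmol; spread over ~half an order of magnitude to mimic
    # compound-dependent ionization efficiency
    factors = {}
    for idx, record in enumerate(default_compound_library()):
        factors[record.name] = 2.0e5 * (1.0 + 0.45 * (idx % 6))
    return factors


@dataclass(frozen=True)
class InstrumentConfig:
    """Response model of the simulated LC-MS instrument.

    Amount unit is pmol throughout; response factors are peak-area counts
    per pmol in the well.
    """

    response_factor: Mapping[str, float] = field(default_factory=_default_response_factors)
    noise_cv: float = 0.10
    sample_cv: float = 0.05
    internal_standard_area: float = 5.0e6
    internal_standard_cv: float = 0.03
    extract_volume: float = 12.0  # μL
    qc_aliquot: float = 2.0  # μL
    loq_amount: Mapping[str, float] = field(default_factory=dict)  # pmol
    mz_jitter_ppm: float = 0.5
    rt_jitter_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.extract_volume > self.qc_aliquot >= 0:
            raise ValueError("require extract_volume > qc_aliquot >= 0")
        if any(v <= 0 for v in self.response_factor.values()):
            raise ValueError("response factors must be positive")
        for name in ("noise_cv", "sample_cv", "internal_standard_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noiseless(self) -> "InstrumentConfig":
        """Copy with every stochastic term switched off."""
        return InstrumentConfig(
            response_factor=self.response_factor,
            noise_cv=0.0,
            sample_cv=0.0,
            internal_standard_cv=0.0,
            internal_standard_area=self.internal_standard_area,
            extract_volume=self.extract_volume,
            qc_aliquot=self.qc_aliquot,
            loq_amount=self.loq_amount,
            mz_jitter_ppm=0.0,
            rt_jitter_s=0.0,
        )


# ---------------------------------------------------------------------------
# presets

def _leaf_sa() -> tuple[CellTypeSpec, ...]:
    return (
        CellTypeSpec(
            "idioblast", 0.025, (28.0, 45.0),
            {
                "serpentine": (1.0, (1.0, 50.0)),
                "catharanthine": (0.9, (10.0, 300.0)),
                "vindoline": (0.9, (10.0, 200.0)),
                "vindolinine": (0.8, (1.0, 50.0)),
                "vindorosine": (0.6, (1.0, 50.0)),
                "ajmalicine": (0.5, (0.5, 20.0)),
                "anhydrovinblastine": (1.0, (0.3, 10.0)),
                # one cell in ~202 overall: 1/202 / 0.025 within idioblasts
                "vinblastine": (0.198, (0.01, 0.08)),
            },
        ),
        CellTypeSpec(
            "ipap", 0.10, (18.0, 32.0),
            {
                "loganic acid": (1.0, (10.0, 300.0)),
                "loganin": (0.4, (1.0, 20.0)),
            },
        ),
        CellTypeSpec(
            "epidermis_secologanin", 0.30, (16.0, 40.0),
            {
                "secologanin": (1.0, (50.0, 600.0)),
                "strictosidine": (0.3, (0.5, 10.0)),
                "loganin": (0.3, (1.0, 10.0)),
            },
        ),
        CellTypeSpec(
            "epidermis_flavonoid", 0.30, (16.0, 40.0),
            {
                "mauritianin": (1.0, (5.0, 100.0)),
                "rutin": (0.4, (1.0, 30.0)),
                "secologanin": (0.8, (1.0, 40.0)),
            },
        ),
        CellTypeSpec(
            "mesophyll", 0.275, (16.0, 38.0),
            {
                "secologanin": (0.2, (0.1, 5.0)),
                "loganin": (0.1, (0.1, 2.0)),
            },
        ),
    )


def _root_sa() -> tuple[CellTypeSpec, ...]:
    return (
        CellTypeSpec(
            "idioblast", 0.03, (25.0, 42.0),
            {
                "catharanthine": (1.0, (10.0, 300.0)),
                "tabersonine": (0.7, (1.0, 50.0)),
                "serpentine": (0.6, (1.0, 30.0)),
                "ajmalicine": (0.4, (0.5, 10.0)),
            },
        ),
        CellTypeSpec(
            "iridoid_strictosidine", 0.25, (18.0, 38.0),
            {
                "loganic acid": (0.8, (5.0, 100.0)),
                "secologanin": (0.7, (5.0, 80.0)),
                "strictosidine": (1.0, (1.0, 50.0)),
            },
        ),
        CellTypeSpec(
            "strictosidine_only", 0.20, (18.0, 38.0),
            {"strictosidine": (1.0, (1.0, 50.0))},
        ),
        CellTypeSpec(
            "ground", 0.52, (16.0, 36.0),
            {"loganin": (0.1, (0.1, 2.0))},
        ),
    )


def _petal_sa() -> tuple[CellTypeSpec, ...]:
    return (
        CellTypeSpec(
            "anthocyanin_flavonoid", 0.30, (18.0, 42.0),
            {
                "rutin": (1.0, (5.0, 100.0)),
                "peonidin 3-O-rutinoside": (1.0, (5.0, 100.0)),
            },
        ),
        CellTypeSpec(
            "mauritianin_cells", 0.25, (18.0, 42.0),
            {"mauritianin": (1.0, (5.0, 100.0))},
        ),
        CellTypeSpec(
            "alkaloid_cells", 0.10, (20.0, 42.0),
            {
                "catharanthine": (1.0, (5.0, 100.0)),
                "vindoline": (0.8, (1.0, 50.0)),
                "serpentine": (0.7, (1.0, 30.0)),
                "vindolinine": (0.5, (1.0, 20.0)),
            },
        ),
        CellTypeSpec(
            "secologanin_specialist", 0.08, (16.0, 40.0),
            {"secologanin": (1.0, (5.0, 50.0))},
        ),
        CellTypeSpec(
            "parenchyma", 0.27, (16.0, 38.0),
            {"secologanin": (0.2, (0.5, 5.0))},
        ),
    )


def _petal_lbe() -> tuple[CellTypeSpec, ...]:
    return (
        CellTypeSpec(
            "alkaloid_cells", 0.10, (20.0, 42.0),
            {
                "catharanthine": (1.0, (20.0, 200.0)),
                "vindoline": (1.0, (20.0, 150.0)),
                "serpentine": (1.0, (5.0, 50.0)),
                "vindolinine": (0.8, (5.0, 50.0)),
                "anhydrovinblastine": (0.5, (0.3, 10.0)),
            },
        ),
        # in LBE secologanin nearly always colocalizes with flavonoids: the
        # only secologanin-bearing type always carries mauritianin
        CellTypeSpec(
            "secologanin_flavonoid", 0.25, (16.0, 40.0),
            {
                "secologanin": (1.0, (5.0, 50.0)),
                "mauritianin": (1.0, (5.0, 100.0)),
                "rutin": (0.5, (1.0, 30.0)),
            },
        ),
        CellTypeSpec(
            "anthocyanin_cells", 0.30, (18.0, 42.0),
            {
                "rutin": (1.0, (5.0, 100.0)),
                "peonidin 3-O-rutinoside": (1.0, (5.0, 100.0)),
            },
        ),
        CellTypeSpec(
            "parenchyma", 0.35, (16.0, 38.0),
            {"mauritianin": (0.2, (0.5, 5.0))},
        ),
    )


def _petal_abh() -> tuple[CellTypeSpec, ...]:
    return (
        CellTypeSpec(
            "alkaloid_cells", 0.10, (20.0, 42.0),
            {
                "catharanthine": (1.0, (5.0, 100.0)),
                "vindoline": (0.8, (1.0, 50.0)),
                "serpentine": (0.7, (1.0, 30.0)),
            },
        ),
        CellTypeSpec(
            "secologanin_specialist", 0.10, (16.0, 40.0),
            {"secologanin": (1.0, (5.0, 50.0))},
        ),
        CellTypeSpec(
            "anthocyanin_cells", 0.35, (18.0, 42.0),
            {
                "peonidin 3-O-rutinoside": (1.0, (5.0, 100.0)),
                "rutin": (0.8, (2.0, 50.0)),
            },
        ),
        CellTypeSpec(
            "parenchyma", 0.45, (16.0, 38.0),
            {"mauritianin": (0.1, (0.5, 5.0))},
        ),
    )


PRESETS: dict[str, tuple] = {
    "leaf-SA": ("leaf", "SA", _leaf_sa, 202),
    "root-SA": ("root", "SA", _root_sa, 187),
    "petal-SA": ("petal", "SA", _petal_sa, 232),
    "petal-LBE": ("petal", "LBE", _petal_lbe, 232),
    "petal-ABH": ("petal", "ABH", _petal_abh, 232),
}


def build_preset(
    tissue_cultivar: str,
    n_cells: int | None = None,
    cross_contamination_rate: float = 0.0,
    seed: int = 0,
) -> PopulationConfig:
    """Population config for one of the study's five tissue/cultivar samples.

    Labels: ``leaf-SA`` (202 cells), ``root-SA`` (187), ``petal-SA`` (232),
    ``petal-LBE`` (232), ``petal-ABH`` (232).
    """
    if tissue_cultivar not in PRESETS:
        raise ValueError(
            f"unknown preset {tissue_cultivar!r}; known: {sorted(PRESETS)}"
        )
    tissue, cultivar, factory, default_n = PRESETS[tissue_cultivar]
    return PopulationConfig(
        tissue=tissue,
        cultivar=cultivar,
        cell_types=factory(),
        n_cells=default_n if n_cells is None else n_cells,
        cross_contamination_rate=cross_contamination_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sampling


def generate_population(config: PopulationConfig, seed: int | None = None) -> list[CellRecord]:
    """Draw ``config.n_cells`` cells: type, diameter, per-compound concentrations."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    proportions = np.array([t.proportion for t in config.cell_types])
    cells: list[CellRecord] = []
    for i in range(config.n_cells):
        spec = config.cell_types[rng.choice(len(proportions), p=proportions)]
        lo, hi = spec.diameter_range
        diameter = float(rng.uniform(lo, hi))
        concentrations: dict[str, float] = {}
        for compound, (presence, (clo, chi)) in spec.profile.items():
            if rng.random() < presence:
                concentrations[compound] = float(
                    math.exp(rng.uniform(math.log(clo), math.log(chi)))
                )
        cells.append(
            CellRecord(
                cell_id=f"{config.tissue}-{config.cultivar}-{i + 1:04d}",
                tissue=config.tissue,
                true_type=spec.name,
                diameter=diameter,
                true_concentrations=concentrations,
            )
        )
    return cells


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative log-normal noise; exactly 1 when cv == 0."""
    if cv == 0.0:
        rng.normal()  # keep the stream aligned across noise settings
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return math.exp(rng.normal(-0.5 * sigma * sigma, sigma))


def _well_label(index: int) -> str:
    plate, pos = divmod(index, 96)
    row, col = divmod(pos, 12)
    return f"P{plate + 1}-{'ABCDEFGH'[row]}{col + 1}"


def simulate_measurement(
    cells: Sequence[CellRecord],
    instrument: InstrumentConfig | None = None,
    compounds: Sequence[CompoundRecord] | None = None,
    seed: int = 0,
    cross_contamination_rate: float = 0.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate LC-MS of each cell's 12 μL extract.

    Returns a feature table (one feature per library compound observed in
    the population, plus the ajmaline internal standard) and the matching
    cell metadata frame.  Areas are ``response_factor × amount`` with
    multiplicative noise; sub-LOQ amounts still produce signal — censoring
    belongs to the quantification stage.
    """
    instrument = instrument or InstrumentConfig()
    compounds = list(compounds) if compounds is not None else default_compound_library()
    by_name = {c.name: c for c in compounds}
    rng = np.random.default_rng(seed)

    present: set[str] = set()
    for cell in cells:
        for compound, conc in cell.true_concentrations.items():
            if compound not in by_name:
                raise ValueError(f"compound {compound!r} not in library")
            if conc < 0:
                raise ValueError(f"negative concentration for {compound!r}")
            present.add(compound)
    feature_compounds = [
        c for c in compounds if c.name in present or c.name == INTERNAL_STANDARD
    ]

    rows = []
    for idx, record in enumerate(feature_compounds):
        theo = ion_mz(record.neutral_formula, record.adduct)
        mz = theo * (1 + rng.uniform(-1, 1) * instrument.mz_jitter_ppm * 1e-6)
        rt = record.expected_rt + rng.uniform(-1, 1) * instrument.rt_jitter_s
        rows.append({"feature_id": f"F{idx + 1:03d}", "mz": mz, "rt": max(rt, 0.0)})
    features = pd.DataFrame(rows, columns=["feature_id", "mz", "rt"])

    # pmol of each compound in each well, before instrument response
    amounts = np.zeros((len(feature_compounds), len(cells)))
    comp_index = {c.name: i for i, c in enumerate(feature_compounds)}
    for j, cell in enumerate(cells):
        if cell.diameter <= 0:
            raise ValueError(f"{cell.cell_id}: nonpositive diameter")
        volume_pl = math.pi / 6.0 * cell.diameter**3 / 1000.0
        for compound, conc in cell.true_concentrations.items():
            amounts[comp_index[compound], j] = conc * volume_pl * _MM_PL_TO_PMOL

    # cross-contamination: a picked cell may carry over a small fraction of
    # a random other cell's content
    if cross_contamination_rate > 0 and len(cells) > 1:
        contamination = np.zeros_like(amounts)
        for j in range(len(cells)):
            if rng.random() < cross_contamination_rate:
                donor = int(rng.integers(len(cells) - 1))
                donor = donor if donor < j else donor + 1
                contamination[:, j] = rng.uniform(0.0, 0.05) * amounts[:, donor]
        amounts = amounts + contamination

    areas = np.zeros_like(amounts)
    sample_labels = []
    meta_rows = []
    for j, cell in enumerate(cells):
        sample_factor = _lognormal_factor(rng, instrument.sample_cv)
        for i, record in enumerate(feature_compounds):
            if record.name == INTERNAL_STANDARD:
                areas[i, j] = (
                    instrument.internal_standard_area
                    * _lognormal_factor(rng, instrument.internal_standard_cv)
                    * sample_factor
                )
            elif amounts[i, j] > 0:
                rf = instrument.response_factor[record.name]
                areas[i, j] = (
                    rf * amounts[i, j] * _lognormal_factor(rng, instrument.noise_cv) * sample_factor
                )
        sample_labels.append(cell.cell_id)
        meta_rows.append(
            {
                "cell_id": cell.cell_id,
                "well": _well_label(j),
                "diameter": cell.diameter,
                "fluorescent": "serpentine" in cell.true_concentrations,
                "colored": any(
                    by_name[c].compound_class == "anthocyanin"
                    for c in cell.true_concentrations
                ),
                "tissue": cell.tissue,
            }
        )

    area_frame = pd.DataFrame(
        areas, index=pd.Index(features["feature_id"], name="feature_id"), columns=sample_labels
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["cell_id", "well", "diameter", "fluorescent", "colored", "tissue"]
    )
    return FeatureTable(features, area_frame), metadata


def calibration_sample_label(compound: str, level: float, replicate: int = 1) -> str:
    return f"cal|{compound}|{level!r}|{replicate}"


def parse_calibration_sample_label(label: str) -> tuple[str, float]:
    parts = label.split("|")
    if parts[0] != "cal" or len(parts) not in (3, 4):
        raise ValueError(f"not a calibration sample label: {label!r}")
    return parts[1], float(parts[2])


def simulate_calibration_series(
    compounds: Sequence[CompoundRecord],
    levels: Sequence[float] = DEFAULT_CALIBRATION_LEVELS,
    instrument: InstrumentConfig | None = None,
    seed: int = 0,
    n_replicates: int = 3,
) -> FeatureTable:
    """External-calibration injections of authentic standards.

    One sample per (compound, level, replicate); ``levels`` are extract
    concentrations in nM, strictly positive and increasing.  Triplicate
    injections per level (the default) let the back-calculation accuracy
    filter judge each level by its replicate mean.  Areas follow the same
    response model as the cell measurements, with the internal standard
    spiked into every injection.
    """
    instrument = instrument or InstrumentConfig()
    levels = list(levels)
    if not levels:
        raise ValueError("calibration level list must not be empty")
    if any(l <= 0 for l in levels):
        raise ValueError("calibration levels must be strictly positive")
    if sorted(levels) != levels:
        raise ValueError("calibration levels must be sorted ascending")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    rng = np.random.default_rng(seed)
    targets = [c for c in compounds if c.quantifiable]
    by_name = {c.name: c for c in compounds}
    if INTERNAL_STANDARD in by_name:
        feature_compounds = targets + [by_name[INTERNAL_STANDARD]]
    else:
        feature_compounds = list(targets)

    rows = []
    for idx, record in enumerate(feature_compounds):
        theo = ion_mz(record.neutral_formula, record.adduct)
        mz = theo * (1 + rng.uniform(-1, 1) * instrument.mz_jitter_ppm * 1e-6)
        rt = record.expected_rt + rng.uniform(-1, 1) * instrument.rt_jitter_s
        rows.append({"feature_id": f"F{idx + 1:03d}", "mz": mz, "rt": max(rt, 0.0)})
    features = pd.DataFrame(rows, columns=["feature_id", "mz", "rt"])

    comp_index = {c.name: i for i, c in enumerate(feature_compounds)}
    labels = []
    areas = np.zeros((len(feature_compounds), len(targets) * len(levels) * n_replicates))
    col = 0
    for record in targets:
        rf = instrument.response_factor[record.name]
        for level in levels:
            for rep in range(1, n_replicates + 1):
                sample_factor = _lognormal_factor(rng, instrument.sample_cv)
                amount = level * _NM_UL_TO_PMOL * instrument.extract_volume  # pmol
                areas[comp_index[record.name], col] = (
                    rf * amount * _lognormal_factor(rng, instrument.noise_cv) * sample_factor
                )
                if INTERNAL_STANDARD in comp_index:
                    areas[comp_index[INTERNAL_STANDARD], col] = (
                        instrument.internal_standard_area
                        * _lognormal_factor(rng, instrument.internal_standard_cv)
                        * sample_factor
                    )
                labels.append(calibration_sample_label(record.name, level, rep))
                col += 1

    area_frame = pd.DataFrame(
        areas, index=pd.Index(features["feature_id"], name="feature_id"), columns=labels
    )
    return FeatureTable(features, area_frame)
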