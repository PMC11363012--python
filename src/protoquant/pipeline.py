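"""End-to-end runs: simulate → annotate → calibrate → quantify → partition.

Thin glue over the stage modules; both the command-line interface and the
reproduction scripts call these functions so that every entry point
exercises the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import partition as _partition
from .formula import match_known_compounds
from .io import CompoundRecord, FeatureTable
from .library import default_compound_library
from .quantify import (
    CalibrationCurve,
    QuantMatrix,
    fit_calibration,
    quantify_cells,
)
from .synthetic import (
    DEFAULT_CALIBRATION_LEVELS,
    CellRecord,
    InstrumentConfig,
    PopulationConfig,
    build_preset,
    generate_population,
    parse_calibration_sample_label,
    simulate_calibration_series,
    simulate_measurement,
)

__all__ = ["SimulatedStudy", "simulate_study", "quantify_study", "partition_study"]


@dataclass
class SimulatedStudy:
    """One simulated tissue sample: ground truth plus raw measurements."""

    config: PopulationConfig
    cells: list[CellRecord]
    table: FeatureTable
    metadata: pd.DataFrame
    calibration: FeatureTable
    instrument: InstrumentConfig
    library: list[CompoundRecord]


def simulate_study(
    preset: str,
    n_cells: int | None = None,
    seed: int = 0,
    instrument: InstrumentConfig | None = None,
    cross_contamination_rate: float = 0.0,
    levels: Sequence[float] = DEFAULT_CALIBRATION_LEVELS,
) -> SimulatedStudy:
    """Generate a full synthetic study for one tissue preset."""
    instrument = instrument or InstrumentConfig()
    library = default_compound_library()
    config = build_preset(preset, n_cells=n_cells, seed=seed,
                          cross_contamination_rate=cross_contamination_rate)
    cells = generate_population(config)
    table, metadata = simulate_measurement(
        cells, instrument, library, seed=seed + 1,
        cross_contamination_rate=config.cross_contamination_rate,
    )
    calibration = simulate_calibration_series(library, levels, instrument, seed=seed + 2)
    return SimulatedStudy(config, cells, table, metadata, calibration, instrument, library)


def calibration_long_table(calibration: FeatureTable, library: Sequence[CompoundRecord],
                           tol_ppm: float = 2.0, rt_window: float = 10.0) -> pd.DataFrame:
    """(compound, level, area) rows recovered from a calibration feature table."""
    assignments = match_known_compounds(calibration, library, tol_ppm, rt_window)
    by_feature = dict(assignments)
    rows = []
    for sample in calibration.samples:
        compound, level = parse_calibration_sample_label(sample)
        for fid, name in by_feature.items():
            if name == compound:
                rows.append(
                    {"compound": compound, "level": level,
                     "area": float(calibration.areas.loc[fid, sample])}
                )
    return pd.DataFrame(rows, columns=["compound", "level", "area"])


def fit_study_calibration(
    study: SimulatedStudy, weighting: str = "1/x^2",
    tol_ppm: float = 2.0, rt_window: float = 10.0,
) -> dict[str, CalibrationCurve]:
    long = calibration_long_table(study.calibration, study.library, tol_ppm, rt_window)
    curves = {}
    for compound, group in long.groupby("compound"):
        group = group.sort_values("level")
        curves[compound] = fit_calibration(
            group["level"].to_numpy(), group["area"].to_numpy(), weighting, compound
        )
    return curves


def quantify_study(
    study: SimulatedStudy,
    weighting: str = "1/x^2",
    tol_ppm: float = 2.0,
    rt_window: float = 10.0,
    normalize_is: bool = True,
) -> QuantMatrix:
    """Annotate features, fit calibrations, and quantify every cell."""
    curves = fit_study_calibration(study, weighting, tol_ppm, rt_window)
    assignments = match_known_compounds(study.table, study.library, tol_ppm, rt_window)
    return quantify_cells(
        study.table,
        study.metadata,
        curves,
        assignments,
        library=study.library,
        extract_volume=study.instrument.extract_volume,
        normalize_is=normalize_is,
    )


def partition_study(
    study: SimulatedStudy,
    quant: QuantMatrix,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 50,
    pseudocount: float = 1.0,
) -> dict:
    """Volume-normalized clustering and marker typing of a quantified study."""
    from .quantify import cell_volume_from_diameter

    meta = study.metadata.set_index("cell_id").loc[quant.cells]
    volumes = [cell_volume_from_diameter(d) for d in meta["diameter"]]
    areas = study.table.areas.T.loc[quant.cells]
    transformed = _partition.log_volume_normalize(areas, volumes, pseudocount)
    km = _partition.kmeans_cluster(transformed, k=k, seed=seed, n_restarts=n_restarts)
    rules = _partition.default_marker_rules()
    # a marker compound never detected in the run cannot fire its rule
    present = tuple(r for r in rules.rules if r.compound in quant.compounds)
    types = _partition.annotate_cell_types(
        quant, _partition.MarkerRules(present, rules.fallback)
    )
    summary = _partition.population_summary(quant, library=study.library)
    heatmap = _partition.cluster_mean_heatmap(transformed, km.labels)
    return {
        "transformed": transformed,
        "kmeans": km,
        "cell_types": types,
        "summary": summary,
        "heatmap": heatmap,
    }
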