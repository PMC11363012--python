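"""Accurate-mass molecular formula arithmetic, enumeration, and compound matching.

High-resolution MS assigns an elemental composition to a feature when some
candidate formula's ion m/z falls within a small relative tolerance (here
2 ppm by default, the assignment filter used for the untargeted single-cell
data) and the candidate is chemically plausible by its ring-plus-double-bond
equivalents (RDBE).  All arithmetic is done on most-abundant-isotope masses
and includes the electron mass in ion m/z, which matters at the fourth
decimal place.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ELEMENT_MASSES",
    "ADDUCTS",
    "ElementBounds",
    "FormulaCandidate",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "rdbe",
    "enumerate_formulas",
    "match_known_compounds",
]

# Most-abundant-isotope masses (Da), CODATA/AME2020 rounded to 1e-7.
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.9737615120,
    "S": 31.9720706912,
    "Na": 22.9897696620,
}

ELECTRON_MASS = 0.0005485799
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS  # 1.0072764520

# adduct label -> (mass added to the neutral molecule, charge).  The added
# mass already accounts for electrons gained or lost on ionization.
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+NH4]+": (ELEMENT_MASSES["N"] + 4 * ELEMENT_MASSES["H"] - ELECTRON_MASS, 1),
    "[M+Na]+": (ELEMENT_MASSES["Na"] - ELECTRON_MASS, 1),
    "[M+2H]2+": (2 * PROTON_MASS, 2),
    "[M]+": (-ELECTRON_MASS, 1),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element-count map.

    Accepts an already-parsed mapping unchanged (after validation).
    """
    if isinstance(formula, Mapping):
        counts = dict(formula)
    else:
        counts = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos or not match.group(0):
                break
            pos = match.end()
            counts[match.group(1)] = counts.get(match.group(1), 0) + int(
                match.group(2) or 1
            )
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    for element, n in counts.items():
        if element not in ELEMENT_MASSES:
            raise ValueError(f"unknown element symbol {element!r}")
        if n < 0:
            raise ValueError(f"negative count for element {element!r}")
    return counts


def formula_to_string(counts: Mapping[str, int]) -> str:
    """Hill notation: C first, H second, the rest alphabetical."""
    order = ["C", "H"] + sorted(e for e in counts if e not in ("C", "H"))
    parts = []
    for element in order:
        n = counts.get(element, 0)
        if n == 0:
            continue
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, in Da."""
    counts = parse_formula(formula)
    return sum(ELEMENT_MASSES[e] * n for e, n in counts.items())


def ion_mz(formula: str | Mapping[str, int], adduct: str, charge: int | None = None) -> float:
    """m/z of the given adduct ion of a neutral molecule.

    ``([M] + adduct mass) / z`` with the adduct mass electron-corrected.
    ``charge`` is optional; when given it must agree with the adduct label.
    """
    if adduct not in ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        )
    delta, z = ADDUCTS[adduct]
    if charge is not None and charge != z:
        raise ValueError(f"adduct {adduct} implies charge {z}, got {charge}")
    return (monoisotopic_mass(formula) + delta) / z


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def rdbe(formula: str | Mapping[str, int]) -> float:
    """Ring-plus-double-bond equivalents: C - H/2 + N/2 + 1."""
    counts = parse_formula(formula)
    return counts.get("C", 0) - counts.get("H", 0) / 2 + counts.get("N", 0) / 2 + 1


@dataclass(frozen=True)
class ElementBounds:
    """Inclusive per-element count bounds for formula enumeration."""

    c: tuple[int, int] = (0, 60)
    h: tuple[int, int] = (0, 100)
    n: tuple[int, int] = (0, 6)
    o: tuple[int, int] = (0, 20)
    p: tuple[int, int] = (0, 2)
    s: tuple[int, int] = (0, 2)

    def __post_init__(self) -> None:
        for element, (lo, hi) in self.as_dict().items():
            if not 0 <= lo <= hi:
                raise ValueError(f"bad bounds for {element}: ({lo}, {hi})")

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {
            "C": self.c,
            "H": self.h,
            "N": self.n,
            "O": self.o,
            "P": self.p,
            "S": self.s,
        }


@dataclass(frozen=True)
class FormulaCandidate:
    """One elemental composition consistent with a queried ion m/z."""

    formula: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    rdbe: float


def enumerate_formulas(
    mz: float,
    adduct_set: Iterable[str],
    tol_ppm: float = 2.0,
    bounds: ElementBounds | None = None,
    rdbe_range: tuple[float, float] = (0.0, 40.0),
) -> list[FormulaCandidate]:
    """All CHNOPS compositions whose ion m/z lies within ``tol_ppm`` of ``mz``.

    For each composition of C, N, O, P, S the admissible hydrogen count is
    solved from the residual mass window, so the search is linear in the
    size of the C*N*O*P*S grid rather than the full six-element grid.
    Candidates are sorted by \\|ppm\\|, ties broken by lower RDBE then by
    formula string.
    """
    adducts = list(adduct_set)
    if not adducts:
        raise ValueError("adduct set must not be empty")
    if mz <= 0 or tol_ppm <= 0:
        raise ValueError("mz and tol_ppm must be positive")
    bounds = bounds or ElementBounds()
    bd = bounds.as_dict()
    h_mass = ELEMENT_MASSES["H"]

    out: list[FormulaCandidate] = []
    for adduct in adducts:
        if adduct not in ADDUCTS:
            raise ValueError(f"unsupported adduct {adduct!r}")
        delta, z = ADDUCTS[adduct]
        # neutral-mass window implied by the ppm window on the ion m/z
        m_lo = mz * z * (1 - tol_ppm * 1e-6) - delta
        m_hi = mz * z * (1 + tol_ppm * 1e-6) - delta
        for c, n, o, p, s in itertools.product(
            range(bd["C"][0], bd["C"][1] + 1),
            range(bd["N"][0], bd["N"][1] + 1),
            range(bd["O"][0], bd["O"][1] + 1),
            range(bd["P"][0], bd["P"][1] + 1),
            range(bd["S"][0], bd["S"][1] + 1),
        ):
            base = (
                c * ELEMENT_MASSES["C"]
                + n * ELEMENT_MASSES["N"]
                + o * ELEMENT_MASSES["O"]
                + p * ELEMENT_MASSES["P"]
                + s * ELEMENT_MASSES["S"]
            )
            if base > m_hi:
                continue
            h_min = max(bd["H"][0], int(-(-(m_lo - base) // h_mass)))  # ceil
            h_max = min(bd["H"][1], int((m_hi - base) // h_mass))
            for h in range(max(h_min, 0), h_max + 1):
                counts = {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s}
                mass = base + h * h_mass
                theo = (mass + delta) / z
                err = ppm_error(mz, theo)
                if abs(err) > tol_ppm:
                    continue
                dbe = c - h / 2 + n / 2 + 1
                if not rdbe_range[0] <= dbe <= rdbe_range[1]:
                    continue
                out.append(
                    FormulaCandidate(
                        formula=formula_to_string(counts),
                        adduct=adduct,
                        theoretical_mz=theo,
                        ppm_error=err,
                        rdbe=dbe,
                    )
                )
    out.sort(key=lambda cand: (abs(cand.ppm_error), cand.rdbe, cand.formula))
    return out


def match_known_compounds(
    table,
    library: Sequence,
    tol_ppm: float = 2.0,
    rt_window: float = 10.0,
) -> dict[str, str]:
    """Assign features to library compounds by accurate m/z and retention time.

    A feature is assigned to a compound iff the ppm error against the
    compound's ion m/z is within ``tol_ppm`` AND the retention-time offset is
    within ``rt_window`` seconds.  Isobaric compounds (identical formula,
    e.g. catharanthine / vindolinine / tabersonine) are disambiguated by
    retention time alone: the closest-RT in-window compound wins.

    Parameters
    ----------
    table : FeatureTable
    library : sequence of CompoundRecord
    tol_ppm : ppm tolerance on the ion m/z.
    rt_window : seconds.

    Returns
    -------
    dict mapping feature_id -> compound name for matched features only.
    """
    if len(library) == 0:
        raise ValueError("compound library must not be empty")
    names = [c.name for c in library]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate compound names in library: {dup}")

    targets = [(c, ion_mz(c.neutral_formula, c.adduct)) for c in library]
    assignments: dict[str, str] = {}
    for feat in table.features.itertuples():
        best: tuple[float, float, str] | None = None
        for compound, theo in targets:
            err = ppm_error(feat.mz, theo)
            drt = abs(feat.rt - compound.expected_rt)
            if abs(err) <= tol_ppm and drt <= rt_window:
                key = (drt, abs(err), compound.name)
                if best is None or key < best:
                    best = key
        if best is not None:
            assignments[feat.feature_id] = best[2]
    return assignments
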