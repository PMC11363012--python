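"""Built-in compound library for Catharanthus roseus natural products.

Sixteen quantifiable metabolites across four classes (iridoid monoterpenes,
monoterpene indole alkaloids, flavonoids, anthocyanins) plus ajmaline, the
spiked internal standard.  Retention times are nominal positions on a rapid
7-minute reversed-phase gradient and serve to disambiguate isobaric
alkaloids (catharanthine, vindolinine and tabersonine share C21H24N2O2);
serpentine, natively a quaternary cation, is handled as the [M+H]+ ion of
the C21H20N2O3 composition, which reproduces its observed m/z 349.15.
Peonidin 3-O-rutinoside ionizes as its native flavylium cation [M]+.
"""

from __future__ import annotations

from .io import CompoundRecord

__all__ = ["default_compound_library", "INTERNAL_STANDARD"]

INTERNAL_STANDARD = "ajmaline"

_LIBRARY: list[tuple[str, str, str, int, float, str, bool]] = [
    # name, neutral formula, adduct, charge, RT (s), class, quantifiable
    ("loganic acid", "C16H24O10", "[M+NH4]+", 1, 62.0, "iridoid", True),
    ("loganin", "C17H26O10", "[M+H]+", 1, 95.0, "iridoid", True),
    ("secologanin", "C17H24O10", "[M+H]+", 1, 118.0, "iridoid", True),
    ("strictosidine", "C27H34N2O9", "[M+H]+", 1, 132.0, "alkaloid", True),
    ("serpentine", "C21H20N2O3", "[M+H]+", 1, 156.0, "alkaloid", True),
    ("ajmalicine", "C21H24N2O3", "[M+H]+", 1, 210.0, "alkaloid", True),
    ("catharanthine", "C21H24N2O2", "[M+H]+", 1, 172.0, "alkaloid", True),
    ("vindolinine", "C21H24N2O2", "[M+H]+", 1, 196.0, "alkaloid", True),
    ("tabersonine", "C21H24N2O2", "[M+H]+", 1, 262.0, "alkaloid", True),
    ("vindoline", "C25H32N2O6", "[M+H]+", 1, 184.0, "alkaloid", True),
    ("vindorosine", "C24H30N2O5", "[M+H]+", 1, 222.0, "alkaloid", True),
    ("anhydrovinblastine", "C46H56N4O8", "[M+2H]2+", 2, 238.0, "alkaloid", True),
    ("vinblastine", "C46H58N4O9", "[M+2H]2+", 2, 246.0, "alkaloid", True),
    ("mauritianin", "C33H40O19", "[M+H]+", 1, 142.0, "flavonoid", True),
    ("rutin", "C27H30O16", "[M+H]+", 1, 150.0, "flavonoid", True),
    ("peonidin 3-O-rutinoside", "C28H33O15", "[M]+", 1, 128.0, "anthocyanin", True),
    ("ajmaline", "C20H26N2O2", "[M+H]+", 1, 164.0, "internal_standard", False),
]


def default_compound_library() -> list[CompoundRecord]:
    """The 16 quantifiable metabolites plus the ajmaline internal standard."""
    return [
        CompoundRecord(
            name=name,
            neutral_formula=formula,
            adduct=adduct,
            charge=charge,
            expected_rt=rt,
            compound_class=klass,
            quantifiable=quant,
        )
        for name, formula, adduct, charge, rt, klass, quant in _LIBRARY
    ]
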