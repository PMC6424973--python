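"""Published reference data for PltM halogenation reactions.

Curated inputs used throughout the package:

* :data:`KINETIC_CONSTANTS` — the published macroscopic kinetic constants
  (kcat, Km, kcat/Km with standard errors) for chlorination and
  bromination of resorcinol (compound 3), 3,5-dihydroxybenzyl alcohol
  (compound 11) and 3-aminophenol (compound 16).  Symmetric substrates 3
  and 11 follow the sequential two-cycle scheme; asymmetric 16 gives two
  mono-halogenated intermediates (branches a/b) and follows the branched
  scheme.
* :data:`SUBSTRATES` — six-position ring descriptors and molecular
  formulas for the characterized substrates.

Units: kcat min⁻¹, Km µM, efficiency min⁻¹ µM⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mechanism import (
    DEFAULT_KA,
    KineticScheme,
    MacroscopicParameters,
    scheme_from_macroscopic,
)
from .products import RingSubstrate, parse_formula

__all__ = [
    "KineticRow",
    "KINETIC_CONSTANTS",
    "SUBSTRATES",
    "reference_scheme",
    "ASSIGNED_PRODUCTS",
]


@dataclass(frozen=True)
class KineticRow:
    """One published step: kcat ± se (min⁻¹), Km ± se (µM), efficiency ± se."""

    step: str  # "1", "2" (sequential) or "1a", "1b", "2a", "2b" (branched)
    kcat: float
    kcat_se: float
    km: float
    km_se: float
    efficiency: float
    efficiency_se: float

    @property
    def macroscopic(self) -> MacroscopicParameters:
        return MacroscopicParameters(self.kcat, self.km)


#: (substrate, halide) -> (topology, rows). Steps of substrate 16 carry
#: branch labels; its first-cycle Km is printed identically for both
#: branches (one shared enzyme–substrate complex).
KINETIC_CONSTANTS: dict[tuple[str, str], tuple[str, tuple[KineticRow, ...]]] = {
    ("3", "Cl"): (
        "sequential",
        (
            KineticRow("1", 2.3, 0.1, 7.6e-2, 1.3e-2, 30.0, 5.0),
            KineticRow("2", 0.40, 0.01, 0.11, 0.02, 3.5, 0.6),
        ),
    ),
    ("3", "Br"): (
        "sequential",
        (
            KineticRow("1", 1.9, 0.1, 0.71, 0.2, 2.7, 0.6),
            KineticRow("2", 0.38, 0.01, 0.78, 0.17, 0.49, 0.11),
        ),
    ),
    ("11", "Cl"): (
        "sequential",
        (
            KineticRow("1", 1.6, 0.1, 8.4, 0.4, 0.19, 0.01),
            KineticRow("2", 0.18, 0.01, 0.44, 0.02, 0.41, 0.02),
        ),
    ),
    # bromination of 11 stops at the mono product; only the first cycle
    # was quantified
    ("11", "Br"): (
        "sequential",
        (KineticRow("1", 0.24, 0.02, 1.1e3, 0.2e3, 2.2e-4, 0.2e-4),),
    ),
    ("16", "Cl"): (
        "branched",
        (
            KineticRow("1a", 0.35, 0.01, 1.1, 0.3, 0.31, 0.09),
            KineticRow("1b", 0.22, 0.01, 1.1, 0.3, 0.19, 0.06),
            KineticRow("2a", 0.95, 0.01, 18.0, 5.0, 5.2e-2, 1.4e-2),
            KineticRow("2b", 1.0, 0.1, 15.0, 9.0, 7.0e-2, 4.4e-2),
        ),
    ),
    ("16", "Br"): (
        "branched",
        (
            KineticRow("1a", 0.47, 0.04, 151.0, 20.0, 3.1e-3, 0.5e-3),
            KineticRow("1b", 2.2, 0.1, 151.0, 20.0, 1.5e-2, 0.2e-2),
            KineticRow("2a", 0.21, 0.02, 6.0, 1.2, 3.5e-2, 0.8e-2),
            KineticRow("2b", 2.0, 0.1, 1.3e3, 0.1e3, 1.5e-3, 0.2e-3),
        ),
    ),
}


def reference_scheme(
    substrate: str, halide: str, ka_fixed: float = DEFAULT_KA
) -> KineticScheme:
    """Kinetic scheme instantiated at the published constants.

    The association rate is not determined by progress-curve fractions
    and is fixed at ``ka_fixed``.
    """
    key = (substrate, halide)
    if key not in KINETIC_CONSTANTS:
        raise KeyError(
            f"no published constants for substrate {substrate!r} with {halide!r}; "
            f"available: {sorted(KINETIC_CONSTANTS)}"
        )
    topology, rows = KINETIC_CONSTANTS[key]
    if len(rows) < 2:
        raise ValueError(
            f"substrate {substrate}/{halide}: only the first cycle was quantified; "
            "cannot instantiate a full two-cycle scheme"
        )
    steps = {row.step: row.macroscopic for row in rows}
    return scheme_from_macroscopic(topology, steps, ka_fixed=ka_fixed)


def _sub(name: str, formula: str, positions: str) -> RingSubstrate:
    pos = {int(p.split(":")[0]): p.split(":")[1] for p in positions.split(",")}
    return RingSubstrate(name=name, positions=pos, formula=parse_formula(formula))


#: characterized substrates; ring maps use each compound's input numbering.
#: Compound 19's exact structure (a nitrobenzene derivative) was not
#: specified; 3-nitrophenol stands in as a representative nitro ring.
SUBSTRATES: dict[str, RingSubstrate] = {
    "1": _sub("phloroglucinol", "C6H6O3", "1:OH,3:OH,5:OH"),
    "3": _sub("resorcinol", "C6H6O2", "1:OH,3:OH"),
    "8": _sub("2-chlororesorcinol", "C6H5ClO2", "1:OH,2:Cl,3:OH"),
    "9": _sub("orcinol", "C7H8O2", "1:OH,3:OH,5:CH3"),
    "11": _sub("3,5-dihydroxybenzyl alcohol", "C7H8O3", "1:CH2OH,3:OH,5:OH"),
    "15": _sub("2,4,6-trihydroxyacetophenone", "C8H8O4", "1:COCH3,2:OH,4:OH,6:OH"),
    "16": _sub("3-aminophenol", "C6H7NO", "1:OH,3:NH2"),
    "18": _sub("1,3-diaminobenzene", "C6H8N2", "1:NH2,3:NH2"),
    "19": _sub("3-nitrophenol", "C6H5NO3", "1:OH,3:NO2"),
    "23": _sub("resveratrol", "C14H12O3", "1:styrenyl(4-hydroxy),3:OH,5:OH"),
}

#: NMR-assigned halogenation products: substrate key -> (halide, positions
#: in the substrate's input numbering)
ASSIGNED_PRODUCTS: dict[str, tuple[str, frozenset[int]]] = {
    "3": ("Cl", frozenset({4, 6})),
    "8": ("Cl", frozenset({4, 6})),
    "9": ("Cl", frozenset({2, 4})),
    "11": ("Cl", frozenset({2, 6})),
    "15": ("Cl", frozenset({3, 5})),
    "16": ("Cl", frozenset({4, 6})),
    "18": ("Cl", frozenset({4, 6})),
    "23": ("Cl", frozenset({4})),
    "3+Br": ("Br", frozenset({4, 6})),
}
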