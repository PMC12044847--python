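"""Element data for the Slater-type pseudoatom model.

The spherical core and valence densities are built from single-zeta Slater
shells with Clementi-Raimondi exponents; the aspherical deformation radial
functions are single-zeta Slater functions r^{n_l} exp(-zeta_l r) with the
standard n_l choices per period (H: n_l = 1, 2; first-row: 2, 2, 3, 4).  All
exponents are stored in bohr^-1 and may be overridden per atom through the
multipole parameter set.

Anomalous-dispersion terms f', f'' are International-Tables values for Mo
K-alpha radiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["BOHR", "ElementData", "get_element", "ELEMENTS"]

#: Bohr radius in Angstrom; the single unit-conversion constant of the model.
BOHR = 0.529177210903


@dataclass(frozen=True)
class Shell:
    n: int  # principal quantum number -> density radial power 2(n-1)
    zeta: float  # orbital exponent, bohr^-1
    occupancy: float  # electrons in the shell


@dataclass(frozen=True)
class ElementData:
    symbol: str
    z: int
    core_shells: tuple
    valence_shells: tuple
    #: deformation radial powers n_l for l = 1..4
    n_l: tuple
    #: deformation exponent, bohr^-1 (shared across l by default)
    def_zeta: float
    f_prime: float
    f_double_prime: float

    @property
    def n_core(self) -> float:
        return sum(s.occupancy for s in self.core_shells)

    @property
    def n_valence(self) -> float:
        return sum(s.occupancy for s in self.valence_shells)

    def density_terms(self, which: str):
        """Spherical density as [(weight, power, alpha_A)] with each term a
        unit-normalized Slater density r^p exp(-alpha r); weights sum to 1."""
        shells = self.core_shells if which == "core" else self.valence_shells
        total = sum(s.occupancy for s in shells)
        if total == 0:
            return []
        return [
            (s.occupancy / total, 2 * (s.n - 1), 2.0 * s.zeta / BOHR) for s in shells
        ]


def _el(symbol, z, core, valence, n_l, def_zeta, fp, fpp):
    return ElementData(
        symbol,
        z,
        tuple(Shell(*s) for s in core),
        tuple(Shell(*s) for s in valence),
        n_l,
        def_zeta,
        fp,
        fpp,
    )


# Clementi-Raimondi single-zeta exponents (bohr^-1)
ELEMENTS = {
    "H": _el("H", 1, [], [(1, 1.0000, 1)], (1, 2, 2, 3), 2.00, 0.0000, 0.0000),
    "C": _el("C", 6, [(1, 5.6727, 2)], [(2, 1.6083, 2), (2, 1.5679, 2)],
             (2, 2, 3, 4), 3.18, 0.0033, 0.0016),
    "N": _el("N", 7, [(1, 6.6651, 2)], [(2, 1.9237, 2), (2, 1.9170, 3)],
             (2, 2, 3, 4), 3.84, 0.0061, 0.0033),
    "O": _el("O", 8, [(1, 7.6579, 2)], [(2, 2.2458, 2), (2, 2.2266, 4)],
             (2, 2, 3, 4), 4.47, 0.0106, 0.0060),
    "F": _el("F", 9, [(1, 8.6501, 2)], [(2, 2.5638, 2), (2, 2.5500, 5)],
             (2, 2, 3, 4), 5.11, 0.0171, 0.0103),
}


def get_element(symbol: str) -> ElementData:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise ConfigurationError(
            f"no scattering/density data for element {symbol!r}; "
            f"available: {sorted(ELEMENTS)}"
        ) from None
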