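"""Static periodic-table data for the supported element set.

The surrogate electronic-structure provider and the A1 identity features both
draw on this table.  Electronegativities are Pauling values, hardnesses are
Pearson absolute hardnesses (eV) and covalent radii are the Cordero single-bond
radii (Angstrom).  Valence populations are those of the neutral ground-state
configuration; d populations are zero for the whole supported main-group set.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElementData:
    symbol: str
    z: int            # nuclear charge
    group: int
    period: int
    r_cov: float      # covalent radius, Angstrom
    chi: float        # Pauling electronegativity
    eta: float        # Pearson absolute hardness, eV
    val_s: float      # neutral valence s population
    val_p: float
    val_d: float
    cap_sigma: float  # sigma-orbital capacity (surrogate overlap prefactor)
    cap_pi: float
    cap_delta: float


# symbol: (Z, group, period, r_cov, chi, eta, val_s, val_p, val_d, sig, pi, delta)
_TABLE = {
    "H":  (1,   1, 1, 0.31, 2.20, 6.43, 1, 0, 0, 1, 0, 0),
    "C":  (6,  14, 2, 0.76, 2.55, 5.00, 2, 2, 0, 2, 2, 0),
    "N":  (7,  15, 2, 0.71, 3.04, 7.23, 2, 3, 0, 2, 2, 0),
    "O":  (8,  16, 2, 0.66, 3.44, 6.08, 2, 4, 0, 2, 2, 0),
    "F":  (9,  17, 2, 0.57, 3.98, 7.01, 2, 5, 0, 2, 2, 0),
    "P":  (15, 15, 3, 1.07, 2.19, 4.88, 2, 3, 0, 2, 2, 0),
    "S":  (16, 16, 3, 1.05, 2.58, 4.14, 2, 4, 0, 2, 2, 0),
    "Cl": (17, 17, 3, 1.02, 3.16, 4.68, 2, 5, 0, 2, 2, 0),
    "Br": (35, 17, 4, 1.20, 2.96, 4.22, 2, 5, 0, 2, 2, 0),
    "I":  (53, 17, 5, 1.39, 2.66, 3.69, 2, 5, 0, 2, 2, 0),
}

ELEMENTS: dict[str, ElementData] = {
    sym: ElementData(sym, *vals) for sym, vals in _TABLE.items()
}

SUPPORTED_ELEMENTS = frozenset(ELEMENTS)


class UnsupportedElementError(ValueError):
    """Raised when a structure contains an element outside the supported set."""


def element_data(symbol: str) -> ElementData:
    """Look up the data row for ``symbol`` (canonical capitalisation applied)."""
    canon = canonical_symbol(symbol)
    try:
        return ELEMENTS[canon]
    except KeyError:
        raise UnsupportedElementError(
            f"element {symbol!r} is not in the supported set "
            f"{sorted(SUPPORTED_ELEMENTS)}"
        ) from None


def canonical_symbol(symbol: str) -> str:
    """Canonicalise an element symbol: 'CL' / 'cl' -> 'Cl'."""
    s = symbol.strip()
    if not s or not s.isalpha():
        raise UnsupportedElementError(f"malformed element symbol {symbol!r}")
    return s[0].upper() + s[1:].lower()
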