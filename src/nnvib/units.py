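"""Unit registry and energy/length conversions.

Internal working units are atomic units (hartree, bohr, electron mass);
files use Å and hartree.  The vibrational modules report wavenumbers in
cm⁻¹ and training errors in meV per atom, so exact conversion factors
between those scales live here (CODATA 2018).
"""

from __future__ import annotations

# CODATA 2018
HARTREE_EV = 27.211386245988
HARTREE_CM = 219474.6313632
BOHR_ANGSTROM = 0.529177210903
AMU_ME = 1822.888486209  # electron masses per unified amu
EV_CM = HARTREE_CM / HARTREE_EV  # 8065.543937... cm^-1 per eV
MEV_CM = EV_CM / 1000.0  # 8.0655... cm^-1 per meV

# speed of light in atomic units (1/alpha)
C_AU = 137.035999084

_ENERGY_TO_HARTREE = {
    "hartree": 1.0,
    "ev": 1.0 / HARTREE_EV,
    "mev": 1.0 / (HARTREE_EV * 1000.0),
    "cm-1": 1.0 / HARTREE_CM,
    "kcal/mol": 1.0 / 627.509474063,
}

_LENGTH_TO_BOHR = {
    "bohr": 1.0,
    "angstrom": 1.0 / BOHR_ANGSTROM,
}

_ALIASES = {
    "eh": "hartree",
    "ha": "hartree",
    "cm^-1": "cm-1",
    "wavenumber": "cm-1",
    "a": "angstrom",
    "ang": "angstrom",
    "a0": "bohr",
}


class UnknownUnitError(ValueError):
    pass


def _canonical(unit: str) -> tuple[str, bool]:
    """Return (base unit, per_atom flag)."""
    u = unit.strip().lower()
    per_atom = False
    for suffix in ("/atom", " per atom"):
        if u.endswith(suffix):
            u = u[: -len(suffix)].strip()
            per_atom = True
    u = _ALIASES.get(u, u)
    return u, per_atom


def convert_energy(value: float, from_unit: str, to_unit: str,
                   n_atoms: int | None = None) -> float:
    """Convert an energy between any two known units.

    Per-atom units (e.g. ``"meV/atom"``) convert to per-system scales by
    multiplying with ``n_atoms``; the reverse divides.  This is the dual
    meV/atom ↔ cm⁻¹ reporting convention used for fit errors
    (1 meV/atom on a 10-atom system is 80.6554 cm⁻¹).
    """
    fu, f_per = _canonical(from_unit)
    tu, t_per = _canonical(to_unit)
    for u in (fu, tu):
        if u not in _ENERGY_TO_HARTREE:
            raise UnknownUnitError(f"unknown energy unit: {u!r}")
    if f_per != t_per and n_atoms is None:
        raise ValueError("n_atoms required for per-atom <-> per-system conversion")
    x = value * _ENERGY_TO_HARTREE[fu]
    if f_per and not t_per:
        x *= n_atoms
    elif t_per and not f_per:
        x /= n_atoms
    return x / _ENERGY_TO_HARTREE[tu]


def convert_length(value: float, from_unit: str, to_unit: str) -> float:
    fu, _ = _canonical(from_unit)
    tu, _ = _canonical(to_unit)
    for u in (fu, tu):
        if u not in _LENGTH_TO_BOHR:
            raise UnknownUnitError(f"unknown length unit: {u!r}")
    return value * _LENGTH_TO_BOHR[fu] / _LENGTH_TO_BOHR[tu]


# Standard atomic weights (amu) for the elements this toolkit meets in
# practice (organic clusters and the toy oracles).
ATOMIC_MASS_AMU = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "He": 4.002603254,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "F": 18.99840322,
    "Ne": 19.9924401754,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Ar": 39.9623831225,
}


def mass_au(element: str) -> float:
    """Atomic mass in electron masses."""
    try:
        return ATOMIC_MASS_AMU[element] * AMU_ME
    except KeyError:
        raise UnknownUnitError(f"unknown element symbol: {element!r}") from None
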