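"""Unit conversions and physical constants, pinned in one place.

All electrostatics inside the package is done in Hartree atomic units;
coordinates are accepted in Angstrom and converted on entry.
"""

from __future__ import annotations

#: Bohr radius in Angstrom (CODATA 2018).
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

#: Hartree in electronvolt (CODATA 2018).
EV_PER_HARTREE = 27.211386245988

#: hc in eV*nm, used for wavelength <-> photon-energy conversion.
HC_EV_NM = 1239.841984

#: 1 kcal/mol in eV.
EV_PER_KCAL_MOL = 0.0433641


def angstrom_to_bohr(x):
    """Convert length(s) in Angstrom to Bohr."""
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    """Convert length(s) in Bohr to Angstrom."""
    return x * ANGSTROM_PER_BOHR


def nm_to_ev(wavelength_nm: float) -> float:
    """Photon energy in eV for a wavelength in nm.

    E[eV] = hc / lambda with hc = 1239.841984 eV nm. The mapping is an
    involution: nm_to_ev(nm_to_ev(x)) == x to machine precision.
    """
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return HC_EV_NM / wavelength_nm


def ev_to_nm(energy_ev: float) -> float:
    """Wavelength in nm for a photon energy in eV."""
    if energy_ev <= 0:
        raise ValueError(f"energy must be positive, got {energy_ev}")
    return HC_EV_NM / energy_ev


def kcal_mol_to_ev(e: float) -> float:
    """Convert kcal/mol to eV (chemical accuracy, 1 kcal/mol ~ 0.04 eV)."""
    return e * EV_PER_KCAL_MOL
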