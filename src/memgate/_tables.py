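"""Bundled element tables: van der Waals radii, atomic masses, CG bead radii.

Radii are the Bondi set; anything not listed falls back to carbon (1.70 Å)
with a warning at parse time. Masses are standard atomic weights, used for
mass-weighted centres of mass.
"""

from __future__ import annotations

# Bondi van der Waals radii, Å
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "MG": 1.73,
    "ZN": 1.39,
    "NA": 2.27,
    "K": 2.75,
}

DEFAULT_VDW_RADIUS = 1.70

# Standard atomic weights, u
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "FE": 55.845,
    "MG": 24.305,
    "ZN": 65.38,
    "NA": 22.990,
    "K": 39.098,
}

DEFAULT_MASS = 12.011

# Radii for common MARTINI-style coarse-grained beads (regular bead 2.64 Å,
# small bead 2.30 Å), keyed by bead name. Used when an atom name matches a
# bead name and no element can be inferred.
CG_BEAD_RADII: dict[str, float] = {
    "PO4": 2.64,
    "NC3": 2.64,
    "NH3": 2.64,
    "GL1": 2.64,
    "GL2": 2.64,
    "ROH": 2.30,
    "BB": 2.64,
    "SC1": 2.30,
    "SC2": 2.30,
    "SC3": 2.30,
    "SC4": 2.30,
    "W": 2.64,
}

# Two-letter element symbols that can legitimately start a PDB atom name;
# used when the element column is blank.
_TWO_LETTER = {"CL", "BR", "FE", "MG", "ZN", "NA"}


def infer_element(name: str, resname: str = "") -> str:
    """Best-effort element symbol from a PDB/GRO atom name.

    Digits are stripped; a leading two-letter symbol is recognised only for
    ions/metals to avoid reading "CA" (alpha carbon) as calcium.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    upper = stripped.upper()
    if upper[:2] in _TWO_LETTER and resname.strip().upper() not in (
        "CA",
    ):
        # "NA " sodium vs "NA" of adenine handled by residue context upstream
        if upper[:2] in ("FE", "MG", "ZN", "CL", "BR"):
            return upper[:2]
        if upper == resname.strip().upper():
            return upper[:2]
    return upper[0]


def vdw_radius_for(element: str, atom_name: str = "") -> tuple[float, bool]:
    """Return (radius, known). CG bead names win over element inference."""
    name = atom_name.strip().upper()
    if name in CG_BEAD_RADII:
        return CG_BEAD_RADII[name], True
    el = element.strip().upper()
    if el in VDW_RADII:
        return VDW_RADII[el], True
    return DEFAULT_VDW_RADIUS, False


def mass_for(element: str) -> float:
    return ATOMIC_MASSES.get(element.strip().upper(), DEFAULT_MASS)
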