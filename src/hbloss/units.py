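"""Unit conversions between hemoglobin mass, red-cell volume and whole-blood volume.

A loss of red cells can be expressed interchangeably as grams of hemoglobin,
millilitres of packed red cells, or millilitres of whole blood, because the
three are tied together by the mean corpuscular hemoglobin concentration and
a typical hematocrit.  The conversion constants used throughout the package:

* 1 g Hb ~ 2.87 mL packed red cells
* 1 g Hb ~ 6.79 mL whole blood
* 1 packed red-cell transfusion unit ~ 50 g Hb

These hold for normocytic, normochromic blood; they are not valid in
relevant micro- or macrocytic anemia.
"""

from __future__ import annotations

RBC_ML_PER_G_HB: float = 2.87
BLOOD_ML_PER_G_HB: float = 6.79
G_HB_PER_RBC_UNIT: float = 50.0

_TARGETS = ("rbc_mL", "blood_mL", "rbc_units")


def convert_hb(mass_g: float, target: str) -> float:
    """Convert a hemoglobin mass (g) into an equivalent volume or unit count.

    Parameters
    ----------
    mass_g : float
        Hemoglobin mass in grams; must be non-negative.
    target : {"rbc_mL", "blood_mL", "rbc_units"}
        Output quantity: packed red-cell volume (mL), whole-blood volume
        (mL), or number of 50 g-Hb transfusion units.

    Returns
    -------
    float
    """
    if mass_g < 0:
        raise ValueError(f"hemoglobin mass must be >= 0 g, got {mass_g}")
    if target == "rbc_mL":
        return RBC_ML_PER_G_HB * mass_g
    if target == "blood_mL":
        return BLOOD_ML_PER_G_HB * mass_g
    if target == "rbc_units":
        return mass_g / G_HB_PER_RBC_UNIT
    raise ValueError(f"unknown conversion target {target!r}; choose one of {_TARGETS}")


def to_hb_grams(value: float, source: str) -> float:
    """Inverse of :func:`convert_hb`: express a loss given in ``source`` units as g Hb."""
    if source == "hb_g":
        return value
    if source == "rbc_mL":
        return value / RBC_ML_PER_G_HB
    if source == "blood_mL":
        return value / BLOOD_ML_PER_G_HB
    if source == "rbc_units":
        return value * G_HB_PER_RBC_UNIT
    raise ValueError(f"unknown source quantity {source!r}")
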