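"""Whole-blood hemoglobin absorption spectra.

Blood is characterised by a hematocrit of 43%, a hemoglobin concentration of
145 g/l blood and a mean cell hemoglobin concentration of 345 g/l RBC.  The
bundled tabulations (see ``data/``) are synthetic stand-ins for the standard
public molar-extinction compilations for oxygenated and reduced hemoglobin;
they reproduce the canonical Soret/Q-band structure and isosbestic crossings
of the visible range.  Molar extinction epsilon(lambda) in cm^-1/M is
converted to a whole-blood absorption coefficient in mm^-1 as

    mu_a = ln(10) * epsilon * c_hb / M_hb / 10

with c_hb = 145 g/l and hemoglobin molar mass M_hb = 64500 g/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .spectra import Spectrum, resample_to_grid

__all__ = ["ChromophoreSet", "load_chromophores", "HEMATOCRIT",
           "HB_CONCENTRATION_G_PER_L", "MCHC_G_PER_L_RBC", "HB_MOLAR_MASS"]

HEMATOCRIT = 0.43
HB_CONCENTRATION_G_PER_L = 145.0  # g hemoglobin per litre whole blood
MCHC_G_PER_L_RBC = 345.0  # mean cell hemoglobin concentration, g/l RBC
HB_MOLAR_MASS = 64500.0  # g/mol (tetramer)

_OXY_FILE = "hb_oxy_extinction_synthetic.csv"
_RED_FILE = "hb_red_extinction_synthetic.csv"


@dataclass(frozen=True)
class ChromophoreSet:
    """Whole-blood absorption spectra for fully oxygenated and reduced blood."""

    mu_a_oxy: Spectrum  # mm^-1
    mu_a_red: Spectrum  # mm^-1
    hematocrit: float = HEMATOCRIT
    hb_concentration: float = HB_CONCENTRATION_G_PER_L
    mchc: float = MCHC_G_PER_L_RBC

    def __post_init__(self) -> None:
        for name in ("mu_a_oxy", "mu_a_red"):
            s: Spectrum = getattr(self, name)
            if np.any(s.values <= 0):
                raise ValueError(f"{name} must be positive over the grid")


def _read_two_column_csv(name: str) -> np.ndarray:
    ref = resources.files("msiox.data").joinpath(name)
    try:
        with ref.open("rb") as fh:
            arr = np.loadtxt(fh, delimiter=",", comments="#")
    except (FileNotFoundError, ValueError) as exc:
        raise RuntimeError(f"bundled reference table {name!r} missing or corrupt") from exc
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise RuntimeError(f"bundled reference table {name!r} is not two-column")
    return arr


def extinction_to_mu_a(epsilon: Spectrum,
                       hb_concentration: float = HB_CONCENTRATION_G_PER_L) -> Spectrum:
    """Molar extinction (cm^-1/M) -> whole-blood absorption (mm^-1)."""
    factor = np.log(10.0) * hb_concentration / HB_MOLAR_MASS / 10.0
    return Spectrum(epsilon.values * factor, epsilon.grid)


def load_chromophores(hb_concentration: float = HB_CONCENTRATION_G_PER_L) -> ChromophoreSet:
    """Load the bundled hemoglobin tabulations as whole-blood mu_a spectra.

    The conversion is linear in ``hb_concentration`` (g/l blood).
    """
    oxy = resample_to_grid(_read_two_column_csv(_OXY_FILE))
    red = resample_to_grid(_read_two_column_csv(_RED_FILE))
    return ChromophoreSet(
        mu_a_oxy=extinction_to_mu_a(oxy, hb_concentration),
        mu_a_red=extinction_to_mu_a(red, hb_concentration),
        hb_concentration=hb_concentration,
    )
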