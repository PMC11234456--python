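"""Regenerate the bundled synthetic reference spectra in src/msiox/data/.

The hemoglobin tabulations are *synthetic stand-ins* for the standard public
molar-extinction compilations: smooth monotone (PCHIP-in-log) interpolations
through anchor points that reproduce the canonical features of oxygenated and
deoxygenated hemoglobin in the visible range — the Soret bands near 415/430 nm,
the oxy Q-bands at 542/577 nm, the single broad deoxy band at 555 nm, and
isosbestic crossings near 500/529/545/570/584 nm.  Values are in cm^-1/M.

The lamp file is the package's default synthetic white-LED emission shape
(blue die peak at 450 nm plus a broad phosphor band near 560 nm), in relative
irradiance units.

Run from the repository root:  python scripts/generate_reference_spectra.py
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

DATA = Path(__file__).resolve().parents[1] / "src" / "msiox" / "data"

# (wavelength nm, molar extinction cm^-1/M) anchors, oxygenated hemoglobin
OXY_ANCHORS = [
    (398, 230000), (400, 266000), (406, 350000), (414, 490000), (420, 480000),
    (430, 246000), (440, 102600), (450, 62800), (460, 44500), (470, 33200),
    (480, 26600), (490, 23700), (500, 21000), (510, 20000), (520, 24200),
    (530, 39000), (535, 46000), (542, 54500), (548, 50000), (553, 44000),
    (560, 32600), (565, 34500), (570, 45000), (577, 57000), (583, 42000),
    (590, 15000), (600, 3200), (610, 1100), (620, 600), (640, 400),
    (660, 320), (680, 290), (700, 290), (702, 290),
]

# anchors, deoxygenated (reduced) hemoglobin
RED_ANCHORS = [
    (398, 180000), (400, 223000), (410, 304000), (424, 460000), (430, 530000),
    (436, 470000), (440, 413000), (450, 103300), (455, 80000), (460, 72100),
    (470, 55500), (480, 50100), (490, 40000), (500, 22500), (505, 20500),
    (510, 25800), (520, 31000), (530, 38800), (540, 46600), (545, 51500),
    (550, 53400), (555, 54500), (560, 53800), (565, 50000), (570, 45500),
    (577, 38000), (584, 30000), (590, 25000), (600, 14700), (610, 9000),
    (630, 5300), (650, 3750), (660, 3200), (680, 2400), (700, 1800),
    (702, 1790),
]


def tabulate(anchors):
    a = np.asarray(anchors, dtype=float)
    f = PchipInterpolator(a[:, 0], np.log(a[:, 1]))
    wl = np.arange(398.0, 703.0, 1.0)
    return wl, np.exp(f(wl))


def write_csv(name, wl, val, header):
    out = DATA / name
    with out.open("w") as fh:
        fh.write(header)
        for w, v in zip(wl, val):
            fh.write(f"{w:.1f},{v:.6g}\n")
    print(f"wrote {out} ({out.stat().st_size} bytes)")


def lamp_spectrum(wl):
    blue = 1.00 * np.exp(-0.5 * ((wl - 450.0) / 10.0) ** 2)
    phosphor = 0.60 * np.exp(-0.5 * ((wl - 560.0) / 52.0) ** 2)
    return blue + phosphor + 0.01


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    wl, oxy = tabulate(OXY_ANCHORS)
    write_csv(
        "hb_oxy_extinction_synthetic.csv", wl, oxy,
        "# Synthetic stand-in tabulation of oxygenated hemoglobin molar "
        "extinction (cm^-1/M)\n# wavelength_nm,epsilon\n",
    )
    wl, red = tabulate(RED_ANCHORS)
    write_csv(
        "hb_red_extinction_synthetic.csv", wl, red,
        "# Synthetic stand-in tabulation of deoxygenated hemoglobin molar "
        "extinction (cm^-1/M)\n# wavelength_nm,epsilon\n",
    )
    write_csv(
        "lamp_white_led_synthetic.csv", wl, lamp_spectrum(wl),
        "# Synthetic white-LED emission spectrum (relative irradiance)\n"
        "# wavelength_nm,value\n",
    )


if __name__ == "__main__":
    main()
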