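"""Regenerate the bundled 120-kVp tungsten spectrum table.

A tabulated approximation of a filtered tungsten-anode spectrum:
thick-target bremsstrahlung (Kramers photon fluence ~ (E_max/E - 1))
hardened by 3 mm aluminum-equivalent inherent filtration, plus the tungsten
K fluorescence lines (K-alpha/K-beta, appearing above the 69.5 keV K edge
excitation), then 4.3 mm external aluminum filtration.  The line group is
normalized to ~8% of the continuum fluence before external filtration, a
typical value for heavily filtered 120-kVp beams.  The table is committed
as package data; rerun this script only to regenerate it.
"""

from pathlib import Path

import numpy as np

from pbisim.materials import builtin_table

KVP = 120.0
INHERENT_AL_MM = 3.0
EXTERNAL_AL_MM = 4.3
ENERGIES = np.arange(12.0, 120.0, 1.0)
K_LINES = {57.98: 0.291, 59.32: 0.508, 66.95: 0.057, 67.24: 0.110, 69.07: 0.034}
K_LINE_FRACTION = 0.08

OUT = Path(__file__).resolve().parents[1] / "src" / "pbisim" / "data" / "tungsten_120kvp_al4p3mm.csv"


def main():
    al = builtin_table()["aluminum"]
    mu = np.array([al.mu_at(e) for e in ENERGIES])
    fluence = (KVP / ENERGIES - 1.0) * np.exp(-mu * INHERENT_AL_MM)
    for e, w in K_LINES.items():
        idx = int(np.argmin(np.abs(ENERGIES - e)))
        fluence[idx] += w * K_LINE_FRACTION * fluence.sum()
    fluence *= np.exp(-mu * EXTERNAL_AL_MM)
    fluence /= fluence.max()
    mean = float((ENERGIES * fluence).sum() / fluence.sum())
    with open(OUT, "w") as fh:
        fh.write("# 120-kVp tungsten spectrum, 4.3 mm Al external filtration\n")
        fh.write("# approximation: Kramers continuum + 3 mm Al-equivalent inherent\n")
        fh.write("# filtration + W K lines; fluence-weighted mean energy "
                 f"{mean:.2f} keV\n")
        fh.write("# energy_keV relative_fluence\n")
        for e, f in zip(ENERGIES, fluence):
            if f > 1e-8:
                fh.write(f"{e:.1f} {f:.6g}\n")
    print(f"wrote {OUT} (mean energy {mean:.2f} keV, {np.count_nonzero(fluence > 1e-8)} bins)")


if __name__ == "__main__":
    main()
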