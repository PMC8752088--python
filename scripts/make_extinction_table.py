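"""Regenerate the packaged synthetic extinction table.

Run from the repository root:  python scripts/make_extinction_table.py
"""

from pathlib import Path

import numpy as np

import oispec.spectra as sp

HEADER = """\
# Synthetic haemoglobin extinction spectra (NOT measured data).
# Parametric Gaussian-band approximation of the qualitative visible-range
# oxy-/deoxy-haemoglobin spectra (alpha/beta bands at 542/577 nm, broad
# deoxy band at 556 nm, Soret-edge tails), generated by
# oispec.spectra.synthetic_extinction; see scripts/make_extinction_table.py.
# Coefficients are Napierian (natural-log) molar extinction, 1/(M*cm).
# Sampled every 1 nm over 450-650 nm.
"""


def main() -> None:
    lam = np.arange(450.0, 651.0, 1.0)
    eps_hbo, eps_hbr = sp.synthetic_extinction(lam)
    out = Path(__file__).resolve().parents[1] / "src" / "oispec" / "data" / "extinction_synthetic.tsv"
    with open(out, "w") as fh:
        fh.write(HEADER)
        fh.write("wavelength_nm\teps_hbo\teps_hbr\n")
        for l, eo, er in zip(lam, eps_hbo, eps_hbr):
            fh.write(f"{l:.0f}\t{eo:.6g}\t{er:.6g}\n")
    print(f"wrote {out} ({out.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
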