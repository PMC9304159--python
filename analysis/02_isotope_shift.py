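#!/usr/bin/env python
"""Iron(IV)-oxo stretch: frequency scaling and the 18O isotope shift.

Builds a diatomic 56Fe-16O oscillator whose stretch is tuned to 860 cm^-1,
recomputes the mode from the mass-weighted Hessian, applies the standard
0.95 harmonic scaling, and substitutes 18O to obtain the isotope shift that
identifies the ferryl stretch in difference spectra.
Writes results/isotope_shift.tsv.
"""

import argparse
from pathlib import Path

from oxoscope.masses import ISOTOPES
from oxoscope.synthetic_data import HarmonicPrescription, gen_harmonic_system
from oxoscope.thermochem import (
    hessian_frequencies,
    isotope_frequencies,
    scale_frequencies,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()

    presc = HarmonicPrescription(
        masses=[ISOTOPES["Fe56"], ISOTOPES["O16"]],
        wavenumbers=[860.0], elements=["Fe", "O"], label="FeO")
    rec = gen_harmonic_system(presc, seed=args.seed)
    nu16 = hessian_frequencies(rec.hessian, rec.geometry)[0]
    nu18 = isotope_frequencies(rec.hessian, rec.geometry, {1: "O18"})[0]
    nu16_scaled = scale_frequencies(
        hessian_frequencies(rec.hessian, rec.geometry), 0.95)[0]
    shift = nu16 - nu18

    lines = [
        "quantity\tvalue\tunit",
        f"nu_Fe16O\t{nu16:.2f}\tcm^-1",
        f"nu_Fe16O_scaled_0.95\t{nu16_scaled:.2f}\tcm^-1",
        f"nu_Fe18O\t{nu18:.2f}\tcm^-1",
        f"shift_16O_18O\t{shift:.2f}\tcm^-1",
        f"shift_scaled_0.95\t{0.95 * shift:.2f}\tcm^-1",
    ]
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "isotope_shift.tsv").write_text("\n".join(lines) + "\n")

    print(f"Fe=O stretch: {nu16:.1f} cm^-1 unscaled, "
          f"{nu16_scaled:.1f} cm^-1 with the 0.95 factor.")
    print(f"18O substitution lowers the stretch by {shift:.1f} cm^-1 "
          f"({0.95 * shift:.1f} cm^-1 on the scaled spectrum) - the "
          "signature used to assign the ferryl band.")


if __name__ == "__main__":
    main()
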