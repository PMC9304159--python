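#!/usr/bin/env python
"""Reaction landscapes and the selectivity reversal between cluster models.

Generates the two preset quintet-surface landscapes — the singly-protonated
His70 model ("B", barriers in a narrow window, lowest on C2) and the
doubly-protonated model ("C", C1 barriers far below C2) — runs the relative
-energy tables, spin-state ordering and Boltzmann selectivity verdicts, and
evaluates the published per-model free-energy barrier sets.
Writes results/landscape_*.tsv and results/selectivity.tsv.
"""

import argparse
from pathlib import Path

from oxoscope.landscape import (
    relative_table,
    selectivity_from_barriers,
    selectivity_report,
    spin_ordering,
)
from oxoscope.synthetic_data import TABLE1_DG, gen_landscape, preset_landscape


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    for name in ("tauD-modelB", "tauD-modelC"):
        scape = gen_landscape(preset_landscape(name), seed=args.seed)
        table = relative_table(scape)
        table.to_csv(out / f"landscape_{name.split('-')[-1]}.tsv",
                     sep="\t", index=False)
        verdict = next(iter(selectivity_report(scape).values()))
        print(f"{name}: lowest barrier {verdict.lowest_pathway} "
              f"({min(verdict.barriers.values()):.1f} kcal/mol), "
              f"window {verdict.window:.1f} kcal/mol -> "
              f"{verdict.dominant_carbon} {verdict.call}")
        res = [p for p in scape.points if p.role == "Re"]
        if len(res) > 1:
            so = spin_ordering(res)
            gaps = ", ".join(f"2S+1={m}: +{g:.1f}" for m, g in so.ordering[1:])
            print(f"  reactant ground state 2S+1={so.ground_multiplicity}; "
                  f"gaps (kcal/mol): {gaps}")

    lines = ["model\tlowest\twindow_kcal_mol\tC1_fraction\tcarbon\tcall"]
    for model, barriers in TABLE1_DG.items():
        v = selectivity_from_barriers(barriers, model=model)
        lines.append(f"{model}\t{v.lowest_pathway}\t{v.window:.2f}\t"
                     f"{v.carbon_fractions.get('C1', 0.0):.4f}\t"
                     f"{v.dominant_carbon}\t{v.call}")
    (out / "selectivity.tsv").write_text("\n".join(lines) + "\n")

    print("\nPer-model verdicts from the published free-energy barriers "
          "(see results/selectivity.tsv): the protonation state of the "
          "active-site histidine flips the preferred carbon - models with "
          "doubly protonated His70 (C) and the small-QM-region QM/MM model "
          "(DA) give C1, models B and DB put the lowest barrier on C2.")


if __name__ == "__main__":
    main()
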