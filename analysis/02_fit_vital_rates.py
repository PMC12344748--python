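#!/usr/bin/env python
"""Fit and select the community vital-rate models.

For every functional group x treatment: assemble the persistence /
expansion / colonisation transition rows, fit all candidate models
(32 + 32 + 8 per cell), select by AICc within two units subject to the
biological-plausibility screen, and export the selected coefficients.
Prints the sign pattern of the cross-group interaction coefficients —
the competition-to-facilitation shift across the precipitation gradient.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from coverdyn.pipeline import RunConfig, stage_fit
from coverdyn.survey import read_cover_table
from coverdyn.vitalrates import params_to_frame


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    records = read_cover_table(args.results / "survey.csv")
    cfg = RunConfig(mesh_m=30)
    fit = stage_fit(records, cfg)
    fit.selection_table().to_csv(args.results / "selected_models.csv",
                                 index=False)
    coefs = params_to_frame(fit.params_by_gt)
    coefs.to_csv(args.results / "vital_rate_params.csv", index=False)
    print(f"selected {len(fit.selected)} models "
          f"-> {args.results/'selected_models.csv'}")

    # interaction-sign table: cross-group abundance terms per treatment
    inter = coefs[(coefs["role"].isin(["persistence", "expansion_mean",
                                       "colonisation_mean"]))
                  & (coefs["term"].isin(["ug", "ul", "uf"]))
                  & (coefs["estimate"] != 0.0)]
    for tr in ("irrigation", "control", "drought"):
        sub = inter[inter["treatment"] == tr]
        neg = int((sub["estimate"] < 0).sum())
        pos = int((sub["estimate"] > 0).sum())
        print(f"{tr:11s}: {neg} competitive (-), {pos} facilitative (+) "
              f"abundance terms selected")


if __name__ == "__main__":
    main()
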