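#!/usr/bin/env python
"""Nitrogen budget of peptide decomposition and phosphorus demand.

Closes the four-pool nitrogen budget (hydrolysis products, ammonium,
bacterial biomass, residual DON) for every active bottle at 24 h, using
the unamended control of the same depth for the ammonium correction, and
converts each bottle's cell increase into its phosphate demand.  Writes
results/nitrogen_budget.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from peptide_sip import ConversionConstants
from peptide_sip import io as sip_io
from peptide_sip.mass_balance import (
    biomass_n_fraction,
    close_budget,
    hydrolysis_fraction,
    phosphorus_demand,
    remineralization_fraction,
)

BASE = Path(__file__).resolve().parent.parent / "results"
REFERENCE_TIME_H = 24.0
F_BEARING = ("F", "VF", "FA", "VFA")  # each carries exactly one phenylalanine


def main() -> None:
    constants = ConversionConstants()
    series = sip_io.read_incubation_series(BASE / "synthetic" / "incubation.tsv")
    controls = {s.depth: s for s in series if s.treatment == "control"}
    rows = []
    for s in series:
        if s.treatment not in ("12C", "13C"):
            continue
        t = np.asarray(s.times)
        i = int(np.argmin(np.abs(t - REFERENCE_TIME_H)))
        consumed = s.peptide[0] - s.peptide[i]
        if consumed <= 0:
            continue
        f_products = sum((s.analytes or {}).get(a, (0.0,) * len(t))[i] for a in F_BEARING)
        ctrl = controls[s.depth]
        d_nh4 = s.ammonium[i] - s.ammonium[0]
        d_nh4_ctrl = ctrl.ammonium[i] - ctrl.ammonium[0]
        d_cells = max(max(s.cells[: i + 1]) - s.cells[0], 0.0)
        budget = close_budget(
            hydrolysis_fraction(f_products, consumed),
            remineralization_fraction(d_nh4, d_nh4_ctrl, consumed, constants.N_per_peptide),
            biomass_n_fraction(d_cells, constants, consumed),
            reference_time_h=REFERENCE_TIME_H,
        )
        rows.append(
            {
                "treatment": s.treatment,
                "depth": s.depth,
                "replicate": s.replicate,
                "time_h": REFERENCE_TIME_H,
                "peptide_consumed_uM": consumed,
                "hydrolysis": budget.hydrolysis_fraction,
                "remineralization": budget.remineralization_fraction,
                "biomass": budget.biomass_fraction,
                "residual_DON": budget.residual_DON_fraction,
                "delta_cells_per_mL": d_cells,
                "P_demand_uM": phosphorus_demand(d_cells, constants),
            }
        )
    budget_table = pd.DataFrame(rows)
    budget_table.to_csv(BASE / "nitrogen_budget.tsv", sep="\t", index=False)

    for depth, grp in budget_table.groupby("depth"):
        print(
            f"{depth} (mean of {len(grp)} bottles at {REFERENCE_TIME_H:.0f} h): "
            f"hydrolysis {grp.hydrolysis.mean():.0%}, "
            f"ammonium {grp.remineralization.mean():.0%}, "
            f"biomass {grp.biomass.mean():.0%}, "
            f"residual DON {grp.residual_DON.mean():.0%}; "
            f"P demand {grp.P_demand_uM.min():.3f}-{grp.P_demand_uM.max():.3f} uM"
        )


if __name__ == "__main__":
    main()
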