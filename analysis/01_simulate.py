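#!/usr/bin/env python
"""Generate the synthetic study datasets.

Builds a 10-taxon coastal community with three peptide incorporators,
simulates paired unlabeled/labeled CsCl gradients for surface and bottom
water plus the full incubation bottle set, and writes every table under
results/synthetic/.  Downstream scripts read these files only.
"""

from pathlib import Path

from peptide_sip import SimulationConfig, default_community
from peptide_sip import io as sip_io
from peptide_sip.synthetic_data import simulate_gradient_pair, simulate_incubation

SEED = 20260926
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    community = default_community()
    config = SimulationConfig(seed=SEED)

    for depth in ("surface", "bottom"):
        pair = simulate_gradient_pair(community, config, seed=SEED, depth=depth)
        for key in ("12c", "13c"):
            sip_io.write_fraction_table(
                pair[f"profile_{key}"], OUT / f"fractions_{depth}_{key.upper()}.tsv"
            )
            sip_io.write_taxon_table(
                pair[f"table_{key}"], OUT / f"taxa_{depth}_{key.upper()}.tsv"
            )
    series = simulate_incubation(config, seed=SEED)
    sip_io.write_incubation_series(series, OUT / "incubation.tsv")

    labeled = [t.label for t in community.taxa if t.atom_fraction_13c > 0]
    print(f"seed {SEED}: wrote gradients and incubation series to {OUT}")
    print(f"community: {len(community.taxa)} taxa, incorporators: {labeled}")
    print(f"bottles: {len(series)} (duplicated treatments + controls, 2 depths)")


if __name__ == "__main__":
    main()
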