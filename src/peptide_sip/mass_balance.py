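"""Nitrogen mass balance of peptide decomposition and phosphorus demand.

The nitrogen of a decomposed tetrapeptide is partitioned into four pools:
extracellular hydrolysis products (tracked via phenylalanine and
F-containing fragments, since F uptake is slow on the 24 h timescale),
remineralization to ammonium (treatment-minus-control, nitrification
assumed negligible), incorporation into bacterial biomass (from the cell
increase via a carbon-per-cell conversion and a bacterial C/N ratio), and
a residual dissolved-organic-nitrogen pool computed as the closure term.
A companion calculation converts an observed cell increase into the
phosphate it must have consumed, from cell dry mass and cellular P
content.

Conventions: fractions are reported unclipped (measurement noise can make
them slightly negative; they are flagged, not truncated) and nominal
atomic masses (N = 14, P = 31 g/mol) match the precision of the input
constants.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ConversionConstants",
    "NitrogenBudget",
    "hydrolysis_fraction",
    "remineralization_fraction",
    "biomass_nitrogen_um",
    "biomass_n_fraction",
    "close_budget",
    "phosphorus_demand",
]

_FRACTION_BOUNDS = (-0.05, 1.05)  # noise-tolerant plausibility band


@dataclass(frozen=True)
class ConversionConstants:
    """Cell-to-element conversion factors.

    fg_C_per_cell: carbon content per bacterial cell, fg (default 20).
    bacterial_CN: bacterial C/N mass ratio, dimensionless (default 4).
    cell_dry_mass_pg: dry mass per cell, pg (default 0.2).
    P_content: phosphorus mass fraction of dry mass (default 0.013).
    N_per_peptide: nitrogen atoms per substrate molecule (4 for a
    tetrapeptide of A, V, F with no side-chain nitrogen).
    """

    fg_C_per_cell: float = 20.0
    bacterial_CN: float = 4.0
    cell_dry_mass_pg: float = 0.2
    P_content: float = 0.013
    N_per_peptide: int = 4
    atomic_mass_N: float = 14.0
    atomic_mass_P: float = 31.0

    def __post_init__(self) -> None:
        for name in (
            "fg_C_per_cell",
            "bacterial_CN",
            "cell_dry_mass_pg",
            "P_content",
            "N_per_peptide",
            "atomic_mass_N",
            "atomic_mass_P",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class NitrogenBudget:
    """Four-way nitrogen partition; residual DON closes the budget to 1."""

    hydrolysis_fraction: float
    remineralization_fraction: float
    biomass_fraction: float
    residual_DON_fraction: float
    reference_time_h: float | None = None
    over_closure: bool = False
    negative_inputs: bool = False

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (
            self.hydrolysis_fraction,
            self.remineralization_fraction,
            self.biomass_fraction,
            self.residual_DON_fraction,
        )


def _check_consumed(peptide_consumed_um: float) -> None:
    if peptide_consumed_um <= 0:
        raise ValueError("peptide consumption must be > 0 to compute a fraction")


def hydrolysis_fraction(f_products_um: float, peptide_consumed_um: float) -> float:
    """Fraction of consumed peptide found as F and F-containing fragments.

    Each product molecule carries one phenylalanine, so the mole sum of
    F-bearing products over the peptide consumed estimates the share that
    was hydrolyzed extracellularly rather than taken up whole.
    """
    _check_consumed(peptide_consumed_um)
    if f_products_um < 0:
        raise ValueError("product concentration must be >= 0")
    return f_products_um / peptide_consumed_um


def remineralization_fraction(
    delta_nh4_treatment_um: float,
    delta_nh4_control_um: float,
    peptide_consumed_um: float,
    n_per_molecule: int = 4,
) -> float:
    """Fraction of peptide nitrogen remineralized to ammonium.

    Control-corrected ammonium increase over the peptide nitrogen consumed
    (consumed peptide x N atoms per molecule), assuming nitrification is
    negligible on the incubation timescale.  Small negative results from
    measurement noise are returned as-is.
    """
    _check_consumed(peptide_consumed_um)
    net = delta_nh4_treatment_um - delta_nh4_control_um
    return net / (peptide_consumed_um * n_per_molecule)


def biomass_nitrogen_um(
    delta_cells_per_ml: float,
    constants: ConversionConstants = ConversionConstants(),
) -> float:
    """Nitrogen bound in a cell increase, uM N.

    cells/mL x fg C/cell -> g C/L (x 1e-12), divided by the C/N mass ratio
    to g N/L, divided by 14 g/mol to mol/L, expressed in uM.
    """
    if delta_cells_per_ml < 0:
        raise ValueError("cell increase must be >= 0")
    g_c_per_l = delta_cells_per_ml * constants.fg_C_per_cell * 1e-12
    g_n_per_l = g_c_per_l / constants.bacterial_CN
    return g_n_per_l / constants.atomic_mass_N * 1e6


def biomass_n_fraction(
    delta_cells_per_ml: float,
    constants: ConversionConstants,
    peptide_consumed_um: float,
) -> float:
    """Fraction of peptide nitrogen incorporated into bacterial biomass."""
    _check_consumed(peptide_consumed_um)
    n_um = biomass_nitrogen_um(delta_cells_per_ml, constants)
    return n_um / (peptide_consumed_um * constants.N_per_peptide)


def close_budget(
    hydrolysis: float,
    remineralization: float,
    biomass: float,
    reference_time_h: float | None = None,
) -> NitrogenBudget:
    """Close the nitrogen budget: residual DON = 1 - (sum of measured pools).

    The residual pool is never measured; it is the closure term for
    peptide nitrogen not recovered as fragments, ammonium, or biomass.
    Inputs summing beyond 1.05 are flagged as over-closure but still
    returned.
    """
    lo, hi = _FRACTION_BOUNDS
    inputs = (hydrolysis, remineralization, biomass)
    for name, v in zip(("hydrolysis", "remineralization", "biomass"), inputs):
        if not lo <= v <= hi:
            raise ValueError(
                f"{name} fraction {v} outside the plausible band [{lo}, {hi}]"
            )
    total = sum(inputs)
    return NitrogenBudget(
        hydrolysis_fraction=hydrolysis,
        remineralization_fraction=remineralization,
        biomass_fraction=biomass,
        residual_DON_fraction=1.0 - total,
        reference_time_h=reference_time_h,
        over_closure=total > hi,
        negative_inputs=any(v < 0 for v in inputs),
    )


def phosphorus_demand(
    delta_cells_per_ml: float,
    constants: ConversionConstants = ConversionConstants(),
) -> float:
    """Phosphate demand of an observed cell increase, uM P.

    cells/mL x pg dry mass/cell x P mass fraction -> g P/L (x 1e-9),
    divided by 31 g/mol, expressed in uM.
    """
    if delta_cells_per_ml < 0:
        raise ValueError("cell increase must be >= 0")
    g_p_per_l = (
        delta_cells_per_ml * constants.cell_dry_mass_pg * constants.P_content * 1e-9
    )
    return g_p_per_l / constants.atomic_mass_P * 1e6
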