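"""Elemental composition, isotope-labeling accounting, and SIM m/z for peptides.

A peptide given by its one-letter sequence is condensed from free amino
acids with loss of one water per peptide bond.  The module tracks which
carbon positions carry a heavy isotope (site-specific ``13C`` labeling
schemes, e.g. a tetrapeptide with 17 of 20 carbons labeled) and computes
the nominal [M+H]+ m/z used for selected-ion-monitoring quantitation on a
quadrupole instrument, where each ``13C`` adds one nominal mass unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "PeptideSpec",
    "RESIDUE_FORMULAS",
    "AVFA_LABEL_SCHEME",
    "compose_peptide",
    "count_labeled_carbons",
    "sim_mz",
    "monoisotopic_mass",
]

# Free (un-condensed) amino-acid molecular formulas, element -> atom count.
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 5, "N": 1, "O": 2},
    "A": {"C": 3, "H": 7, "N": 1, "O": 2},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2},
    "I": {"C": 6, "H": 13, "N": 1, "O": 2},
    "N": {"C": 4, "H": 8, "N": 2, "O": 3},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2},
}

# Nominal (integer) atomic masses: SIM channels on a quadrupole are integer m/z.
NOMINAL_MASS: dict[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32}

# Monoisotopic masses, exposed as a secondary output only.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
}

#: Labeling scheme of the model tetrapeptide AVFA: all three carbons of each
#: alanine, all five of valine, and the six aromatic-ring carbons of
#: phenylalanine -> 17 of 20 carbons.
AVFA_LABEL_SCHEME: dict[int, int] = {0: 3, 1: 5, 2: 6, 3: 3}


@dataclass(frozen=True)
class PeptideSpec:
    """Condensed peptide: sequence, elemental composition, and label bookkeeping.

    ``composition`` is the formula of the whole peptide (residues joined with
    loss of one water per bond).  ``labeled_carbons`` counts heavy-carbon
    positions under ``label_scheme``, a mapping of 0-based residue position to
    the number of labeled carbons contributed by that residue.
    """

    sequence: str
    composition: Mapping[str, int]
    labeled_carbons: int = 0
    label_scheme: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition counts must be non-negative")
        if self.labeled_carbons > self.composition.get("C", 0):
            raise ValueError(
                f"labeled_carbons ({self.labeled_carbons}) exceeds total "
                f"carbon count ({self.composition.get('C', 0)})"
            )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def compose_peptide(
    sequence: str, label_scheme: Mapping[int, int] | None = None
) -> PeptideSpec:
    """Build a :class:`PeptideSpec` from a one-letter amino-acid sequence.

    The composition is the sum of the free amino-acid formulas minus
    ``(n - 1)`` waters.  A single residue is the free amino acid itself.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a letter outside the 20
        standard amino acids.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    comp: dict[str, int] = {}
    for ch in sequence:
        try:
            formula = RESIDUE_FORMULAS[ch]
        except KeyError:
            raise ValueError(f"unknown residue letter {ch!r}") from None
        for el, n in formula.items():
            comp[el] = comp.get(el, 0) + n
    n_bonds = len(sequence) - 1
    comp["H"] -= 2 * n_bonds
    comp["O"] -= n_bonds
    spec = PeptideSpec(sequence=sequence, composition=comp)
    if label_scheme is not None:
        n = count_labeled_carbons(spec, label_scheme)
        spec = PeptideSpec(
            sequence=sequence,
            composition=comp,
            labeled_carbons=n,
            label_scheme=dict(label_scheme),
        )
    return spec


def count_labeled_carbons(
    spec: PeptideSpec, scheme: Mapping[int, int] | Sequence[int]
) -> int:
    """Total heavy carbons under a per-residue-position labeling scheme.

    ``scheme`` maps 0-based residue position to the number of labeled carbons
    at that position (a plain sequence of per-position counts is also
    accepted).  Each count must not exceed the carbon count of the residue at
    that position.
    """
    if not isinstance(scheme, Mapping):
        scheme = dict(enumerate(scheme))
    total = 0
    for pos, n_labeled in scheme.items():
        if pos < 0 or pos >= len(spec.sequence):
            raise ValueError(f"scheme position {pos} outside sequence")
        residue = spec.sequence[pos]
        n_carbons = RESIDUE_FORMULAS[residue]["C"]
        if n_labeled < 0 or n_labeled > n_carbons:
            raise ValueError(
                f"labeled count {n_labeled} at position {pos} exceeds the "
                f"{n_carbons} carbons of residue {residue!r}"
            )
        total += n_labeled
    return total


def sim_mz(spec: PeptideSpec, n_labeled: int) -> int:
    """Nominal [M+H]+ m/z of a singly protonated peptide with ``n_labeled`` 13C.

    Each heavy carbon adds exactly one nominal mass unit, so the SIM channel
    for the labeled form sits ``n_labeled`` units above the unlabeled one.
    """
    n_carbons = spec.composition.get("C", 0)
    if not 0 <= n_labeled <= n_carbons:
        raise ValueError(
            f"n_labeled must be in [0, {n_carbons}], got {n_labeled}"
        )
    mass = sum(NOMINAL_MASS[el] * n for el, n in spec.composition.items())
    return mass + 1 + n_labeled


def monoisotopic_mass(spec: PeptideSpec) -> float:
    """Monoisotopic neutral mass (secondary output; SIM channels use nominal)."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in spec.composition.items())
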