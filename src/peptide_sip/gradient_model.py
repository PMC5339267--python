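"""CsCl buoyant-density gradient fractions and qPCR normalization.

After isopycnic ultracentrifugation a gradient is collected as ~30
fractions; each fraction has a buoyant density (measured directly or via
refractive index) and a 16S rRNA gene copy number from qPCR.  Copy numbers
are normalized within a gradient to its maximum ("ratio of quantities",
max = 1), the dense "heavy window" is selected for the enrichment
statistic, and a density shift between paired labeled/unlabeled gradients
converts to a percent-13C-incorporation estimate via the full-label shift
of 100 atom% 13C DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Fraction",
    "GradientProfile",
    "HeavyWindow",
    "DEFAULT_RI_SLOPE",
    "DEFAULT_RI_INTERCEPT",
    "DEFAULT_FULL_LABEL_SHIFT",
    "density_from_ri",
    "ri_from_density",
    "normalize_quantities",
    "select_heavy",
    "default_heavy_window",
    "incorporation_from_shift",
]

# CsCl at 20 degC: linear refractive-index -> density calibration.
DEFAULT_RI_SLOPE = 10.8601
DEFAULT_RI_INTERCEPT = -13.4974

#: Buoyant-density shift of fully (100 atom%) 13C-labeled DNA, g mL^-1.
DEFAULT_FULL_LABEL_SHIFT = 0.036

_DENSITY_BOUNDS = (1.60, 1.85)  # sanity range for CsCl gradients
_RI_BOUNDS = (1.34, 1.42)
_DENSITY_DECIMALS = 4  # densities compared at 4 decimals (boundary stability)


@dataclass(frozen=True)
class Fraction:
    """One collected gradient fraction (index 1 = densest end, collection order)."""

    index: int
    density: float
    copies: float
    refractive_index: float | None = None
    copies_sd: float | None = None
    below_detection: bool = False

    def __post_init__(self) -> None:
        lo, hi = _DENSITY_BOUNDS
        if not lo <= self.density <= hi:
            raise ValueError(
                f"fraction {self.index}: density {self.density} g/mL outside "
                f"plausible CsCl range [{lo}, {hi}]"
            )
        if self.copies < 0:
            raise ValueError(f"fraction {self.index}: copies must be >= 0")


@dataclass(frozen=True)
class GradientProfile:
    """Ordered fractions of one treatment's gradient, optionally normalized."""

    treatment: str  # "12C" | "13C"
    depth: str  # "surface" | "bottom"
    fractions: tuple[Fraction, ...]
    ratio_of_quantities: tuple[float, ...] | None = None

    def __init__(
        self,
        treatment: str,
        depth: str,
        fractions: Sequence[Fraction],
        ratio_of_quantities: Sequence[float] | None = None,
    ) -> None:
        object.__setattr__(self, "treatment", treatment)
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "fractions", tuple(fractions))
        object.__setattr__(
            self,
            "ratio_of_quantities",
            None if ratio_of_quantities is None else tuple(ratio_of_quantities),
        )

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.density for f in self.fractions])

    @property
    def copies(self) -> np.ndarray:
        return np.array([f.copies for f in self.fractions])

    def fraction_ids(self) -> list[int]:
        return [f.index for f in self.fractions]


@dataclass(frozen=True)
class HeavyWindow:
    """Closed density interval [density_min, density_max] for enrichment sums."""

    density_min: float
    density_max: float

    def __post_init__(self) -> None:
        if not self.density_min < self.density_max:
            raise ValueError("density_min must be < density_max")

    def contains(self, density: float) -> bool:
        d = round(density, _DENSITY_DECIMALS)
        return (
            round(self.density_min, _DENSITY_DECIMALS)
            <= d
            <= round(self.density_max, _DENSITY_DECIMALS)
        )


def density_from_ri(
    refractive_index: float,
    slope: float = DEFAULT_RI_SLOPE,
    intercept: float = DEFAULT_RI_INTERCEPT,
) -> float:
    """Buoyant density (g mL^-1) from refractive index via a linear calibration."""
    lo, hi = _RI_BOUNDS
    if not lo <= refractive_index <= hi:
        raise ValueError(
            f"refractive index {refractive_index} outside plausible CsCl "
            f"range [{lo}, {hi}]"
        )
    return slope * refractive_index + intercept


def ri_from_density(
    density: float,
    slope: float = DEFAULT_RI_SLOPE,
    intercept: float = DEFAULT_RI_INTERCEPT,
) -> float:
    """Inverse of :func:`density_from_ri` (requires non-zero slope)."""
    if slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    return (density - intercept) / slope


def normalize_quantities(profile: GradientProfile) -> GradientProfile:
    """Attach per-fraction ratios of quantities (copies / gradient maximum).

    The highest copy number in the gradient maps to exactly 1, accounting
    for differential total DNA between gradients.  All-zero gradients are
    rejected — there is nothing to normalize.
    """
    copies = profile.copies
    peak = copies.max() if len(copies) else 0.0
    if peak <= 0:
        raise ValueError(
            f"gradient {profile.treatment}/{profile.depth}: all copy numbers "
            "are zero; cannot normalize"
        )
    return replace(profile, ratio_of_quantities=tuple(copies / peak))


def select_heavy(profile: GradientProfile, window: HeavyWindow) -> list[Fraction]:
    """Fractions whose density lies in the closed heavy window, order preserved."""
    return [f for f in profile.fractions if window.contains(f.density)]


def default_heavy_window(
    profile_12c: GradientProfile, profile_13c: GradientProfile
) -> HeavyWindow:
    """Heavy window from the paired gradients' normalized profiles.

    Default rule: among the contiguous runs of fractions in which the
    labeled gradient's ratio of quantities exceeds the unlabeled one's
    (the unlabeled ratio is interpolated onto the labeled gradient's
    densities when the two gradients were not fractionated identically),
    take the run with the largest cumulative excess, breaking ties toward
    the dense end.  This mirrors reading the dominant dense-side excess
    region off a ratio-vs-density plot without hard-coding numeric bounds;
    labeling shifts DNA denser, so the dominant excess run sits at the
    dense side, while isolated noise flickers in near-empty tail fractions
    carry negligible cumulative excess and are ignored.
    """
    p12 = (
        profile_12c
        if profile_12c.ratio_of_quantities is not None
        else normalize_quantities(profile_12c)
    )
    p13 = (
        profile_13c
        if profile_13c.ratio_of_quantities is not None
        else normalize_quantities(profile_13c)
    )
    d13 = p13.densities
    order13 = np.argsort(d13)
    d13s = d13[order13]
    r13s = np.asarray(p13.ratio_of_quantities)[order13]
    d12 = p12.densities
    order12 = np.argsort(d12)
    r12_on_13 = np.interp(
        d13s, d12[order12], np.asarray(p12.ratio_of_quantities)[order12]
    )
    diff = r13s - r12_on_13
    excess = diff > 0
    if not excess.any():
        raise ValueError(
            "labeled gradient nowhere exceeds the unlabeled one; no default "
            "heavy window — supply explicit bounds"
        )
    # contiguous excess runs, scored by cumulative excess; densest wins ties
    runs: list[tuple[float, int, int]] = []
    i = 0
    while i < len(excess):
        if excess[i]:
            j = i
            while j + 1 < len(excess) and excess[j + 1]:
                j += 1
            runs.append((float(diff[i : j + 1].sum()), i, j))
            i = j + 1
        else:
            i += 1
    _, lo, hi = max(runs, key=lambda r: (r[0], r[2]))
    if lo == hi:
        # single-fraction run: pad to half the local fraction spacing so the
        # window is a proper interval still containing only that fraction
        pad = float(np.median(np.diff(d13s))) / 2 if len(d13s) > 1 else 1e-4
        return HeavyWindow(density_min=d13s[lo] - pad, density_max=d13s[hi] + pad)
    return HeavyWindow(density_min=d13s[lo], density_max=d13s[hi])


def incorporation_from_shift(
    delta_density: float,
    full_label_shift: float = DEFAULT_FULL_LABEL_SHIFT,
) -> tuple[float, int]:
    """Percent 13C incorporation implied by a buoyant-density shift.

    Linear in the shift: 100 * delta / full_label_shift, where
    ``full_label_shift`` is the density increase of fully 13C-labeled DNA
    (default 0.036 g mL^-1).  Returns ``(raw_percent, rounded_percent)``.
    """
    if delta_density < 0:
        raise ValueError("delta_density must be >= 0")
    if full_label_shift <= 0:
        raise ValueError("full_label_shift must be > 0")
    raw = 100.0 * delta_density / full_label_shift
    return raw, int(round(raw))
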