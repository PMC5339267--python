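"""Zero-order decay kinetics for peptide incubation time series.

Peptide decomposition in these incubations is enzyme-limited: the
concentration falls linearly with time, so the rate is the negative OLS
slope of concentration vs. time.  Points after the substrate is exhausted
carry no kinetic information and would bias the slope low, so the fit uses
only observations up to and including the first one below the quantitation
floor.  Rates are normalized to initial cell abundance for cell-specific
comparisons, and groups of rates are compared with a Welch two-sample
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IncubationSeries",
    "RateEstimate",
    "DEFAULT_QUANT_FLOOR",
    "fit_zero_order",
    "cell_specific_rate",
    "compare_rates",
]

#: Default quantitation floor for the peptide HPLC-MS assay, uM.
DEFAULT_QUANT_FLOOR = 0.01

#: Killed-control peptide is expected "nearly unchanged": flag if it moves
#: by more than this fraction of its initial value.
KILLED_CONTROL_TOLERANCE = 0.20


@dataclass(frozen=True)
class IncubationSeries:
    """Time-resolved concentrations and cell counts for one bottle.

    ``times`` in hours, strictly increasing from 0.  ``peptide`` in uM.
    ``analytes`` maps analyte names (free amino acids A/V/F and fragments
    AV/VF/FA/VFA) to uM series; ``ammonium`` and ``phosphate`` in uM;
    ``cells`` in cells per mL.  Optional series may be None.
    """

    treatment: str  # "12C" | "13C" | "control" | "killed"
    depth: str  # "surface" | "bottom"
    replicate: str
    times: tuple[float, ...]
    peptide: tuple[float, ...]
    analytes: dict[str, tuple[float, ...]] | None = None
    ammonium: tuple[float, ...] | None = None
    phosphate: tuple[float, ...] | None = None
    cells: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if len(t) == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        for name, series in self._all_series():
            if series is not None and len(series) != len(t):
                raise ValueError(f"{name} length does not match times")
            if series is not None and any(v < 0 for v in series):
                raise ValueError(f"{name} has negative concentrations")

    def _all_series(self):
        yield "peptide", self.peptide
        yield "ammonium", self.ammonium
        yield "phosphate", self.phosphate
        yield "cells", self.cells
        for k, v in (self.analytes or {}).items():
            yield k, v

    def killed_control_drifted(self, tolerance: float = KILLED_CONTROL_TOLERANCE) -> bool:
        """True if a killed control's peptide moved > tolerance x initial value."""
        c = np.asarray(self.peptide)
        return bool(np.abs(c - c[0]).max() > tolerance * c[0])


@dataclass(frozen=True)
class RateEstimate:
    """Zero-order fit result: k in uM/h (positive = loss)."""

    k: float
    intercept: float
    n_points_used: int
    depletion_time: float
    k_stderr: float | None = None
    cell_specific_k: float | None = None


def fit_zero_order(
    series: IncubationSeries | None = None,
    floor: float = DEFAULT_QUANT_FLOOR,
    *,
    times: np.ndarray | None = None,
    concentrations: np.ndarray | None = None,
) -> RateEstimate:
    """OLS zero-order rate from a peptide time series.

    Uses the points up to and including the first observation below the
    quantitation floor (that point anchors depletion; later bottomed-out
    points are excluded).  ``depletion_time`` is the first sub-floor time,
    or the last observed time if the substrate never depleted.  Accepts a
    full :class:`IncubationSeries` or raw ``times``/``concentrations``.
    """
    if series is not None:
        t = np.asarray(series.times, dtype=float)
        c = np.asarray(series.peptide, dtype=float)
    else:
        if times is None or concentrations is None:
            raise ValueError("provide a series or both times and concentrations")
        t = np.asarray(times, dtype=float)
        c = np.asarray(concentrations, dtype=float)

    below = np.flatnonzero(c < floor)
    if below.size:
        last = below[0]  # keep the first sub-floor point, drop the rest
        depletion_time = float(t[last])
    else:
        last = len(t) - 1
        depletion_time = float(t[-1])
    t_fit, c_fit = t[: last + 1], c[: last + 1]
    if len(t_fit) < 2:
        raise ValueError(
            f"fewer than 2 usable points above the {floor} uM floor; cannot fit"
        )
    fit = stats.linregress(t_fit, c_fit)
    return RateEstimate(
        k=-fit.slope,
        intercept=fit.intercept,
        n_points_used=len(t_fit),
        depletion_time=depletion_time,
        k_stderr=float(fit.stderr) if len(t_fit) > 2 else None,
    )


def cell_specific_rate(k: float, initial_cells: float) -> float:
    """Rate per cell: k / initial abundance, uM h^-1 cell^-1 mL."""
    if initial_cells <= 0:
        raise ValueError("initial cell count must be > 0")
    return k / initial_cells


def compare_rates(rates_a, rates_b) -> dict[str, float]:
    """Ratio of group means with a Welch two-sample t-test.

    Degenerate zero-variance groups are reported (``degenerate=True``,
    p-value NaN) rather than raising.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 rate values per group")
    ratio = a.mean() / b.mean()
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate:
        # no within-group spread: the test statistic is ill-defined
        equal = np.isclose(a.mean(), b.mean())
        t_stat = 0.0 if equal else np.inf * np.sign(a.mean() - b.mean())
        p_value = 1.0 if equal else 0.0
    else:
        t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
    return {
        "ratio_of_means": float(ratio),
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "degenerate": bool(degenerate),
    }
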