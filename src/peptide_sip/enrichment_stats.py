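"""Per-taxon SIP percentage enrichment and its noise threshold.

The core statistic of the analysis.  Within a heavy density window, each
taxon's read proportion per fraction is multiplied by that fraction's 16S
gene copy number and summed; the sums are normalized to the window total
(relative gene copy numbers, correcting for total-DNA differences between
gradients), and the labeled gradient is compared to the unlabeled one:

    percent_enrichment = 100 * (rel_13C - rel_12C) / rel_12C

so a taxon twice as abundant in the labeled heavy window scores 100%.
A noise threshold is estimated from the strictly positive enrichment
values, either as the upper limit of a 95% t-confidence interval of their
mean or as their 97.5th percentile; taxa are flagged when strictly above
it and when they pass a community-abundance floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .gradient_model import GradientProfile, HeavyWindow, select_heavy

__all__ = [
    "FractionTaxonTable",
    "taxon_copy_numbers",
    "relative_copy_numbers",
    "percent_enrichment",
    "noise_threshold",
    "flag_enriched",
    "collapse_to_class",
    "enrichment_report",
]


@dataclass(frozen=True)
class FractionTaxonTable:
    """Taxon x fraction read counts at one taxonomic rank.

    ``counts`` is indexed by taxon label with one column per fraction
    identifier; values are non-negative read counts.  ``rank`` is the
    taxonomic rank of the rows ("class" or "genus").  Proportions are
    derived per fraction (columns sum to 1 where the column has reads);
    all-zero fractions are flagged, never silently zero-filled.
    """

    counts: pd.DataFrame
    rank: str = "genus"

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon labels within rank: {dups}")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def zero_fractions(self) -> list:
        """Fraction identifiers with no reads (proportions undefined there)."""
        totals = self.counts.sum(axis=0)
        return list(totals.index[totals == 0])

    @property
    def proportions(self) -> pd.DataFrame:
        """Column-normalized counts; all-zero columns become NaN."""
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = self.counts / totals.replace(0, np.nan)
        return props

    def mean_relative_abundance(self) -> pd.Series:
        """Community-wide mean proportion per taxon across informative fractions."""
        return self.proportions.mean(axis=1, skipna=True)


def taxon_copy_numbers(
    table: FractionTaxonTable,
    profile: GradientProfile,
    window: HeavyWindow,
) -> pd.Series:
    """Per-taxon 16S copies within the heavy window.

    For each taxon, sum over the window's fractions of (taxon proportion in
    the fraction) x (fraction's qPCR copy number).  Table columns must match
    the profile's fraction identifiers one-to-one.
    """
    profile_ids = set(profile.fraction_ids())
    table_ids = set(table.counts.columns)
    if profile_ids != table_ids:
        missing = sorted(profile_ids ^ table_ids)
        raise ValueError(
            f"fraction identifiers do not match between taxon table and "
            f"gradient profile; unmatched: {missing}"
        )
    heavy = select_heavy(profile, window)
    result = pd.Series(0.0, index=table.counts.index)
    props = table.proportions
    for frac in heavy:
        col = props[frac.index]
        if col.isna().all():
            continue  # no reads in this fraction: contributes nothing
        result = result + col.fillna(0.0) * frac.copies
    return result


def relative_copy_numbers(taxon_copies: pd.Series) -> pd.Series:
    """Normalize window copy numbers to the window total (sums to 1)."""
    total = taxon_copies.sum()
    if total <= 0:
        raise ValueError("total copy number in window is zero; cannot normalize")
    return taxon_copies / total


def percent_enrichment(rel_13c: pd.Series, rel_12c: pd.Series) -> pd.Series:
    """Percentage enrichment of the labeled over the unlabeled gradient.

    100 * (rel13 - rel12) / rel12 per taxon, over the outer join of taxa.
    Where the unlabeled relative copy number is zero (or the taxon is
    absent from one side) the statistic is undefined and reported as NaN,
    never as infinity and never dropped.
    """
    idx = rel_13c.index.union(rel_12c.index)
    r13 = rel_13c.reindex(idx)
    r12 = rel_12c.reindex(idx)
    out = pd.Series(np.nan, index=idx, dtype=float)
    ok = r12.notna() & (r12 > 0) & r13.notna()
    out[ok] = 100.0 * (r13[ok] - r12[ok]) / r12[ok]
    return out


def noise_threshold(
    enrichments: pd.Series | np.ndarray,
    method: str = "ci_mean",
) -> dict[str, float]:
    """Noise threshold from the strictly positive enrichment values.

    ``ci_mean``: upper limit of the two-sided 95% t-confidence interval of
    the mean of the positive values (threshold = mean + half-width).
    ``percentile``: the 97.5th percentile of the positive values.

    Returns a dict with ``threshold``, ``noise`` (the half-width, or the
    threshold-minus-mean spread for the percentile method), ``mean`` and
    ``n_positive``.  At least two positive values are required.
    """
    values = np.asarray(enrichments, dtype=float)
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size < 2:
        raise ValueError(
            f"need >= 2 positive enrichment values to estimate noise, "
            f"got {positive.size}"
        )
    mean = positive.mean()
    if method == "ci_mean":
        sem = stats.sem(positive, ddof=1)
        half_width = stats.t.ppf(0.975, df=positive.size - 1) * sem
        threshold = mean + half_width
        noise = half_width
    elif method == "percentile":
        threshold = float(np.percentile(positive, 97.5))
        noise = threshold - mean
    else:
        raise ValueError(f"unknown method {method!r}; use 'ci_mean' or 'percentile'")
    return {
        "threshold": float(threshold),
        "noise": float(noise),
        "mean": float(mean),
        "n_positive": int(positive.size),
    }


def flag_enriched(
    report: pd.DataFrame,
    threshold: float,
    abundance_floor: float = 0.001,
) -> pd.DataFrame:
    """Flag taxa strictly above the noise threshold and the abundance floor.

    ``report`` must carry ``percent_enrichment`` and ``mean_abundance``
    columns; returns a copy with ``above_threshold``, ``threshold_used``
    and ``abundance_filter_passed`` filled in.  The threshold comparison is
    a strict inequality.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = report.copy()
    out["above_threshold"] = out["percent_enrichment"] > threshold
    out["threshold_used"] = threshold
    out["abundance_filter_passed"] = out["mean_abundance"] >= abundance_floor
    return out


def collapse_to_class(
    table: FractionTaxonTable, class_of: Mapping[str, str]
) -> FractionTaxonTable:
    """Genus-level table -> class-level table by summing read counts.

    Class proportions are computed from the summed counts, not by averaging
    genus-level statistics, so the class statistic is the statistic of the
    pooled reads.
    """
    missing = [t for t in table.taxa if t not in class_of]
    if missing:
        raise ValueError(f"no class assignment for taxa: {missing}")
    grouped = table.counts.groupby(
        table.counts.index.map(lambda t: class_of[t])
    ).sum()
    return FractionTaxonTable(counts=grouped, rank="class")


def enrichment_report(
    table_12c: FractionTaxonTable,
    table_13c: FractionTaxonTable,
    profile_12c: GradientProfile,
    profile_13c: GradientProfile,
    window: HeavyWindow,
    threshold_method: str = "ci_mean",
    abundance_floor: float = 0.001,
) -> pd.DataFrame:
    """Full per-taxon enrichment report for one paired-gradient comparison.

    Columns: rel_copies_12C, rel_copies_13C, percent_enrichment, rank,
    mean_abundance, above_threshold, threshold_used,
    abundance_filter_passed.  Undefined enrichments (taxon absent from the
    unlabeled window) are NaN and excluded from the threshold estimate.
    """
    copies12 = taxon_copy_numbers(table_12c, profile_12c, window)
    copies13 = taxon_copy_numbers(table_13c, profile_13c, window)
    rel12 = relative_copy_numbers(copies12)
    rel13 = relative_copy_numbers(copies13)
    enr = percent_enrichment(rel13, rel12)
    abund = (
        pd.concat(
            [table_12c.mean_relative_abundance(), table_13c.mean_relative_abundance()],
            axis=1,
        )
        .mean(axis=1)
        .reindex(enr.index)
    )
    report = pd.DataFrame(
        {
            "rel_copies_12C": rel12.reindex(enr.index),
            "rel_copies_13C": rel13.reindex(enr.index),
            "percent_enrichment": enr,
            "rank": table_13c.rank,
            "mean_abundance": abund,
        }
    )
    report.index.name = "taxon"
    ci = noise_threshold(enr, method=threshold_method)
    report = flag_enriched(report, ci["threshold"], abundance_floor)
    report.attrs["noise"] = ci
    return report
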