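"""Tab-separated table formats, config loading, and run logs.

All tables are plain TSV with documented headers:

* fraction table — ``fraction``, ``refractive_index`` (optional),
  ``density`` (optional; at least one of the two required), ``copies``,
  ``copies_sd`` (optional); one file per gradient;
* taxon table — ``taxon``, ``rank``, then one integer read-count column
  per fraction identifier;
* incubation series — long format ``treatment``, ``depth``, ``replicate``,
  ``time_h``, ``analyte``, ``value`` with analyte vocabulary ``peptide``,
  ``A``, ``V``, ``F``, ``AV``, ``VF``, ``FA``, ``VFA``, ``NH4``, ``Pi``,
  ``cells``.

Run configuration is a YAML mapping with a closed schema: unknown keys
are rejected so typos fail loudly.  Every run writes a log with the seed
and the fully resolved configuration, from which a stochastic run can be
reproduced exactly.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .enrichment_stats import FractionTaxonTable
from .gradient_model import (
    DEFAULT_RI_INTERCEPT,
    DEFAULT_RI_SLOPE,
    Fraction,
    GradientProfile,
    HeavyWindow,
    density_from_ri,
)
from .kinetics import IncubationSeries
from .mass_balance import ConversionConstants
from .synthetic_data import SimulationConfig

__all__ = [
    "read_fraction_table",
    "write_fraction_table",
    "read_taxon_table",
    "write_taxon_table",
    "read_incubation_series",
    "write_incubation_series",
    "write_enrichment_report",
    "RunConfig",
    "load_config",
    "write_run_log",
]

ANALYTE_VOCAB = (
    "peptide", "A", "V", "F", "AV", "VF", "FA", "VFA", "NH4", "Pi", "cells",
)


def _numeric(series: pd.Series, column: str, path) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise ValueError(
            f"{path}: non-numeric value {series[bad.idxmax()]!r} in column "
            f"{column!r} at line {row}"
        )
    return converted


def read_fraction_table(
    path,
    treatment: str = "",
    depth: str = "",
    slope: float = DEFAULT_RI_SLOPE,
    intercept: float = DEFAULT_RI_INTERCEPT,
) -> GradientProfile:
    """Read one gradient's fraction table into a :class:`GradientProfile`.

    Densities are computed from refractive index where the density column
    is absent; fractions are sorted by density (descending, densest
    first).  Duplicate fraction identifiers and non-numeric cells are
    rejected with the offending row.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "fraction" not in df.columns or "copies" not in df.columns:
        raise ValueError(f"{path}: fraction table needs 'fraction' and 'copies' columns")
    if df["fraction"].duplicated().any():
        dups = df["fraction"][df["fraction"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicated fraction identifiers {dups}")
    has_ri = "refractive_index" in df.columns
    has_density = "density" in df.columns
    if not has_ri and not has_density:
        raise ValueError(
            f"{path}: need at least one of 'refractive_index' or 'density'"
        )
    copies = _numeric(df["copies"], "copies", path)
    if has_density:
        density = _numeric(df["density"], "density", path)
    else:
        ri = _numeric(df["refractive_index"], "refractive_index", path)
        density = ri.map(lambda r: density_from_ri(r, slope, intercept))
    sd = (
        _numeric(df["copies_sd"], "copies_sd", path)
        if "copies_sd" in df.columns
        else pd.Series([np.nan] * len(df))
    )
    ri_col = (
        _numeric(df["refractive_index"], "refractive_index", path)
        if has_ri
        else pd.Series([np.nan] * len(df))
    )
    fractions = [
        Fraction(
            index=int(f),
            density=float(d),
            copies=float(c),
            refractive_index=None if pd.isna(r) else float(r),
            copies_sd=None if pd.isna(s) else float(s),
            below_detection=bool(c == 0),
        )
        for f, d, c, r, s in zip(df["fraction"], density, copies, ri_col, sd)
    ]
    fractions.sort(key=lambda fr: -fr.density)
    return GradientProfile(treatment=treatment, depth=depth, fractions=fractions)


def write_fraction_table(profile: GradientProfile, path) -> None:
    rows = {
        "fraction": [f.index for f in profile.fractions],
        "refractive_index": [f.refractive_index for f in profile.fractions],
        "density": [f.density for f in profile.fractions],
        "copies": [f.copies for f in profile.fractions],
        "copies_sd": [f.copies_sd for f in profile.fractions],
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_taxon_table(path, rank: str | None = None) -> FractionTaxonTable:
    """Read a taxon x fraction read-count matrix.

    First column ``taxon``, second ``rank``, remaining columns one per
    fraction identifier.  Counts must be non-negative integers.  If the
    file mixes ranks, ``rank`` selects which to load.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns[:2]) != ["taxon", "rank"]:
        raise ValueError(f"{path}: first two columns must be 'taxon' and 'rank'")
    if rank is not None:
        df = df[df["rank"] == rank]
        if df.empty:
            raise ValueError(f"{path}: no rows at rank {rank!r}")
    ranks = df["rank"].unique()
    if len(ranks) != 1:
        raise ValueError(
            f"{path}: mixed ranks {sorted(ranks)}; pass rank= to select one"
        )
    counts = df.drop(columns=["rank"]).set_index("taxon")
    for col in counts.columns:
        counts[col] = _numeric(counts[col], col, path)
    if (counts.values < 0).any():
        raise ValueError(f"{path}: negative read counts")
    counts.columns = [int(c) if str(c).isdigit() else c for c in counts.columns]
    return FractionTaxonTable(counts=counts, rank=str(ranks[0]))


def write_taxon_table(table: FractionTaxonTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "rank", table.rank)
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_incubation_series(path) -> list[IncubationSeries]:
    """Read a long-format incubation file into one series per bottle."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"treatment", "depth", "replicate", "time_h", "analyte", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    unknown = set(df["analyte"]) - set(ANALYTE_VOCAB)
    if unknown:
        raise ValueError(f"{path}: unknown analytes {sorted(unknown)}")
    df["value"] = _numeric(df["value"], "value", path)
    out = []
    for (treatment, depth, replicate), grp in df.groupby(
        ["treatment", "depth", "replicate"], sort=True
    ):
        wide = grp.pivot_table(index="time_h", columns="analyte", values="value")
        wide = wide.sort_index()
        times = tuple(float(t) for t in wide.index)

        def col(name):
            if name not in wide.columns:
                return None
            return tuple(float(v) for v in wide[name])

        analytes = {
            a: col(a) for a in ("A", "V", "F", "AV", "VF", "FA", "VFA") if col(a)
        }
        out.append(
            IncubationSeries(
                treatment=str(treatment),
                depth=str(depth),
                replicate=str(replicate),
                times=times,
                peptide=col("peptide") or tuple(0.0 for _ in times),
                analytes=analytes or None,
                ammonium=col("NH4"),
                phosphate=col("Pi"),
                cells=col("cells"),
            )
        )
    return out


def write_incubation_series(series_list: list[IncubationSeries], path) -> None:
    rows = []
    for s in series_list:
        named = {"peptide": s.peptide, "NH4": s.ammonium, "Pi": s.phosphate,
                 "cells": s.cells}
        named.update(s.analytes or {})
        for analyte, values in named.items():
            if values is None:
                continue
            for t, v in zip(s.times, values):  # noqa: B007
                rows.append(
                    {
                        "treatment": s.treatment,
                        "depth": s.depth,
                        "replicate": s.replicate,
                        "time_h": t,
                        "analyte": analyte,
                        "value": v,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_enrichment_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", na_rep="NA")


# --- run configuration -----------------------------------------------------

_CONFIG_KEYS = {
    "seed", "out_dir", "heavy_window", "threshold_method", "abundance_floor",
    "full_label_shift", "constants", "simulation", "inputs", "verbosity",
}
_INPUT_KEYS = {
    "fractions_12c", "fractions_13c", "taxa_12c", "taxa_13c", "incubation",
}


@dataclass
class RunConfig:
    """Resolved run configuration (file values overridable by CLI flags)."""

    seed: int = 0
    out_dir: str = "results"
    heavy_window: HeavyWindow | str | None = None  # bounds, "auto", or unset
    threshold_method: str = "ci_mean"
    abundance_floor: float = 0.001
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    inputs: dict[str, str] = field(default_factory=dict)
    verbosity: int = 0

    def to_dict(self) -> dict[str, Any]:
        hw = self.heavy_window
        if isinstance(hw, HeavyWindow):
            hw = {"density_min": hw.density_min, "density_max": hw.density_max}
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "heavy_window": hw,
            "threshold_method": self.threshold_method,
            "abundance_floor": self.abundance_floor,
            "constants": vars(self.constants).copy(),
            "simulation": vars(self.simulation).copy(),
            "inputs": dict(self.inputs),
            "verbosity": self.verbosity,
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])
    if "threshold_method" in raw:
        cfg.threshold_method = str(raw["threshold_method"])
    if "abundance_floor" in raw:
        cfg.abundance_floor = float(raw["abundance_floor"])
    if "verbosity" in raw:
        cfg.verbosity = int(raw["verbosity"])
    hw = raw.get("heavy_window")
    if hw is not None:
        if hw == "auto":
            cfg.heavy_window = "auto"
        elif isinstance(hw, dict) and {"density_min", "density_max"} <= set(hw):
            cfg.heavy_window = HeavyWindow(
                density_min=float(hw["density_min"]),
                density_max=float(hw["density_max"]),
            )
        else:
            raise ValueError(
                f"{path}: heavy_window must be 'auto' or a mapping with "
                "density_min and density_max"
            )
    if "constants" in raw:
        cfg.constants = ConversionConstants(**raw["constants"])
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        sim.setdefault("seed", cfg.seed)
        cfg.simulation = SimulationConfig(**sim)
    if "inputs" in raw:
        unknown_in = set(raw["inputs"]) - _INPUT_KEYS
        if unknown_in:
            raise ValueError(f"{path}: unknown input keys {sorted(unknown_in)}")
        cfg.inputs = {k: str(v) for k, v in raw["inputs"].items()}
    return cfg


def write_run_log(out_dir, config: RunConfig, command: str) -> Path:
    """Write the resolved config, seed and versions next to the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import peptide_sip

    log = {
        "command": command,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": config.seed,
        "versions": {
            "peptide_sip": peptide_sip.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config.to_dict(),
    }
    path = out / f"run_log_{command}.yaml"
    path.write_text(yaml.safe_dump(log, sort_keys=False))
    return path
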