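"""Synthetic SIP incubation and gradient datasets.

Generates data with the statistical structure the analysis assumes, so
every stage of the pipeline can be exercised end-to-end without any
external sequencing data:

* paired unlabeled/labeled CsCl gradients of ~30 fractions spanning
  1.66-1.77 g/mL, where each taxon's DNA bands at a GC-dependent buoyant
  density (rho = 1.660 + 0.098 x GC) shifted upward by
  atom_fraction_13C x 0.036 g/mL in the labeled treatment, spread with a
  Gaussian band kernel; per-fraction qPCR copy numbers carry lognormal
  noise and per-fraction reads are a multinomial draw over taxa;
* incubation time series in which the peptide decays at a zero-order rate
  until exhaustion, the killed control stays flat, hydrolysis fragments
  rise and fall, ammonium accumulates after depletion, and cells bloom
  and decline, with duplicate bottles sharing structure but not noise.

All randomness flows from one integer seed through named substreams
(CRC32 of a stream tag mixed into the seed sequence), so the same seed
reproduces every dataset bit-for-bit and the draw order is documented by
the tags.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .gradient_model import Fraction, GradientProfile, normalize_quantities
from .enrichment_stats import FractionTaxonTable
from .kinetics import IncubationSeries

import pandas as pd

__all__ = [
    "TaxonSpec",
    "SyntheticCommunity",
    "SimulationConfig",
    "ATOM_FRACTION_CAP",
    "default_community",
    "unlabeled_density",
    "band_center",
    "simulate_gradient_pair",
    "simulate_incubation",
    "analytic_depletion_time",
]

#: Maximum DNA carbon atom fraction attainable from the substrate: 17 of
#: the tetrapeptide's 20 carbons are labeled.
ATOM_FRACTION_CAP = 0.85

_TIMES = (0.0, 8.0, 13.0, 24.0, 48.0)


@dataclass(frozen=True)
class TaxonSpec:
    """One community member and its labeling/growth behaviour."""

    label: str
    class_name: str
    genus: str
    abundance: float
    gc_content: float
    atom_fraction_13c: float = 0.0
    growth_response: float = 1.0

    def __post_init__(self) -> None:
        if not 0.25 <= self.gc_content <= 0.75:
            raise ValueError(f"{self.label}: GC content outside [0.25, 0.75]")
        if not 0.0 <= self.atom_fraction_13c <= ATOM_FRACTION_CAP:
            raise ValueError(
                f"{self.label}: atom fraction outside [0, {ATOM_FRACTION_CAP}] "
                "(capped by the substrate's 17/20 labeled carbons)"
            )
        if self.abundance < 0 or self.growth_response <= 0:
            raise ValueError(f"{self.label}: invalid abundance or growth response")


@dataclass(frozen=True)
class SyntheticCommunity:
    taxa: tuple[TaxonSpec, ...]

    def __init__(self, taxa) -> None:
        taxa = tuple(taxa)
        if not taxa:
            raise ValueError("community must contain at least one taxon")
        total = sum(t.abundance for t in taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")
        labels = [t.label for t in taxa]
        if len(set(labels)) != len(labels):
            raise ValueError("taxon labels must be unique")
        object.__setattr__(self, "taxa", taxa)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.taxa]

    def unlabel(self) -> "SyntheticCommunity":
        """The same community with all atom fractions zeroed (the 12C scenario)."""
        return SyntheticCommunity(
            replace(t, atom_fraction_13c=0.0) for t in self.taxa
        )

    def class_of(self) -> dict[str, str]:
        return {t.label: t.class_name for t in self.taxa}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the generator.

    Gradient: 30 fractions over 1.66-1.77 g/mL; unlabeled band density
    rho = gc_density_intercept + gc_density_slope x GC; full 13C labeling
    shifts a band by 0.036 g/mL; band spread sigma 0.006 g/mL; lognormal
    qPCR noise sigma 0.15; 5000 reads per fraction.  Incubation: initial
    peptide 0.35 uM decaying at depth-specific zero-order rates (surface
    0.014, bottom 0.0265 uM/h, the midpoints of the observed ranges) with
    0.01 uM measurement noise.
    """

    n_fractions: int = 30
    density_min: float = 1.66
    density_max: float = 1.77
    gc_density_intercept: float = 1.660
    gc_density_slope: float = 0.098
    full_label_shift: float = 0.036
    band_sigma: float = 0.006
    band_baseline: float = 0.05
    qpcr_sigma: float = 0.15
    reads_per_fraction: int = 5000
    total_copies: float = 1.0e7
    initial_peptide_um: float = 0.35
    decay_rate_surface: float = 0.014
    decay_rate_bottom: float = 0.0265
    peptide_noise_sd: float = 0.01
    quant_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 2 or self.density_min >= self.density_max:
            raise ValueError("need >= 2 fractions and density_min < density_max")
        for name in ("band_sigma", "full_label_shift", "total_copies",
                     "initial_peptide_um", "decay_rate_surface",
                     "decay_rate_bottom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _stream(seed: int, *tags: str) -> np.random.Generator:
    """Named substream: the seed plus CRC32 of each tag, in draw order."""
    entries = [int(seed)] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(entries)


def default_community() -> SyntheticCommunity:
    """A 10-taxon coastal community with three peptide incorporators.

    Mimics the mix observed in such incubations: copiotrophic
    alphaproteobacterial and gammaproteobacterial genera take up the
    labeled peptide (atom fractions 0.85, 0.55, 0.30), the rest stay
    unlabeled; GC contents span the realistic 0.34-0.62 marine range.
    """
    spec = [
        # label, class, genus, abundance, GC, atom_fraction
        ("Ruegeria", "Alphaproteobacteria", "Ruegeria", 0.12, 0.58, 0.85),
        ("Colwellia", "Gammaproteobacteria", "Colwellia", 0.08, 0.38, 0.55),
        ("Thalassococcus", "Alphaproteobacteria", "Thalassococcus", 0.10, 0.60, 0.30),
        ("Synechococcus", "Cyanobacteria", "Synechococcus", 0.20, 0.55, 0.0),
        ("SAR11", "Alphaproteobacteria", "Pelagibacter", 0.15, 0.30, 0.0),
        ("OCS155", "Acidimicrobiia", "OCS155_marine_group", 0.08, 0.50, 0.0),
        ("Saprospiraceae", "Sphingobacteriia", "Saprospiraceae_uncl", 0.07, 0.42, 0.0),
        ("Flavobacterium", "Flavobacteriia", "Flavobacterium", 0.09, 0.34, 0.0),
        ("Planctomyces", "Planctomycetacia", "Planctomyces", 0.06, 0.56, 0.0),
        ("Balneatrix", "Gammaproteobacteria", "Balneatrix", 0.05, 0.45, 0.0),
    ]
    return SyntheticCommunity(
        TaxonSpec(
            label=lab, class_name=cls, genus=gen,
            abundance=ab, gc_content=gc, atom_fraction_13c=af,
        )
        for lab, cls, gen, ab, gc, af in spec
    )


def unlabeled_density(gc_content: float, config: SimulationConfig) -> float:
    """Buoyant density of unlabeled DNA from GC content (linear CsCl relation)."""
    return config.gc_density_intercept + config.gc_density_slope * gc_content


def band_center(taxon: TaxonSpec, config: SimulationConfig) -> float:
    """Band center: GC-dependent unlabeled density plus the labeling shift."""
    return (
        unlabeled_density(taxon.gc_content, config)
        + taxon.atom_fraction_13c * config.full_label_shift
    )


def _fraction_densities(config: SimulationConfig) -> np.ndarray:
    """Densities by collection order: fraction 1 is the densest."""
    return np.linspace(config.density_max, config.density_min, config.n_fractions)


def _taxon_mass_matrix(
    community: SyntheticCommunity, config: SimulationConfig
) -> np.ndarray:
    """DNA mass per taxon (rows) and fraction (cols), noise-free.

    Each taxon's DNA follows a Gaussian band around its buoyant-density
    center plus a small uniform smear across the gradient
    (``band_baseline`` of its mass), emulating the diffusion, partial
    labeling and time-point pooling that spread real SIP signal over the
    whole density range.  The kernel is normalized over the gradient's
    fractions, so total mass is conserved regardless of band position.
    """
    densities = _fraction_densities(config)
    mass = np.empty((len(community.taxa), len(densities)))
    for i, taxon in enumerate(community.taxa):
        center = band_center(taxon, config)
        kernel = np.exp(-0.5 * ((densities - center) / config.band_sigma) ** 2)
        kernel /= kernel.sum()
        kernel = (
            (1.0 - config.band_baseline) * kernel
            + config.band_baseline / len(densities)
        )
        mass[i] = taxon.abundance * taxon.growth_response * kernel
    return mass


def _simulate_one_gradient(
    community: SyntheticCommunity,
    config: SimulationConfig,
    treatment: str,
    depth: str,
    seed: int,
    noise: bool,
) -> tuple[GradientProfile, FractionTaxonTable]:
    densities = _fraction_densities(config)
    mass = _taxon_mass_matrix(community, config)
    column_mass = mass.sum(axis=0)
    copies = column_mass / column_mass.sum() * config.total_copies
    if noise and config.qpcr_sigma > 0:
        rng = _stream(seed, f"{treatment}:{depth}", "qpcr")
        copies = copies * rng.lognormal(0.0, config.qpcr_sigma, size=copies.size)
    fractions = [
        Fraction(index=i + 1, density=float(d), copies=float(c))
        for i, (d, c) in enumerate(zip(densities, copies))
    ]
    profile = normalize_quantities(
        GradientProfile(treatment=treatment, depth=depth, fractions=fractions)
    )

    with np.errstate(invalid="ignore"):
        probs = mass / column_mass
    if noise:
        rng = _stream(seed, f"{treatment}:{depth}", "reads")
        counts = np.column_stack(
            [
                rng.multinomial(config.reads_per_fraction, probs[:, j])
                for j in range(probs.shape[1])
            ]
        )
    else:
        counts = probs * config.reads_per_fraction  # expected (real-valued) reads
    index = pd.Index(community.labels, name="taxon")
    table = FractionTaxonTable(
        counts=pd.DataFrame(
            counts, index=index, columns=[f.index for f in fractions]
        ),
        rank="genus",
    )
    return profile, table


def simulate_gradient_pair(
    community: SyntheticCommunity,
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
    depth: str = "surface",
    noise: bool = True,
) -> dict:
    """Paired 12C/13C gradients plus taxon read tables for one depth.

    The 12C scenario is the same community with every atom fraction set to
    zero.  Returns a dict with keys ``profile_12c``, ``profile_13c``,
    ``table_12c``, ``table_13c``.  Deterministic given the seed; with
    ``noise=False`` copy numbers and read counts are their expectations.
    """
    if seed is None:
        seed = config.seed
    p12, t12 = _simulate_one_gradient(
        community.unlabel(), config, "12C", depth, seed, noise
    )
    p13, t13 = _simulate_one_gradient(community, config, "13C", depth, seed, noise)
    return {
        "profile_12c": p12,
        "profile_13c": p13,
        "table_12c": t12,
        "table_13c": t13,
    }


def analytic_depletion_time(initial_um: float, k_um_per_h: float) -> float:
    """Time at which a zero-order decay reaches zero: c0 / k."""
    if k_um_per_h <= 0:
        raise ValueError("decay rate must be positive")
    return initial_um / k_um_per_h


def _hump(t: np.ndarray, t_peak: float) -> np.ndarray:
    """Produce-then-consume shape: 0 at t=0, peak 1 at t_peak, decaying after."""
    x = np.clip(t / t_peak, 0.0, None)
    return x * np.exp(1.0 - x)


def _one_series(
    config: SimulationConfig,
    treatment: str,
    depth: str,
    replicate: str,
    seed: int,
) -> IncubationSeries:
    t = np.array(_TIMES)
    rng = _stream(seed, f"incubation:{treatment}:{depth}:{replicate}")
    k = (
        config.decay_rate_surface if depth == "surface" else config.decay_rate_bottom
    )
    c0 = config.initial_peptide_um
    sd = config.peptide_noise_sd

    def noisy(values: np.ndarray, scale: float) -> np.ndarray:
        # peptide_noise_sd == 0 switches the whole bottle noise-free
        if scale <= 0 or sd <= 0:
            return np.clip(values, 0.0, None)
        return np.clip(values + rng.normal(0.0, scale, size=values.size), 0.0, None)

    if treatment == "killed":
        peptide = noisy(np.full_like(t, c0), sd / 2)
        peptide[0] = c0
    elif treatment == "control":
        peptide = np.zeros_like(t)  # no substrate amended
    else:
        peptide = noisy(np.clip(c0 - k * t, 0.0, None), sd)
        peptide[0] = c0

    active = treatment in ("12C", "13C")
    t_dep = analytic_depletion_time(c0, k)
    # hydrolysis products: larger and later in the surface, smaller in the bottom
    frag_scale = 1.0 if depth == "surface" else 0.3
    analytes: dict[str, tuple[float, ...]] = {}
    peaks = {"A": 0.04, "V": 0.05, "F": 0.15, "AV": 0.008, "VF": 0.010,
             "FA": 0.008, "VFA": 0.011}
    for name, peak in peaks.items():
        base = peak * frag_scale * _hump(t, min(t_dep, 24.0)) if active else np.full_like(t, 0.005)
        analytes[name] = tuple(noisy(base, sd / 4))

    nh4_base = 0.5
    if active:
        rise = 0.10 * frag_scale / (1.0 + np.exp(-(t - t_dep) / 4.0))
        ammonium = noisy(nh4_base + rise, 0.02)
    else:
        ammonium = noisy(np.full_like(t, nh4_base), 0.02)
    phosphate = noisy(np.full_like(t, 0.45 if depth == "bottom" else 0.10), 0.02)

    c0_cells = 1.0e6
    if active:
        bloom_peak = 13.0 if depth == "surface" else 24.0
        cells = c0_cells * (1.0 + 0.45 * _hump(t, bloom_peak))
    elif treatment == "killed":
        cells = np.full_like(t, c0_cells)
    else:
        cells = c0_cells * (1.0 - 0.1 * t / t[-1])
    cells = noisy(cells, 0.0 if sd <= 0 else 0.02 * c0_cells)

    return IncubationSeries(
        treatment=treatment,
        depth=depth,
        replicate=replicate,
        times=tuple(t),
        peptide=tuple(peptide),
        analytes=analytes,
        ammonium=tuple(ammonium),
        phosphate=tuple(phosphate),
        cells=tuple(cells),
    )


def simulate_incubation(
    config: SimulationConfig = SimulationConfig(), seed: int | None = None
) -> list[IncubationSeries]:
    """The full bottle set: duplicates of 12C/13C at both depths plus controls.

    Sampling times 0, 8, 13, 24, 48 h.  Labeled and unlabeled substrate
    behave identically chemically; the killed control stays flat and the
    unamended control has no peptide.  Deterministic given the seed.
    """
    if seed is None:
        seed = config.seed
    series: list[IncubationSeries] = []
    for depth in ("surface", "bottom"):
        for treatment in ("12C", "13C"):
            for replicate in ("a", "b"):
                series.append(_one_series(config, treatment, depth, replicate, seed))
        series.append(_one_series(config, "killed", depth, "a", seed))
        series.append(_one_series(config, "control", depth, "a", seed))
    return series
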