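# peptide-sip

Quantitative analysis for DNA stable-isotope probing (SIP) of peptide
decomposition in seawater: who eats a ¹³C-labeled tetrapeptide, how fast it
is degraded, and where its nitrogen ends up.

In a SIP incubation, a community is fed an isotopically heavy substrate —
here the tetrapeptide alanine–valine–phenylalanine–alanine (AVFA) with 17
of its 20 carbons as ¹³C. Bacteria that assimilate the label build denser
DNA, which bands deeper in an isopycnic CsCl gradient. After
ultracentrifugation the gradient is collected as ~30 fractions, each with a
buoyant density (from refractive index) and a 16S rRNA gene copy number
(qPCR), and each fraction's reads give per-taxon proportions. This package
implements the downstream arithmetic of that experiment as a tested
library, for microbial ecologists running or re-analyzing peptide/amino
acid SIP incubations:

* **Percentage enrichment** — the per-taxon activity statistic. Within a
  heavy density window *W*, a taxon's copy number is
  Σ_{f∈W} p_{t,f} · C_f (read proportion × qPCR copies), normalized to the
  window total to give relative copy numbers r. Then

  > enrichment(t) = 100 · (r₁₃C(t) − r₁₂C(t)) / r₁₂C(t)

  so a taxon twice as abundant in the labeled heavy window scores 100 %. A
  noise threshold is estimated from the strictly positive enrichments
  (95 % t-interval of their mean, or their 97.5th percentile), and taxa are
  flagged when strictly above it and ≥ 0.1 % of the community.
* **Gradient bookkeeping** — refractive index → density (linear CsCl
  calibration), per-gradient "ratio of quantities" normalization (max = 1),
  heavy-window selection (explicit bounds or the dominant dense-side excess
  of the ¹³C over the ¹²C profile), and conversion of a density shift Δρ to
  percent ¹³C incorporation via 100 · Δρ / 0.036 g mL⁻¹.
* **Peptide chemistry** — elemental composition of any one-letter peptide
  sequence, site-specific labeling accounting (AVFA: 3+5+6+3 = 17 ¹³C), and
  nominal [M+H]⁺ SIM m/z (AVFA: 407 unlabeled, 424 labeled).
* **Kinetics** — zero-order (linear) decay rates by OLS with a
  quantitation-floor truncation rule, cell-specific rates, Welch t
  comparison between depths.
* **Nitrogen mass balance** — partition of consumed peptide N into
  extracellular hydrolysis (via phenylalanine-bearing products),
  remineralization to ammonium, biomass (20 fg C cell⁻¹, C/N = 4), and
  residual dissolved organic nitrogen as the closure term; plus the
  phosphate demand of observed growth (0.2 pg dry mass, 1.3 % P).
* **Synthetic data** — a generator for paired ¹²C/¹³C gradients
  (GC-dependent band densities ρ = 1.660 + 0.098·GC, labeling shift,
  Gaussian band kernel, lognormal qPCR noise, multinomial reads) and
  incubation time series, so the whole pipeline is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (`python analysis/01_simulate.py` … `04_mass_balance.py`). The
simulated community has 10 genera, three of which incorporate the peptide
(atom fractions 0.85, 0.55, 0.30). Script 02 prints, for the surface
gradient pair:

```
surface: heavy window [1.7207, 1.7700] g/mL
  genus: noise half-width 1186%, threshold 1479% (3 positive values); enriched: none
```

and the genus table (`results/enrichment_surface_genus.tsv`) ranks the
three simulated incorporators on top:

```
                rel_copies_12C  rel_copies_13C  percent_enrichment
Colwellia               0.0111          0.1044            844.1
Ruegeria                0.2651          0.3456             30.4
Thalassococcus          0.2915          0.3039              4.3
Planctomyces            0.0941          0.0563            -40.1
...
```

Colwellia's unlabeled DNA (38 % GC) bands below the heavy window; labeling
shifts it in, hence the large enrichment. Ruegeria (58 % GC) already bands
near the window unlabeled, so its enrichment is smaller — the statistic
measures the *gain* in heavy-window share, not abundance. With only three
positive values the t-interval threshold is extremely wide and flags
nothing; ranking, not flagging, is the informative output at this
community size (see `docs/methods.md`). Scripts 03–04 print:

```
surface k = 0.0121 +/- 0.0034 uM/h (n=4); bottom k = 0.0263 +/- 0.0006 uM/h (n=4)
bottom/surface ratio of means 2.17, Welch t = 8.12, p = 0.0031
bottom (mean of 4 bottles at 24 h): hydrolysis 13%, ammonium 3%, biomass 12%, residual DON 73%; ...
surface (mean of 4 bottles at 24 h): hydrolysis 56%, ammonium 1%, biomass 12%, residual DON 31%; ...
```

— bottom-water decomposition runs about twice as fast, and the surface
budget is hydrolysis-dominated while the bottom budget routes more
nitrogen to unaccounted DON, mirroring the contrast the analysis is built
to quantify.

A `sip-enrich` CLI wraps the same stages
(`sip-enrich simulate|enrich|kinetics|massbalance|report --config cfg.yaml
[--seed N] [--out DIR]`).

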