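# siampeat

Stable-isotope-assisted metabolomics (SIAM) and CO₂ flux partitioning for
litter-amendment incubation experiments in peat.

## The problem

When fresh plant litter is added to peat, microbes may not only decompose
the litter but also accelerate (or suppress) decomposition of the
pre-existing soil organic matter — the *priming effect*. Detecting priming
is hard: the signal is small, transient, and invisible in bulk CO₂
measurements. Labeling the litter with ¹³C makes both the gas flux and the
metabolome traceable: litter-derived carbon shows up as mass-shifted
isotopologue patterns in LC-MS feature tables and as an enriched
¹³CO₂/CO₂ ratio in the headspace.

`siampeat` implements the complete desk-side analysis for such an
experiment:

- **Isotopologue detection** — filter LC-MS features (mass window,
  intensity, S/N), group co-eluting features spaced by multiples of the
  ¹³C–¹²C mass difference (1.0033548 Da) into isotopologue clusters, and
  classify compounds as labeled.
- **Enrichment estimation** — under uniform labeling, a compound with
  n_C carbons and per-carbon ¹³C probability *p* has a Binomial(n_C, *p*)
  isotopologue envelope. Observed envelopes are deconvolved against the
  natural-abundance contribution by solving `f_obs = C · f_corr` with
  non-negative least squares, where column *j* of `C` is the natural
  envelope of the n_C − j carbons not carrying tracer. Fractional label
  incorporation is `100 · Σ k·f_corr[k] / n_C` (excess atom percent);
  adding natural abundance back gives the total atom percent comparable to
  bulk IRMS values.
- **Two-pool flux partitioning** — with F_Net the total CO₂ flux, R_Net its
  ¹³C atom fraction, R_Soil the mean ratio of unamended jars and R_Litter
  the litter enrichment,

  ```
  litter respiration = F_Net · (R_Net − R_Soil) / (R_Litter − R_Soil)
  peat  respiration  = F_Net − litter respiration
  priming            = peat respiration (amended) − F_Net (unamended)
  ```

- **Multivariate statistics** — median normalization, Pareto scaling,
  Manhattan-distance PCoA, average-linkage clustering and seed-reproducible
  PERMANOVA.
- **Multiblock sparse PLS-DA** — an N-integration discriminant model
  coupling the LC-MS and NMR blocks to the amended/unamended contrast, with
  per-block sparsity; plus log₂ fold-change trajectories relative to
  unamended peat at T0.
- **Synthetic-data generator** — emulates the full study design (3
  treatments × 4 timepoints × 2 replicates, 52.4 at-% litter enrichment,
  100–1200 Da features, gas sampling days 1, 3, 5, then every 5 days to
  day 40) with complete ground truth, so every stage is testable without
  any external download.

## Worked example

```python
import numpy as np
from siampeat import (
    annotate_clusters, build_design, cluster_isotopologues, filter_features,
    generate_feature_table, generate_species, partition_series,
    simulate_flux_series, summarize_detection, total_atom_percent,
)
from siampeat.synth import FluxConfig

design = build_design(replicates=2)
species = generate_species(60, enrichment=0.524, seed=7)
table, truth = generate_feature_table(species, design, seed=8)

filtered = filter_features(table)            # 100-1200 Da, >=2e6, S/N > 3
clusters = cluster_isotopologues(filtered)   # 5 ppm, 0.2 min RT window
labeled = [s.sample_id for s in design if s.label_status == "labeled"]
controls = [s.sample_id for s in design if s.label_status == "unlabeled"]
annotate_clusters(clusters, sample_ids=labeled, control_sample_ids=controls)

summary = summarize_detection(clusters)
print(f"{summary.n_features_total} compounds detected; "
      f"{summary.n_labeled} labeled ({summary.pct_labeled:.2f}%)")
enr = [total_atom_percent(c.enrichment_at_pct) for c in clusters if c.label_call]
print(f"mean 13C enrichment of labeled compounds: {np.mean(enr):.1f} at-%")

obs, flux_truth = simulate_flux_series(FluxConfig(), seed=9)
part = partition_series(obs, r_litter=0.524)
day5 = part.per_jar_day.query("day == 5")[
    ["litter_flux", "peat_flux", "priming_flux"]].mean()
print(f"day-5 mean fluxes (umol CO2 g^-1 d^-1): litter {day5.litter_flux:.2f}, "
      f"peat {day5.peat_flux:.2f}, priming {day5.priming_flux:.2f}")
```

prints

```
106 compounds detected; 22 labeled (20.75%)
mean 13C enrichment of labeled compounds: 50.3 at-%
day-5 mean fluxes (umol CO2 g^-1 d^-1): litter 4.48, peat 2.94, priming 0.83
```

The 22 labeled compounds are the generated litter-derived species whose
envelopes survived the detection filters; their mean recovered enrichment
sits near the 52.4 at-% the generator labeled them with (individual
table-derived estimates scatter a few at-% because envelope tails fall
below the detection limits). The day-5 partition shows the injected
picture: litter respiration dominating early, the peat baseline, and a
positive priming pulse peaking near one week.

The same run is available from the shell:

```
siampeat --seed 7 --outdir run run-all
```

which writes the feature/metadata/NMR/flux tables, per-stage results
(clusters, detection summary, partition tables, PCoA coordinates,
PERMANOVA, sPLS-DA loadings, fold changes), a markdown report with a JSON
twin, and a manifest with per-stage seeds and output checksums.

## Layout

| module | contents |
|---|---|
| `siampeat.synth` | species, envelope, feature-table, NMR-block and flux simulators with ground truth |
| `siampeat.design` | incubation sample design and the timepoint↔day codec |
| `siampeat.isotopologue` | filters, clustering, natural-abundance correction, enrichment, label calls |
| `siampeat.flux` | isotope conversions and the two-pool partition with priming |
| `siampeat.multivariate` | normalization, scaling, Manhattan PCoA, clustering, PERMANOVA |
| `siampeat.discriminant` | `MultiblockSPLSDA` model / `DiscriminantResults`, fold-change trajectories |
| `siampeat.io`, `siampeat.pipeline`, `siampeat.cli` | canonical CSV formats, orchestration, manifest, CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
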