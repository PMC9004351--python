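# exodna

Analysis pipeline for **marine exocellular DNA metagenomes** — the DNA that
passes a 0.1 µm filter and splits into vesicle-enclosed, virus-encapsidated
and free-DNA pools. The package is aimed at microbial oceanographers who
have per-sample gene count tables (from read mapping against a
depth-resolved reference gene catalog, 0–4,000 m) and want to know **what**
the exocellular DNA is and **where in the water column it came from**.

## What it computes

* **Taxonomic composition** (`exodna.count_io`) — proportional count
  tables at domain, family and tag level (unannotated sequences as an
  explicit category; high-light/low-light *Prochlorococcus* ecotype and
  viral known-host splits), and major-taxon selection at a strict >0.5 %
  contribution cutoff.
* **Depth-of-origin attribution** (`exodna.depth_origin`) — for a gene
  *g* with catalog coverage `cov[g, d]` across depths *d*, the probability
  a matching sequence originated at depth *d* is

  ```
  P[g, d] = cov[g, d] / Σ_d' cov[g, d']
  ```

  Multiplying `P[g, d]` by the gene's normalized coverage in a sample and
  summing portions the sample's mass over origin depths; results are
  aggregated by domain, binned into named zones (upper euphotic, DCM band,
  upper/lower mesopelagic, deep) and summarized as the euphotic-zone
  (0–200 m) derived fraction. Genes carrying no depth information go to an
  explicit *unassigned* bucket, so attribution conserves the sample total.
* **DNA export flux** (`exodna.export_flux`) — Martin-curve bookkeeping
  `F(z) = F_ref · (z/z_ref)^(-b)` for particle-delivered DNA, converted to
  a volumetric daily supply and compared with free-DNA standing stocks
  (percent of stock per day).
* **Fragment-size spectra** (`exodna.size_spectrum`) — electropherogram
  normalization, molecular-weight band fractions (<350 bp, <1,000 bp LMW,
  1,000–40,000 bp HMW) and peak detection with distinct (<5,000 bp wide)
  vs broad (>10,000 bp) classification.
* **Community comparison** (`exodna.ordination`) — square-root
  transformed proportions → Bray-Curtis distances → nonmetric
  multidimensional scaling (Kruskal stress-1) and one-way PERMANOVA
  (Anderson's pseudo-F, permutation p-values), pairwise across groups with
  Benjamini–Hochberg correction.
* **Synthetic data** (`exodna.synthetic`) — seeded generators for
  depth-resolved catalogs, mixture samples with multinomial counting noise
  and multi-peak electropherograms, so the entire pipeline is testable
  without any download.

## Worked example

Attribute a synthetic mesopelagic free-DNA sample whose true origin mixture
puts 67 % of its DNA in the euphotic zone, then ask whether a Martin-curve
DNA flux could sustain the standing stock at depth:

```python
from exodna import (make_catalog, make_sample, MixtureSpec,
                    origin_probabilities, attribute_sample, euphotic_fraction,
                    FluxModel, StockProfile, martin_flux, flux_supply_ratio)
from exodna.depth_origin import bin_origins

catalog = make_catalog(n_genes=2000, n_taxa=16, depth_exclusive_frac=0.5, seed=1)
spec = MixtureSpec(sample_id="free_500m", fraction_type="free",
                   collection_depth=500.0,
                   weights={75.0: 0.4, 100.0: 0.17, 125.0: 0.1,
                            500.0: 0.23, 750.0: 0.1},
                   read_depth=1_000_000, seed=2)
sample = make_sample(catalog, spec)

result = attribute_sample(sample, origin_probabilities(catalog), catalog)
print(bin_origins(result).sum(axis=1).round(3))
of_assigned, _ = euphotic_fraction(result)
print(f"euphotic-derived (0-200 m): {of_assigned:.2f} of assigned mass")

model = FluxModel(F_ref=1500.0, z_ref=175.0, b=0.86)
stocks = StockProfile(stocks={500.0: 0.10, 1000.0: 0.08}, layer_thickness=100.0)
print(f"DNA flux at 500 m: {martin_flux(500.0, model):.0f} ug m-2 d-1")
print(f"daily supply vs stock at 500 m: "
      f"{flux_supply_ratio(500.0, model, stocks):.1f} % per day")
```

Output:

```
upper_euphotic       0.310
dcm_band             0.273
upper_mesopelagic    0.061
lower_mesopelagic    0.273
deep                 0.082
unassigned           0.000
dtype: float64
euphotic-derived (0-200 m): 0.61 of assigned mass
DNA flux at 500 m: 608 ug m-2 d-1
daily supply vs stock at 500 m: 6.1 % per day
```

The sample collected at 500 m is attributed mostly to depths *above* its
collection depth — the allochthonous, surface-derived signature. With only
half the genes depth-exclusive the recovered euphotic share (0.61)
underestimates the generating 0.67; with fully depth-exclusive marker
genes the mixture is recovered to binomial error (see the tests). The flux
ratio says sinking particles deliver ~6 % of the 500 m free-DNA stock per
day under these parameters.

## Command line

```sh
exodna run-all --config examples/demo_config.yaml --outdir runs/demo
```

runs simulate → compose → attribute → flux → sizespec → compare end-to-end
from one YAML config and writes TSV outputs plus a JSON manifest; each
stage is also available as its own subcommand (`exodna attribute …`,
`exodna flux …`, `exodna compare …`). Reruns with the same config are
byte-identical.

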