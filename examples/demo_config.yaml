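# Demo pipeline configuration: a small synthetic study mirroring the
# layout of an open-ocean exocellular-DNA survey (vesicle / virus / free
# fractions collected between 75 and 1,000 m).  Mixture weights encode
# mostly-autochthonous euphotic samples and mesopelagic samples with a
# substantial surface-derived component.
seed: 42

catalog:
  n_genes: 2000
  n_taxa: 16
  depth_exclusive_frac: 0.3
  unannotated_frac: 0.25

samples:
  - {sample_id: vesicle_75m,  fraction_type: vesicle, collection_depth: 75,
     read_depth: 50000, weights: {75: 0.8, 125: 0.15, 250: 0.05}}
  - {sample_id: vesicle_125m, fraction_type: vesicle, collection_depth: 125,
     read_depth: 50000, weights: {125: 0.7, 75: 0.2, 500: 0.1}}
  - {sample_id: vesicle_500m, fraction_type: vesicle, collection_depth: 500,
     read_depth: 50000, weights: {75: 0.4, 125: 0.2, 500: 0.4}}
  - {sample_id: virus_75m,    fraction_type: virus, collection_depth: 75,
     read_depth: 50000, weights: {75: 0.9, 125: 0.1}}
  - {sample_id: virus_100m,   fraction_type: virus, collection_depth: 100,
     read_depth: 50000, weights: {100: 0.85, 75: 0.15}}
  - {sample_id: virus_125m,   fraction_type: virus, collection_depth: 125,
     read_depth: 50000, weights: {125: 0.8, 100: 0.15, 250: 0.05}}
  - {sample_id: virus_250m,   fraction_type: virus, collection_depth: 250,
     read_depth: 50000, weights: {250: 0.65, 125: 0.2, 500: 0.15}}
  - {sample_id: virus_500m,   fraction_type: virus, collection_depth: 500,
     read_depth: 50000, weights: {500: 0.7, 250: 0.2, 75: 0.1}}
  - {sample_id: free_75m,     fraction_type: free, collection_depth: 75,
     read_depth: 50000, weights: {75: 0.85, 125: 0.1, 250: 0.05}}
  - {sample_id: free_100m,    fraction_type: free, collection_depth: 100,
     read_depth: 50000, weights: {100: 0.8, 75: 0.15, 500: 0.05}}
  - {sample_id: free_125m,    fraction_type: free, collection_depth: 125,
     read_depth: 50000, weights: {125: 0.75, 100: 0.15, 500: 0.1}}
  - {sample_id: free_250m,    fraction_type: free, collection_depth: 250,
     read_depth: 50000, weights: {75: 0.3, 125: 0.2, 250: 0.3, 500: 0.2}}
  - {sample_id: free_500m,    fraction_type: free, collection_depth: 500,
     read_depth: 50000, weights: {75: 0.4, 100: 0.17, 125: 0.1, 500: 0.23, 750: 0.1}}
  - {sample_id: free_1000m,   fraction_type: free, collection_depth: 1000,
     read_depth: 50000, weights: {75: 0.3, 125: 0.16, 500: 0.2, 1000: 0.34}}

traces:
  - {sample_id: free_75m,   peaks: [[8000, 0.08, 0.62], [400, 0.12, 0.23]],
     smear_fraction: 0.15}
  - {sample_id: free_125m,  peaks: [[6000, 0.2, 0.5], [300, 0.15, 0.25]],
     smear_fraction: 0.25}
  - {sample_id: free_500m,  peaks: [[5000, 0.3, 0.4], [250, 0.18, 0.3]],
     smear_fraction: 0.3}
  - {sample_id: free_1000m, peaks: [[3000, 0.4, 0.35]],
     smear_fraction: 0.65}

# DNA export: flux at the euphotic-zone base attenuated by a Martin curve,
# compared with free-DNA standing stocks at depth.
flux:
  model: {F_ref: 1500.0, z_ref: 175.0, b: 0.86}
  stocks: {500: 0.10, 1000: 0.08}
  layer_thickness: 100

permutations: 199
major_taxon_cutoff: 0.005
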