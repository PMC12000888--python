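# fdomlink

A pipeline linking fluorescent dissolved organic matter (FDOM) chemistry to
bacterial community structure and assembly. It covers the full computational
chain used in lake FDOM–microbiome studies:

- **EEM preprocessing** — blank subtraction, absorbance-based inner-filter
  correction, Raman-unit normalization, Rayleigh/Raman scatter excision and
  interpolation, wavelength trimming (`fdomlink.eem`).
- **PARAFAC** — nonnegative trilinear decomposition of the EEM stack with
  multi-start HALS-ALS, missing-cell handling, core consistency, split-half
  validation, Fmax scores, peak-based component classification and offline
  reference-library matching (`fdomlink.parafac`).
- **Optical indices** — FI, BIX, HIX (Zsolnay/Ohno), SUVA254, spectral slopes
  and the slope ratio SR (`fdomlink.optical`).
- **Community analysis** — feature-table I/O (TSV / BIOM-v1 JSON), Chao1,
  Shannon, Gini–Simpson, Pielou, Bray–Curtis, nonmetric MDS, group tests
  (`fdomlink.community`).
- **Assembly null models** — cophenetic distances, abundance-weighted βMNTD,
  βNTI via the taxa-shuffle null, stochastic/deterministic fractions
  (`fdomlink.assembly`).
- **Sloan neutral community model** — occurrence-frequency prediction from the
  Beta stationary distribution, migration-rate fitting, R², Wilson 95% bands
  and per-ASV partitioning (`fdomlink.neutral`).
- **Co-occurrence networks** — Spearman + Benjamini–Hochberg edge calling,
  topology metrics including average path length and modularity
  (`fdomlink.networks`).
- **DOM–bacteria linkage** — taxon-level Spearman maps and the Mantel-style
  |βNTI| vs FDOM-component-distance test (`fdomlink.linkage`).
- **Synthetic data** — seeded generators with machine-readable ground truth
  for every stage: EEM stacks, absorbance spectra, Yule phylogenies, neutral
  and niche-filtered communities, and a full study-like bundle
  (`fdomlink.synth`).

## CLI

```sh
# generate a synthetic two-group (HH/LH/R) × two-matrix (water/sediment) study
fdomlink simulate --preset study-like --seed 7 --out bundle/

# run the full chain: preprocess → PARAFAC → indices → diversity →
# assembly → NCM → networks → linkage
fdomlink run-all --input bundle/ --out report/

# individual stages
fdomlink parafac --input bundle/ --out report/ --k 4:8
fdomlink ncm --input bundle/ --out report/
fdomlink diversity --input bundle/ --out report/
```

Configuration is a flat YAML file validated against known keys (unknown keys
are rejected); CLI flags override it. Reruns with the same config and seed are
byte-identical. Exit codes: 0 success, 2 config error, 3 data error,
4 numeric failure.

## Input formats

All formats are plain text: wide-matrix EEM CSVs (emission in rows,
excitation in the header), two-column absorbance CSVs, a sample metadata TSV
(`sample_id`, `matrix_type`, `group`, `doc_mg_per_L`, environmental columns),
an ASV count TSV (ASVs in rows), a taxonomy TSV and a newick tree.
`fdomlink simulate` writes a complete example bundle.

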