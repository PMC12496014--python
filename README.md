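# mvdst

Multiview denoising for spatially resolved transcriptomics (SRT).

`mvdst` treats an SRT sample as three views — expression, spatial
coordinates, and (optionally) histology-derived morphology features — and
learns spot features that are consistent across them:

1. **View construction** — expression is smoothed with a self-loop
   renormalized graph low-pass filter (`H^t` with
   `H = D̃^{-1/2}(A + I)D̃^{-1/2}`); spatial coordinates and morphology each
   yield a binary symmetric KNN affinity graph.
2. **Dual-encoder autoencoder** — two MLP encoders map the filtered
   expression to latent branches `Z1` and `Z2` (the second branch receives
   Gaussian perturbation as stochastic augmentation); a decoder reconstructs
   expression from the fused `Z = (Z1 + Z2)/2`.
3. **Consistency training** — full-batch Adam minimizes
   `‖X − D(Z)‖² + α‖A − A_spatial‖² + β‖A − A_morph‖²`, where
   `A = Ẑ1 Ẑ2ᵀ` is the latent transcription affinity (row-L2-normalized
   branches). With no morphology view, β is 0 and the morphology term is
   omitted exactly.
4. **Downstream** — K-means spatial domains on `Z`, denoising/clustering
   metrics (MSE, ARI, silhouette, Davies-Bouldin), and per-domain
   one-vs-rest Wilcoxon differential expression (exact tie-aware null
   distribution for small groups) with fraction-expressed / log2FC /
   Benjamini-Hochberg FDR filters.

A built-in simulator generates multiview datasets with shared clustered
latent structure, spatially contiguous domains, a Gaussian-noise sweep,
entry dropout, and cluster merging, retaining clean ground truth for
benchmarking.

The model is implemented in NumPy with hand-derived gradients (no deep
learning framework required), so training runs are exactly reproducible
from a seed and analytic gradients are verified against finite differences
in the test suite.

## Quick start (Python)

```python
import mvdst

# simulate a multiview dataset with ground truth
ds, truth = mvdst.simulate_multiview(
    mvdst.SimulationConfig(n_spots=900, n_clusters=15, noise_var=0.3, seed=0)
)

# end-to-end: graphs -> filter -> train -> latent + denoised expression
result = mvdst.run_pipeline(ds, mvdst.ModelConfig(epochs=300, seed=0))

labels = mvdst.identify_domains(result.Z, k=truth.n_clusters, seed=0)
report = mvdst.evaluate_clustering(labels, truth=truth.labels)
mse = mvdst.evaluate_mse(truth.clean_expression, result.denoised)
print(report.ari, mse)
```

Real data comes in through `mvdst.load_visium(dir)` (Space Ranger layout:
Matrix Market counts, barcode/feature tables, tissue positions; gzipped
variants accepted; off-tissue spots dropped) or
`mvdst.load_tables(expr_csv, coords_csv, morph_csv)`, followed by
`filter_genes`, `normalize_log`, and optionally `banksy_augment`.
Morphology features can be extracted from an H&E raster with
`extract_morphology`, which accepts any callable patch featurizer and ships
a deterministic seeded random-projection fallback (no pretrained weights
are downloaded, ever).

## Command line

A single `mvdst` entry point with subcommands. Every command takes an
optional flat YAML `--config` (flags override file entries; unknown keys
are rejected) and writes the fully resolved config next to its outputs.

```sh
# synthetic dataset with ground truth
mvdst simulate --out sim/ --n-spots 900 --n-clusters 15 --noise-var 0.3 --seed 0

# denoise it (simulator output is already on expression scale)
mvdst denoise --out run/ --expr sim/expression.csv --coords sim/coords.csv \
    --morph sim/morphology.csv --normalized --epochs 300 --seed 0

# spatial domains + metrics (k inferred from truth if given)
mvdst cluster --out cl/ --features run/Z.csv --truth sim/truth_labels.tsv

# differential expression per domain
mvdst deg --out de/ --expr run/denoised.csv --labels cl/labels.tsv

# noise/dropout sweep, one TSV row per (noise, dropout, seed)
mvdst benchmark --out bench/ --noise-vars 0,0.3,0.6,0.9 --seeds 0,1,2
```

For count data from a Space Ranger directory use
`mvdst denoise --visium <dir> ...` (gene filtering and log-normalization
are applied by default; add `--banksy` for neighbourhood augmentation).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (filter oracle,
loss/gradient correctness, no-morphology equivalence, training sanity,
parameter recovery, denoising benefit, statistics oracles, simulator
calibration). End-to-end criteria run on a reduced simulation scale
(300 spots, 20 genes) to stay within a small CPU budget; the asserted
properties are scale-free. The full suite takes a few minutes on one CPU.

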