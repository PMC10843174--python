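# Methods

## The analysis in brief

`nucphase` treats the MNase-seq signal over each yeast gene as one
functional observation: a window of 1200 bp spanning 200 bp upstream to
1000 bp downstream of the +1 nucleosome dyad (anchor at index 200, Crick
genes reversed so the index always increases into the gene body). The
window covers 6–7 nucleosomes of an average (~1.5 kb) gene. The analysis
asks how the *whole* nucleosome array behaves — coordinated positioning —
rather than scoring individual nucleosomes.

The stages are:

1. **Profile similarity.** Pairwise Pearson cross-correlation
   r_xy = Σ(x_i − x̄)(y_i − ȳ) / √(Σ(x_i − x̄)² Σ(y_i − ȳ)²) over the
   1200 positions. Pearson ignores amplitude scaling, so two genes are
   similar when their nucleosomes rise and fall at the same places.
2. **Clustering.** k-means under the correlation distance d = 1 − r.
   Implementation: rows are standardized (zero mean, unit norm), which
   maps d to squared Euclidean distance up to a factor of 2; Lloyd's
   algorithm then runs with centroids re-standardized each step, best of
   `n_init` (default 25) random initializations kept. The number of
   clusters is selected by the mean silhouette computed under the same
   1 − r distance (the silhouette distance is not independently
   meaningful otherwise).
3. **Partition significance.** Inter-cluster correlations (|r| over all
   cross-cluster gene pairs) are compared against 500 random partitions
   preserving the two cluster sizes. Because the number of pairs is huge
   and the KS test over-rejects at large n, 500 values are subsampled per
   side (with replacement when fewer pairs exist) and a one-sided
   two-sample KS test asks whether the observed inter-cluster
   correlations are stochastically lower; the mean p over the 500
   repetitions is reported and compared with α = 0.05.
4. **Functional PCA.** Each profile is projected onto 20 cubic B-splines
   (open-uniform knots on the window); 20 bases over 1200 bp smooth out
   sub-nucleosomal wiggles by construction, so the default ridge penalty
   is 0. With mean function μ(t), the eigenfunctions φ¹, φ², … of the
   empirical covariance operator successively maximise
   Var(∫ (X(t) − μ(t)) φ(t) dt) subject to ‖φ‖ = 1 and orthogonality;
   per-gene scores are ζ_k = ∫ (X − μ) φ^k dt. Two components (K = 2)
   are kept for interpretation; up to 10 for diagnostics.
5. **Cluster boundary.** In the (ζ¹, ζ²) plane the two clusters are
   separated by a linear SVM (C = 1, no feature scaling; the two axes
   share units). Only the boundary slope m = dζ²/dζ¹ is interpreted —
   eigenfunction signs are arbitrary, so |m| is compared. Near-vertical
   boundaries are reported through the angle parameterization
   (0° = separation purely along ζ², 90° = purely along ζ¹).
6. **Replicate-calibrated comparison.** With two replicates per strain,
   s(i) = (μ_i − μ_ref)² / |(|m_A|−|m_B|)_i · (|m_A|−|m_B|)_ref|, where μ
   is the mean absolute slope of the two replicates. s > 1 flags a
   *notable* change: the strain-vs-reference slope difference exceeds the
   within-replicate variability. The reference compared against itself
   gives s = 0 identically.
7. **Combined discriminator.** φ′ = (m φ¹ + φ²)/(m + 1); the band
   mean ± 5·φ′ shows which window positions drive the classification.
   Effect curves for single components use mean ± 20·φ^k (20 is the upper
   end of the typical score range).
8. **Cluster–factor association.** Scalar factors (Pol II occupancy, NDR
   length, AT ratio, …) are median-binarized into −1/+1 halves; the two
   clusters are balanced to equal size first (the excess genes of the
   larger cluster with the highest mean correlation to the smaller
   cluster change sides, one-shot ranking). A zero-hidden-layer
   perceptron with Hebbian weight w_j = (N_agree − N_disagree)/N and a
   step output (fires 1 when Σ w_j x_j > 0) then gives an
   accuracy-vs-0.5 readout. This is a descriptive correlation measured
   on the same genes, deliberately not a cross-validated predictor.

Gene size classes: small ≤ 1000 bp, large > 1000 bp, very large ≥ 3000 bp
(a subclass of large). Cross-strain comparisons run on large genes by
default, because a small gene's window extends past its 3′ end and mixes
genic with non-genic signal.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| window | 200 bp up / 1000 bp down | +1-anchored analysis window |
| n_basis / order | 20 / 4 (cubic) | B-spline representation |
| smoothing penalty | 0 | 20 bases already smooth strongly |
| K | 2 | components kept for interpretation |
| n_init | 25 | k-means restarts |
| n_random / subsample | 500 / 500 | KS significance protocol |
| α | 0.05 | significance threshold on the mean p |
| SVM C | 1.0 | boundary regularization |
| effect scale / band scale | 20 / 5 | eigenfunction and discriminator display |
| s threshold | 1 | notability of a boundary change |
| JS bins | 50 | shared equal-width histogram bins |

## Conventions and edge cases

- Coordinates are 0-based half-open throughout; 1-based annotation inputs
  must be declared (`one_based=True` / `--one-based`). Watson windows are
  [P−200, P+1000); Crick windows are [P−999, P+201) reversed.
- Windows that cross a chromosome edge are skipped with a logged count;
  padding would distort the correlation.
- Constant profiles (zero variance) have undefined correlation and are
  excluded with a warning before clustering.
- Eigenfunction signs are fixed so each score distribution has
  non-negative skew — purely cosmetic; every downstream statistic (|m|,
  JS distances, reconstructions, s) is invariant to joint sign flips.
- The s-statistic denominator is taken in absolute value. The literal
  product of replicate differences can be negative while the statistic is
  meant as a variability ratio; the absolute convention keeps s ≥ 0 and
  reproduces the published strain panel exactly. A flag restores the
  literal signed form.
- Zero denominator (identical replicate slopes in the reference): s is
  reported infinite with a warning, unless the numerator is also zero
  (self-comparison), which is s = 0.
- Median binarization sends values strictly above the median to +1; heavy
  ties trigger a warning when the halves differ by more than 10%. A
  perceptron activation of exactly 0 maps to class 0 (zero counts as
  non-positive); flag-switchable.
- KS subsampling draws with replacement when an inter-cluster set is
  smaller than the subsample size, so small synthetic runs remain valid.
- Balancing ties are broken by gene order (deterministic).

## The synthetic generator

The generator emulates the geometry of +1-anchored mononucleosome
coverage: a Gaussian bump train (width 30 bp SD, spacing 165 bp) starting
at the anchor, an upstream NDR attenuated by 80%, a baseline of 0.1, unit
nominal peak height, additive Gaussian read noise (default SD 0.1)
truncated at zero. Gene lengths are log-normal with mean 1500 bp and
log-SD 0.65, clipped to [300, 6000] bp.

Two modelling choices deserve explanation:

- **Per-peak height jitter** (log-normal, σ = 0.5) is part of a gene's
  latent profile and is shared between replicates. Without it, genes of
  one archetype are identical curves plus iid noise: the leading
  eigenfunction then explains nearly all variance and any archetype
  difference, however small or early in the window, stays linearly
  separable — unlike sequencing data, where within-class gene-to-gene
  variability dominates and the leading components explain only tens of
  percent. The jitter level was fixed once so that the synthetic
  variance structure has that realistic character.
- **Disordered post-TTS fill.** With `truncate_phasing_at_gene_end`, the
  phased train stops at the gene's 3′ end and the rest of the window is
  filled with a disordered bump train (uniform random gaps of 0.5–1.5
  spacings, jittered heights). Beyond a real TTS the DNA is still
  occupied by nucleosomes of neighbouring regions — the signal does not
  drop to a flat line — but those nucleosomes hold no phase relation to
  this gene's +1, and the fill has no dominant period (verified
  spectrally, whitening by the single-peak kernel). A flat fill would
  also leak the gene's in-window mean level into the tail in an
  archetype-dependent way.

Two canonical conditions are provided:

- `two_archetype_config`: equal mixture of archetypes with opposite
  downstream amplitude trends (peak j scaled by 1 ± 0.15·j), the
  "growing vs decaying signal" flavour of cluster structure. A trend of
  ±0.25 makes the archetypes well separated.
- `spacing_archetype_config`: archetypes with spacings 163 vs 169 bp.
  Dyad displacement accumulates with distance from the +1 barrier
  (6 bp per nucleosome index), so the archetypes are nearly identical
  over the first 2–3 nucleosomes and clearly distinct over a full 6–7
  nucleosome array. This is the condition for gene-boundary experiments:
  when phasing is limited to the gene body, short genes expose too few
  peaks to carry the archetype signal, and the all-gene cluster labels
  become unrecoverable from small-gene data — while with phasing running
  past gene ends the same experiment stays fully separable. The
  gene-boundary readout is averaged over 5 simulation replicates because
  single-draw SVM training accuracies on ~160 small genes fluctuate.

Model selection experiments (silhouette k-selection) run on the
large-gene subset: with truncation on, gene length is a genuine second
axis of variation in all-gene data and occasionally dominates the
silhouette, exactly the size bias that motivates the large-gene protocol
in the first place.

What the generator does **not** emulate: sequence-dependent MNase bias,
fragment-length selection artefacts, coverage-depth variation and
mappability gaps, correlated positional fuzziness along the array,
asymmetric NDR structure, and any coupling between factors (Pol II, NDR
length) and the profile shape beyond the programmed label association.
Passing tests therefore demonstrate that the pipeline recovers the kinds
of structure it claims to measure under controlled conditions — not that
real chromatin data contains that structure.

## Problem sizes

Simulated experiments use 400 genes (≈230 large), 25 k-means restarts,
and the full 500 × 500 significance protocol; the gene-boundary
experiment uses 5 × 400 genes per condition. These sizes give stable
statistics for every stage while keeping a full run in minutes on one
core.

## Known limitations

- The correlation k-means is Lloyd's algorithm with random restarts; as
  with any k-means it only approximates the global optimum. Restart
  counts and seeds are recorded in every result object.
- The s statistic is defined for exactly two replicates; more replicates
  would need a different variability calibration, which is out of scope.
- Significance of association accuracies is deliberately not computed
  (raw ratios against the 0.5 line only).
- With only two score dimensions, the SVM boundary slope can be unstable
  when clusters overlap heavily; the angle parameterization and the
  training accuracy are reported to make this visible.
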