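# Methods

## Differential expression

Expression is transformed as y = log2(x + 1); the pseudocount handles the
zeros common in RNA-Seq quantifications. For each cancer type the tumor and
matched-normal groups are compared per gene: the log fold change is the
difference of group means of y, and |FC| ≥ 2 is therefore |log2FC| ≥ 1.
The residual variance s²_g (pooled, df = n_A + n_B − 2) is shrunk toward a
common prior by empirical Bayes. The prior degrees of freedom d₀ and prior
variance s₀² are fit by method of moments on e_g = log s²_g − ψ(df/2) +
log(df/2): the mean of e identifies s₀² and its excess variance over
ψ′(df/2) identifies d₀ through a trigamma inversion (Newton iteration).
When the observed spread of log variances does not exceed its sampling
expectation, d₀ = ∞ and every gene uses s₀². The moderated statistic is

    t_g = log2FC_g / sqrt( s̃²_g (1/n_A + 1/n_B) ),
    s̃²_g = (d₀ s₀² + df s²_g) / (d₀ + df),

with df + d₀ degrees of freedom (normal in the d₀ = ∞ limit). The
`prior_df` argument exposes the two limits explicitly: 0 reduces to the
ordinary pooled t, ∞ uses s₀² alone — both are verified against closed
forms in the tests. Degenerate genes (zero variance everywhere, zero
difference) are declared null (t = 0, p = 1).

Multiple-testing adjustment is Benjamini–Hochberg (statsmodels). The DEG
union keeps a gene if it passes |log2FC| ≥ 1 (inclusive) and p_adj < 0.01
(strict) in at least one cancer. Exact parity with any particular
moderated-t software release is not a goal; the contracts are the limit
identities above.

## Spectral grid embedding

The shared network is the largest connected component of the PPI graph
induced on the DEG union (ties on component size broken by the
lexicographically smallest member, so pipelines are reproducible). Its
combinatorial Laplacian L = D − A (integer, symmetric, rows summing to 0)
is eigendecomposed densely up to 2048 nodes and by shift-invert Lanczos
above that. Eigenvalues below 1e−8 × max degree count as zero; two
numerically-zero eigenvalues mean a disconnected graph, which is refused
with a pointer to the component extraction. The two smallest non-zero
eigenpairs supply x and y; each eigenvector is unit-norm with sign fixed so
its largest-magnitude entry is positive (first index on exact ties), making
coordinates independent of solver sign conventions and node input order.
Degenerate eigenvalues (e.g. the 4-cycle's repeated 2) leave eigenvectors
non-unique; only the eigenvalues are contractual there, and coordinate
tests use non-degenerate graphs.

Binning is per-axis affine min–max to [0, 1] with cell index
min(⌊u·G⌋, G−1); a constant axis maps to index 0. Row = y-bin, col = x-bin,
0-based. The embedding is computed once from the shared subnetwork and
reused for every sample image.

## Image rendering

Each occupied cell holds the arithmetic mean of log2(x+1) expression over
its genes; unoccupied cells are exactly 0. Images are max-normalized to
[0, 1] per sample by default: raw quantification magnitudes (10⁴–10⁶)
would otherwise saturate the network inputs. A raw mode (no normalization
and/or no log) exists behind flags for linearity checks. Embedded genes
missing from a profile contribute nothing to their cell's mean rather than
counting as zero, to avoid diluting occupied cells.

## CNN

Implemented in NumPy: im2col valid convolutions (stride 1), 2×2 stride-2
max pooling in ceil mode (odd sides padded with −inf), ReLU, dense layers,
softmax cross-entropy, full backpropagation (verified against finite
differences in the tests) and Adam (lr 1e−3, β = 0.9/0.999). Ceil-mode
pooling is the only choice consistent with the 96→48, 46→23, 21→11 shape
chain that flattens to 11×11×64 on a 100×100 input; floor mode yields side
10 and fails the contract test. He-normal initialization, batch size 32,
and a stratified 75/25 train/test split inside `train` are all driven by
one seed, so accuracy curves are bit-reproducible. No dropout or weight
decay is applied by default. Prediction restricts the argmax to the trained
class vocabulary with lowest-index tie-break.

## Splits, repeated experiments, survival

Per cancer, training takes ⌈normal_fraction · n_normals⌉ random normals
(default half, rounded up — with 113 normals this yields the reference 57)
and exactly `tumor_per_normal` (default 3) times that many random tumors;
everything else is validation. Repeated experiments derive seed_i =
root_seed + 7919·i, so experiment i is reproducible in isolation. The
prediction log records train and validation roles for every experiment;
misjudgment of a tumor counts both wrong-cancer and tumor→normal calls.

The survival table counts, per cancer and by default over unique samples
across all experiments (a per-experiment mode exists): tumors with ≥ 1
error (n_error), those ever misjudged into normal (m), tumors never wrong
(c), and among the deceased of each group those who lived ≥ 2 years
(730 days on the survival-days field) — a and b. The reported statistic is
the ratio of proportions (a/m)/(b/c); the literature this mirrors labels it
an odds ratio, but the printed values follow the proportion formula, so
that is what is computed (NA when a denominator is 0 or clinical data are
absent; 0 when a = 0 with b > 0). Mean-similarity analysis of misjudged
samples uses Pearson r on DEG-restricted profiles, excluding the sample
itself from its own class.

## Synthetic data

The generator emulates the pipeline's assumed structure, not any real
cohort: per-gene baseline log2 levels ~ N(4, 1.5) (lognormal on the raw
scale, mimicking RNA-Seq skew); tumors of class c shift their signature
genes by `effect_log2fc` (default 3, an 8-fold change typical of strong
markers); Gaussian noise of sd `noise_sd` (default 0.5) on the log scale;
values back-transformed and clipped at 0. Default cohort: 3 classes × (16
tumors + 5 normals) = 63 samples over 300 genes with 20-gene signatures.
The `planted_partition` graph puts each signature in its own dense
community (p_in = 0.3) over a sparse background (0.02); Erdős–Rényi and
Barabási–Albert alternatives exist. Disconnected draws are bridged with
logged extra edges. Clinical tables assign death with probability 0.3 and
survival uniform on [0, 3650] days, independent of expression — survival
hazards tied to expression are out of scope.

What the synthetic cohorts do **not** model: batch effects, library-size
variation, isoform structure, gene–gene correlation beyond the planted
shifts, and realistic class imbalance. Passing tests therefore demonstrate
the machinery (selection, embedding, rendering, optimisation, bookkeeping)
under the stated generative assumptions, not clinical-grade performance.

The confusability fixture shares 80% of the signature genes between two
classes and raises noise to sd 1.5, emulating tumor pairs from the same
tissue of origin whose transcriptomes overlap; it is designed to produce
misclassifications concentrated on the shared pair, which the directional
confusion-matrix assertion checks.

## Problem sizes and numerical choices

End-to-end demonstrations use a 32×32 grid (shape chain 28→14, 12→6, 4→2),
63-sample cohorts, and 5–20 epochs — sizes at which the full pipeline runs
in seconds while exercising every stage; the architecture itself is
validated at the full 100×100 geometry via its shape contract and forward
pass. The spectral zero-tolerance (1e−8 × max degree) is relative because
Laplacian spectra scale with degree. BH adjustment, eigensolvers, the
stratified splitter and graph containers are delegated to statsmodels,
scipy, scikit-learn and networkx respectively.
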