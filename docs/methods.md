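# Methods

This note documents the models and procedures implemented in `thymotrace`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the package's known limitations.

## Staging model

The seven γδ thymocyte populations A–G are defined by positivity patterns
over six surface markers:

| stage | CD24 | CD25 | CD73 | CD117 | CD200 | CD371 |
|-------|------|------|------|-------|-------|-------|
| A | hi | + | − | any | − | + |
| B | hi | − | − | any | − | + |
| C | hi | − | − | any | − | − |
| D | hi | any | − | any | + | any |
| E | hi | any | + | + | any | any |
| F | hi | any | + | − | any | any |
| G | lo | any | any | any | any | any |

Assignment uses a fixed decision-tree order (G, then E/F, then D, then
A/B, else C) that mirrors conventional bi-axial gating and makes the
assignment a total partition: every event gets exactly one stage, and the
result is invariant under any monotone per-marker transform applied
consistently to events and thresholds. The signature table is
user-overridable; at load time each stage's own pattern is checked to gate
back to that stage, so ambiguous tables are rejected. CD117 for stage D is
treated as uninformative ("any"): the gate never consults it before D is
assigned.

One positivity threshold per marker is used for both +/− and hi/lo
distinctions. The default `valley` method places the cut at the
kernel-density minimum between the two largest density modes
(scipy `gaussian_kde` on a 512-point grid); unimodal markers raise an
error directing the user to a manual threshold, and a quantile-of-negative-
control method (default q = 0.999) is available when a labelled negative
subset exists. The arcsinh cofactor defaults to 150, the conventional
scale for fluorescence cytometry.

## Unsupervised population discovery

The self-organizing map is batch-trained: codebook vectors are initialized
from randomly sampled events; each epoch assigns every event to its best
matching unit (ties broken toward the lowest node index) and replaces each
codebook vector with the Gaussian-neighborhood-weighted mean of the
assigned events. The neighborhood radius shrinks linearly from half the
grid diameter to 0.5 over the epochs. Defaults — 10×10 grid, 20 epochs —
are FlowSOM-like desk-scale settings; with one grid node the batch update
converges to the data mean in a single epoch, a property the tests use.
Metaclustering is a deterministic average-linkage agglomeration of the
codebook cut at exactly k clusters (default k = 7); event labels inherit
through the best matching unit. The consensus-resampling step some
implementations add is deliberately omitted so results are exactly
reproducible. Cluster mean profiles are matched to stages by thresholding
the profile and testing stage signatures in gating-order priority;
profiles satisfying no signature are reported "unassigned" and collisions
are kept but flagged.

t-SNE (scikit-learn, PCA initialization, fixed random state) is exposed
only for visualization; the package's contract for it is shape,
determinism and better-than-random neighborhood preservation, not any
specific geometry.

## Lineage inference

Population distances are Euclidean over all retained genes of
log₂(CPM+1) profiles, with biological replicates averaged per population
first and an optional gene exclusion list (e.g. erythrocyte-contamination
transcripts) removed before computing distances. "Connecting the least
different populations" is formalized as the minimum spanning tree: the
minimal-weight connected acyclic graph over the distance matrix, computed
by Kruskal over a lexicographically pre-sorted edge list so ties are
deterministic. Leaves of the tree are candidate export end points; nodes
of degree ≥ 3 are branch points. A symmetrized k-NN graph is provided as
an alternative connection rule, since a nearest-neighbor sketch is another
reasonable reading of "shortest distances". The package deliberately does
not root or direct the graph: directionality is a biological argument, not
an algorithmic output.

Isomap follows the classical recipe: seeded uniform downsampling to
n = 100 cells per population, symmetrized k-NN graph (default k = 10),
Dijkstra geodesics, classical MDS of the geodesic matrix (eigenvalue
floor 1e-9, deterministic sign convention). With a complete graph the
geodesics equal the raw distances and the method reduces exactly to MDS —
a limit the tests exploit. The diffusion map uses a Gaussian kernel with
the median pairwise distance as default bandwidth, the α = 1
density-normalization (divide the kernel by the outer product of its
degrees) to remove sampling-density effects, and returns the top
non-trivial right eigenvectors of the row-stochastic Markov matrix scaled
by their eigenvalues, computed through the symmetric conjugate for
numerical stability.

## Surface-marker screen

Differential testing is a plain one-way ANOVA per gene (vectorized;
p from the F(g−1, n−g) distribution), which for two groups equals the
squared pooled t statistic. Genes with zero variance everywhere are
flagged (F = NaN, p = 1 by convention). FDR control is
Benjamini–Hochberg step-up. Note BH is not idempotent — re-adjusting
adjusted values can raise them further (e.g. [0.25, 1.0] → [0.5, 1.0] →
[1.0, 1.0]); the implementation matches the reference statsmodels values
exactly. The candidate filter is the conjunction of four strict
predicates: |log₂FC| > 3 (absolute by default, signed optional, because a
marker may be enriched in either compartment), q < 0.05, membership in a
cell-surface GO term (GO:0009986 or GO:0005886; genes missing from the
annotation count as non-members and are logged), and maximum group-mean
log₂ expression > 7, read as "detectably expressed in at least one of the
compared compartments". The module consumes an already normalized,
batch-corrected matrix; `normalize_log2` offers simple library-size
log₂(CPM+1) normalization for raw counts, not a replacement for a full
RNA-seq normalization pipeline.

## Repertoire statistics

In-frame clonotypes are defined by the standard clonotype-tool
convention: CDR3 nucleotide length divisible by 3 and no stop ('*') or
frameshift ('_') character in the amino-acid sequence. Depth equalization
samples reads without replacement (multivariate hypergeometric), so
expected clone fractions are preserved; libraries below the target depth
raise an error because such libraries must be excluded, not upsampled.
Motif abundance is a case-insensitive regular-expression match on the
CDR3 amino-acid sequence, with all reads of the filtered, depth-equalized
table as denominator. Motif patterns are configuration, never built-in:
the effector-associated CDR3 motifs in the literature are not published
as explicit regular expressions, so the defaults ship as named
placeholders the user must fill. Diversity is the plug-in inverse Simpson
index 1/Σpᵢ² (an unbiased finite-sample variant is available via
`unbiased=True`).

## Emigration-blockade analysis

Stage-wise accumulation is summarized as fold changes over the untreated
group; a stage is called terminal when its late (10 d) fold is at least 3
and its sustained-growth ratio fold₁₀d/fold₅d is at least 1.5. These
defaults separate stages that accumulate roughly an order of magnitude and
keep growing from stages that rise modestly and saturate; both thresholds
are configuration, since the biological boundary between "continues to
accumulate" and "increased only slightly" is narrative rather than
numeric. Group comparisons use the two-sided equal-variance Student's
t test (pooled df = nₓ + n_y − 2), matching standard reporting practice;
no multiple-testing correction is applied across stages.

## Synthetic study conditions

The generators define the default conditions under which the pipeline is
validated.

**Cytometry.** Each stage × marker intensity is one log-normal component:
negative ≈ 20, positive ≈ 2000, CD24-high ≈ 3000, CD24-low ≈ 80 (raw
scale), all with log-spread 0.35. After asinh(x/150) the component means
separate by roughly 9σ (≈ 4.5σ against the CD24 hi/lo valley), so valley
thresholds are essentially error-free — the generator validates gating
logic, not threshold robustness. Stage fractions default to 1/7 each;
subsets Vγ1.1/Vγ2 to 0.5/0.5. Counts are allocated by largest-remainder
rounding, so they are exact, and treatment groups scale expected stage
counts multiplicatively: by day 10 stages C, E, G reach 10×, 5×, 10×
untreated while D and F saturate at 1.6×/1.8× — the planted analogue of
blockade-driven accumulation at the terminal stages. Not emulated:
spillover/compensation, doublets, debris, FMO controls, staining
variability; a perfect staging score here does not imply 99% accuracy on
real cytometry.

**Expression.** The designed lineage is the tree A–B–C–D with D branching
to E and to F–G (branch point at D, leaves A, E, G). Each of the six tree
edges owns a disjoint block of 40 signature genes (of 500) shifted by
+1.5 log₂ in every stage beyond that edge, making squared distances
between designed stage means additive along the tree, so the MST of the
noiseless means is exactly the designed topology. Per-gene baselines are
6.0 ± 0.8 (log₂); counts are gamma-Poisson with dispersion 0.05 (typical
for bulk RNA-seq of sorted replicates), two replicates per stage and
subset (28 samples), then log₂(CPM+1). At dispersion → 0 the output equals
the designed means exactly, which anchors the noiseless-limit tests. Not
emulated: gene–gene correlation, library-size imbalance, batch effects,
replicate-specific contamination.

**Repertoire.** Clone sizes follow rank^(−a) (default a = 1). Planted
motifs occupy their target fraction of the in-frame read mass across a
small set of motif-bearing clones; out-of-frame mass goes to clones with a
frameshifted nucleotide length and '_'-marked amino-acid field. A single
multinomial draw of `total_reads` produces counts, so realized fractions
deviate from targets only by sampling error (SE ≈ √(f(1−f)/N)). V labels
are assigned to clones by a largest-remaining-deficit rule on expected
read mass so read-level usage tracks the target within multinomial noise.
Not emulated: sequencing error, PCR amplification bias, clonotype
assembly artifacts.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  public stochastic operation takes an explicit seed and is
  bit-reproducible.
- BMU and argmin ties resolve to the lowest index; MST ties resolve
  lexicographically; MDS component signs are fixed by making the
  largest-magnitude loading positive.
- Degenerate inputs fail loudly: double arcsinh transform, unimodal
  valley fitting, zero library sizes, zero baseline counts, disconnected
  k-NN graphs, zero pooled variance, empty clonotype tables.
- The FCS reader/writer supports the common list-mode float/integer
  layouts of FCS 3.0/3.1 and stores marker names as channel names; it is
  intentionally minimal, and CSV (markers plus `meta_`-prefixed
  annotation columns) is the lossless round-trip format.
- Problem sizes used in the validation suite — 10,000 events, 100
  simulation replicates of 500 × 28 expression matrices, 700-cell
  progression sets, 1200/724-read libraries — were chosen to match the
  scale of the corresponding real experiments while keeping a full run on
  a single CPU in well under a minute for the acceptance script.

## Limitations

- Thresholded staging assumes pre-gated (TCRδ⁺, viable, singlet) input;
  no debris or doublet modeling.
- The screen expects normalized, batch-corrected expression; RMA/ComBat
  style preprocessing is out of scope.
- Clonotype assembly and error correction are upstream of this package;
  the repertoire module starts from clonotype tables.
- The lineage graph is undirected and unrooted by construction; pseudotime
  direction must come from external biology.
- Synthetic validation demonstrates algorithmic correctness under the
  stated generative models, not performance on real cytometry or RNA-seq
  noise structures.
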