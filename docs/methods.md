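# Methods

This note documents the models and procedures the package implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices that were genuinely open.

## Synthetic tissue model

An ROI is a 1000×1000 µm rectangle observed at 1 µm²/pixel, the standard
IMC acquisition geometry. Cell populations are placed by one of:

- **CSR** — homogeneous Poisson: N ~ Poisson(density × area), uniform
  positions. The null model for all spatial statistics.
- **Thomas cluster process** — Poisson parents (default 10–25 /mm²),
  Poisson offspring displaced by an isotropic Gaussian (default sd
  25–60 µm). Used for the organised Schwann-cell sheets of dense
  (Antoni A-like) regions.
- **Perivascular** — uniform along a vessel polyline with a uniform
  radial offset inside the vessel halo (default 30 µm). Vessels are
  random gently-curved polylines spanning the ROI.
- **Co-clusters** — a planted pair (A, B) shares one Thomas parent set
  with type-specific offspring. This is the simplest generative model
  that guarantees ĝ_AB > 1 at short range; the `strength` parameter
  scales the offspring sd as base_sd/√strength, so gr20 increases
  monotonically with strength.

Marker intensities are profile mean × log-normal noise (sd =
`dispersion`, default 0.15) plus a small exponential background, times a
multiplicative per-(case, marker) log-normal batch factor (sd 0.15) — the
intensity-scale artefact that batch-balanced graph construction targets.
Offspring falling outside the window are redrawn around their parent with
bounded retries; an expected count above 2×10⁵ cells/ROI raises rather
than silently truncating.

The default study (`simulate_study`) uses 6 cases × 3 ROIs with a
2:1 Antoni A:B region mix, total densities of roughly 2700 (A) and
950 (B) cells/mm², ~11 populations across the four parent groups, and
clinical covariates (severity in thirds, a bevacizumab-treated tail, a
log-normal volumetric growth rate). These sizes keep a full pipeline run
in minutes while preserving the contrasts the analysis is built to
detect; they are desk-scale stand-ins, not a claim about real cohort
sizes.

Expression counts are negative-binomial (dispersion θ = 2, baseline gene
means log-uniform on [0.5, 5], shared across populations so the null is
exchangeable); a planted ligand–receptor pair multiplies the ligand mean
in its sender and the receptor mean in its receiver by `fold`
(default 8).

**What the generator does not emulate**: IMC noise physics (hot pixels,
spillover, denoising), irregular cell shapes (cells are discs), true
spatial exclusion (the "TAM aggregates exclude Schwann cells" motif is
approximated by independent parent sets, not by repulsion), and
intra-population expression heterogeneity. Passing tests therefore show
the *statistics* behave correctly under known truth, not that the
pipeline is robust to every acquisition artefact of real tissue.

## Quantification

Nuclear labels are dilated by `expansion_px` (default 1) steps of an
8-connected structuring element; a contested pixel goes to the cell with
the nearest nuclear *centroid*, exact ties to the lower label. (Common
practice is expansion by Euclidean distance to the nearest nuclear
*pixel*; at one pixel the two differ only on contested pixels, and the
centroid rule is deterministic and order-free.) Pixel centres sit at
integer + 0.5 µm, origin top-left, y downward; this convention is used
everywhere. Rendering uses hard discs whose signal radius covers the
expansion region, so quantification round-trips recover planted means to
the float32 storage precision of the stack (~10⁻⁷ relative).

Jaccard QC samples 50 automatic cells per ROI without replacement (all of
them, logged, when fewer exist), matches each to the manual object of
maximal overlap and reports J = |∩|/|∪|; unmatched cells score 0 and are
flagged.

## Phenotyping

Each marker is divided by its 99.9th percentile (linear-interpolation
order statistic — implementations differ, so this is pinned) and clipped
to [0, 1]; divisors are stored for reuse, making the operation
idempotent. The neighbour graph takes each cell's k nearest neighbours
(default 3) separately *within every case* and unions them, weighting
edges by 1/(1+d) — the batch-balancing construction that stops per-case
intensity shifts from fragmenting populations. Leiden community detection
(RBConfiguration objective, seed-deterministic) runs at resolution 1.0;
coarse clusters map to the parent group with the highest mean canonical
marker (below 0.1 → "Other"), each group is re-embedded and re-clustered
at resolution 1.5, and sub-clusters are annotated by ordered
positive/negative mean-threshold rules from YAML. The resolutions and k
are configuration defaults, not values validated against any acquired
dataset.

## Spatial statistics

ĝ_AB(r) uses 1 µm bins to 20 µm; **gr20** is the final [19, 20) bin.
Edge correction divides each count by the exact annulus∩rectangle area,
computed in closed form (half-plane and corner-segment areas with
reflection identities) and verified against numerical integration; with
correction off, ĝ_AB = ĝ_BA exactly. Empty populations flag the result
rather than propagating NaN.

Significance permutes population labels over all cells of the ROI,
positions fixed: p = (1 + #{|g*₂₀−1| ≥ |ĝ₂₀−1|})/(n_perm+1), two-sided
around the CSR value 1, direction from sign(ĝ₂₀−1). ACN "contact" is
centroid distance ≤ 10 µm (about one cell diameter; mask adjacency is a
reasonable alternative the interfaces accommodate) and its permutation
test is two-sided around the permutation-null mean, since a proportion
has no fixed null centre. BH-FDR is applied across pairs within each ROI;
a region-class network edge requires significance in a majority of that
class's ROIs, with mean gr20 as the edge weight and mean abundance as the
node size.

**Calibration caveat.** The permutation test is exact-conservative, never
anti-conservative. At CSR intensity 100/type/mm² the [19, 20) µm bin
holds ~1.2 (A,B) pairs per ROI, so the permutation distribution of gr20
is a few atoms; with ties counted in the p-value the empirical type-I
rate at α = 0.05 is ~0.01 (and the ACN statistic's smallest achievable p
often lands exactly on 0.05). At intensity 500/type/mm² the rate reaches
≈ 0.045. Tests of validity therefore assert rate ≤ α + 2·SE; users who
need nominal-size behaviour at sparse densities should raise dr, pool
bins, or use more permutations with a mid-p variant (not implemented).

## Cellular neighbourhoods

The spatial graph is a Delaunay triangulation trimmed at 30 µm — unlike a
kNN graph it needs no density-dependent k. Features concatenate the
cell's own normalised markers with the mean over each hop shell 1..L
(default L = 3; empty shells are zero-padded and flagged). Full-covariance
GMMs (variance floor 10⁻⁶) are fitted R = 10 times per K; stability(K) is
the mean pairwise FMI among the repeats, K* the argmax with ties to the
smaller K (parsimony), and the final model is the best-likelihood fit at
K*. The between-K variant (FMI against K±1 labelings) is available via
`mode="between"`.

A known degeneracy: if two K values are both perfectly stable — e.g. a
perfectly symmetric mixture where K=2 merges the same two components in
every repeat — the tie resolves to the smaller K. Real tissue is
asymmetric enough that this rarely matters, but symmetric toy data can
select a merged solution; the benchmark suites use asymmetric mixtures.

Proximity z-scores compare each CN's directed edge fractions against CN
label shuffles on the fixed graph (shuffling within ROI when several
ROIs' graphs are pooled); rows are senders, columns receivers. CN
derivation runs per region class by default and every output is tagged
with its scope — combined and per-region models are never mixed silently.

## Receptor–ligand scoring

score = ½(mean ligand expression in sender + mean receptor expression in
receiver); complexes contribute the per-cell subunit minimum. Input is
library-size-normalised log1p counts (raw-count mode works identically).
The one-sided permutation test shuffles labels over cells
(p = (1+#{score* ≥ score})/(n_perm+1)). Filtering requires the ligand
expressed in ≥ 5% of sender cells AND the receptor in ≥ 5% of receiver
cells (the OR reading of this rule is available behind `frac_mode`); BH
runs within each (sender, receiver) combination by default
(`bh_family="global"` for one family); survivors are ranked by score,
keeping the top 20. The `direction` column records lymphocyte
orientation: "sender" when the lymphocyte expresses the ligand.

## Case-level statistics

All comparisons act on case averages — one value per case — to avoid ROI
pseudo-replication (an ROI-level mode exists for diagnostics only).
Shapiro–Wilk at α = 0.05 gates the test: two normal groups → unpaired t,
switching to Welch when the variance ratio exceeds 4 (the threshold is a
package choice; both plain and Welch t-tests are in scope); otherwise
Mann–Whitney U. Three groups → ANOVA + Tukey HSD, or Kruskal–Wallis +
Dunnett's T3. T3 is implemented as pairwise Welch statistics with
Welch–Satterthwaite df and a Šidák-type adjustment 1−(1−p)^m, which
equals the studentized-maximum-modulus criterion under independence — no
SciPy/statsmodels implementation of T3 exists. Constant groups make
normality undefined and force the nonparametric branch, logged. Every
result records the gate evidence, so the choice of test is auditable.

Match accounting reports aligned% = 100·n_aligned/n_total (2 dp) and
matched% = 100·n_matched/n_aligned (1 dp), with the match-score threshold
(default 0.3) carried through.

## Benchmark problem sizes

The reproduction script and acceptance tests use: 200 CSR ROIs for the
gr20 calibration and 500 for the permutation type-I rate (199
permutations per test — permutation counts of 199 keep simulation suites
at interactive speed while exceeding the 99 needed for α = 0.05
resolution); 100 seeds for co-cluster detection; 10 repeats × 10 GMM fits
for planted-K recovery; 20 seeds for the planted ligand–receptor pair;
1000 simulations at 13 vs 10 cases for the two-group type-I rate. All
randomness descends from one root seed through named substreams.

## Known limitations

- The one-pixel-expansion tie rule and structuring element are stated
  choices, not an inference about any particular upstream pipeline.
- Permutation p-values are conservative under heavy ties (see the
  calibration caveat); reported rejection rates under sparse nulls sit
  below the nominal level.
- Stability selection cannot separate two perfectly stable K values;
  ties go to the smaller K by design.
- The generator's exclusion motifs are approximate; repulsive point
  processes (e.g. Strauss) are not implemented.
- Mask-adjacency contact, mixed-effects models across ROIs within cases,
  and spatially-smoothed CN labels are out of scope.
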