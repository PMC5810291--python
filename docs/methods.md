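# Methods

## Model and procedure

The package infers a *coalteration network* from coordinate-based VBM
meta-analysis data: experiments (one VBM contrast each) report alteration
foci in Talairach millimetre space; the question is which brain loci are
altered together across experiments more often than independence predicts.

**ALE stage.** Each focus contributes an isotropic 3-D Gaussian
p(d) = (σ³(2π)^{3/2})⁻¹ exp(−d²/2σ²), σ = FWHM/√(8 ln 2), modeling the
spatial uncertainty of a reported coordinate. The density is converted to a
per-voxel probability by multiplying by the voxel volume, so modeled-
alteration (MA) values live in [0, 1] and the union formula below is a
valid probability statement. Within one experiment, foci combine by
voxel-wise **maximum** (a locus reported twice is not more altered);
across experiments, ALE = 1 − ∏ᵢ(1 − MAᵢ), the probability that at least
one experiment's alteration covers the voxel. Significance is a max-
statistic Monte-Carlo null: datasets with the same per-experiment foci
counts but uniformly random in-mask locations are re-analyzed, the maximum
in-mask ALE recorded per iteration, and the (1 − α) empirical quantile
(conservative "higher" interpolation) is the voxel-level FWE threshold at
α = 0.05. A cluster-size null (largest 6-connected suprathreshold cluster
at a user-set forming threshold) is provided as an alternative.

**Node stage.** Three filters, all monotone in the node count: (i) an
atlas region is altered only if ≥ `min_region_voxels` (default 20) of its
voxels survive thresholding; (ii) local ALE maxima (26-connectivity;
equal-valued plateaus contribute one peak at the centroid-nearest voxel)
are kept only above the `peak_percentile` (default 90th) of the
suprathreshold voxel-value distribution, strict comparison; (iii) greedy
non-maximum suppression enforces `min_interpeak_mm` (default 10 mm, the
mean spatial-location uncertainty of reported coordinates) with an
inclusive boundary — two peaks exactly 10 mm apart both survive, since
equality lies within that uncertainty. Surviving peaks become nodes named
`<Region>_<k>`, numbered within each region by descending y (rostrocaudal),
ties by descending ALE value.

**Coalteration stage.** Cell (e, j) of the binary experiments × nodes
matrix is 1 iff experiment e reports a focus within `assign_radius_mm`
(default 10 mm — the same uncertainty constant) of node j's peak; a
region-membership rule is available as `assign_rule: region`. For a node
pair, the four joint-state frequencies give θ̂₁…θ̂₄ and Patel's κ

    κ = (θ₁ − E) / (D·(max(θ₁) − E) + (1 − D)·(E − min(θ₁))),

with E = (θ₁+θ₂)(θ₁+θ₃), max(θ₁) = min(θ₁+θ₂, θ₁+θ₃),
min(θ₁) = max(0, 2θ₁+θ₂+θ₃−1) and D = 1{θ₁ ≥ E}, which pins κ to [−1, 1]
with the endpoints attained exactly at perfect co-occurrence and perfect
complementarity. With both marginals strictly inside (0, 1) the active
denominator is strictly positive, so κ is well defined; columns altered in
all or no experiments are excluded from pair evaluation (their κ is
undefined). Edge significance samples θ from
Dirichlet(1+n₁, …, 1+n₄) — a flat prior, the minimal-assumption choice —
and declares an edge significant when P(κ > e | data) ≥ 1 − p with e = 0,
p = 0.01. The reported κ̂ per edge is the maximum-likelihood point estimate
n/N, so printed values match the closed-form examples. No correction
across pairs is applied by default (`bonferroni: true` divides p by the
number of evaluated pairs).

**Topology stage.** The graph is simple, undirected and unweighted for
topology (κ colors edges, never weights paths). Degree, edge betweenness
(each unordered pair counted once; ties among equal shortest paths split
fractionally by default, an integral-counting mode is available), k-core
decomposition via iterative pruning with the maximal non-empty core
reported as the core subnetwork, interhemispheric/intrahemispheric edge
counts (midline-tagged endpoints count as intrahemispheric), and a
region-merged view (parallel edges keep the maximum κ; intra-region edges
drop as self-loops, counted).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `fwhm_mm` | 10 | Gaussian kernel FWHM (mm); matches the ~10.2 mm mean coordinate uncertainty |
| `trunc_factor` | 3 | kernel truncation radius in FWHMs (error < 10⁻⁶; 5 gives < 10⁻¹²) |
| `alpha` | 0.05 | voxel-level FWE level |
| `n_null_iterations` | 1000 | null ALE datasets simulated |
| `mask_mode` / `mask_dilation` | atlas / 1 | in-brain mask: atlas nonzero voxels dilated 1 voxel; `full` = whole box (for sparse toy atlases whose regions do not tile a brain) |
| `min_region_voxels` | 20 | region-rule threshold (voxels) |
| `peak_percentile`, basis | 90, voxels | peak filter; percentile of suprathreshold voxel values (the peak-value basis is config-switchable); 0 disables the strict filter |
| `min_interpeak_mm` | 10 | minimum peak separation (inclusive) |
| `region_filter_order` | after | drop peaks in failing regions after distance suppression (a strong peak in a failing region still suppresses neighbors) |
| `assign_radius_mm` | 10 | focus-to-node assignment radius |
| `e_threshold`, `p_threshold` | 0, 0.01 | edge significance: P(κ > e) ≥ 1 − p |
| `n_mc_samples`, `prior_alpha` | 10⁴, 1 | Dirichlet draws and prior |
| grid | 2 mm, x∈[−70,70], y∈[−104,68], z∈[−60,78] | default Talairach bounding box; all coordinates treated as Talairach mm, no MNI transform |

Conventions recorded in every run manifest: 26-connectivity for maxima,
6-connectivity for clusters, "higher" quantile interpolation, betweenness
tie mode, Dirichlet prior.

## Synthetic data generator

`GenerativeSpec` realizes the multinomial model the statistics are defined
under: per experiment, a binary alteration pattern over cuboid toy-atlas
regions, with planted pairwise couplings implemented by Gaussian-copula
thresholding of latent normals — any feasible 4-cell θ table is attainable,
including the Fréchet boundaries (latent correlation ±1), and the
population κ of every pair is available in closed form. Defaults: 60
experiments; 10 regions (5 mirrored L/R pairs, half-extent 8 mm, placed at
medial-temporal/parietal-like Talairach coordinates); base alteration
probability 0.4; 4 disjoint planted couplings with joint excess 0.17
(population κ ≈ 0.708); 2–6 foci per altered region, Gaussian-scattered
(SD 4 mm ≈ the σ of a 10 mm-FWHM kernel) and truncated to the region
cuboid; 0–3 noise foci uniform over the bounding box (incidental reports
the region rule should remove; an otherwise focus-free experiment receives
one, since an experiment enters a meta-analysis only by reporting
something). Everything is reproducible from the spec seed, down to
byte-identical foci files.

What the generator does **not** emulate: anatomically realistic cortical
geometry, subject-count-dependent kernel widths, higher-order (beyond
pairwise) alteration dependencies, spatially correlated noise, and
between-study heterogeneity in smoothing or registration. Passing tests
therefore demonstrate statistical correctness of the chain under its own
generative model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

Foci snap to the nearest voxel center; out-of-box foci are dropped with a
warning (an all-out-of-box experiment is an error). Duplicate foci are
absorbed by the within-experiment maximum. Dirichlet draws with a
degenerate marginal (probability zero up to floating-point underflow) are
rejected and redrawn, counted in the result. The greedy interpeak filter
orders by descending value with lexicographic voxel-index tie-break, so
its output is independent of input order. Per-pair Monte-Carlo seeds are
spawned deterministically from the run seed.

## Simulation sizes used in the validation suite

The test suite runs desk-scale versions of each check: ALE oracle
equivalence on a 4 mm grid (10 fixtures × 10 foci); FWE calibration on a
6 mm grid (1000-iteration null, 500 fresh null datasets, 99% binomial
band around α); edge-significance calibration with 2000 independent
Bernoulli pairs at N = 57 and 10⁴ draws; end-to-end planted-structure
recovery on a 4 mm grid with a 200-iteration null. The κ̂-recovery band of
±0.15 is tight relative to the sampling error of the ML κ estimator at
N = 60 (SD ≈ 0.11, upward bias ≈ +0.05 near the upper Fréchet bound), so
individual fixed-seed draws can land outside it even for a correct
implementation; the suite asserts it as stated.

## Limitations

Coordinate-based input only (no image-level data); Talairach space assumed
throughout with no MNI conversion or resampling; the focus→node assignment
rule is a modeling choice (the radius rule shares the 10 mm uncertainty
constant); per-edge significance is uncorrected for the number of pairs by
default; κ is symmetric — no directionality is inferred; the cluster-size
null is provided but voxel-level FWE is the default inference.
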