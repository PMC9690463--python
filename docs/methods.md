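# Methods

## The problem

A meta-QTL analysis condenses QTLs reported by many independent mapping
studies into consensus loci. Three obstacles make this more than
averaging: each study uses its own genetic map (different marker panels,
slightly different cM scales), each reports positional uncertainty
inconsistently (if at all), and the number of underlying "real" loci is
unknown. The pipeline addresses these in order: a common coordinate
system (consensus map), a uniform uncertainty model (recalculated CIs),
and model selection over the number of loci (mixture + AIC).

## Consensus map

**Model.** Marker positions on different maps are treated as noisy
measurements of inter-marker *distances*; absolute coordinates carry no
information across maps. The consensus coordinates x of the markers on a
chromosome minimise

    Σ_m  w_m  Σ_{(a,b) adjacent shared markers of map m} ((x_b − x_a) − d_ab^(m))²

where d_ab^(m) is map m's observed distance and w_m its weight. Only
adjacent pairs enter: all-pairs distances would double-count intervals and
correlate errors; adjacent intervals are the standard composite-map
formulation. The system is a weighted graph Laplacian, solved by normal
equations with one marker pinned (below). Markers present in only one
source carry no cross-map information and are placed afterwards by linear
interpolation between their nearest flanking shared markers on their own
map.

**Weights.** The merge weight defaults to the study's population size
(overridable per map): a map estimated from more lines constrains
distances more tightly. The weighted formulation leaves the choice open.

**Merge order and exclusion rules.** Maps join the growing consensus one
at a time in descending weight. A chromosome of an incoming map is
excluded from that map's contribution if it shares fewer than two markers
with the consensus so far (a single shared marker cannot orient a
chromosome), reported as such in the build report. Before a map's
chromosome is accepted, marker-order conflicts against the current
consensus are removed: every pair of common markers ordered oppositely in
the two maps is flagged, exhaustively over pairs. A flagged pair separated
by ≥ 1 cM on the consensus loses both markers (genuinely inconsistent
loci); a pair closer than 1 cM — markers so tightly linked that their true
order is effectively unresolved by either map — loses exactly one, chosen
greedily to retain the maximum number of markers (highest conflict count
first, then largest rank displacement, then name). The greedy rule is an
approximation to minimum vertex cover; conflicts are sparse and the exact
cover is not worth its complexity. The 1 cM threshold is measured on the
consensus-side separation (configurable).

**Anchoring and ordering.** Distances determine positions only up to a
per-chromosome translation, so the smallest-position reference marker is
pinned to its reference coordinate; if the fit still produces negative
positions the chromosome is shifted to start at 0 (reported). After
fitting, reference-marker order is enforced against the reference by
pool-adjacent-violators (ties allowed); with inversion filtering upstream
this is almost always a no-op. Connected components of the constraint
graph that do not contain the anchor cannot be placed and are dropped with
a report, never silently positioned.

**Properties.** Merging a map with itself reproduces it exactly (RSS = 0);
translating any single map leaves the consensus unchanged; as one map's
weight grows its distances dominate; on small chromosomes the solution
equals a direct normal-equations solve to 1e-8 cM. All four are asserted
in tests.

**Known behaviour.** Merging many jittered maps under the order filter
*contracts* the consensus scale slightly (1–2% at marker spacings
comparable to the jitter): surviving constraints are conditioned on not
having inverted, and the kept member of a close inverted pair carries
conditioned extreme noise. This is a property of consensus mapping
generally, not of this implementation; downstream comparisons are
therefore made within the consensus frame (see Recovery).

## Confidence-interval recalculation

The 95% CI of a QTL position, in cM, is taken as

    CI = k(pop) / (N · R²)

with k = 530 for F2 and backcross populations, 163 for recombinant inbred
lines, and 287.30 for doubled haploids; N is the number of lines and R²
the fraction of phenotypic variance explained. These are the empirical
constants of the QTL-precision literature for dense-map interval mapping.
The DH constant is configurable: compendia disagree on its printing, and
287.30 is the value consistent in magnitude with the F2/RIL constants
(a constant five orders larger would imply CIs of thousands of cM).
Records lacking R² or N cannot be given a CI and are routed to the
unprojectable set with a reason — the recalculated CI is what the
meta-analysis consumes, so there is no useful degraded mode.

## Projection

A source-map position is transferred to the consensus through the
piecewise-linear map defined by the markers the two share: within an
interval, result = P_a + (pos − p_a)/(p_b − p_a) · (P_b − P_a). Outside
the shared span the nearest interval's scale is extended, and the result
is clamped to [0, chromosome length] with a warning flag. CI endpoints
(peak ± CI/2 on the source scale) are projected through the same map, so a
locally stretched consensus stretches the interval with it. To guarantee
a monotone transfer even if residual order conflicts survive between a
particular study map and the consensus, the anchor set is reduced to the
longest subsequence of shared markers whose consensus positions are
nondecreasing in source order. Projection is exact at shared markers and
order-preserving everywhere (property-tested).

## Meta-QTL detection

**Model.** On one chromosome, each projected QTL contributes an
observation x_i (its consensus peak) with known standard deviation
s_i = CI_i/3.92 (a 95% normal interval spans 3.92 sds). The positions are
modelled as

    x_i ~ Σ_{k=1..K} π_k · Normal(μ_k, s_i²)

— a mixture over K putative real loci in which only the component means
μ and the mixing weights π are free; the variances are data. EM
alternates responsibilities r_ik ∝ π_k φ(x_i; μ_k, s_i²) with
μ_k = Σ r_ik x_i/s_i² / Σ r_ik/s_i² and π_k = mean r_ik. Convergence:
relative log-likelihood change < 1e-6 or 500 iterations; 10 restarts
(first from quantile-spaced means, the rest jittered, seed default 17),
best likelihood kept. The log-likelihood is nondecreasing across
iterations (asserted in tests at every step); K = 1 reduces to the
precision-weighted mean in closed form and the EM path reproduces it to
1e-9.

**Model selection.** AIC = −2 lnL + 2(2K−1), the parameter count being K
means plus K−1 free weights. K runs from 1 to K_max (default 8 in the
pipeline; capped at n); ties prefer the smaller K. BIC/AICc variants
would be one-line additions; AIC is the selector used throughout.

**Measurement-error correction.** The claimed s_i describes mapping
precision on the source map, but a projected position also carries
map-transfer error: marker placement noise in the source map and in the
consensus. The consensus build estimates this per chromosome from its own
unweighted residuals — sd = sqrt(mean(r²)/2), each distance observation
having two noisy endpoints — and the pipeline adds it in quadrature to
every s_i before model selection. Without the correction, QTLs with very
narrow recalculated CIs (large N·R²) claim sub-0.3 cM precision that the
consensus coordinates cannot support, and AIC dutifully splits their
clusters: in the recovery experiment below the correct-K rate drops from
≈95% to ≈86%. The term is estimated from the data of each run, not set
by hand; `fit_mixture` itself accepts raw sds, so the correction is a
caller-level choice.

**Extraction.** QTLs are hard-assigned to their maximum-responsibility
component (the published tables imply hard counts); responsibilities are
retained for diagnostics. Empty components are dropped and reported.
Components become MQTLs numbered by ascending peak (MQTL<chr>.<rank>),
with 95% CI μ_k ± 1.96/√(Σ_i r_ik/s_i²) (pooled precision), the mean of
member R² as the summary effect (the maximum is reported alongside — the
literature rarely states which statistic its MQTL R² is, and the two
bracket the plausible readings), per-stress member counts, and the nearest
consensus markers on either side of the peak. Chromosomes are analysed
independently.

## Reporting

The distribution table counts projected QTLs per chromosome × stress with
MQTL counts in brackets; when built from pipeline objects each MQTL is
counted once under its modal member stress so the brackets partition the
MQTL set, matching the published layout. Effect-size tiers: mega iff
R² > 0.30, major iff 0.20 < R² ≤ 0.30 (read exclusively of mega),
ordinary otherwise; thresholds configurable. Candidate-gene lookup maps
an MQTL's CI endpoints from cM to bp by piecewise-linear interpolation
between marker anchors (nearest-interval extrapolation with a warning
outside the anchored span) and returns genes overlapping the closed bp
interval on either strand, boundary-inclusive.

Transcriptions of the published barley abiotic-stress summary tables
(chromosome × stress distribution, per-MQTL stress overlap, per-MQTL R²
and physical coordinates) ship as package data and load into the same
structures the pipeline produces; their margins (585 projected QTLs, 128
MQTLs, tier counts 3/8, memberships up to 38) are recomputed by the
reporting code, not stored as expected values. The published consensus
scale (2,124.43 cM, 0.25 cM mean spacing) and the original 1162 → 585
projection cannot be reproduced here — the 28 source maps and the
literature catalog were never deposited — so the pipeline's correctness
on those stages rests on the algebraic properties and the synthetic
recovery below. The physical (bp) coordinates in the transcription are
display data only.

## Synthetic data and recovery

The generator emulates the structure of the published corpus: 7
chromosomes of 150 cM with 120 markers each; 26 studies, each subsampling
70% of the master markers with Normal(0, 0.5²) cM positional jitter
(re-sorted, which also produces realistic inversions for the filter to
handle); population types mixed 60/20/10/10 DH/RIL/F2/BC with 72–317
lines; R² ~ U(0.03, 0.55) and LOD ~ U(2.5, 15); three planted MQTLs per
chromosome at ≥ 20 cM separation, ten member QTLs each, stress labels in
the proportions of the published 585-QTL margin. Each QTL's reported peak
scatters around its planted position with the sd implied by its own
recalculated CI (CI/3.92), capped at 5 cM: scatter and claimed precision
are the same quantity in a coherent recovery experiment, and the cap keeps
low-precision QTLs (tiny N·R²) from scattering across half a chromosome.
Everything derives from one integer seed; identical seeds give
byte-identical outputs.

What the generator does **not** emulate: genotype-level noise (no QTL
mapping is re-run), marker-name inconsistencies between studies,
systematically distorted maps, and literature curation errors. Passing
recovery therefore demonstrates that the consensus/projection/mixture
machinery is correct and calibrated under its own assumptions — not that
any particular literature compilation is.

**Recovery results** (asserted in the acceptance tests): over 100 seeds of
the default configuration, AIC selects the planted K on ≥ 90% of
chromosome runs (measured ≈ 95%) and the recovered peaks sit within 2 cM
RMSE of the planted positions (measured ≈ 0.4 cM), with MQTL memberships
partitioning the projected set in every run. The RMSE is computed in the
consensus frame: planted positions are transported through the master
map's own projection first, so the consensus contraction noted above —
an upstream coordinate-system property — is not charged to the mixture
model. The 100-seed sweep takes a few minutes on one core; the
acceptance script's descriptive recovery entries use 30 seeds.

## Numerical choices and degenerate inputs

- cM positions are double precision; order comparisons use a 1e-9 cM
  tolerance so text round-trips cannot flip marker order.
- Zero-length intervals (co-positioned markers) are collapsed before
  interpolation; chains shorter than two markers raise projection errors
  rather than guessing.
- All positions identical with K > 1: EM returns duplicate means, flagged
  degenerate; selection still works (the AIC penalty picks K = 1).
- Mixing weights are floored at 1e-12 during EM to keep logs finite;
  empty components surface at extraction, not as NaNs.
- Rejected catalog rows are never dropped silently: every rejection and
  every unprojectable record carries a reason string.

## Limitations

- The consensus builder is a least-squares composite mapper, not a
  likelihood-based remapping from genotype data; it cannot correct a map
  that is internally wrong, only reconcile scales.
- The known-variance mixture inherits the CI formula's assumptions; if a
  study's reported R² is inflated, its QTL is overweighted.
- AIC is the only selector wired in; on very small chromosomes (n < 10)
  it can be liberal, and the per-chromosome independence assumption
  ignores cross-chromosome information by design.
- The 48-of-65 vs 37-experiments curation step of the original
  compilation is not modelled; curation is the user's input.
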