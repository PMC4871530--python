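# Methods

## Scope and data model

`otunet` consumes a rarefied samples-by-OTUs count table (every sample sums
to a common depth) with per-sample group and tank labels, and optionally a
Greengenes lineage per OTU. All statistics operate on rarefied counts, not
relative abundances: equal depth makes count means and rank tests
comparable across samples, which is the convention the whole battery
assumes. Sequence-level processing (OTU picking, taxonomy assignment) is
out of scope; the table is the interface.

## Filtering

An OTU is kept iff (a) its maximum per-sample relative abundance is at
least `max_rel_abund_threshold` (default 0.001) and (b) it is non-zero in
at least `ceil(min_prevalence · n_samples)` samples (default 0.10, i.e. 5
of 45). The two cuts are applied jointly as a single AND filter; a removal
log records which cut removed each OTU. The prevalence rule is a ceiling by
design — "about 10% of samples" has no exact integer reading, so the count
is also directly configurable. Rarefaction draws an exact uniform subsample
without replacement (multivariate hypergeometric), so the expected
per-OTU count is depth·Nᵢ/N and row sums are exact.

## Diversity

* **Shannon entropy** uses natural log by default (the convention of the
  classical ecology toolkits); the base is configurable.
* **Rarefied richness** uses the closed form
  E(S) = Σᵢ [1 − C(N−Nᵢ, d)/C(N, d)] evaluated via `gammaln` so large
  binomials stay finite; default depth 5,000 against tables rarefied to
  10,000.
* **Bray–Curtis** is Σ|x−y|/Σ(x+y); symmetric, zero-diagonal, bounded by 1.
  It is not a metric — the triangle inequality is neither assumed nor
  asserted anywhere.
* **NMDS** minimizes Kruskal stress-1 with SMACOF iterations under isotonic
  regression, k = 2, 20 restarts initialized from classical (Torgerson)
  scaling plus 5% Gaussian jitter (restart 0 unjittered), convergence at
  stress change < 1e-6 or 500 iterations. The best-stress restart wins; all
  restart stresses are reported.
* **Permutation tests.** ANOSIM R = (r̄_between − r̄_within)/(M/2) on
  tie-averaged ranks of the dissimilarities; PERMANOVA is the one-factor
  pseudo-F with SS_total = Σ_{i<j} d²ᵢⱼ/N and per-group within sums;
  envfit's factor r² is 1 − SS_within-centroid/SS_total over the
  ordination scores. All three use unrestricted label shuffles (fish are
  the units; tank structure is deliberately ignored, matching the
  cross-sectional design) and the (1+b)/(1+nperm) p estimator, which can
  never return 0 and counts the identity permutation as one tie. Defaults
  are 5,000 permutations (10,000 for envfit). Every test is deterministic
  under its seed; permutation nulls are evaluated with vectorized einsum
  contractions in chunks, which is what makes the 1,000-simulation
  calibration tests affordable.
* **Dispersion**: all within-group pairwise dissimilarities per group,
  compared with the same Kruskal–Wallis / Holm–Mann–Whitney battery used
  for univariate responses.

## Differential abundance and the susceptibility rubric

Per feature: tie-corrected Kruskal–Wallis across groups; Storey q-values
across all features tested together; features passing the gate
(q < 0.2 and p < 0.05) get pairwise two-sided Mann–Whitney tests for every
group pair with Holm correction within the feature. Direction is read from
group medians (mean tiebreak). Fold change adds 0.01 to every count first
and divides each experimental sample by the normalizing group's mean, so
all-zero features give exactly 1.

Storey's π₀ is estimated on the λ-grid 0.05…0.95 with a cubic smoother
evaluated at λ = 0.95; below 100 tests the smoother is unstable, so π₀
falls back to 1 and the q-values reduce to Benjamini–Hochberg. q-values are
computed separately per taxonomic rank (OTU vs each phylotype level): the
rank collapses are not independent tests of distinct hypotheses families,
and pooling them would couple their FDR estimates.

The rubric, applied to gated features: *susceptible-persistent* = significant
decrease vs the reference in both exposure contrasts; *susceptible-resilient*
= significant decrease only in the late contrast; *resistant-bloom* =
significant increase in either; *resistant-stable* = omnibus p > 0.05 with
mean abundance > 100 counts; otherwise unclassified. Calls are evaluated in
that order and are mutually exclusive.

## Indicator species

IndVal: A_ij = (mean abundance of OTU i in class j) / (summed class means),
B_ij = occurrence fraction in class j, IV = A·B, reported class = argmax.
Significance permutes class labels over samples and compares the permuted
max-class IV to the observed one, (1+b)/(1+nperm) with nperm ≥ 999.
Selection keeps IV ≥ 0.4, p ≤ 0.05, q ≤ 0.2. The exposure analysis pools
the two exposed groups into one class against unexposed by default; the
pooling map is an argument. IndVal runs on rarefied counts (configurable),
since equal depth makes count means comparable.

## Networks

Per group: midrank Spearman ρ for every OTU pair, with two-sided p from the
t = ρ√((n−2)/(1−ρ²)) approximation on n−2 df. At n = 15 with the heavy
tying of rarefied counts, exact permutation nulls per pair are impractical;
the t approximation is the main source of divergence anyone should expect
when replicating published edge counts from deposited data. q-values are
computed within each group's correlation matrix separately — each network
stands alone. Edges require |ρ| ≥ 0.5, p ≤ 0.05 and q ≤ 0.2; self and
duplicate pairs are trimmed; OTUs without a surviving edge are not
vertices (published vertex counts below the filtered-OTU count are only
consistent with that convention).

Topology: degree; Brandes betweenness normalized by (n−1)(n−2)/2 (the
~10⁻⁵ magnitudes in published summaries are only consistent with the
normalized convention on sparse graphs); Clauset–Newman–Moore greedy
modularity on the unweighted, sign-stripped graph (modularity is undefined
with negative weights), with deterministic ordering of the output.
Comparison: two-sided Fisher's exact test on the 2×2 positive/negative
edge table (Holm across the three group pairs), Mann–Whitney on per-vertex
degree and betweenness (vertices treated as independent observations, as
published comparisons implicitly do), and shared-vertex Venn counts.

## The synthetic generator

Per sample s and OTU i the latent log-abundance is

    log λ_si = log a_i + log m_{g(s),i} + t_{tank(s),i} + Σ_k L_ik f_ks + ε_si

with baseline a_i = exp(−0.04·rank) over 200 OTUs (a geometric rank-
abundance decay that spans ~360 expected counts down to fractions of a
count, so the prevalence/abundance filters remove a realistic tail);
archetype multipliers m (persistent ×0.25 in both exposed groups,
resilient ×0.25 late only, bloom ×4 early, stable ×1 at high baseline);
tank effects t ~ N(0, 0.2²) shared by the five fish of a tank; one latent
factor per planted pair; and log-normal noise ε ~ N(0, 0.5²), the model's
overdispersion. Counts are multinomial at depth 10,000 given the
normalized λ, so every sample sums exactly to the depth, as a rarefied
table would. The default design is 3 groups × 3 tanks × 5 fish, 10 OTUs
per responsive archetype and 16 stable OTUs placed at the most abundant
ranks (the rubric's >100-count requirement is a property of the layout,
not a tuned constant).

**Planted correlations.** 15 positive and 10 negative pairs each get a
private standard-normal factor; a pair's members load with ±L and carry a
small idiosyncratic noise (sd 0.1) instead of the background σ = 0.5, so
the pair correlation is L²/(L² + 0.1² + 0.2²), set to 0.95 by default.
That strength is a power-analysis consequence of the edge filter, not a
free choice: with ~7,000 pairs per group entering the q ≤ 0.2 screen at
n = 15, an edge needs p ≈ 10⁻⁴, i.e. observed |ρ| ≳ 0.8, while the
sampling sd of Spearman's ρ at n = 15 is ≈ 0.29 on the Fisher-z scale.
Pairs planted near 0.85 straddle the detection boundary and recovery is
erratic; pairs planted at 0.95 with tight coupling sit safely above it.
Ecologically this models strongly co-varying taxa (shared niche or
cross-feeding partners whose abundances move together over orders of
magnitude), which is the regime in which count-based co-occurrence edges
are detectable at all at this sample size.

**What the generator does not emulate:** compositional closure beyond the
multinomial (no strict negative-correlation bias — with 200 OTUs each a
small fraction of the total, closure effects are negligible); phylogenetic
signal; sequencing/chimera noise; zero-inflation beyond what log-normal ×
multinomial produces. Passing recovery tests on this generator shows the
statistics and thresholds behave as intended on data with the study's
shape; it does not certify performance on real tables, where compositional
effects and unmodeled covariates can matter.

A known consequence of the tank term: fish within a tank are
pseudo-replicates, so with tank_sd > 0 the per-OTU Kruskal–Wallis test
across groups is mildly anticonservative (~12% rejections at the 5% level
under the group-null at tank_sd = 0.2). Calibration tests therefore use a
tank-free null design; the default design keeps the tank term because the
real study has it, and its permutation tests likewise shuffle fish
without tank restriction.

## Problem sizes in the test suite

Unit and property tests run on small constructed examples, the default
45 × 200 study (session-shared), and a reduced 60-OTU study for
end-to-end checks. Calibration suites use 1,000 null simulations at 499
permutations for the three beta-diversity tests, 200 random graphs (≤ 12
vertices) against a shortest-path-enumeration betweenness oracle, and
10,000-replicate Monte-Carlo checks of the rarefaction closed form. These
sizes give stable pass/fail behavior (3-SE bands for Monte-Carlo
comparisons) at a few minutes of total runtime.

## Known limitations

- Compositional differential-abundance methods (CLR/ALDEx2/ANCOM-style)
  are deliberately absent; the battery is the classical rank-test one.
- Spearman p-values use the t approximation (see above); exact nulls for
  tied small-n data are not implemented.
- No stratified/blocked permutations by tank, and no phylogenetic
  diversity (no tree in the data model).
- `envfit` covers a single factor (the group), not continuous vectors.
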