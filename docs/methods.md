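# Methods

This note records the statistical models, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that make runs reproducible.

## Bilateral asymmetry

For a bilateral measure with right and left values R, L > 0 (mm):

* %DA = (R − L) / ((R + L)/2) × 100 — signed; positive means right larger.
* %AA = |R − L| / ((R + L)/2) × 100 — per specimen, %AA = |%DA| identically.

Whether a measure is asymmetric at all is screened by OLS of R on L; the
measure is flagged when |slope − 1| > k·SE(slope) with k = 1 by default.
The ±1 SE band is a deliberately liberal screen, not a hypothesis test:
under perfect symmetry it flags ≈ 32 % of measures (P(|t| > 1)), which
errs on the side of *not* substituting one side for the other.  `k` is a
parameter (`se_multiplier`); k = 2 gives a conventional ≈ 95 % band.  On
exactly collinear data the residual SE is 0 and the slope is recovered
exactly.

Regional differences in per-specimen %DA (signed) and %AA are tested as
two separate families with two-sample t-tests — pooled-variance Student's
form by default, Welch optional — under a Bonferroni threshold α/m.  The
family size m defaults to the nine bilateral measures and is always an
explicit parameter, never inferred from however many p-values happen to be
passed.  Signed %DA is used (rather than |%DA|) because the regional means
being compared are reported signed.

## Standardization and group comparison

Raw skeletal measures confound region with age and sex.  Every comparison
measure is divided by a within-specimen reference: cranial (mastoid) width
CW for the 12 skull/tusk measures, mandible width MW for the 4 mandible
measures.  These two references are the defaults because, among the
candidates, they track age and sex most strongly; `rank_standardizers`
reproduces that choice on data with known age/sex by ranking candidates on
the R² of measure ~ age + sex (ordinary least squares, sex as an M
indicator).  Bilateral measures contribute the side with more data (ties
go left).  The standardizers themselves are excluded from the ratio
matrix.

Each dimensionless ratio is compared between two regions with the
following selection rule at α = 0.05, applied per measure with pairwise
deletion: if both groups pass Shapiro–Wilk normality *and* a two-sided F
variance-ratio test, use a Welch two-sample t-test; otherwise use the
Wilcoxon rank-sum test (implemented as the two-sided Mann–Whitney U, which
is what R's `wilcox.test` computes).  Pairing the Welch statistic with the
equal-variance branch looks inverted — Welch's correction exists for the
unequal-variance case — but this is the documented selection rule of the
original analysis and is preserved as-is; the practical consequence is
only a slightly conservative t-test in the branch where variances are
equal anyway.  Degenerate zero-variance samples are routed to the
rank-sum branch.

## DAPC and the isolation metric

Complete cases (per analysis block — skull, tusk, mandible — not across
all 16 measures, which would waste specimens) are decomposed by PCA.
Correlation scaling is the default because the ratios differ in magnitude
by an order (tusk-length ratios ≈ 2 vs thickness ratios ≈ 0.16);
covariance scaling is available.  Signs follow a fixed convention (the
largest-magnitude loading of each component is positive), eigenvalues are
non-increasing, and scores reconstruct the scaled centered matrix to
machine precision.

The leading components — by default the smallest set explaining ≥ 90 % of
variance, configurable including "all" — feed a canonical discriminant
analysis: generalized eigenvectors of S_b v = λ S_w v, at most
(groups − 1) axes.  Groups below a minimum size (default 2 for the bare
operation; the pipeline uses 5, so that a 1–4 specimen group is projected
onto the axes but never drives scatter estimation or isolation claims).

Isolation of a group pair is assessed on the first two discriminant axes
(one axis when only two groups enter): the groups are *isolated* iff their
convex hulls (intervals in 1D) do not intersect, and the overlap measure
is the intersection area (length in 1D).  This is a strict criterion —
one extreme specimen on either side breaks it.  Under the default
generator conditions (10 % ratio shift, CV 5 %, 60 specimens per group)
the skull-block separation on LD1 is ≈ 5 within-group SD while the extreme
points of two 60-draw samples span ≈ 2.3 SD each, so strict disjointness
is achieved in roughly 80 % of seeded runs (the acceptance output's
`dapc_isolation_rate_shift` computes this rate); a coverage-based
criterion such as 2/3-coverage circles would report isolation essentially
always at that separation.  Under a null with no group effect the rate is
0.  The strict hull rule is kept because it is conservative and has an
unambiguous geometric meaning.

## Haplotype collapsing and diversity

Analysed sites are the alignment columns in which *every* sequence carries
an unambiguous A/C/G/T (complete deletion of gaps, Ns and IUPAC
ambiguity); optional truncation to a leading window is applied first, which
can merge haplotypes that differ only beyond the window.  Sequences
identical on the analysed sites merge; haplotype ids are
`<region-of-first-occurrence><ordinal>`, deterministic in input order.

With region counts c_i (n = Σc_i, p_i = c_i/n):

* h = n(1 − Σp_i²)/(n − 1), with Nei's sampling variance
  V(h) = 2/(n(n−1)) · {2(n−2)[Σp_i³ − (Σp_i²)²] + Σp_i² − (Σp_i²)²}.
* k_within = frequency-weighted mean Hamming mismatch count over all
  C(n,2) sample pairs; k_between averages over the n_A × n_B cross pairs
  (self-pairs never enter the within mean, so duplicating a region gives
  k_between = k_within · (n−1)/n).
* π = k_within / L_analysed, equivalently n/(n−1) Σ_{i≠j} x_i x_j π_ij;
  its variance uses Nei's no-recombination sampling formula
  V(π) = (n+1)π/(3(n−1)L) + 2(n²+n+3)π²/(9n(n−1)).

π · L_analysed = k_within holds exactly by construction, and the analysed
site count is always reported so that a π/k pair can be reconciled to the
effective sequence length that produced it.  The parenthetical values
reported alongside h and π are the square roots of these sampling
variances.  Distances are raw mismatch counts on A/C/G/T only — no
transition/transversion weighting, matching the network stage.

## Median-joining network

Construction (deterministic throughout):

1. **MSN_ε.** From the Hamming matrix, single-linkage join thresholds
   σ(u,v) are computed with a union–find sweep over pair distances in
   ascending (distance, index) order; the ε-relaxed minimum spanning
   network keeps every pair with d(u,v) ≤ σ(u,v) + ε.  ε = 0 yields
   exactly the union of all minimum spanning trees.
2. **Median vectors.** Triples of nodes with at least two of their three
   pairs linked in the current MSN are scanned in lexicographic id order.
   Each triple proposes its quasi-medians: site-wise majority state, with
   all combinations where a site shows three states (capped at 1,000
   candidates; exceeding the cap is an error rather than a silent
   truncation).  A candidate is accepted iff it strictly reduces the
   minimum spanning cost of the current node set (Prim's algorithm on the
   Hamming graph); scanning restarts after every acceptance, so the
   result is a fixpoint independent of hash order.  Total spanning cost is
   therefore non-increasing by construction.
3. **Pruning.** Medians whose removal leaves the minimum spanning cost
   unchanged are deleted (rescanning after each deletion); survivors are
   relabelled mv1…mvk.  Links are then re-derived as the MSN_ε over the
   surviving node set, and every edge records its weight (= recomputed
   Hamming distance) and the 1-based analysed-site positions that mutate.

ε defaults to 0, the common practice with this construction; larger ε
admits more parallel paths and more median candidates.  The
maximum-parsimony post-processing step some implementations offer is
deliberately not included.  The canonical three-sequence example
{AAA, TTA, TAT} (pairwise distance 2) yields exactly one median vector
TAA with three weight-1 edges, reducing the spanning cost from 4 to 3.

## Synthetic data

**Morphometrics.** Standardizers follow a linear allometry
a + b·age + c·(sex = M) + N(0, sd) (defaults: CW = 150 + 4·age + 25·M ± 5
mm over ages 2–26, MW = 110 + 3·age + 20·M ± 4 mm); every comparison
measure is region-ratio × standardizer × (1 + ε) with ε ~ N(0, CV),
CV = 5 % by default; bilateral right sides are left × (1 + DA/100) ×
(1 + ε).  Note the %DA statistic of a pair generated at DA = 10 centers on
200(ρ−1)/(ρ+1) ≈ 9.52, not 10.0, because the denominator is the bilateral
mean.  Defaults encode the study-shaped conditions: MAR ratios 10 % above
ATL across the board, strong (10 %) directional asymmetry on the two tusk
lengths and slight (0.5 %) elsewhere, no missingness unless requested.
Entries can be deleted missing-at-random.  The generator does not emulate
measurement-device granularity, observer effects, correlated missingness
(whole broken elements), or age-structure differences between regions —
so recovery tests demonstrate estimator correctness under the stated
model, not robustness to those real-data features.

**Sequences.** One uniform-random ancestral sequence (default 344 bp);
each region's haplotype pool holds variants carrying a fixed number of
mutations (default 2) at *globally distinct* sites drawn from a shared
permutation — no recurrent or back mutation, so all pairwise distances are
sums of private mutation counts and the ground-truth h and π are exactly
computable.  Regions therefore share no haplotypes unless
`share_ancestral` places the ancestor in every pool.  Sample counts are a
multinomial draw over Dirichlet weights (concentration per region;
defaults 0.2 for the skewed 8-haplotype MAR-like pool of 28 samples, 0.5
for the 28-haplotype ATL-like pool of 88), so rare pool haplotypes may go
unobserved.  The truth record retains weights, realized counts and
sequences; `truth_summary` reports both population targets (h_pop = 1 −
Σq², π_pop from the weight-weighted distance matrix) and realized-sample
statistics by direct enumeration.  Not emulated: recurrent mutation,
indels/alignment error, sequencing error or ancient-DNA damage, and any
within-region geographic structure.

## Numerical conventions and degenerate inputs

* All simulation randomness flows through an explicit integer seed
  (`numpy.random.default_rng`); no global state.  Identical inputs and
  configuration produce byte-identical result files.
* Two identical samples compare as t = 0, p = 1 rather than NaN; zero
  spanning variance routes univariate tests to the rank-sum branch.
* PCA requires ≥ 3 complete cases and ≥ 2 columns and refuses
  zero-variance columns; DFA reports a singular within-group scatter as an
  instruction to retain fewer components.
* Isolation falls back from 2D hulls to axis-1 intervals when a group has
  fewer than 3 points; hulls of collinear points degenerate gracefully to
  segments (overlap measured as length).
* Results tables are written at 6 significant digits; round-tripping a
  dataset through CSV preserves values to that precision.

## Known limitations

* Haplotype diversity's small-sample floor: with one dominant haplotype
  and s singletons among n samples, h cannot fall below
  n/(n−1)·(1 − ((n−s)² + s)/n²); printed literature values just below
  that floor for their stated n and haplotype count cannot be reproduced
  by any frequency tally (see the partition-enumeration acceptance test).
* The univariate selection rule inherits the Welch-in-the-equal-variance
  branch quirk described above.
* Median-vector search is exponential in principle (quasi-median
  combinations, triple rescans); the cap plus star-like real haplotype
  clouds keep it fast, but adversarial unrelated sequences can hit the
  candidate cap by design.
* No phylogenetic model (no likelihood, no rate heterogeneity): distances
  are raw mismatches, appropriate for closely related control-region
  haplotypes only.
* No classification cross-validation for DAPC; the isolation metric
  describes the training scores themselves.
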