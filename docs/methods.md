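# Methods

This note records the statistical conventions the package implements,
the defaults chosen where the field's practice varies, and what the
synthetic-data generator does and does not emulate.

## Pollution indices

CF = C_total / C_background per metal; PLI is the geometric mean of
the CFs of the four assessed metals (Cd, Cu, Pb, Zn), computed as
`exp(mean(log CF))` for numerical stability and undefined at CF ≤ 0.
CF uses total (not DTPA-extractable) concentrations — the printed PLI
values of the fixture survey are consistent with totals. Backgrounds
for Cd (0.11 mg/kg) and Pb (20.78 mg/kg) are the reported regional
values; Cu (22.3) and Zn (62.6) are not published for the region and
ship as synthetic constants back-solved from the two fixture rows
whose printed PLI reconciles exactly with the printed concentrations
(YX_1 and YX_8); both are overridable in the backgrounds table. The
Cd risk screen is strict (`>` the screening value); above pH 6.5, the
GB 15618-2018 band for paddy soil is outside the fixture's range, so
the threshold is configuration-supplied (default 0.6 mg/kg) and the
result is flagged as extrapolated.

## Diversity

Shannon entropy is reported in bits (log base 2, the QIIME 1.9
convention); Chao1 is the bias-corrected form, ACE uses the standard
rare-abundance cutoff of 10, Good's coverage is 1 − F1/N. Counts are
used as loaded — no rarefaction — with per-sample depth logged.
Bray–Curtis is computed on raw counts. NMDS minimises Kruskal
stress-1 by monotone regression (scikit-learn's non-metric MDS on the
precomputed distance matrix), starting from the classical (Torgerson)
configuration plus seeded random restarts (default 20) and keeping
the best-stress solution; the classical start matters, as random
initialisation alone is unreliable on low-dimensional configurations.
Axis signs are arbitrary; NMDS1 is canonicalised so its correlation
with the rank of sample read depth is non-negative. Downstream uses
only enter through R², so the choice is cosmetic.

## Association statistics

Mantel tests correlate the upper triangles of two distance matrices
(Spearman by default) and permute the rows and columns of the second
matrix jointly; the one-tailed p-value is
(1 + #{r_perm ≥ r_obs}) / (B + 1) with B = 999 by default. The
partial Mantel statistic is the first-order partial correlation
r_AB·C = (r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²)), recomputed under
the same permutation scheme; controlling for B itself is treated as
the removable 0/0 case and returns 0. Environmental distance is
Euclidean on z-scored variables, community distance Bray–Curtis.

Variation partitioning Hellinger-transforms the community matrix,
computes redundancy-analysis R² for each predictor block and their
union, applies the Ezekiel adjustment (1 − (1−R²)(n−1)/(n−p−1)), and
reports unique/shared/residual fractions; the combined block may be
collinear (its effective rank is used as p), but each individual
block must be full rank. The fractions match `vegan::varpart` to
1e-6 on test fixtures.

Random-forest importance fits a regression forest (500 trees,
mtry = ⌈p/3⌉) and permutes each predictor within each tree's
out-of-bag samples; `importance` is the mean MSE increase as a
percentage of the mean out-of-bag MSE (for ranking, as in importance
bar plots), and `raw_increase` keeps the unnormalised increase, which
is the quantity comparable across models. The Spearman grid reports
rho, raw p (t-approximation) and Benjamini–Hochberg adjusted p across
the whole grid; the correction choice is conservative and raw p is
always kept alongside.

## Network construction

OTUs present in fewer than ⌈0.9 n⌉ samples are removed. Pearson
correlation is computed on log10 relative abundances after filling
zeros with half the smallest nonzero relative abundance (recorded in
the scan metadata; `transform="none"` disables it).

The RMT threshold scan walks candidate cutoffs (default 0.30–0.99,
step 0.01). At each cutoff the correlation matrix is thresholded, rows
without surviving off-diagonal entries are dropped, and the remaining
eigenvalues are unfolded: near-duplicate eigenvalues (gap < 1e-8) are
removed and the cumulative spectral function is smoothed with a
10-knot cubic spline so spacings have unit mean. The nearest-neighbour
spacing distribution is histogrammed on [0, 3] with bin width 0.1 plus
an overflow bin, and compared by Pearson chi-square against the
Poisson density exp(−d) and the Wigner surmise (πd/2)exp(−πd²/4),
pooling adjacent bins until each expected count reaches 5 (Cochran's
rule — without pooling, near-empty tail bins dominate the statistic on
the ~10²-eigenvalue spectra typical at high cutoffs). The selected St
is the smallest candidate where the Poisson chi-square both beats the
GOE chi-square and falls below the 0.95 chi-square critical value for
the pooled bins, sustained for two consecutive candidates. The scan
errors out ("no RMT transition") if the retained submatrix shrinks
below 10 nodes first.

Edges carry |r| as weight and the correlation sign; isolated nodes
are dropped. Topology: avgK = 2E/N; GD averages shortest paths within
components (finite on disconnected graphs); avgCC counts degree-< 2
nodes as zero; the power-law R² is OLS on log10 frequency vs log10
degree. Modules come from Clauset–Newman–Moore greedy modularity
maximisation on the unweighted graph, labelled M1, M2, … by
decreasing size for determinism. The null ensemble performs 10·E
attempted double-edge swaps per replicate (rejecting self-loops and
multi-edges, so the degree sequence is conserved exactly) and records
GD, avgCC and Q per replicate; replicate metrics run on igraph's C
implementation of the same greedy agglomeration for speed, which
matches the networkx values to ~1e-3 — far below the ensemble spread.
Zi is the z-score of within-module degree among module mates (0 when
the module is degree-homogeneous); Pi = 1 − Σ_s (k_is/k_i)²; the
Guimerà–Amaral cutoffs 2.5 / 0.62 define the four roles. Per-module
environment tests restrict the community matrix to module members and
run the Spearman Mantel against each z-scored variable; modules under
5 OTUs are skipped.

## Synthetic data

The generator emulates the downstream product of a ~45-field, ~120k
reads/sample 16S survey with a pH-driven community: a truncated-normal
pH-like gradient g ~ N(5.4, 0.3) on [4.5, 6.5]; soil covariates (SOM,
CEC, TN, AN, AP, AK, texture) as increasing linear functions of g plus
noise; log-normal total metals with Cd mildly tied to acidity and
Beta-distributed DTPA fractions below totals. Per OTU, log-intensity
is baseline + β·z + λ·u_m + ε with z the standardised gradient, u_m a
per-module latent factor shared within each of the 8 planted modules
(sizes 20–100), λ the module loading (default 1.2; members draw
0.7–0.95 of it, the designated hub draws it fully), and ε ~ N(0, 0.5).
Planted modules 1 and 2 respond to the gradient (β = ±1); 30 % of
unplanted OTUs carry a diffuse β ~ N(0, 0.8) so the gradient — not the
module factors — dominates community-wide turnover, as in pH-driven
field data. Counts are multinomial over the softmax of intensities at
a uniform 110k–128k depth, so the data face the same compositional
coupling as real amplicon counts. Everything is deterministic given
the seed.

What passing tests show: the pipeline recovers planted module
structure, gradient associations and pollution arithmetic under
compositional, multinomial noise at realistic depth and sample size.
What they do not show: robustness to chimeras/sequencing error,
taxonomy misassignment, unequal library-size artefacts, or the much
larger OTU inventories (3.5–6k observed per sample) of real surveys —
the generator's 2000 taxa keep desk-scale runs tractable.

## Numerical and design choices

- Texture sums validate to 100 ± 0.5 (printed values are rounded).
- PLI's "square root" phrasing vs the displayed 1/n exponent: the 1/n
  geometric-mean form reproduces the printed PLI values and is used.
- Eigenvalue dedup tolerance 1e-8, spline knots 10, NNSD bin width
  0.1, the two-candidate stability rule, and Zi/Pi cutoffs 2.5/0.62
  are fixed constants, logged with scan output.
- Stage seeds derive from the master seed by fixed offsets
  (diversity +101, association +202, network +303) so stages can be
  rerun independently.
- Acceptance-scale problem sizes: the planted-recovery check runs the
  generator defaults (45 × 2000, strong loading λ = 1.5, σ = 0.3) with
  a 100-replicate null ensemble; calibration checks use 2000 Mantel
  replicates (n = 20, 99 permutations) and 1000 regression replicates.

## Known limitations

- The RMT scan needs enough retained eigenvalues (≥ ~50 nodes) for a
  stable spacing histogram; smaller matrices warn.
- Greedy modularity has the usual resolution limit; very small planted
  modules inside a large graph may merge.
- Partial Mantel p-values use the simple permute-B scheme; residual
  permutation variants are not implemented.
- The Cd screen above pH 6.5 extrapolates beyond the fixture's range
  and is flagged rather than authoritative.
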