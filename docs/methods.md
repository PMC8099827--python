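# Methods

This note records the statistical models `colocpipe` implements, the choices
made where more than one reasonable design existed, and what the synthetic
experiments do and do not demonstrate.

## Synthetic two-trait GWAS data

**Haplotype panel.** Haplotypes are generated from a Gaussian copula with
AR(1) latent correlation: variant *j* of a haplotype carries the alternative
allele when its latent standard normal falls below Φ⁻¹(f_j), with latent
autocorrelation `ld_rho` between adjacent variants and allele frequencies
f_j drawn uniformly from `maf_range` (default 0.05–0.5). One parameter thus
reproduces the monotone LD decay of a regional association plot, and the
implied allelic correlation has a closed form via the bivariate-normal
orthant probability, which the tests use as an independent oracle. Variants
sit on a 1-based grid with 2 kb spacing by default, so a 200-variant region
spans 0.4 Mb and exercises the 0.5 Mb windowing stage realistically.

**Cohorts.** Individuals are formed by drawing two panel haplotypes with
replacement. Disease status follows a population logistic model
logit P(case) = α + Σ β_k g_k, with α solved numerically (Brent's method) so
the population prevalence equals the configured baseline (default 0.1 per
trait). Case-control ascertainment is plain rejection sampling until the
requested case and control counts are filled, with a bounded draw budget so
an unreachable request fails fast instead of hanging. Rejection sampling
keeps the odds ratios interpretable as population ORs; the 0.1 default
prevalence keeps the case oversampling factor (≈1/prevalence) modest while
leaving log-OR estimates essentially unchanged relative to rarer diseases.
The two traits' cohorts are drawn on the *same* panel (shared LD) but from
independent individuals — the no-sample-overlap assumption of the
colocalisation model, and how two separately collected GWAS actually relate.

**What the generator does not emulate:** imputation dosage uncertainty,
relatedness, population structure and covariates, strand ambiguity beyond
the palindrome filter, X-chromosome inheritance, and genuine recombination
hotspot structure (AR(1) decay is smooth). Passing tests therefore certify
the statistical machinery under clean LD and perfect genotypes, not
robustness to cohort artefacts.

## Association scans and FDR

Single-variant effects are maximum-likelihood logistic regressions of
phenotype on dosage with an intercept, Wald standard errors and two-sided
p-values. Because dosages take only the values {0, 1, 2}, each variant's
likelihood depends on the data only through its 3×2 dosage-by-phenotype
table; the scan therefore runs a Newton iteration vectorised across
variants on those tables — the identical MLE a row-level fit produces
(pinned against statsmodels in the tests) at a small fraction of the cost,
which is what makes the 500-replicate null-calibration experiments
practical. Multi-covariate conditional fits aggregate the design to its
unique dosage patterns and run frequency-weighted IRLS. Monomorphic variants
and perfectly separated fits (|β̂| ≥ 15) are flagged, carry missing
estimates, and are excluded downstream.

FDR is Benjamini–Hochberg (via statsmodels) across *all* clean variants
supplied per trait — genome-wide scope, since region selection happens after
the FDR step. p-values are floored at the smallest positive double rather
than reported as 0.

**Harmonization** matches variants across traits by chromosome and
position, reconciling swapped and strand-flipped allele pairs by flipping
the sign of β and mirroring the frequency. Strand-ambiguous (A/T, C/G)
variants with alternative-allele frequency in [0.42, 0.58] in either trait
are removed — the conventional window inside which the strand cannot be
inferred from frequency. Irreconcilable allele pairs are dropped with a
logged reason.

## Region selection

Overlap variants are those with q strictly below the threshold (default
0.01) in both traits. Windowing is greedy: the overlap variant with the
smallest max(q1, q2) seeds a window of exactly `window_bp` (default 500 kb,
seed ± 250 kb), absorbing every overlap variant inside; the procedure
repeats on the remainder, and windows that overlap or abut are merged,
keeping the more significant seed. The result is independent of input order,
covers every overlap variant exactly once, and is clipped at position 1.
Internally coordinates are 1-based inclusive; BED output is 0-based
half-open (start−1, end), tested in both directions.

## Conditional signal dissection

Within each region, forward stepwise logistic regression adds the variant
with the smallest conditional Wald p while it is below `p_enter`. The entry
threshold defaults to 1e-5 — a conventional locus-wide bound, surfaced in
config and logs since reasonable analyses vary it. Candidates whose dosage
is correlated with the span of the current model at |r| > 0.99 are skipped
as collinear (logistic fits are unstable beyond that). The rank-r signal
conditions on the index variants of ranks 1..r−1 and carries the full
conditional region scan as its summary statistics.

The summary-statistic mode reproduces conditioning without individual-level
data from marginal z-scores plus a reference LD matrix R:
z_cond(j) = (z_j − R_{jC}R_{CC}⁻¹z_C)/√s_j with s_j the Schur complement,
se_cond = se_j/√s_j, and β_cond = z_cond·se_cond. This is the joint-fit
(partial-regression) convention, chosen so summary-mode β/se match what an
individual-level conditional fit reports; the conditional z-score — the
quantity that drives the Bayes factors — is identical under either the
joint-coefficient or conditional-score convention. A near-singular
conditioning block receives a logged ridge of 1e-6; records whose allele
frequency disagrees with the panel's by more than 0.2 are dropped.

Every trait-1 signal is then paired with every trait-2 signal in the region
(the full cross), so a secondary signal masked by a stronger primary one can
still be tested for sharing — the situation that motivates conditioning in
the first place.

## Colocalisation

Per-variant evidence is the Wakefield approximate Bayes factor with a
N(0, W²) effect prior, W = 0.2 on the log-OR scale for both case-control
traits (the standard binary-trait choice; configurable). Hypothesis sums
S0..S4 are evaluated entirely in log space with log-sum-exp; the H3 cross
term Σ_{i≠j}L₁(i)L₂(j) is grouped as Σ_i L₁(i)·(ΣL₂ excluding i) using
prefix/suffix exclusive log-sum-exp, which avoids the catastrophic
cancellation of the naive ΣL₁ΣL₂ − ΣL₁L₂ form when a single variant
dominates both traits (the brute-force comparison is exact to better than
1e-12 even at PP3 ≈ 1e-27). Priors default to p1 = p2 = 1e-4 and
p12 = 5e-6 — the conservative recommendation for a disease pair — and the
decision threshold is PP4 ≥ 0.9; both are flags, so the laxer
p12 = 1e-5 / threshold 0.5 convention is a configuration change, not code.
The two traits' records are intersected on variant id (no imputation of
missing variants), a documented sensitivity. Direction of effect is the
sign product of the two betas at the variant with the largest per-variant
H4 contribution, falling back to the designated index variant when that
variant lacks an estimate in one trait.

## Fine-mapping and CLPP

The secondary check models each trait's regional z-vector as
z | λ ~ N(Σλ, Σ) with the LD matrix Σ, each variant causal independently
with probability γ (default 0.01) and standardized causal effects
N(0, σ²), σ = 5. Enumerating configurations up to size c (default 2, with a
guard refusing more than 10⁷ configurations) gives posterior inclusion
probabilities; the Woodbury identity reduces each configuration's
multivariate-normal likelihood to |S|×|S| algebra, making the enumeration
exact and cheap (tests pin it to a direct full-covariance evaluation at
1e-10). The null configuration is included, so PIPs sum to 1 − P(null) for
c = 1. LD matrices are floored to positive definiteness at eigenvalue 1e-8
and re-symmetrized. CLPP(i) = PIP₁(i)·PIP₂(i); the regional CLPP is the sum
over variants, capped at 1 because with c ≥ 2 several variants can carry
high inclusion probability in both traits simultaneously. No CLPP decision
threshold is enforced — it corroborates the PP4 ranking.

## Pipeline and reporting

The orchestrator is deterministic given the scenario seed; every stage
failure aborts with the stage name and region id, and artifacts are written
atomically (staged in a temporary directory) so no partial outputs remain.
Results are reported from the perspective of trait 2's index variant with
respect to the ALT allele — trait 2 is the designated "large GWAS" — with
95% CIs exp(β ± 1.96·se), the r² between the two traits' index variants
from the panel, PP0–PP4, regional CLPP and the direction flag. The manifest
records parameters, seed, version and the region/signal-pair/colocalisation
counts, with the signal-pair count equal to Σ over regions of
(trait-1 signals × trait-2 signals).

## Validation experiments and problem sizes

The reference experiments (module `colocpipe.experiments`, exercised by the
test suite and by `scripts/acceptance.py`) use one canonical condition: a
200-variant AR(1) region (ρ = 0.9), 10,000 cases and 10,000 controls per
trait, and per-allele OR 1.3 at planted causal variants. Measured there:

* shared-causal replicates reach PP4 ≥ 0.9 in ≳80% of replicates and every
  detected discordant locus is labelled discordant;
* distinct-causal replicates (causal variants ~100 variants apart,
  realised r² < 0.05) give PP3 > PP4 in ≳95%;
* 500 null replicates produce no PP4 ≥ 0.9 false positive;
* with a primary trait-1 signal (OR 1.5) masking a shared secondary (OR
  1.3), the conditional secondary pair colocalises in ≳70% of replicates
  while the unconditioned primary pair rarely does;
* a five-locus genome (four discordant shared loci, one concordant,
  OR 1.4, loci 1.3 Mb apart) is recovered end-to-end: five regions, five
  signal pairs, ≥4 loci at PP4 ≥ 0.9, all directions correct.

Oracle comparisons use 300–1,000 random small regions (n ≤ 5 for the
colocalisation enumeration, n ≤ 12 and c ≤ 2 for fine-mapping, against
brute-force/direct-MVN implementations) and 1,000 random BH inputs. These
sizes make the whole validation run in a few minutes on one CPU while
keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* At most one causal variant per trait is assumed by the colocalisation
  enumeration itself; multiplicity is handled upstream by conditioning, so
  signals missed by the stepwise entry threshold are never tested.
* The summary-level conditional approximation inherits the usual COJO
  caveats: it degrades when the LD reference mismatches the GWAS cohort and
  near-collinear conditioning sets are ridge-stabilised rather than solved.
* Fine-mapping enumeration is exact but limited to small causal counts;
  stochastic search for large c is out of scope.
* Direction classification reads the sign at a single variant; for shared
  signals with PP4 barely above threshold and diffuse H4 mass it can rest
  on a variant with modest evidence.
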