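# Methods

## Scoring model

A reference profile is a signed rank vector over a gene universe of size
*N*: ranking is by descending |differential expression|, so the most
regulated probe holds |rank| = *N* and the least |rank| = 1; the sign is
the regulation direction relative to vehicle control. Ties in |value| are
broken by stable input order (the earlier probe receives the larger
|rank|) — a deterministic convention chosen for reproducibility; a zero
differential value gets sign + and is logged, since its direction is
undefined.

For a signature of *m* probes with signs *sᵢ*, the per-profile connection
strength is

    c = Σᵢ rank(gᵢ)·sᵢ / c_max,   c_max = Σ_{j=0}^{m−1} (N − j),

so c ∈ [−1, 1] with |c| = 1 exactly when the signature genes occupy the
top-*m* ranks with fully concordant (or fully anti-concordant) signs. The
set-level **setscore** is the arithmetic mean of *c* over the set's
profiles. Because the score is linear in the ranks, a set is fully
summarised by its per-probe mean signed-rank vector; scoring uses that
vector throughout. A mean (rather than a √SetSize-scaled sum) keeps the
setscore on the same [−1, 1] scale for all set sizes and shrinks
naturally for large heterogeneous sets; the alternative scaling is a
documented open question of the scoring framework this reconstructs, and
every internal test targets the definition above.

## Null model and p-values

The empirical null draws random signatures: *m* distinct genes uniformly
without replacement, each with an independent ±1 sign (an unsigned mode
exists but is non-default). P-values are two-sided on |setscore|. In
Monte-Carlo mode p = (b + 1)/(K + 1) with b the number of null scores at
or above the observed one — never exactly 0, and uniform on its grid
under the null. Exhaustive mode enumerates all C(N, m)·2^m signatures
(capped at 2·10⁶ enumerated signatures) and uses the exact proportion
with no pseudocount. The default K = 100,000 resolves p-values well below
1/n_sets for databases up to ~1000 sets; tests and the acceptance script
use K = 20,000 against 100–200 sets, which already resolves 1/200 with
two orders of magnitude to spare.

Within one database query a single pool of K null signatures is scored
against every reference set. Each set still has its own null setscore
distribution (its own mean-rank vector); sharing the draws only
correlates the *estimates* across sets and leaves each p-value unbiased,
while cutting the cost of a 200-set query to about a second. The
single-set `null_distribution` path draws independently and is the one
checked against exhaustive enumeration.

Significance is declared when p falls strictly below 1/n_sets (unless
overridden), so one false connection per queried signature is expected
by construction; this calibration is verified empirically in the
acceptance suite (mean 1.0 ± 0.3 over 100 random signatures at 200 sets).

## Signature construction

Per-probe two-sample t-tests compare case against control log2
intensities. Welch's unequal-variance test is the default (the safer
assumption when group variances are not known to match); pooled-variance
and paired variants are options. A probe constant in both groups is
assigned p = 1. The significant list is sized by the expected number of
false positives: with G probes, the p-threshold is t = enfp_cut / G and
probes with p ≤ t are retained, so the expected false-positive count at
the boundary equals the cut. Two further filters follow: a probe is kept
when its mean log2 intensity reaches `min_log2` (default 6) in *either*
group — only probes dim in both groups are dropped — and when
|log2 ratio| exceeds `min_abs_log2_ratio` (default 1) strictly. The
signature is the top-k survivors by ascending p-value, signed by the
direction of the mean difference. No cross-array normalisation is
applied; inputs are taken as-is, and users who want normalised data
normalise upstream.

## Perturbation analysis

A length-*m* signature yields *m* leave-one-out variants; the original
plus the variants (TabNo = m + 1) are each queried with an independently
derived sub-seed (base seed + signature index — nulls must be redrawn
anyway since the null depends on signature length). Per compound, SS
counts significant connections among the TabNo queries, *including* the
original's; PS = SS/TabNo, so PS lies on the lattice {k/(m+1)} and PS = 1
requires the original and every perturbation to connect significantly.
The reported setscore (SetNo) is always the original signature's. The
default reporting scope is `any_significant` (a record for any compound
significant in at least one query); `original_significant` restricts to
compounds whose original connection is significant. Ranking filters by
connection direction, minimum PS and minimum SetSize, then sorts by PS,
SetSize, |setscore| and finally compound name — a deterministic total
order; PS is displayed rounded to 4 decimals.

## Synthetic data

The generators are pure functions of (parameters, seed). A null database
is i.i.d. uniform signed-rank permutations. A planted compound's profiles
are built by convex blending: a "perfect" pattern (target gene j at
signed value ±(N − j), concordant signs for a mimicking plant,
anti-concordant for an inverse one; remaining magnitudes randomly
assigned) is mixed with an independent random pattern at weight
`strength` and re-ranked, which guarantees a valid signed-rank
permutation at every strength, with strength 1 forcing setscore ±1
against the matching signature and strength 0 reducing to the null.
Expression matrices are Gaussian log2 intensities (default baseline 7,
σ = 0.5) with a ±`effect_log2` mean shift on the planted probes in the
case group; defaults (1000 probes, 40 planted, effect 2, 20+20 samples)
emulate a bright two-group microarray comparison at desk scale. The
statistical pipeline consumes only means and variances, so Gaussianity
exercises every code path; what these simulations do *not* model is
probe-level correlation, batch effects, heavy-tailed intensity noise, or
a real compound catalogue — passing tests demonstrate correctness and
calibration of the method, not field performance on any particular
microarray dataset.

## Problem sizes and numerical choices

The acceptance suite runs the calibration at 200 sets × 2 profiles ×
1000 genes with 100 signatures (about two minutes); planted-recovery
uses 20 seeds at 100 sets, signature length 10, 400 genes, K = 20,000;
Monte-Carlo/exhaustive agreement covers every universe ≤ 8 and signature
length ≤ 3 at K = 50,000 within three binomial standard errors. The
single-gene-dependency fixture uses 20 profiles per set so that one
top-ranked concordant gene out of a 2-gene signature is decisive for
significance while its removal is not — the method's headline behaviour
exercised end to end.

## Known limitations

- The exact algebraic form of the original framework's set-level score
  and p-value procedure is not restated in the sources this package
  reconstructs; the definitions above are the package's own, stated in
  full so results are reproducible against *them*.
- Empirical p-values are bounded below by 1/(K+1); databases with very
  many sets need K raised accordingly.
- Leave-one-out only; no leave-k-out, no bootstrap variance of the
  setscore, and no automatic choice of signature length.
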