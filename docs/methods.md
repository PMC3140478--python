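# Methods

This note documents the models, defaults and numerical choices behind
`vervetnet`, what the synthetic generator does and does not emulate, and
the known limitations.

## Data model

The unit of replication is the **sampling period**, one calendar day by
default (all days carrying records are indexed in date order). Presence
is tracked per individual-day: an individual is *available* on a day iff
it appears in at least one record that day. All dyadic statistics
condition on joint availability: `d_ij` counts the days both members of a
dyad were available, and every permutation null respects it.

Bout segmentation collapses a time-sorted observation stream into maximal
runs of identical (behaviour, actor, recipient): a gap of **5 seconds or
more**, a behaviour change, or a partner exchange starts a new bout
(the threshold is closed at 5 s — a gap of exactly 5 s splits). Bouts
carry their start time only; all downstream statistics use bout
*frequencies*, never durations.

Proximity association requires a nearest-neighbour scan within
`max_nn_m = 10` m with both individuals beyond `min_feeder_m = 10` m of
the feeders (to keep artificial food from inflating spatial association);
agonistic records feeding the dominance hierarchy are restricted to
`max_feeder_agonism_m = 5` m of the feeders, where contests over access
actually happen. All three radii are config keys. Nearest-neighbour
links are scored either-direction (A naming B suffices); a mutual-only
variant would only discard information at these sample sizes.

## Social differentiation

With `α̂_ij = x_ij / d_ij` (the per-period layer binarised first, so the
index lives in [0, 1] even for count data), the estimator is

    ᾱ    = Σ d_ij α̂_ij / Σ d_ij
    S²   = max(0, Var_w[α̂] − mean_ij[ α̂_ij (1 − α̂_ij) / d_ij ]) / ᾱ²

i.e. the d-weighted variance of the observed indices minus the average
estimated binomial sampling variance, scaled by the squared weighted
mean. Truncation at zero makes S = 0 attainable (and slightly biases
small-S estimates upward, visible in the recovery tests). Only the
moment estimator is provided; a likelihood-based variant is out of scope
for v1. Interpretation bands: < 0.3 homogeneous, 0.3–0.5 intermediate,
0.5–2.0 well differentiated, > 2.0 extreme.

Bootstrap SEs resample sampling days (columns) with replacement —
days, not dyads, are the approximately independent unit — recomputing the
statistic per replicate; replicates where it is undefined are dropped,
and more than 50 % undefined aborts with advice to collect more data.

## Permutation nulls

**Preferred/avoided association.** Per sampling day, the identities of
the individuals present that day are permuted (a random bijection on the
present set); the day's event structure — who-with-whom slots, number of
individuals involved, totals — is untouched. Absent individuals never
enter a permuted day. With exchangeable groups supplied (the small and
large cooperation classes), identities permute only within their class,
preserving the matching-market structure; this is required for validity
on cooperation data, where small–small or large–large events cannot
occur by design. Two statistics are tracked over dyads with d > 0: the
mean dyadic value (index or count) and the SD of dyadic values. Note
that for *count* values the mean over defined dyads is invariant under
relabelling (totals are conserved), so the headline p is the SD test —
concentration of events on preferred partners inflates the spread. All
p-values use (1 + #extreme)/(n_perm + 1), flooring at 1/(n_perm + 1) so
"p ≤ 0.001" is expressible at 10,000 permutations.

Measured behaviour (also recomputed by `scripts/acceptance.py`): under
its own null (uniform partner mixing) the SD test's p is uniform and the
0.05 rejection rate sits at ≈ 0.05; two planted exclusive partnerships
carrying 90 % of events are detected at the permutation floor
essentially always at 20 sessions.

**Mantel tests.** Z = Σ A_ij·B_ij over unmasked off-diagonal cells; MCC
is the Pearson correlation over the same cells. The null permutes B's
individual labels simultaneously for rows and columns, within
exchangeable classes when given — under class-preserving permutations
the between-class mask is invariant, so it never needs recomputing. The
default tail is one-sided "greater" (similarity predicts interaction), so
p near 1 reads as an opposite-direction tendency. The sampled p agrees
with exhaustive enumeration of all label permutations to within Monte
Carlo error (checked on 5×5 problems, and against scikit-bio's Mantel on
the unconstrained route).

**Partial Mantel.** Both matrices are residualised by OLS (with
intercept) on the vectorised control matrices over unmasked cells —
deterministic Smouse-style residuals, not residuals-of-null-permutations
— then the constrained-permutation machinery runs on the residual
matrices. Controls that absorb all of B's variation (e.g. a control
equal to B) raise a degenerate-matrix error.

**Attribute encodings.** Sex and age: same-class indicator. Rank:
1 − |DS_i − DS_j| / max|ΔDS| (rescaled to [0, 1]). Relatedness: the
coefficient as given. These are the minimal monotone choices and are
config-exposed. Individuals whose relatedness coefficients are entirely
missing are *dropped* from relatedness rows (shrinking the reported class
sizes) rather than imputed — with label permutations, dyad-level holes
would break exchangeability, and pedigree imputation is out of scope.

## Dominance and structure

**David's Score** uses raw win proportions P_ij = w_ij/n_ij by default
(dyads with no encounters contribute zero); the Dij correction
P_ij − (P_ij − 0.5)/(n_ij + 1) is available by flag. Raw DS sums to zero
over the scored set — an algebraic identity used as a standing
invariant. Scores are reported at full precision; integer rounding is
display-only. Adding an individual with no interactions can reshuffle
ties; the ordering is not guaranteed stable under that operation.

**Ward clustering** embeds each individual as its row profile of the rate
matrix (undefined cells as 0) and runs Ward's minimum-variance
agglomeration on Euclidean profile distances — the geometry Ward's
objective assumes. Heights are the within-cluster sum-of-squares
increments (scipy's merge distance h maps to an increment of h²/2);
they are non-decreasing, so the tree has no inversions. A direct
distance-input mode exists for matrices that already are distances, with
the usual caveat about non-Euclidean inputs. The merge sequence and the
cophenetic matrix are both verified against per-step exhaustive oracles.
The cophenetic coefficient is the Pearson correlation between cophenetic
and input distances; 1.0 is attained exactly on two-level ultrametric
input, and ≥ 0.8 is flagged as a good fit.

**Modularity.** Weighted Newman modularity with node strength in place
of degree. The study groups are small (7–19 individuals), so networks of
up to 8 nodes are solved *exactly* by enumerating all set partitions
(Bell(8) = 4140); larger networks use leading-eigenvector bipartitioning
with Kernighan–Lin single-node refinement, applied recursively while a
split improves Q. Ties between equal-Q partitions break toward the
lexicographically smallest canonical label vector, making results
deterministic and relabelling-invariant.

## Synthetic generator

The generator emulates one study group under the feeder experiment; its
defaults are the study-like conditions used throughout the tests.

| parameter | default | rationale |
|---|---|---|
| `n_individuals` | 12 | groups of 7–19 individuals excluding infants |
| `n_small_class` | 2 | the experimental design (one male + one female, one adult + one juvenile, one high- + one low-ranking, at the rank extremes) |
| `n_periods` | 25 | 13–51 daily sessions per group and condition |
| `presence_prob` | 0.9 | mean individuals identified per day sits somewhat below group size |
| `scans_per_period` | 48 | 10-minute scans over an 8-hour observation day |
| `events_per_period` | 30 | daily all-occurrence cooperation record counts of order 20–40 |
| `true_assoc_mean` | 0.2 | dyads together on a minority of joint days |
| `true_assoc_cv` | 0.5 | a moderately differentiated baseline society |
| rank scores | n−1 … 0 | steep despotic hierarchy: adjacent-rank contests settle ≈ 73:27 (logistic with unit spacing), giving decisive agonistic data of the kind cercopithecine groups produce |
| `relatedness_noise_sd` | 0.05 | marker-based relatedness is an estimate, not pedigree truth; noise keeps the coefficients from being an exact linear function of the matriline/sibling indicators |

Latent association probabilities are Beta-distributed with the requested
mean and CV — the minimal two-parameter family on [0, 1] matching the
mean/CV parameterisation of differentiation; the feasibility bound
CV < √((1−μ)/μ) is enforced with a helpful error. Presence is i.i.d.
Bernoulli per individual-day. Cooperation partner choice follows
exp(−β·Δrank/range): monotone, single-parameter, uniform at β = 0;
planted exclusive partnerships with a fidelity parameter support power
studies. Agonistic outcomes are logistic in the rank gap. Matriline
membership is randomly assigned by default so kinship is independent of
rank (a rank-aligned variant exists to emulate matrilineal rank
inheritance); each matriline contains one designated full-sibling pair
(r = 0.5), other same-matriline dyads get r = 0.25.

What the generator does **not** emulate: spatial/home-range structure,
learning dynamics across sessions, observer error and inter-observer
disagreement, temporal autocorrelation of presence (an i.i.d. day is the
default; real presence is sticky), multi-partner cooperation events
(events are dyadic), and seasonal drift. Tests passing on this generator
therefore certify the *inference machinery* — calibration, power, oracle
agreement, determinism — not the field realism of any particular dataset.

## Determinism

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from the master seed and stage name (CRC-based, stable
across processes). Two runs with the same config produce byte-identical
`report.json`. The report embeds seed, permutation/bootstrap counts and
a config hash.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: differentiation recovery
at 15 individuals × 40 days × 50 seeds per CV level; permutation-test
calibration at 400–800 null simulations × 1,000 permutations and 100
power runs; Mantel enumeration agreement on 20 random 5×5 problems at
10,000 permutations; rank-assortment power over 100 pipeline runs at
10 individuals × 25 days; oracle equality on 20-instance batches for
David's Scores (6 individuals) and Ward/cophenetic (5–7 individuals); and
exact-modularity agreement on 6–8-node networks. These sizes give stable
Monte Carlo estimates while keeping a full run to well under a minute.

## Known limitations

- The moment estimator of S is biased upward near S = 0 (truncation) and
  slightly downward for very skewed association distributions at small
  dyad counts; the recovery tests quantify both.
- The preferred-association mean statistic is uninformative for count
  data (conserved totals); use the index statistic or rely on the SD test.
- Partial Mantel inference permutes residual matrices, inheriting the
  usual caveats of residual-permutation tests at small n.
- Ward on raw distance input is only exact for Euclidean-embeddable
  distances; the default profile embedding avoids the issue.
- The permutation engine reshuffles identities within days; the classic
  sequential checkerboard-swap null for group-membership matrices is not
  offered, because events here are dyadic (actor–recipient) rather than
  gambit-of-the-group records, and the swap scheme is defined on the
  latter.
- No temporal network analysis (lagged association rates), no Elo or
  Bayesian dominance models, no GUI, and no formal cross-group tests —
  groups are compared informally via SE bars, as in the study design the
  package mirrors.
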