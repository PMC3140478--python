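# vervetnet

Social-network inference for field experiments on **induced cooperation in
wild primate groups** — from raw behavioural event logs to
social-differentiation estimates, presence-constrained permutation tests of
preferred association, masked (partial) Mantel tests of partner-choice
drivers, David's Score dominance hierarchies, and Ward/modularity cluster
structure.

The package targets the analysis shape of experiments in which a group of
monkeys is split into a two-member "small" cooperation class and a larger
class, and food can only be accessed when members of *both* classes operate
joined feeders together — a matching market in which the small class forms
the short side. It is written for behavioural ecologists who want that
entire inference chain as tested, scriptable, reproducible code, and ships
a synthetic-data generator so every stage can be exercised (and its power
and type-I behaviour measured) without any field data.

## The statistics at the core

**Association index.** For dyad *(i, j)*, `α̂_ij = x_ij / d_ij`: the
proportion of sampling days the two were recorded together, out of the
days both were observable. Proximity associations come from scan-sampled
nearest neighbours within 10 m, with both individuals more than 10 m from
the feeders; affiliative and cooperation networks count behavioural bouts
(a bout ends after a gap of ≥ 5 s, a behaviour change, or a partner
exchange).

**Social differentiation** *S* estimates the coefficient of variation of
the *latent* dyadic association probabilities by removing binomial
sampling variance from the observed CV (method of moments):

    S² = max(0, Var_w[α̂] − E[α̂(1 − α̂)/d]) / ᾱ²

with d-weighted mean and variance. Rule of thumb: S < 0.3 homogeneous,
0.5–2.0 well differentiated, > 2.0 extremely differentiated. Standard
errors come from bootstrapping sampling days (10,000 replicates by
default).

**Preferred/avoided association test.** Identities are reshuffled *within
each sampling day*, only among the individuals actually present that day
("semi-random" permutations — an individual not found in the surroundings
never enters that day's permuted matrix), optionally only within
cooperation classes. The spread (SD) of dyadic values against its
permutation null detects concentration of events on few preferred
partners; p-values floor at 1/(n_perm + 1).

**Mantel Z-tests** correlate the cooperation (or feeding-proximity) matrix
with attribute-similarity matrices (same sex, same age class, rank
similarity from David's Scores, genetic relatedness), restricted by a
between-class mask to the market-relevant dyads, with class-constrained
label permutations. A partial variant residualises both matrices on
matriline and sibling indicator matrices before testing, asking whether
relatedness matters *beyond* the family structure the animals already
know. MCC is the Pearson correlation over unmasked cells.

**David's Score** turns directed agonistic win counts (recorded within
5 m of the feeders) into a cardinal dominance index,
`DS = w + w2 − l − l2`, which sums to zero over the group.

**Structure.** Ward-linkage dendrograms (heights are within-cluster
sum-of-squares increments) with cophenetic correlation as goodness of fit
(≥ 0.8 conventionally good), and community partitions maximising weighted
Newman modularity Q — exact enumeration for the small networks typical of
these experiments, leading-eigenvector bipartitioning with refinement
beyond that.

## Worked example

Simulate one study group — 10 individuals over 25 daily sessions, two
small-class members (top- and bottom-ranked), strong rank-assortative
partner choice (β = 20), three matrilines — and run the full pipeline:

```sh
vnet simulate --config sim.yaml --out demo --seed 42   # roster, events, matrices, truth.json
vnet run --config run.yaml --out demo_report           # report.json, table1.csv, table2.csv
```

`table1.csv` (per-condition differentiation ± bootstrap SE):

```
condition    individuals periods events  S       SE
proximity    10          25      160     0.4486  0.1091
affiliative  10          25      285     0.3854  0.0885
cooperation  10          25      750     2.6823  0.0965
```

Spatial proximity and affiliation are intermediate (S ≈ 0.4); forced
cooperation drives the group to extreme differentiation (S = 2.68): each
small-class member is served by a narrow set of partners.

The preferred-association test on the cooperation network confirms this:
the real SD of dyadic event counts is 62.8 against a permuted-null mean of
26.9 (p = 0.0001 at 10,000 permutations) — events concentrate on far fewer
dyads than presence alone predicts.

`table2.csv` (Mantel grid, between-class mask, class sizes 2/8):

```
identity                                   proximity_p  cooperation_p  cooperation_mcc
sex                                        0.073        0.359           0.061
age                                        0.531        0.726          -0.280
rank                                       0.843        0.0005          0.651
relatedness                                0.856        0.889          -0.312
relatedness | matriline + siblings         0.588        0.509          -0.008
```

Only the rank row is significant, and only under cooperation — partners
assort by dominance, not by sex, age or kinship, exactly the planted
ground truth (β = 20 on ranks, kin structure independent of rank). The
estimated David's Scores span +40 to −41, and the cooperation dendrogram
(cophenetic fit 0.95) splits into two modularity communities (Q = 0.49),
one around each small-class member; the looser foraging network does not
(Q = 0.05).

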