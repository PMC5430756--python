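# Methods

`isosex` implements the quantitative machinery behind neomale-cross
experiments and sex-chromosome transition mapping in terrestrial isopods
(Oniscidea). This note documents the models, the statistical decision
procedure, the simulation conditions, the numerical choices, and the known
limitations — everything a maintainer needs to judge what a passing test
does and does not demonstrate.

## 1. The Mendelian cross model

A genotype is an unordered pair over the alleles {X, Y, Z, W}; only XX, XY,
ZZ, ZW, WW and YY are constructible. Sex phenotype follows the genotype
(XX/ZW/WW female; XY/ZZ/YY male) unless an experimental reversal flag
overrides it: a *neomale* is a female genotype crossed as a male, and a
*Wolbachia*-feminized individual is a ZZ male genotype crossed as a female.
Crosses validate on phenotype (one functional male, one functional female)
and on allele system (X/Y cannot meet Z/W).

`cross` unites gametes with equal probabilities (exact rational arithmetic),
removes classes that are inviable under the viability configuration, and
renormalizes. The diagnostic predictions for a neomale x sister cross are:

| true system | WW viable | expected F1 males |
|---|---|---|
| ZW/ZZ | yes | 1/4 (ZZ; females are ZW + WW) |
| ZW/ZZ | no  | 1/3 (ZZ; females are ZW only) |
| XY/XX | —   | 0 (all offspring XX) |

YY viability defaults to viable; it never affects the neomale crosses above
(no YY offspring arise) but is configurable for other designs.

`wolbachia_progeny` models cytoplasmic sex determination after W loss: every
offspring is ZZ and develops female exactly when it inherits the endosymbiont
(one Bernoulli event per offspring at the maternal transmission rate, default
0.9). Titer dynamics and partial feminization are deliberately out of scope;
only the transmission rate matters to the sex ratio.

## 2. The heterogamety classifier

Input is a table of F1 broods (male/female counts plus the mother's
*Wolbachia* status). The pipeline is:

1. **Infection filter.** Broods from infected mothers are discarded —
   feminization mimics the ZW signal. Untested mothers are treated as
   negative by default (configurable), with a warning.
2. **1:1 filter.** Broods whose sex ratio does not differ from 1:1 at
   `alpha` (Pearson chi-square, 1 df, no continuity correction) are
   discarded: such crosses likely involved a mis-selected undifferentiated
   genetic male rather than a neomale.
3. **Homogeneity check.** A broods-by-sex independence test
   (df = #broods − 1) precedes pooling. Policy options:
   - `trim` (default): while the set is heterogeneous, drop the brood with
     the largest Pearson contribution (at most 1/4 of the broods, never
     below two) and flag it. Rationale: the realistic cause of
     heterogeneity in this design is a stray genetic-male brood that
     slipped past the 1:1 filter (which happens with probability ~alpha per
     contaminant brood); trimming the outlier recovers the species instead
     of abandoning it. With an intact brood set the trimming loop never
     fires at the nominal rate above alpha.
   - `block`: a heterogeneous set is never pooled (verdict UNDETERMINED).
   - `pool`: pool regardless, flagged.
4. **Decision tree** on the pooled counts, all at `alpha` = 0.05:
   significant male excess → UNDETERMINED (no heterogametic prediction
   produces it — the pattern seen in the all-male-brood species);
   zero-male compatible (exact binomial against a configurable male "leak"
   rate, default 0) with both ZW ratios rejected → XY; zero males without
   power to reject ZW → XY flagged `low_power`; otherwise ZW, with WW
   viability read from which ZW ratio survives (1/4 only → viable, 1/3 only
   → inviable, both → indeterminate, neither → UNDETERMINED).

The exact binomial test replaces the chi-square where the expected male
count is zero (the strict XY expectation), where Pearson's statistic is
undefined.

`viability_power` gives the Monte-Carlo power of the pooled test; at n = 30
the power to reject the 1/3 ratio when the truth is 1/4 is below 0.30, which
is why a 30-offspring species cannot settle WW viability.

### Known property: filter-induced selection bias

The 1:1 filter conditions every kept brood on rejecting balance. Small
broods pass only when extremely female-biased, so the pooled male fraction
of a true-1/4 species is biased downward (by a few points at mean brood
size 40 with realistic size dispersion). Consequence, measured by
simulation at the default conditions: in ~6–7% of ZW-viable campaigns both
ZW ratios end up rejected and the species is returned UNDETERMINED, versus
the ~2.5% nominal rate. Per-scenario recovery of the true *system* at the
defaults is ~1.00 (XY), ~0.97 (ZW, WW lethal) and ~0.93 (ZW, WW viable);
across an equal mix of the three scenarios recovery is ~0.96. Correcting
the pooled tests for the truncation would remove the bias but change the
plain-chi-square semantics the classifier intentionally retains; the bias
is documented rather than corrected.

## 3. Transition counting on the phylogeny

Tip states are {XY, ZW, OTHER, UNKNOWN} under two codings: `two_state`
(OTHER folds into UNKNOWN) and `three_state` (OTHER is a reachable third
state). UNKNOWN is missing data everywhere: zero parsimony cost, all-ones
partial likelihoods. All analyses assume W chromosomes are homologous across
species (likewise Y), so same-type turnovers are invisible and every count
is a floor.

**Parsimony.** Sankoff dynamic programming with unit costs, branch lengths
ignored. Direction breakdowns come from *exhaustive enumeration* of all
most-parsimonious internal labelings (children's optimal choices are
independent given the parent state, so the labelings enumerate by preorder
DFS over per-node argmin sets); an enumeration cap (default 10^6) guards
pathological inputs and flags truncation. ACCTRAN/DELTRAN-style resolution
rules are unnecessary at this scale because the enumeration is exact.

**Mk likelihood.** Felsenstein pruning with per-node rescaling; transition
probabilities by eigendecomposition of the symmetric rate matrix (exact for
ER/SYM). Branch lengths are in My, rates per My. The root prior defaults to
the uniform distribution, which is stationary for ER/SYM. Rates are fitted
by bounded search over log rate (golden-section for the single-rate case,
L-BFGS-B with a deterministic multistart ladder for SYM with k = 3); a
maximum at the lower bound (monomorphic data) is flagged. Log-rate bounds
are [ln 1e-8, ln 1e3].

**Ancestral marginals.** Standard up-down pass; each node's vector is the
normalized product of its below-partial and above-partial.

**Stochastic mapping.** Joint node states are sampled exactly (root from
prior x partials, then each child conditional on its parent), and each
branch's substitution history is sampled conditional on its endpoints by
*uniformization* (Poisson rate 1.05 x max leave rate; the jump count is
drawn from its exact endpoint-conditioned distribution, the bridging chain
states sequentially, and virtual self-jumps are not counted). Uniformization
was chosen over rejection sampling for bounded runtime on long branches with
discordant endpoints; means over maps are reproducible given a seed.

**Absolute rates.** Clade-wide silent rate = sum of per-branch dS divided by
sum of per-branch ages (years); global dN/dS = sum dN / sum dS. These
consume externally computed codon-model outputs; zero total dS with nonzero
dN is an error.

## 4. The packaged chronogram and state table

The 26-taxon tree encodes the text-anchored topology (see the fixtures
module docstring): Porcellionidae sister to Trachelipodidae; *Helleria
brevicornis* sister to all other Oniscidea; Philosciidae paraphyletic by
inclusion of *Oniscus asellus*; monophyletic Armadillidiidae; an
(*A. siculorum*, *A. assimile*) pair. Printed node ages (307, 117, 66, 38,
36, 35, 25, 15 My) are honored; all other internal ages are even
interpolations between the bracketing dated nodes and are marked as
approximate in the source. Within-genus order beyond the anchors is a
package choice; the parsimony targets are insensitive to it because the XY
tips inside the crown clade are terminal singletons. Outgroups carry
placeholder ages and are pruned before every reconstruction.

On this fixture: the two-state parsimony minimum is 3 (one XY→ZW at the
crown of the Armadillidiidae–Porcellionidae–Trachelipodidae–Oniscidae–
Philosciidae clade; ZW→XY in *A. nasatum* and in *P. d. dilatatus*), the
three-state minimum is 4 (adding the OTHER origin on the *A. assimile*
lineage). ML expected transition counts depend on the exact branch lengths,
which the interpolated fixture only approximates, so the test suite treats
them as a plausibility band (well above the parsimony floor, below an
order-of-magnitude cap, female→male exceeding male→female) rather than an
exact target.

## 5. The synthetic crossing campaign

`simulate_experiment` emulates the study design per species: injected young
females die with probability 60/135; survivors are mis-selected genetic
males with probability 25/135 (their broods are 1:1 — the contamination the
filter exists to catch); each surviving sire produces 2 broods; mothers are
infected at prevalence 5/43 and infected broods are female-biased at
transmission 0.9 regardless of sire; brood sizes are negative-binomial with
mean 40 and shape 8 (sd ≈ 15; the source experiments report only ranges,
and tens of offspring per brood is typical for these species); sex counts
are binomial around the Mendelian expectation. Defaults: 15 injected
females per species, giving a median pooled count of ~300–470 offspring
after filtering. All generators are bit-reproducible given (config, seed).

What the generator does *not* emulate: brood-size dependence on female
body size, embryonic mortality (none was observed in the source
experiments), within-female correlation across broods, partial *Wolbachia*
titers, or any mechanism for the all-male-brood phenotype. Recovery rates
measured on these simulations therefore speak to the statistical pipeline
under idealized binomial sampling, not to biological failure modes outside
the model.

`simulate_mk_history` is a Gillespie simulation of the Mk chain (root from
the prior, exponential waiting times per branch) returning the full event
history; it is the independent oracle for rate recovery and for the
stochastic-mapping expectation checks.

## 6. Problem sizes used by the test suite

Chosen to keep the default run fast while leaving no assertion starved:
likelihood-vs-enumeration on 5-tip trees (10 + 8 random draws),
Sankoff-vs-exhaustive on trees with up to ~11 internal nodes, rate recovery
as the median of 50 ER fits on simulated 100-tip trees (true rate 0.02/My),
classifier recovery over 200 simulated campaigns (cycling the three
scenarios equally), chi-square size from 10,000 null simulations at n = 500,
and 200–4,000 stochastic maps depending on the check. The full suite runs
in well under a minute on one core.

## 7. Limitations

* Same-heterogamety turnovers (e.g. W replacement by horizontal transfer)
  are invisible to both parsimony and Mk counts; every transition count is
  a lower bound.
* The fixture chronogram's interpolated ages make ML transition counts
  approximate; only parsimony counts are exact targets.
* The classifier's p-values ignore the 1:1 filter's truncation (see §2);
  verdicts near the decision boundaries inherit that bias.
* Hidden-rate and threshold models, polymorphic tips, and multi-locus or
  chromosome–autosome systems are out of scope.
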