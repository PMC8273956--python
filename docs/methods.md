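# Methods

## Model

A discrete Bayesian network *B = (G, θ)* over categorical variables: a DAG
*G* plus one conditional probability table (CPT) per node, the joint
factorising over families. All variables are finite categorical with at
least two levels; level order is declaration order (never lexicographic),
and parent-configuration rows are laid out row-major in the CPT's declared
parent order — this makes BIF/JSON round trips bit-stable. Missing data is
rejected by default; an explicit flag performs listwise deletion
(complete-case analysis, matching how such surveys are analysed).

## Conditional independence testing

`g2_test` computes the likelihood-ratio statistic
G² = 2·Σ O·ln(O·N_z / (N_xz·N_yz)) over the (x, y, z-stratum) contingency
cube, with 0·ln(·) = 0 and df = (|X|−1)(|Y|−1)·Π|Zᵢ|. Degrees of freedom
are *not* reduced for empty strata (documented choice; empty strata
contribute nothing to the statistic). Pearson's χ² is available behind a
flag. A test is *reliable* when n/df ≥ 5 — the classic adequacy heuristic —
and the learners treat unreliable tests as providing no evidence of
dependence (effective p = 1): high-order tests degrade gracefully instead
of producing noise-driven edges. Variables observed at a single level
likewise return independence flagged unreliable rather than raising, so a
learner run never dies on a degenerate column. Association strength for
ranking is −ln p, computed through the χ² log-survival function so extreme
dependence never collapses to a tie at p = 0. The significance level
defaults to α = 0.05 everywhere.

## Constraint phase

MMPC grows a candidate parents-and-children set with the max-min heuristic
(admit the candidate whose weakest association over conditioning subsets of
the current set is strongest; a candidate found independent given any
subset is dropped permanently) and then removes false positives backward.
The IAMB family grows a candidate Markov blanket by argmax association
given the current blanket and shrinks by conditional independence;
*inter* interleaves a full shrinking pass after every admission, *fast*
ranks candidates per pass and admits speculatively while the admission test
stays significant *and* reliable. Conditioning-set size during MMPC
subset search (and the spouse screen) is capped at 3 by default
(configurable, unbounded allowed): beyond that, the reliability heuristic
rejects most tests anyway and runtime explodes combinatorially.

Skeletons use the symmetric AND-rule (adjacency iff each node is in the
other's neighbourhood). For blanket-based learners a spouse-screening pass
follows: adjacency {X,Y} is severed if some subset of MB(X)\{Y} or
MB(Y)\{X} renders X and Y independent — blankets contain spouses, skeletons
must not.

## Score phase

BIC with the (r−1)·q penalty per family, decomposable and memoised per
(node, parent-set); zero-count cells contribute 0. Hill climbing applies
the best strictly improving add/delete/reverse move until none exists.
Tabu search applies the best legal non-tabu move *even when it worsens the
score*, keeps a FIFO list (default capacity 10) of canonical edge-set
fingerprints of visited structures, pardons a tabu move that strictly beats
the best score seen (aspiration), and stops after 15 consecutive
non-improving moves or 200 iterations. These defaults are the package's
own; nothing in the underlying method fixes them. Restricted searches only
*add* within skeleton adjacencies; delete and reverse are always legal.

Determinism: equally scoring moves are broken by the lexicographically
smallest (operation, parent, child) triple. Score-equivalent orientations
agree only to floating-point rounding (~1e−8 on log-likelihood sums of
magnitude 1e5), so deltas within an absolute tolerance of 1e−6 count as
ties; below that, the earlier move in the deterministic enumeration wins.
Fixed data therefore yields a byte-identical DAG.

Hill climbing is genuinely trapped on the bundled sprinkler network: from
the empty graph, after adding Cloudy→Rain, the collider orientation
WetGrass→Rain scores higher than Rain→WetGrass because it absorbs the
not-yet-modelled dependence through Sprinkler, and the search terminates in
a six-edge local optimum scoring below the true DAG (its terminal graph has
no improving move). Tabu search escapes this optimum and reaches the true
equivalence-class score on every tested seed — the concrete motivation for
the tabu hybrids.

## Benchmark networks and sampling

- `sprinkler4`: the canonical cloud/sprinkler/rain/wet-grass network,
  P(Cloudy=T)=0.5, Sprinkler|Cloudy = 0.1/0.5, Rain|Cloudy = 0.8/0.2,
  WetGrass|Sprinkler,Rain = 0.99/0.90/0.90/0.00. Small enough for
  closed-form oracles.
- `car20`: the 20-node / 22-edge car-diagnosis topology. The published
  figure fixes only the structure (the original tool's CPTs are
  proprietary), so the parameterisation is a declared surrogate: all
  variables binary {ok, bad}, roots P(ok)=0.8, non-roots
  P(ok | parents) = max(0.05, 0.95 − 0.60·b) with b the number of "bad"
  parents. Deterministic, portable, and strong enough for recovery
  experiments — but not a claim about the original network's parameters,
  so published benchmark *values* are not reproducible, only the
  qualitative behaviour (errors fall with n; the interleaved-IAMB tabu
  hybrid does not trail MMHC at large n) and the exact S(E) arithmetic.
- `lipid10`: 10 survey variables, 14 arcs. The hyperlipidemia CPT (24 rows
  over physical activity × gender × BMI class) is transcribed from the
  published table; the "no" column is taken as 100 − yes so every row
  normalises exactly. All other CPTs are surrogates chosen once:
  P(male) = 2236/4567; mild activity and BMI gradients; central obesity
  rising steeply with BMI class (0.02/0.20/0.55/0.97); hypertension and
  diabetes by the same noisy-threshold rule as `car20` with risk states
  {yes, ≥6g, ≥25g}. Under these surrogates the enumerated marginal
  P(hyperlipidemia = yes) is 0.45489 (frozen in the fixture notes), inside
  the plausible band around the published detection rate, and the
  sequential risk chain (central obesity → diabetes → BMI ≥ 28 →
  inactivity) is strictly increasing. BMI labels use half-open bins:
  "18.5~" = [18.5, 24), "24.0~" = [24, 28), "28.0~" = [28, ∞).

Sampling is ancestral with numpy's seeded PCG64 generator; replicated
designs derive per-dataset seeds as base_seed·10 000 + size_index·100 + rep
(public contract, so any cell can be regenerated in isolation).

## What the synthetic data does and does not show

The generator reproduces the factorised dependence structure, the published
outcome CPT, and realistic marginal rates. It does not emulate survey
design effects (stratified multi-stage sampling, weights), measurement
error, missingness, or the unpublished true CPTs of the non-outcome nodes.
Passing recovery tests therefore demonstrate correctness of the algorithms
under the stated generating model, not expected accuracy on the original
survey.

A structural consequence worth knowing: the outcome's Markov blanket in
`lipid10` spans all nine other variables (spouses enter through the
hypertension and diabetes colliders), so blanket-based learners condition
on very large sets and lose power for the two weakest parents (gender,
physical activity) at n = 20 000 even though the marginal signal is strong
— a known data-inefficiency of IAMB-type algorithms, visible here as
missing weak adjacencies rather than spurious ones.

## Parameter learning and inference

Maximum likelihood per family, optionally smoothed:
(count + s)/(total + s·r); s = 0 is the default (raw MLE, as used in the
application), s = 1 gives Laplace. Parent configurations never observed get
a uniform row and are flagged in a fit report. Inference is exact variable
elimination with min-degree ordering (correctness is order-independent);
evidence of probability zero raises a dedicated error. Sequential risk
reasoning reports the posterior after each cumulative evidence prefix,
starting from the prior.

## Epidemiology pipeline

Univariate Pearson chi-square screening (no continuity correction) with the
deliberately loose candidate rule p < 0.5; Cochran–Armitage trend test with
equally spaced scores; stepwise logistic regression with Rao score-test
entry at α_in = 0.05 and Wald removal at α_out = 0.10 (the SPSS-style
convention; likelihood-ratio stepping would be a straightforward variant),
coefficients from a plain ML refit of the final set. Covariates enter as a
single numeric code per variable in level order — one coefficient per
variable, matching how such regression tables are printed — not as one-hot
dummies (configurable in principle; documented choice here). Odds ratios
use OR = exp(β) with 95% Wald bounds exp(β ∓ 1.959964·SE); binomial
proportions get Wald intervals (Wilson behind a flag). The comparison
report classifies each covariate as *direct* (graph-adjacent to the
outcome), *indirect* (connected but not adjacent) or *unconnected* — the
distinction a regression coefficient cannot make.

## Problem sizes in the test suite

Oracle comparisons run at n ≤ 500 against brute-force contingency and
dense-joint-tensor computations; recovery experiments use n = 50 000
(sprinkler), n = 20 000 × 10 replicates (car20 benchmark, plus 10
replicates at n = 100 for the sample-size trend), and n = 200 000–500 000
for parameter-recovery spot checks. These sizes give comfortable
statistical margins for the asserted seed counts while keeping the full
suite in the low minutes on one CPU.

## Known limitations

- DAG-vs-DAG error counting is deliberately not equivalence-class aware:
  a Markov-equivalent reversal still counts 0.5, matching how the
  benchmark table tallies reversals (reversals persist even at large n).
- No continuous or hybrid variables; no approximate inference; no
  MAP/most-probable-explanation queries.
- The stepwise procedure inherits the usual caveats of stepwise selection
  (post-selection inference is not adjusted).
- `fit_mle` declares parents in sorted name order; CPTs are semantically
  identical to any other parent order but raw table rows only compare
  across networks after configuration-wise alignment.
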