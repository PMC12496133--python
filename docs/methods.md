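# Methods

This note records the model, the numerical choices, and the design
decisions behind `pathact`, together with what the synthetic cohorts do and
do not demonstrate.

## Ternary omic states

CNA focal scores discretize by sign, with exactly zero meaning normal;
missing scores stay missing. RNA expression (log scale) is compared to a
per-gene Gaussian reference estimated from normal-tissue samples by plain
sample moments (mean, SD with denominator n−1); no robust fitting or
trimming is applied. A tumor value strictly beyond mean ± k·SD (default
k = 2) is called activated/repressed; values exactly on the boundary are
normal. k = 2 is the default because the two-sided Gaussian tail beyond
2 SD (≈ 0.0455) sits just under the conventional 0.05 significance level.
Genes with fewer than two usable normals are unusable; genes with zero
reference variance are degenerate — both yield missing states rather than
calls, because a degenerate reference cannot support the tail test.

## Factor-graph model

Variables are ternary with domain {−1, 0, +1}. A protein whose gene
appears in the supplied omic matrices (whether or not a particular sample
has a value) owns *dna*, *rna* and *activity* variables; other entities
own a single *activity* variable. Wiring:

- dna is a vote-parent of rna; rna is a vote-parent of activity
  (central-dogma chain);
- transcript-level edges enter the target's rna variable (its activity
  variable when no rna layer exists); protein-level edges enter activity;
- `component` edges make a complex the **min** of its sign-adjusted
  members (all components needed); `member` edges make a family the
  **max** (any member suffices); a `membership_rules=False` switch falls
  back to vote everywhere. When a child receives mixed edge classes the
  rule precedence is component > member > regulatory.

A regulation factor assigns probability 1−ε to the child matching the
deterministic combination of its parents and ε/2 to each other state; an
observation factor assigns 1−η to agreement. Defaults ε = η = 0.1; both
are exposed and can be refined by cohort-shared EM (off by default).
Parentless unobserved variables get uniform priors; missing observations
contribute no factor. Self-regulation edges are dropped with a warning
(one variable cannot appear twice in a factor scope). Dense factor tables
bound the parent count at 9; the synthetic networks stay far below this,
and a genuinely high-degree hub would need a structured factor
implementation (a known limitation).

### Inference

Sum-product belief propagation with synchronous (flooding) updates,
normalized linear-domain messages, message tolerance 1e−9 and a sweep cap
of 1e4. On acyclic graphs damping is dropped and flooding converges to the
exact marginals (verified against a brute-force 3ⁿ enumeration oracle,
`exact_posteriors`, on all fixtures up to 12 variables); on cyclic graphs
messages are damped (0.5) and non-convergence is reported as a flag, not
an exception. Message normalization plus the ε/2 floor on factor entries
keeps linear-domain messages away from underflow, making a log-domain
implementation unnecessary. Cohort inference builds the network wiring
once and batches the per-sample observation potentials through the same
engine — bit-for-bit equivalent to per-sample graphs (tested), and one to
two orders of magnitude faster.

The IPL is log₁₀((p₊ + φ)/(p₋ + φ)) with floor φ = 1e−300 on the activity
marginal. Only the sign and null-relative magnitude are consumed
downstream, so the base is a labeled convention.

### EM

ε and η are shared across all edges of their class and across samples.
The E-step runs BP per graph; expected regulation mismatches come from
factor beliefs and expected observation mismatches from variable beliefs;
the M-step is the closed-form mismatch fraction (clipped to
[1e−6, 1−1e−6]). The log-likelihood is the Bethe free energy — exact on
acyclic graphs, where the regulation structure is a Bayes net and the
free energy equals log P(evidence) — and the stopping rule is a
likelihood change below 1e−9 or 1e4 iterations. Monotonicity is asserted
on acyclic fixtures only; on loopy graphs the Bethe estimate is an
approximation and the monotone guarantee does not transfer.

## Permutation null and filtering

The null asks what activity would be inferred if each patient's (CNA,
RNA) pairs were assigned to genes at random: pairs are shuffled uniformly
between all genes of the patient (pairs never split, missingness travels
with the pair; genes missing both layers stay in place as they carry no
information). Identity permutations are not rejected. Per-permutation
seeds derive from (master seed, CRC32 of the patient id, permutation
index) via `SeedSequence`, so any subset can be generated in any order or
in parallel with identical results.

The filter drops a real IPL when |IPL − median| ≤ k·MAD of its permuted
values (default k = 3; unscaled MAD; inclusive boundary, with a 1e−12
equality tolerance so the degenerate MAD = 0 case drops exactly-equal
values and keeps distinct ones). Among survivors, only the
maximum-cardinality connected component of the undirected skeleton (all
interaction types) is retained per patient; ties break to the
lexicographically smallest sorted name tuple for reproducibility. Pathway
state is the sign of the IPL inside the retained component and 0
elsewhere.

## Profiles, grouping, discovery, survival

The overrepresentation universe is the set of all protein entities in the
pathway network (the network defines the hypothesis space, independent of
which genes happened to be measured). The foreground is the universe
members with nonzero state. P-values are one-sided (upper tail) Fisher
exact tests computed as hypergeometric survival probabilities and
BH-adjusted across the collection per patient; profile entries are
−log₁₀(adjusted P) capped at 10 to keep clustering distances finite.
Patients are grouped by Ward/Euclidean hierarchical clustering of profile
columns with a user-chosen k (deterministic); an optional consensus mode
(resampled co-clustering frequencies, average-linkage cut) is available
behind a flag. Display terms for a group are the sets with adjusted
P < 0.05 in at least a fraction (default 0.9) of the group's patients;
lowering the fraction can only add terms.

Submodules are connected components of the skeleton restricted to
entities nonzero in every group patient, requiring ≥5 entities and ≥1
protein with omic observations; mixed signs across patients are allowed
for membership (a strict-sign mode exists behind a flag), while key
proteins additionally require one constant nonzero direction. Survival
stratification labels a patient "activated" only when every listed
protein has strictly positive IPL; the two strata are compared by the
standard two-group log-rank test (via lifelines, cross-checked against a
hand tabulation and a permutation Monte-Carlo null in the tests). Zero
events yield a flagged (0, P = 1) result rather than an exception.

## Synthetic cohorts: what they emulate and what they don't

The generator plants a coherent alteration: in a carrier fraction of
patients (default 50% of 20), the genes of one network module get RNA
shifted by δ·SD (default 3) and CNA focal scores of the planted sign with
probability 0.8; background noise supplies ~5% spurious CNA calls and the
~4.6% RNA tail everywhere. Normal RNA is Gaussian per gene; survival is
exponential with a carrier hazard ratio (default 0.4) under independent
uniform censoring. The omic matrices also contain decoy genes absent from
the network (default 120 against 25 network proteins), mirroring real
cohorts where the assay covers far more genes than the network: decoys
dilute where the within-patient shuffle deposits altered pairs, which is
what makes the permutation null informative at toy scale.

Network schemes: `chain`, `tree`, `one-loop`, `hub-modules` (hub→spokes
stars) and `complex-modules` (proteins joined pairwise into complexes
along a ring). The recovery studies use `complex-modules` deliberately:
under vote semantics a single altered upstream regulator wins the tie
against a normal-anchored target, so deep cascades and star hubs relay
background or permuted alterations — their nulls run hot and lone noise
hits masquerade as module activation. AND-logic complex modules require
every component altered, which both matches the receptor-complex biology
this kind of method highlights and gives the permutation null its
discriminating power; the ring closure keeps a module connected when one
protein is genuinely unaltered (~3% per protein per carrier). The
recovery study conditions are: 50-entity network (25 proteins in rings of
7), 20 patients, 50% carriers, δ = 3, 20 permutations per patient, two
groups, ten seeds.

Passing these studies shows the pipeline recovers a strong, coherent,
module-shaped signal against realistic background rates at desk scale. It
does **not** show performance on real tumor heterogeneity: no subclonal
structure, no segment-level CNA correlation, no RNA count noise, no
batch effects, and a network four orders of magnitude smaller than a
curated pan-cancer pathway file. Submodule recovery is reported at the
module-piece level (a reported submodule of ≥5 entities inside the
planted module with all proteins keyed in the planted direction): because
membership demands a nonzero state in *every* group patient, recovering
all planted proteins simultaneously in all carriers is a coin flip by
construction (0.968⁷⁰ ≈ 0.1), and that fragility is a property of the
method's definition, not of the implementation.

## Problem sizes in the validation suite

Enumeration-vs-BP agreement uses 100 random acyclic fixtures of up to 12
ternary variables (tolerance 1e−6). The Fisher oracle sweep is exhaustive
over universes N ≤ 60 (three representative k per margin pair) plus 2000
seeded random tables up to N = 200, against `scipy.stats.fisher_exact`
(tolerance 1e−10). Null calibration uses 200 hazard-ratio-1 survival
simulations (KS test against uniform) and 25 coin-flip patients × 40
random sets for the enrichment false-positive rate. These sizes keep the
whole validation under a couple of minutes on one CPU while pinning every
numerical claim the package makes.
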