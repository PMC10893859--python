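# Methods

## The meaning algebra

Meanings are flat conjunctions of signed atoms — the smallest algebra that
expresses the lexical glosses and the pragmatic derivation this package
models. There is no disjunction, quantification, or graded/probabilistic
meaning, and negation is one level deep (a literal is an atom or its
negation). The background ontology supplies:

* **entailment edges** between atoms (directed, acyclic);
* **definitions** — a defined atom abbreviates a conjunction
  (`SUBMISSION ⇔ FEAR ∧ AT_ADDRESSEE`). Making submission a *defined* atom
  lets the submission-lexicon system and the fear-lexicon system share one
  ontology: the former's meanings expand to the latter's vocabulary under
  closure;
* **exclusions** — mutually exclusive atom pairs. An exclusion may carry a
  *governing* atom, turning it into a disjunctive axiom: whenever `FEAR`
  holds, exactly one of `AT_ADDRESSEE` / `AT_EXTERNAL` should;
* **incompatibilities** — a signed literal that cannot co-occur with an
  atom (`¬HELP` with `AT_EXTERNAL`: were the threat external, help would be
  welcome).

**Closure** forward-chains positive commitments only: entailment edges and
defined→parts expansion, to a deterministic fixpoint (cycles are rejected
at ontology construction). Negated literals do **not** propagate
contrapositively; negative information interacts with the axioms only
through the consistency check. This is a genuine design choice — closure
could have been reflexive–transitive *and* contrapositive — made because
forward chaining keeps the fixpoint trivially decidable and because the
only negative inference the modelled derivation needs (¬help blocking the
external-threat reading) is exactly an incompatibility axiom. The
parts→defined direction of a definition is likewise not part of closure;
it surfaces as a *relabelling* step during resolution, so `entails` stays
a pure containment check over forward closures.

`entails` is containment of closed literal sets (a preorder), `consistent`
checks sign clashes, exclusions and incompatibilities on the closure, and
`residual(specific, general)` is the set difference of closures — the
surplus content that strengthening negates. All four are verified against
independent naive-scanning oracles by exhaustive enumeration over a
four-atom ontology (3⁴ = 81 meanings, all 6 561 ordered pairs).

## Semantic systems and degrees of freedom

A system is a lexicon plus a composition mode (`holistic` | `trivial`), an
enrichment mode (`none` | `informativity`) and the ontology. Holistic
interpretation is exact lookup of the whole signal form, with a hard
"unstipulated signal" error on a miss — holism has no fallback. Trivial
composition conjoins component meanings; the neutral face is modelled as a
real component with empty meaning (rather than an absence), which keeps
signal identity and the data cells unambiguous while contributing nothing
semantically.

Degrees of freedom count independent lexical stipulations against an
explicit *attested inventory* (what was observed, not what the lexicon
could cover): holistic systems need one per attested signal form, trivial
systems one per distinct non-neutral component. Two asymmetries are
deliberate and documented rather than smoothed over: faces never attested
in isolation add no holistic entry (there is nothing to stipulate a
meaning *for*), and the neutral face is excluded from the compositional
count because its empty meaning is a convention, not a free parameter.
With the default inventory (2 isolated gestures + 4 combinations) this
yields 6 vs 4; with g gestures and f faces fully crossed it is g + g·f vs
g + f, which is the parsimony argument in general form.

The packaged holistic preset stipulates combination meanings equal to the
glosses the compositional system derives. These are placeholders: a
holistic system is free to stipulate anything, which is precisely its
weakness, and the preset documents that freedom rather than hiding it.

## Pragmatic strengthening and resolution

Alternative sets are policy-driven. The default policy
(`same-face-gesture-swap`) takes attested signals sharing the target's
face and differing in gesture; a `uniform` policy (any attested one-
component swap) is selectable. Both policies make the isolated gestures
and the same-face combination pairs compete, so under the fear-lexicon
preset three signals are strengthened with `¬HELP` (isolated Stretched,
Stretched+Hoot, Stretched+Bared); only for Stretched+Bared does the added
negation go on to interact with the fear axioms. Whether informativity
*should* touch the first two is not settled by the data being modelled;
both policies are shipped so the question stays inspectable, and glosses
report positive commitments (negative content lives in the meaning and the
trace), matching the convention of the summary tables this package
reproduces.

Strengthening requires *strict* entailment by the competitor (synonyms
trigger nothing). With several stronger competitors, negations are applied
in sorted competitor order; a negation that would make the meaning
inconsistent is skipped and the skip is logged in the trace. This
skip-and-log rule is an implementation decision for a case the modelled
derivation never reaches.

Resolution handles governed disjunctions: if the governor is entailed and
neither disjunct present, the single consistent disjunct is added; if both
are consistent the meaning stays unresolved with an ambiguity logged
(context, e.g. "dominants are not usually afraid of their subordinates",
can be injected as extra premise literals — `¬AT_ADDRESSEE` steers the
same machinery to the external-threat reading). Resolution never removes
literals and never returns an inconsistent meaning.

Every derivation is a replayable trace — literal conjunction, competitor
comparison, strengthening, resolution, relabelling — exportable as text or
CSV rows.

## The synthetic generator

The generator emulates the *observed table*, not the animals: exactly
`cell_counts[(gesture, face, recipient_dominant)]` rows per cell, with the
binary response drawn from `logit(p) = logit(cell_prob) + Σ u_factor`,
Gaussian random intercepts per grouping factor (initiator, recipient,
dyad, group, year) on the log-odds scale. Defaults: 40 individuals in 4
groups over 2 years (a plausible sanctuary population for the record counts
emulated), all intercept SDs 0 — so cell probabilities are exact in
expectation — and all contexts positive (a configurable negative-context
fraction exists to exercise the filter). Dyads are unordered within-group
pairs with a strict rank order; each dyad is used in a single orientation,
so the recipient's dominance status is constant within a dyad.

Default cell parameters instantiate the published per-cell figures:
probabilities 0.50 / 0.22 / 0.11 / 0.75 for the four dominant-recipient
cells that have printed percentages, and counts that preserve the printed
totals (isolated-gesture counts 8/20 and 21/18 entered by initiator rank
and inverted to the recipient flag; the Bent+Hoot split 15+16 sums to the
printed 31; the dominant-signalled Bared split 4+6 sums to the printed 10;
cell sizes 9 and 12 make 1/9 ≈ 11% and 9/12 = 75% exact). Cells with no
published value are placeholders, flagged per cell in the config's
provenance map; the Hoot placeholders are chosen so the published
aggregate Hoot-vs-neutral contrast (57% → 25%) holds in expectation. Cell
values are primary: the overall dominance marginals (72%/29%) cannot be
fixed simultaneously with the printed cells and counts, and emerge only
approximately (~64%/~32% in expectation). Degenerate probabilities (0 or
1) with nonzero heterogeneity are clamped to [10⁻⁶, 1−10⁻⁶] before the
logit, with a warning.

What passing tests on these data do **not** show: the generator has no
production model (which signal an initiator chooses), no missingness
mechanism beyond blank fields injected by tests, balanced dyad usage
rather than the skewed exposure of real observation, and independence
across rows at SD = 0. Recovery results on synthetic tables therefore
validate the *pipeline*, not the field conclusions.

## Statistics

Filters (positive context; face, gesture, rank and response all encoded)
run before any summary, preserving order and reporting removals per
reason. Cell percentages are tallies; marginals aggregate counts, never
average percentages; rounding to integer percent happens only at the
reporting layer.

The inferential layer is deliberately a fixed-effects logistic regression
plus a cluster bootstrap, not a crossed random-effects GLMM: with a
handful of observations per dyad and individual, mixed models of these
tables routinely go singular, while whole-cluster percentile resampling
propagates within-cluster dependence without a variance-component fit. The
IRLS implementation is the package's own (deterministic; deviance
convergence at relative 10⁻¹⁰, 100-iteration cap) and is checked against a
reference GLM implementation to 10⁻⁶ in tests. Rank-deficient designs are
rejected with the aliased terms named (greedy rank scan). Separation is
detected as any fitted probability within 10⁻⁸ of 0/1 and reported as a
flag with `converged=False` — the maximum-likelihood estimate is on the
boundary and Wald inference there is not trustworthy; an optional ridge
term gives finite estimates on request but is off by default. p-values are
two-sided normal throughout. The cluster bootstrap requires ≥ 2 clusters
and is reproducible given a seed.

## Evaluation

The three directional observations are pure predicates over cell tallies,
with a minimum-n guard (default 5, reflecting how thin some cells are)
applied to every tally entering a comparison: a guarded comparison yields
"insufficient data", never a verdict. "Especially for Stretched" is
operationalized as gap(Stretched) ≥ gap(Bent) — no threshold is published,
and ≥ is the weakest reading that still distinguishes the gestures. The
Hoot observation aggregates over dominance by default (the published
contrast does); the claim machinery accepts any grouping, so a stratified
check is a one-liner.

The step from a *meaning* to a predicted response *direction* is the one
genuinely informal link in the argument being modelled, so it is shipped
as an explicit, ordered, user-editable rule table rather than buried in
code: each rule states the literals it requires/forbids, the dominance
flag it applies to, its predicted direction relative to the same-dominance
gesture-alone baseline, and its prose rationale. First match wins
(documented precedence, most specific first); no match predicts
"neutral"; every decision returns the rule id that made it. The scorecard
marks a claim "accounted" for a system when the claim holds in the data
*and* the directions predicted from the system's derived meanings agree
with it, and reports DF alongside — reproducing the qualitative
comparison (6 vs 4 vs 4, all claims accounted) while remaining falsifiable:
a variant lexicon with Bared = antagonism fails the interaction claim.

## Problem sizes and numerical conventions

Exhaustive semantic checks run over ≤ 4-atom ontologies (81 meanings);
conjunction laws are checked exhaustively over 3-atom pairs and
property-based over the 7-atom default ontology. Pipeline checks simulate
at 50× the default cell counts (7 650 rows), recover each cell within 3
binomial standard errors, and recover injected dominance gaps of
0.5/1.0/1.37 log-odds at 2 000 rows per arm within 3 standard errors.
Bootstrap examples use 200 replicates. All randomness flows through
explicit integer seeds; same seed, same bytes.

## Known limitations

* No probabilistic semantics: meanings are crisp conjunctions, and
  graded notions (signal ambiguity, noisy production) are out of scope.
* The pragmatic layer implements exactly one enrichment rule; there is no
  exhaustification beyond it and no iterated reasoning.
* The prediction rule table is a formalization of prose rationales; other
  defensible rule sets exist, which is why it is data, not code.
* Model comparison is DF + qualitative fit only — no likelihoods or
  information criteria, since the systems are not probabilistic models.
* The generator's placeholder cells are honest unknowns; analyses of
  placeholder-dominated contrasts test machinery, not biology.
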