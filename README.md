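# facegest

Chimpanzees combine manual gestures (a *Bent* or *Stretched* arm) with facial
expressions (*Hoot*, *Bared teeth*, or a neutral face), and recipients respond
affiliatively (approach, groom) or not (ignore, attack). Field data show a
puzzle: the same face shifts responses in opposite directions depending on
the gesture — Bared teeth make responses to Stretched *more* affiliative but
responses to Bent *less* so. Taken at face value this argues that
combination meanings are not derivable from component meanings (a *holistic*
semantics). `facegest` implements and compares the formal alternatives:

* **System 1 (holistic)** — every signal form, simple or complex, gets an
  independently stipulated meaning;
* **System 2 (trivial compositionality)** — a combination `[A B]` means
  `[A] ∧ [B]`, with `[Bared] = submission`;
* **System 3 (trivial compositionality + pragmatic strengthening)** — same
  composition rule with `[Bared] = fear`, enriched by the *Informativity
  Principle*: if `[A]` is entailed by a competitor `[B]`, then
  `[A]_prag = [A]_literal ∧ ¬([B]_literal − [A]_literal)`.

Under System 3, `Stretched+Bared` (literally *approach ∧ fear*) competes
with the more specific `Bent+Bared` (*approach ∧ help ∧ fear*), so it is
strengthened to *approach ∧ ¬help ∧ fear*; since fear-of-an-external-threat
is incompatible with declining help, the fear resolves to
fear-of-the-addressee — submission — deriving the puzzling interaction
instead of stipulating it. The systems are compared on *degrees of freedom*
(DF): independent lexical stipulations needed for the attested inventory
(holistic: 6; compositional: 4).

The package is aimed at researchers in animal communication and formal
semantics who want explicit, testable semantic systems for multimodal
signal data. It provides:

* a meaning algebra (conjunctions of signed atoms, entailment closure,
  consistency axioms, residuals) and declarative semantic-system specs
  (JSON) with packaged presets;
* auditable derivation traces (literal conjunction → competitor comparison
  → strengthening → fear resolution);
* a synthetic generator for dyadic observation tables with the study's cell
  structure (per-cell Bernoulli responses, optional random-intercept
  heterogeneity on the logit scale);
* the analysis layer: context/completeness filters, cell percentages,
  fixed-effects logistic fits (own IRLS, statsmodels-verified), odds
  conversions, cluster bootstrap;
* a scorecard checking which systems account for the three directional
  observations (A: dominance lowers affiliativeness, especially for
  Stretched; B: Hoot lowers it for both gestures; C: the Bared interaction).

## Worked example

```bash
$ facegest dof --system system1 --system system2 --system system3
system1: 6 DF
system2: 4 DF
system3: 4 DF
```

The holistic system needs six stipulations (two isolated gestures plus four
combinations; faces were never attested alone), the compositional systems
only four (one per component).

```bash
$ facegest trace --system system3 --gesture STRETCHED --face BARED
== system3: STRETCHED+BARED ==
1. [literal] -> Meaning(APPROACH ∧ FEAR)
   literal meaning of STRETCHED+BARED
2. [competition] -> Meaning(APPROACH ∧ FEAR)
   competitors: BENT+BARED; strictly stronger: BENT+BARED
3. [strengthen] -> Meaning(APPROACH ∧ FEAR ∧ ~HELP)
   negate surplus of BENT+BARED: not(Meaning(HELP))
4. [resolve] -> Meaning(APPROACH ∧ AT_ADDRESSEE ∧ FEAR ∧ ~HELP)
   FEAR is AT_ADDRESSEE or AT_EXTERNAL; AT_EXTERNAL is inconsistent here, so AT_ADDRESSEE holds
5. [relabel] -> Meaning(APPROACH ∧ AT_ADDRESSEE ∧ FEAR ∧ ~HELP)
   AT_ADDRESSEE ∧ FEAR reported as submission
final: Meaning(APPROACH ∧ AT_ADDRESSEE ∧ FEAR ∧ ~HELP)  gloss: approach+submission
```

Simulate a table at 50× the study's cell counts, analyze, and score:

```bash
$ facegest simulate --seed 1 --scale 50 --out obs.csv
7650 records -> obs.csv
$ facegest analyze --data obs.csv --out analysis --bootstrap 200
...
     term      beta       se          z             p
intercept  0.587044 0.036054  16.282354  1.317042e-59
 dominant -1.342954 0.048677 -27.589054 1.505654e-167
dominance odds multiplier: 3.8x (less likely to respond affiliatively)
dominant-recipient affiliative %: 32.0 [30.7, 33.2] (200 dyad resamples)
$ facegest evaluate --data obs.csv --out eval
...
observed C (...): holds
    Stretched: Bared 73.0% vs neutral 22.1%; Bent: Bared 11.6% vs neutral 51.1%
system1: 6 degrees of freedom
  ...
  C: accounted — predicted for dominant recipients: Stretched+Bared increase, Bent+Bared decrease
```

The dominance coefficient (β ≈ −1.34, i.e. dominants ≈ 3.8× less likely to
respond affiliatively on these synthetic data) recovers the generator's
built-in dominance gap; the per-cell percentages land on the configured
cell probabilities (e.g. Stretched+Bared to dominants ≈ 73% vs the 75%
parameter), and all three packaged systems account for observations A–C
while differing in parsimony.

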