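# Methods

This note documents the models and algorithms implemented in `regmcs`, the
conventions and constants that matter, and the boundaries of what the test
suite demonstrates.

## Flux model and task blocking

A metabolic model is held as a stoichiometric matrix `S` (m metabolites × n
reactions) with per-reaction bounds and optional GPR rules. Canonicalisation
splits every reversible reaction into a `_fwd`/`_rev` pair with mirrored
columns, so all fluxes satisfy `r ≥ 0`; results are reported on original
reaction ids. The knockout analysis treats the network as a **cone**: the
primal system is `r ≥ 0`, `S·r = 0`, `tᵀr ≥ r*` with no finite upper bounds,
so a task is either blocked (maximum flux 0) or feasible at any scale. LP
evaluations cap fluxes at `1e3` for numerical purposes and call a task
blocked when its maximum is below `1e-6`; with the unit-scale toy and random
networks used here the gap between "blocked" and "feasible" optima is many
orders of magnitude, so these two constants are uncritical.

Growth-medium application closes the upper bound of every uptake exchange
not in the medium list, then removes reactions whose bounds are fixed at
zero. Flux-variability pruning (additionally removing reactions that cannot
carry flux) is available behind a flag and off by default: bound-based
removal is the defining operation, FVA pruning a stricter optional variant.
Either way the maximal task flux is unchanged (asserted in tests).

## eGPR rules and their token networks

Regulatory layers extend GPR rules gene-wise: layer ℓ gives each
still-unregulated gene of layer ℓ−1 (layer 0 = metabolic genes) a Boolean
equation — an OR over its signed regulators, inhibitors entering as NOT
literals. Genes without an equation are **inputs** whose state is free.

Each reaction's rule system is compiled to an artificial reaction network
over ON/OFF token species:

* every node `X` (gene, intermediate operator node, reaction node) becomes
  `X_ON` and `X_OFF`; the OFF system is the De Morgan complement, so negation
  disappears;
* a conjunction is one reaction consuming one token per conjunct and
  producing the head token; each disjunct is an alternative producer;
* each gene is gated by a knockout node (`g = y_g AND f_g`; `g = y_g` for
  inputs) with input exchanges for `y_g_ON` and `y_g_OFF`; sealing the ON
  exchange knocks the gene out without touching anything upstream;
* input genes additionally get a free `OFF` input exchange, and the reaction
  node gets output exchanges for both polarities.

Node names are deterministic (`<gene>_ON`, `<gene>_y_OFF`,
`<head>_s<k>_ON`, …), so compiled networks are byte-for-byte reproducible.
Intermediate operator nodes carry no knockout gates — only genes are
knockable.

**Semantics.** A knockout pattern K seals `y_ON` for knocked genes and
`y_OFF` for the rest (the two decisions are coupled). The reaction is
blocked iff no steady-state flux reaches the `R_ON` output. Because an
unknocked input gene supplies its ON token (via `y_ON`) and its OFF token
(via the free exchange) *simultaneously*, the network semantics is
existential per polarity: `R_ON` is producible iff the rule evaluates true
when every literal is scored by token derivability. This is deliberately
conservative, and it diverges from "true under some consistent assignment"
exactly when one rule uses a shared input gene in both polarities. The
rule-level derivability recursion in `regmcs.rules` and the independent
fixpoint oracle in `regmcs.synthetic` both implement this semantics; it is
the single source of truth for all equivalence tests.

A consequence worth stating: with NOT literals, blocking is **not monotone**
in K — knocking an inhibitor's inhibitor can re-enable a reaction. This is
the same mechanism as the adaptation pathways below, and it is why the
genome-wide enumeration verifies every candidate.

## Cycle detection

Regulatory feedback produces cyclic rule systems the Boolean machinery
cannot evaluate. The flux-based check (`check_acyclic`) solves: minimise
total flux subject to total flux ≥ 1, steady state, and **all exchanges
sealed**; feasibility means the network sustains an internal token
circulation.

Two structural facts shape the implementation:

1. Every token reaction consumes k ≥ 1 tokens and produces exactly one, so a
   sealed steady state forces zero flux through every k ≥ 2 reaction (sum
   the species balances). Hence the LP is feasible **iff the digraph of
   single-substrate non-exchange reactions has a directed cycle** — an exact
   combinatorial characterisation, implemented as the independent graph
   oracle. The LP/graph agreement tested on random batches is therefore a
   check of the implementation, not a sampled conjecture.
2. With knockout gates inserted, every gene's ON producer consumes an
   exchange-fed `y` token, which seals all circulations. The cycle check
   therefore runs on the network compiled *without* knockout nodes, where
   e.g. a pure self-inhibition `g = NOT g` yields the ON↔OFF token 2-cycle
   and is correctly flagged.

The flux criterion certifies self-sustaining circulations only. Boolean
feedbacks whose complement side is a multi-substrate conjunction (e.g.
`g = r OR NOT g`) do not circulate and are invisible to the LP, yet still
break well-founded evaluation. Layer addition therefore masks cycles found
on the **gene dependency digraph** (regulator → regulated edges), a strictly
stronger criterion: any reaction whose dependency structure becomes cyclic
reverts the offending layer additions (the new equations are masked for that
reaction, the gene reverting to an input there), and the per-layer count of
reverted reactions is reported. The alternative — reverting the entire layer
for that reaction — would discard more regulation than necessary.

## Per-reaction knockout sets (dual MILP)

For one compiled network, a pattern K blocks the output iff a Farkas
certificate exists for the sealed cone: `Sᵀu + Σ_sealed v_j e_j − t·w ≥ 0`,
`v ≥ 0`, `w ≥ c > 0` (t marks the `R_ON` output column). The MILP couples
binary seal decisions to the certificate (`α z ≤ v ≤ M z`), enforces
`z_ON + z_OFF = 1` per gene and at least one knockout, minimises the number
of knocked genes, and enumerates with support-exclusion cuts
`Σ_{J} z_ON ≤ |J|−1`, which also forbid supersets. Because enumeration is
size-ordered, the returned supports are exactly the irreducible (minimal)
blocking sets, including under non-monotone blocking: any non-minimal
blocking set contains a smaller blocking set found earlier and is excluded
by its cut.

**Sign convention.** The certificate is stated with `w ≥ c > 0` and the task
column entering as `−t·w`; this orientation is feasible exactly when the
sealed primal is infeasible, and is validated by oracle equivalence rather
than by symbol-matching.

**Constants.** `α = 1e-3`, `M = 1e3`, `c = 1` by default (configurable).
The certificate is homogeneous, so `c` is a pure scale choice; it is set to
1 so that certificate magnitudes (~1) sit three orders of magnitude above
the worst-case big-M integrality leak (`M ×` the solver's `1e-6` integer
feasibility tolerance `= 1e-3`). With `c` at `1e-3` that leak can fake
certificates — observed, and the reason for the default. All MILPs run on
HiGHS (via scipy) with zero relative MIP gap; HiGHS is deterministic
single-threaded, so enumeration is reproducible at the set level. A
per-solution time limit (default 300 s, irrelevant at test scale) flags
incomplete enumerations rather than failing.

## G/F matrices and dependency weights

Per-reaction minimal knockout sets are merged genome-wide: one row per
distinct gene set `F(i)`, marking the blocked reactions `G(i)`; reactions
without rules contribute nothing; identical rule systems share one
enumeration. Simplification drops rows with more than `max_len` genes and
recomputes dependencies.

The dependency weight is the exclusive contribution
`d_i = |F(i) \ ∪ {F(δ) : F(δ) ⊂ F(i)}|`, with constraints `z_δ ≥ z_β`
whenever `F(β) ⊃ F(δ)`. On **hierarchical families** — where every overlap
between two rows is covered by common subset rows — `Σ d_i z_i` counts the
distinct genes of any dependency-closed activation exactly (this includes
d = 0 rows such as `{gA,gB}` above `{gA}`,`{gB}`). On general families the
weighted sum can strictly overcount (`{gA,gB}`,`{gA,gC}` with no `{gA}` row:
4 vs 3), and no scalar weighting can repair this; the identity batch
therefore draws hierarchical families, and a unit test documents the
overcount on the overlapping case.

## Genome-wide gMCS enumeration

The genome-wide MILP uses the same certificate structure with `Gᵀv` in place
of the per-reaction seals, row indicators `z`, and the dependency
constraints. Because of the overcount above, the objective is **not**
`Σ d_i z_i` but an exact knockout count: per-gene indicator binaries `q_p`
with `q_p ≥ z_i` for every row containing gene p, objective `Σ q_p`. This
keeps proposals in true nondecreasing knockout count regardless of row
overlap structure (the d-weights remain available on the result object).

Candidates are the `q` supports. Each is verified by the primal
(`verify_cut_set`: token-semantics blocking per reaction, then task LP) and
checked for minimality (all proper subsets for small sets — leave-one-out is
insufficient under non-monotone blocking). Verified minimal sets are
reported and their supersets excluded; a candidate failing verification is
excluded by an exact no-good cut only, since its supersets may still be
genuine gMCSs. With this cut discipline the enumeration is provably complete
up to the length bound: every true minimal cut set contains a certificate
support (choose, per blocked reaction, a minimal-within-K blocking subset;
each is a G row) and is never excluded by the posted cuts.

## Essentiality analysis

* **gmcsTH5**: per sample, take each gMCS's maximum-expression gene (ties
  broken towards the lexicographically smallest id; genes deduplicated —
  "repeats avoided" is read as gene-level deduplication), then the 5% lower
  empirical (type-1) quantile of those values. The threshold is always an
  observed expression value, and the convention is order-based, so the
  high/low partition is invariant under monotone transforms. Genes missing
  from the matrix are treated as zero (logged) by default.
* **Calling**: highly expressed means strictly above the threshold
  (boundary genes are lowly expressed). A gene is potentially essential when
  some gMCS has it as the unique highly expressed member; single-gene gMCSs
  call their gene in every sample regardless of expression. When a base
  (unregulated) gMCS list is supplied, thresholds derive from it and are
  applied to the integrated lists.
* **Adaptation**: the whole rule system (knockout gates included) is
  linearised over binaries with the standard AND/OR/NOT encoding; input
  genes are free binaries. With the candidate's knockout node fixed to 0,
  the ILP minimises the number of active partners in the explaining gMCS; a
  positive optimum means every consistent state activates a partner, and the
  call is discarded. Verdicts are cached per (gene, gMCS) pair. The encoding
  is exact: its feasible points are precisely the consistent Boolean states
  (tested exhaustively).
* **Evaluation**: TP/FP and PPV = TP/(TP+FP) per sample against a
  gold-standard list, restricted to covered genes; PPV is reported missing
  when nothing is predicted; macro average across samples.

## Synthetic data and what the tests show

The generators produce linear-pathway metabolic models (uptake → chain with
parallel alternative steps → biomass) with random GPR trees (depth ≤ 3, kept
shallow so the exhaustive oracles stay well under a second per instance) and
layer-wise regulatory equations whose regulators are fresh genes — acyclic
by construction. Defaults: 1–2 regulators per frontier gene, activation
probability 0.7 (curated regulatory databases are activator-biased), total
genes capped at 10–12 so exhaustive enumeration over all knockout subsets is
tractable. Expression fixtures are lognormal (log-scale mean 1.5, sd 1.0)
with planted low/high genes realising a designed essentiality pattern.

Validation batch sizes (also used by `scripts/acceptance.py`): 100 rule
systems for per-reaction MILP vs brute force (size ≤ 4), 50 integrated
models for the full pipeline vs brute-force gMCSs (length ≤ 4, ≤ 2 layers),
200 systems for cycle detection (half with planted self-inhibitions), 100
hierarchical families for the dependency identity (exhaustive over
activations), 100 systems × all knockout patterns for the ILP encoding, 20
models for base-gMCS preservation. Per-instance seeds derive from one master
seed via a seed sequence.

What passing these tests does **not** show: behaviour at genome scale
(thousands of reactions, MILP warm-starting, memory), realistic GPR
complexity (isozyme/complex nesting far deeper than depth 3), realistic
expression distributions or batch effects, or any model with regulatory
*cycles* — cyclic Boolean dynamics are out of scope by design, and layer
additions that would create them are reverted, not modelled.

## Known limitations

* Regulatory cycles are detected and excluded, never simulated; models whose
  biology depends on feedback loops lose those interactions.
* The existential token semantics can keep a reaction nominally active under
  mixed-polarity use of a shared regulator where no consistent Boolean state
  exists; this conservatism is inherited by everything downstream.
* Exclusion-cut enumeration re-solves the MILP once per solution; at genome
  scale a pool-based solver interface would be preferable.
* `simplify_g_matrix` discards long rows for tractability, so gMCSs whose
  support requires a discarded row are not found — the same trade-off as
  searching only up to a length bound.
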