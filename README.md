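# regmcs

Genetic minimal cut sets in metabolic networks extended with signed
regulatory layers, and the downstream transcriptomics-based gene-essentiality
analysis.

## The problem

A **genetic Minimal Cut Set (gMCS)** is a minimal set of gene knockouts whose
simultaneous loss blocks a metabolic task — typically biomass production in
cancer studies, where gMCSs are a mechanistic model of synthetic lethality.
Classical gMCS computation works on genome-scale metabolic models whose
gene-protein-reaction (GPR) rules are negation-free Boolean expressions.
Regulatory networks, however, contribute *inhibitory* interactions: extending
GPR rules with signed regulator→target edges introduces NOT literals (and,
potentially, feedback cycles) that the classical machinery cannot handle.

`regmcs` implements the extended machinery for *acyclic* signed regulatory
layers and is aimed at researchers doing constraint-based modelling of cancer
metabolism: it enumerates gMCSs of integrated metabolic–regulatory models,
and combines them with expression data to call context-specific essential
genes, discarding candidates rescued by regulatory adaptation.

## The method

For a metabolic network with stoichiometry `S` (reversible reactions split so
`r ≥ 0`), a task vector `t` and knockout constraints `G·r ≤ 0`, the flux
system is a cone; the task is blocked exactly when a Farkas certificate
exists:

```
Sᵀu + Gᵀv − t·w ≥ 0,    v ≥ 0,   w ≥ c > 0
```

The package builds this certificate search as a MILP in three stages:

1. **eGPR compilation.** Each reaction's (extended) rule is compiled into an
   artificial token network: every Boolean node is split into `X_ON`/`X_OFF`
   species (De Morgan), conjunctions become multi-substrate reactions,
   disjuncts alternative producers. Knockout nodes `y_g` gate each gene
   (`g = y_g AND f_g`), with paired input exchanges `y_g_ON`/`y_g_OFF`; input
   genes get a free `OFF` exchange (their state is free). Regulatory layers
   are added one at a time (one OR-equation per regulated gene, inhibitors as
   NOT literals); additions that create cyclic dependencies are reverted per
   reaction and counted. Cycle detection solves the sealed-boundary
   circulation LP and is cross-checked by an exact combinatorial oracle.
2. **G/F matrices.** A dual MILP per reaction enumerates the irreducible
   knockout sets that block it (certificate + binary seal decisions
   `α·z ≤ v ≤ M·z`, ON/OFF coupling `z_ON + z_OFF = 1`, support-exclusion
   cuts). Identical gene sets merge into rows of `F` (genes) / `G` (blocked
   reactions), with exclusive-contribution weights `d` and strict-subset
   dependency constraints.
3. **gMCS enumeration.** A genome-wide MILP over the G rows proposes gene
   sets in nondecreasing knockout count; every candidate is verified against
   the primal (token-semantics blocking + LP) and checked for minimality —
   necessary because with negation, blocking is *not* monotone in the
   knockout set.

For essentiality analysis, the **gmcsTH5** threshold is the 5% lower
empirical quantile of each gMCS's maximum-expression gene (deduplicated); a
gene is called essential in a sample when some gMCS has it as the unique
highly expressed member. An integer program over the Boolean rule system then
discards calls whose knockout forces a partner gene on (**adaptation**).

Full mathematical details and design choices are in
[docs/methods.md](docs/methods.md).

## Worked example

The bundled five-reaction toy (uptake → r1..r4 → biomass, five genes) with
one regulatory layer `g4 = g6 OR NOT g7 OR g8`:

```python
from regmcs.synthetic import make_example_toy
from regmcs.gmatrix import build_g_matrix
from regmcs.enumerate import enumerate_gmcs, SolverConfig

model, rules = make_example_toy(n_layers=1)
gf = build_g_matrix(model, rules, max_size=5)
for f, g, d in zip(gf.F_rows, gf.G_rows, gf.d):
    print(f"  {sorted(f)} -> {sorted(g)}  d={d}")
for g in enumerate_gmcs(model, gf, SolverConfig(max_length=5), rules=rules).gmcs:
    print(f"  gMCS {sorted(g.genes)} (length {g.length})")
```

prints

```
  ['g1'] -> ['r1']  d=1
  ['g2'] -> ['r2', 'r3']  d=1
  ['g3'] -> ['r3']  d=1
  ['g5'] -> ['r_bio']  d=1
  ['g2', 'g4'] -> ['r4']  d=1
  gMCS ['g1'] (length 1)
  gMCS ['g2'] (length 1)
  gMCS ['g3'] (length 1)
  gMCS ['g5'] (length 1)
```

Reading the output: knocking `g2` alone blocks both `r2` and `r3` (one G row,
two reactions), which severs the route to biomass — so `{g2}` is a gMCS.
`{g2, g4}` blocks `r4`, but `r4` is not essential for the task, and `g4`
itself cannot be silenced through its regulators: the inhibitory branch
`NOT g7` keeps `g4` producible whatever happens upstream, so no regulator
set ever cuts `r4`'s rule — only the direct `{g2, g4}` knockout does.

The same pipeline runs from the shell:

```sh
regmcs build      --model model.tsv --target r_bio --regnet reg.tsv --layers 1 --out-dir out
regmcs enumerate  --model model.tsv --target r_bio --regnet reg.tsv --layers 1 --out-dir out
regmcs essentiality --model model.tsv --target r_bio --regnet reg.tsv --layers 1 \
                  --expression expr.csv --gold gold.tsv --out-dir out
```

writing `out/gmatrix/` (MatrixMarket G/F + labels + d), `out/gmcs.tsv`,
`out/calls.tsv` and `out/evaluation.tsv` (TP/FP/PPV per sample).

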