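# momaknock

Bi-level strain design for metabolic engineering: find up to *K* reaction
knockouts in a stoichiometric network that maximize the production flux of a
target chemical, under the **MOMA** phenotype assumption — the mutant does
not grow optimally, it stays as close as possible (in squared Euclidean flux
distance) to the wild type.

## Who this is for

Computational/systems biologists doing *in silico* strain design on
constraint-based models (FBA-style, `S v = 0` with flux bounds), who want
knockout suggestions evaluated under the phenotype model that best matches
fresh (non-evolved) deletion mutants, rather than under the
growth-maximization assumption of classical OptKnock-style design.

## The model

Wild-type reference `w`: FBA — maximize biomass flux subject to
`S v = 0`, bounds `v^min ≤ v ≤ v^max`, and a fixed substrate (glucose)
uptake `v_glc = v_glc_uptake`; a minimum-norm second stage makes `w` unique.

The design problem is the bi-level program

```
max_y   v_chemical
s.t.    v  ∈  argmin_v  Σ_{j≠chemical} (v_j − w_j)²          (MOMA inner QP)
               s.t.  S v = 0,  v_glc = v_glc_uptake,
                     v_biom ≥ v_biom^target,
                     v_j^min·y_j ≤ v_j ≤ v_j^max·y_j  ∀j
        Σ_j (1 − y_j) ≤ K,   y_j ∈ {0, 1}
```

The quadratic inner objective is piecewise-linearized: each flux is a convex
combination of grid endpoints, `v_j = Σ_t β_jt v_j^t` with `Σ_t β_jt = 1`,
`β ≥ 0`, turning `(v_j − w_j)²` into the chordal cost
`Σ_t (v_jt² − 2 w_j v_jt) β_jt`. LP strong duality then collapses the inner
problem into a single-level MILP (primal rows + dual rows + a duality row +
big-M products of bound duals with the binaries). An adaptive driver refines
the grid, evaluates each proposed knockout set with the exact QP, and
terminates with a certificate that no better set exists; the converged
solution has zero chordal gap and matches the exact QP value. See
`docs/methods.md` for the algorithm and its guarantees.

Fluxes are mmol/gDW/hr throughout.

## Worked example

Generate a toy mass-balanced network (substrate A, growth branch
A→B→D→biomass, production branch A→C→P→secretion) and design a 2-knockout
strain:

```sh
$ momaknock synth --n 6 --seed 0 -o toy.tsv
wrote toy.tsv (5 metabolites, 9 reactions)

$ momaknock fluxmax --model toy.tsv -R EX_P
EX_P    8.000000

$ momaknock run --model toy.tsv -K 2 -o rep.tsv
iter 1: milp=8.000000 objL=0.000000 max_delta=19.2 endpoints=84 added=26 knockouts=R_AC
iter 2: milp=8.000000 objL=2.495127 max_delta=9 endpoints=108 added=24 knockouts=R2_CD,R_BD
iter 3: milp=8.000000 objL=8.000000 max_delta=1.15e-14 endpoints=30 added=0 knockouts=R2_CD,R_BD
status: converged

$ cat rep.tsv
K   knockouts   design_target   moma_target   moma_biomass   l2_distance   status
2   R2_CD,R_BD  8.000000        8.000000      1.000000       12.975010     converged
```

Reading: the theoretical maximum of the target secretion `EX_P` is
8 mmol/gDW/hr. Deleting `R_BD` (the growth branch) and `R2_CD` (a C→D
shunt) forces the MOMA phenotype to reroute carbon through the production
branch: the mutant secretes the full 8 mmol/gDW/hr (design and MOMA
re-evaluation agree — the hallmark of the MOMA-inner design), keeps biomass
at the 1 mmol/gDW/hr viability floor, and sits at Euclidean distance 12.98
from the wild-type flux distribution. `objL` is the exact lower bound from
the incumbent set at each iteration; `max_delta` is the largest remaining
linearization gap.

`momaknock compare --model toy.tsv --K 1 --K 2` prints the same designs side
by side with the growth-inner (OptKnock-style) baseline, with its MOMA
re-evaluation and per-row flags for degenerate comparisons.

Other subcommands: `fba` (wild-type reference), `moma --knockouts R1,R2`
(evaluate any deletion set), `oracle` (exhaustive enumeration on small
instances), `optknock`.

SBML models work via `--format sbml` with `--target/--biomass/--glucose`
naming the designated reactions; the TSV dialect used above is documented by
example in the generated files (one reaction per line: id, equation, lb, ub,
flags).

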