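# Methods

## Phenotype models

**Wild type (FBA).** The reference flux distribution `w` maximizes the
biomass flux over the steady-state polytope `{v : S v = 0, v^min ≤ v ≤
v^max, v_glc = v_glc_uptake}`. Biomass-optimal vertices are almost always
degenerate, so `w` would not be reproducible from the LP alone; a second
stage minimizes `‖v‖₂` over the biomass-optimal face (a strictly convex QP,
hence a unique minimizer). This tie-break is a package convention —
disable it with `solve_fba(..., minimize_norm=False)` if an arbitrary
optimal vertex is acceptable.

**Mutant (MOMA).** A knockout set `y` forces `v_j = 0` for deleted
reactions; the mutant phenotype minimizes `Σ_{j∈Obj}(v_j − w_j)²` over the
post-knockout polytope, with `Obj` excluding the target reaction inside the
design problem (penalizing target movement would contradict the outer
objective). Because the objective is strictly convex in every non-target
flux, the inner-optimal set is `{v feasible : v_{−target} = v*_{−target}}`
with `v*_{−target}` unique. The *optimistic* follower value — the tie-break
implicit in duality-based single-level reformulations, which the evaluator
must share with the optimizer for the two to agree — is therefore computed
by one LP: maximize `v_target` with the non-target fluxes boxed within
`1e-7·(1+|v*_j|)` of the QP optimum. The QP itself is solved by OSQP at
`eps_abs = eps_rel = 1e-10` with polishing; the box LP by HiGHS.

Lethal sets (empty post-knockout polytope) are reported with
`status="infeasible"` rather than raised, so batch comparisons never abort.

## Piecewise linearization

Each flux is a convex combination of per-reaction grid endpoints
(`v_j = Σ_t β_jt v_j^t`, `Σ_t β_jt = 1`, `β ≥ 0`); the quadratic cost is
replaced by its chord, giving the endpoint cost coefficients
`v_jt² − 2 w_j v_jt` (the constant `w_j²` is dropped). The chord
*over*-estimates the quadratic; the overestimate at a solution is the
per-reaction gap `Δ_j = Σ_t (v_jt − w_j)² β_jt − (v̂_j − w_j)²` with `v̂`
the reconstructed flux, which reduces to the familiar two-endpoint
expression when `β_j` has two adjacent nonzeros and is zero when `β_j` is
concentrated. Degenerate bases with more than two nonzeros are handled by
this generalized form rather than assumed away.

Grids always contain the bounds, and — when strictly inside them — `0`
(the knocked-out state is exactly representable, so knockouts carry no
linearization penalty), `w_j` (the wild type is exactly representable) and
the fixed glucose rate. Defaults: `k_init = 4` uniform initial segments;
gap tolerance `ε = 1e-6·(1 + ‖w‖₂²)` (scales with the cost magnitude);
concentration threshold `θ = 0.999`; merge tolerance `1e-9·(ub_j − lb_j)`.
Fixed fluxes (`lb = ub`) collapse to a single-point grid and are excluded
from refinement and from the concentration test, as is the target reaction
(its inner-cost coefficient is zero, so β spread there causes no error —
demanding concentration would prevent termination without changing any
value).

## Single-level MILP

For a fixed grid the inner problem is an LP in β, and LP strong duality
collapses the bi-level program into one MILP containing the linearized
primal block (convexity, stoichiometry in β-space, glucose equality,
biomass floor, knockout-gated bound rows `v_j^min y_j ≤ v_j ≤ v_j^max y_j`),
the inner dual block (one row per endpoint), the knockout budget, the
strong-duality row, and the outer objective `max Σ_t v_chem^t β_chem,t`.

Sign conventions of the dual block are derived mechanically from the primal
block — `c_j ≥ 0` dual to the lower-bound row, `d_j ≥ 0` to the upper-bound
row, so the dual objective carries `+ v_j^min c_j y_j − v_j^max d_j y_j` —
and the derivation is gated by a numerical test: for random (network,
knockout pattern, grid) triples, the primal and dual LPs must agree to
1e-6 relative. The bilinear products `c_j y_j`, `d_j y_j` become variables
`e_j`, `f_j` through the standard four big-M rows each. `M` defaults to
`10·max(1, max|cost coefficient|, max bound)`; a post-solve audit flags any
active-reaction dual within `1e-4·M` of a bound and retries with `10M`
(bound duals of *knocked-out* reactions are free slack up to M and are
exempt — their products are forced to zero regardless). Everything is
solved by HiGHS through `scipy.optimize.milp`, which is deterministic on a
fixed instance.

### The upper-bounding relaxation

With the duality row as a plain equality, the MILP value for a given `y` is
the target flux maximized over *chord-cost* minimizers. That set need not
contain the exact inner optimum (its chord representation can cost more
than the chord minimum on a coarse grid), so the equality formulation can
both over- and under-rate the optimistic target of a knockout pattern the
iteration has not refined for — and an endpoint-concentrated solution has
zero chordal gap while the grid is still too coarse to expose the true
inner optimum. A convergence test based only on gaps and concentration can
therefore accept a suboptimal design (observed against the brute-force
oracle on a few percent of random instances).

The package instead relaxes the duality row by the per-endpoint chord-error
budget `σ_jt = (max(W_{t−1}, W_t)/2)²` (`W_t` = adjacent segment widths):

```
Σ_jt (q_jt − σ_jt) β_jt  ≤  dual objective
```

Since the chord of a quadratic over a segment of width `W` overestimates it
by at most `(W/2)²`, any exact inner optimum of any `y` — written as the
convex combination of its segment's endpoints — satisfies this row. The
MILP optimum is then a valid **upper bound** on the bi-level optimum,
tightening as segments shrink. The plain equality remains available
(`duality_slack=False`) and is used for the final restriction solve.

## The adaptive driver

`run_momaknock` turns the upper-bounding MILP into a certified
candidate-generation loop:

1. seed the incumbent with the empty knockout set (exact QP value);
2. solve the relaxed MILP with (a) no-good cuts excluding every knockout
   set already evaluated and (b) a cut requiring improvement over the
   incumbent (the warm-start lower bound `objL`);
3. if infeasible, or the optimum is within tolerance of the incumbent: no
   unevaluated set can beat the incumbent even in the relaxation, so the
   incumbent is the certified optimum — stop;
4. otherwise evaluate the proposed set exactly (MOMA QP + optimistic LP),
   update the incumbent, insert the exact inner optimum's coordinates as
   grid endpoints (after which the relaxation can no longer overrate this
   set), apply the per-reaction chordal refinement (insert the
   reconstructed flux wherever `Δ_j > ε` or `max β_j < θ`) and a slack
   refinement (halve segments whose error budget the solution consumed),
   exclude the set with a no-good cut, and iterate (default
   `max_iter = 100`; each iteration retires one candidate set, so the loop
   is finite regardless).

Ties are then polished: among proper subsets of the winner whose exact
target matches within `1e-6·(1+|value|)`, the strain with smaller
`‖v − w‖₂` (then fewer deletions) is preferred — a no-op deletion is never
reported, in keeping with the minimal-adjustment rationale.

Finally a *restriction solve* — binaries pinned to the winner, duality row
as a plain equality, on a minimal grid `{lb, 0, w_j, v*_j, ub}` per
reaction containing the winner's exact inner optimum — reproduces the
converged state the linearization aims for: every `Δ_j` vanishes, every
`β_j` concentrates on an endpoint, and the MILP outer objective equals the
exact QP re-evaluation (to ~1e-7 relative in practice). The minimal grid
matters: near-duplicate endpoints accumulated over iterations (exact points
of different QP solves, ~1e-7 apart) let an optimal basis spread β across a
microscopic segment, which is numerically harmless but fails the
concentration test. Two numerical notes: with all binaries pinned the
restriction is solved as a continuous LP, and HiGHS presolve is disabled
for it — presolve misjudges the degenerate strong-duality face as
infeasible, while the plain simplex solves it (verified by substituting the
separately solved primal/dual LP solutions, which satisfy every row to
1e-13).

The iteration trace (MILP objective, `objL`, max gap, endpoint counts,
proposed set, cut usage) is kept on the result and logged by the CLI.

## Growth-inner baseline

`run_optknock` implements the classical comparator: same outer problem,
inner LP `max v_biom`, collapsed by LP duality into a single-level MILP
directly (no linearization needed). Its duality construction implies the
same optimistic tie-break — among growth-optimal mutant fluxes the target
is maximized — without which the design-phase target column would be
ill-defined. Designs are re-evaluated under MOMA by `solve_moma`, which is
the comparison protocol: growth-inner designs routinely look excellent in
their own design phase and collapse under MOMA, while MOMA-inner designs
evaluate to their design value by construction. `compare_strategies` emits
the side-by-side table and flags degenerate rows (non-productive baseline
designs, lethal designs, and any row where the MOMA-inner design does not
dominate). The distance half of the comparison ("the MOMA-inner design
stays closer to the wild type") is an empirical regularity, not a theorem:
a baseline that suggests a no-op deletion sits at distance zero by
definition, which is why non-productive baseline designs are flagged and
excluded from that particular comparison.

## Synthetic networks

`generate_toy_network(n_internal, seed)` emulates the structure the design
problem needs: a substrate uptake fixed at 10 mmol/gDW/hr, a growth branch
(A→B→D, D feeding a biomass drain) that growth-maximizing wild types use
exclusively, a production branch (A→C+δD, C→P, P secreted) that knockouts
must activate, and `n_internal − 4` random internal conversions (some
reversible) creating alternate routes. Every reaction conserves unit mass,
so no flux-generating loops exist; feasibility (FBA biomass ≥ 1 at the
fixed uptake) is verified by LP with bounded retries. Defaults: uptake 10,
minimum biomass 1, internal bounds ±30.

What these fixtures do *not* emulate: genome-scale size (tested instances
have 6–12 internal reactions so the brute-force oracle stays exhaustive),
cofactor/energy metabolism, compartments, and gene–protein–reaction
structure. Passing tests therefore demonstrate the *algorithmic*
guarantees — oracle equivalence, duality correctness, convergence — on
networks with realistic branching structure, not biological predictions for
any organism.

## Verification instruments

* `brute_force_bilevel`: exhaustive enumeration of candidate subsets up to
  `K` with exact QP inner solves — the ground truth on small instances
  (cap 20,000 subsets; supersets of lethal sets pruned, which cannot change
  the result since knockouts only shrink the feasible set).
* `brute_force_optknock`: the same with the growth-inner LP.
* Independent solver routes in the test suite: GLPK (via cobrapy/optlang)
  re-solves the FBA and flux-maximum LPs; `scipy` trust-constr re-solves
  the MOMA QP; the assembled dual LP is checked against the primal LP on
  random triples.

## Problem sizes and tolerances used in the checks

The standard verification population is 20 generated networks (6–12
internal reactions, K ∈ {1, 2}), on which the adaptive solver matches the
oracle to 1e-5 relative and terminates in 2–10 iterations (seconds per
instance); the strong-duality gate runs 50 random triples at 1e-6
relative; the MOMA identity holds to 1e-8. These sizes keep the exhaustive
oracle exact and the full suite in the minutes range.

## Known limitations

* The candidate-generation certificate evaluates one QP per proposed
  knockout set; on instances where many sets have near-optimal relaxed
  values it degrades toward enumeration. Genome-scale use would want the
  slack refinement to carry more of the load (fewer, tighter pop-ups) and a
  MIP-start interface, which `scipy`'s HiGHS wrapper does not expose.
* Alternate optimal knockout sets are not enumerated; one optimum (after
  the parsimony/distance tie-break) is reported.
* Gene–protein–reaction mapping, regulatory/thermodynamic constraints and
  ROOM/L0/L1 inner objectives are out of scope.
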