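"""Brute-force bi-level references.

These enumerate every candidate knockout subset up to the budget and solve
the inner problem exactly for each — the ground truth the MILP path is
checked against on small fixtures.  ``brute_force_bilevel`` uses the exact
MOMA QP inner problem (the bi-level definition itself); a variant with the
growth-maximizing inner LP backs the OptKnock-style comparator.  Purely a
test instrument: combinatorics limit it to small candidate sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from momaknock.network import MetabolicNetwork, ProblemSpec
from momaknock.steady_state import solve_fba, solve_moma
from momaknock._lp import solve_lp
import scipy.sparse as sp

__all__ = ["OracleResult", "brute_force_bilevel", "brute_force_optknock"]

ENUMERATION_CAP = 20_000


@dataclass
class OracleResult:
    best_knockouts: frozenset[str]
    best_value: float  # optimistic inner-evaluated target flux
    table: pd.DataFrame  # one row per enumerated subset


def _subsets(candidates: list[str], K: int):
    for k in range(K + 1):
        yield from combinations(candidates, k)


def _check_cap(n_cand: int, K: int) -> None:
    total = sum(comb(n_cand, k) for k in range(K + 1))
    if total > ENUMERATION_CAP:
        raise ValueError(
            f"enumeration of {total} subsets exceeds the cap ({ENUMERATION_CAP}); "
            "shrink the instance or lower K"
        )


def brute_force_bilevel(
    net: MetabolicNetwork,
    spec: ProblemSpec,
    candidates: list[str] | None = None,
    K: int | None = None,
    *,
    w: pd.Series | None = None,
) -> OracleResult:
    """Exact bi-level optimum by exhaustive enumeration with QP inner solves.

    Supersets of a lethal (infeasible) set are pruned without solving —
    knocking out more reactions only shrinks the feasible set, so the prune
    never changes the result.  Deterministic and invariant to candidate
    ordering (ties broken by subset size, then lexicographically).
    """
    K = spec.K if K is None else K
    cands = sorted(candidates if candidates is not None else net.knockout_candidates)
    _check_cap(len(cands), K)
    if w is None:
        w = solve_fba(net, spec)
    lethal: list[frozenset[str]] = []
    rows = []
    best: tuple[float, int, tuple[str, ...]] | None = None
    for subset in _subsets(cands, K):
        fs = frozenset(subset)
        if any(l <= fs for l in lethal):
            rows.append((subset, "pruned_lethal", np.nan, np.nan, np.nan))
            continue
        rep = solve_moma(net, w, fs, spec, exclude_target=True)
        if not rep.feasible:
            lethal.append(fs)
            rows.append((subset, "infeasible", np.nan, np.nan, np.nan))
            continue
        rows.append(
            (subset, "optimal", rep.moma_objective, rep.target_flux, rep.biomass_flux)
        )
        key = (rep.target_flux, -len(subset), tuple(sorted(subset)))
        if best is None or rep.target_flux > best[0] + 1e-12:
            best = (rep.target_flux, len(subset), tuple(sorted(subset)))
    table = pd.DataFrame(
        rows, columns=["knockouts", "status", "moma_objective", "target_flux", "biomass_flux"]
    )
    if best is None:
        raise RuntimeError("every enumerated subset (including the empty set) is infeasible")
    return OracleResult(
        best_knockouts=frozenset(best[2]), best_value=best[0], table=table
    )


# ---------------------------------------------------------------------------
# growth-inner variant (OptKnock reference)
# ---------------------------------------------------------------------------


def _growth_inner_optimistic(
    net: MetabolicNetwork, spec: ProblemSpec, knockouts: frozenset[str]
) -> tuple[float, float] | None:
    """Inner LP max biomass under the knockouts, then max target flux among
    biomass-optimal fluxes.  Returns (target, biomass) or None if lethal."""
    M = net.n_reactions
    lb, ub = net.lb.copy(), net.ub.copy()
    for rid in knockouts:
        j = net.rxn_idx(rid)
        lb[j] = 0.0
        ub[j] = 0.0
    glc_row = sp.csr_matrix((np.ones(1), ([0], [net.glucose_idx])), shape=(1, M))
    A = sp.vstack([net.S, glc_row, sp.eye(M, format="csr")])
    lo = np.concatenate([np.zeros(net.n_metabolites), [spec.v_glc_uptake], lb])
    hi = np.concatenate([np.zeros(net.n_metabolites), [spec.v_glc_uptake], ub])
    c = np.zeros(M)
    c[net.biomass_idx] = -1.0
    free = (np.full(M, -np.inf), np.full(M, np.inf))
    res = solve_lp(c, A, lo, hi, *free)
    if res.status != "optimal":
        return None
    biom = -res.fun
    if biom < spec.v_biom_target - 1e-9:
        return None
    lb2, ub2 = lb.copy(), ub.copy()
    lb2[net.biomass_idx] = biom - 1e-9 * (1 + abs(biom))
    lo2 = np.concatenate([np.zeros(net.n_metabolites), [spec.v_glc_uptake], lb2])
    hi2 = np.concatenate([np.zeros(net.n_metabolites), [spec.v_glc_uptake], ub2])
    c2 = np.zeros(M)
    c2[net.target_idx] = -1.0
    res2 = solve_lp(c2, A, lo2, hi2, *free)
    if res2.status != "optimal":
        return None
    return -res2.fun, float(res2.x[net.biomass_idx])


def brute_force_optknock(
    net: MetabolicNetwork,
    spec: ProblemSpec,
    candidates: list[str] | None = None,
    K: int | None = None,
) -> OracleResult:
    """Enumeration reference for the growth-inner (OptKnock-style) bi-level
    problem with the optimistic tie-break."""
    K = spec.K if K is None else K
    cands = sorted(candidates if candidates is not None else net.knockout_candidates)
    _check_cap(len(cands), K)
    rows = []
    best: tuple[float, tuple[str, ...]] | None = None
    for subset in _subsets(cands, K):
        out = _growth_inner_optimistic(net, spec, frozenset(subset))
        if out is None:
            rows.append((subset, "infeasible", np.nan, np.nan))
            continue
        tgt, biom = out
        rows.append((subset, "optimal", tgt, biom))
        if best is None or tgt > best[0] + 1e-12:
            best = (tgt, tuple(sorted(subset)))
    table = pd.DataFrame(rows, columns=["knockouts", "status", "target_flux", "biomass_flux"])
    if best is None:
        raise RuntimeError("every enumerated subset is infeasible")
    return OracleResult(best_knockouts=frozenset(best[1]), best_value=best[0], table=table)
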