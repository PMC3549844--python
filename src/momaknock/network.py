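"""Stoichiometric network data model, I/O and synthetic fixture generation.

A :class:`MetabolicNetwork` is the minimal constraint-based representation:
a sparse stoichiometric matrix ``S`` (metabolites x reactions), per-reaction
flux bounds, and three designated reactions — biomass drain, glucose (substrate)
uptake, and the target secretion whose flux the strain design maximizes.
Fluxes are in mmol/gDW/hr throughout.

Two on-disk formats are supported: SBML (read through cobrapy) and a small
tab-separated dialect defined here (one reaction per line: id, equation,
lower bound, upper bound, comma-separated flags).  The TSV dialect exists so
that toy models round-trip exactly and remain human-readable in tests.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MetabolicNetwork",
    "ProblemSpec",
    "CandidatePolicy",
    "ModelValidationError",
    "read_model",
    "write_model",
    "candidate_knockouts",
    "generate_toy_network",
]


class ModelValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class ProblemSpec:
    """Scalar design parameters shared by every phenotype computation.

    v_glc_uptake : fixed substrate consumption rate (mmol/gDW/hr)
    v_biom_target : minimum biomass flux a viable mutant must sustain
    K : knockout budget, max number of reactions with y_j = 0
    """

    v_glc_uptake: float = 10.0
    v_biom_target: float = 1.0
    K: int = 1

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("knockout budget K must be >= 0")
        if self.v_biom_target < 0:
            raise ValueError("minimum biomass must be >= 0")


@dataclass
class MetabolicNetwork:
    """Stoichiometric model with designated biomass / glucose / target reactions.

    ``S`` is an N x M sparse matrix (metabolites x reactions).  ``lb`` and
    ``ub`` are length-M flux bounds; reversible reactions carry lb < 0 rather
    than being split into forward/backward pairs, so the gated knockout bound
    lb_j*y_j <= v_j <= ub_j*y_j zeroes both directions at y_j = 0.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    biomass_rxn: str
    glucose_rxn: str
    target_rxn: str
    knockout_candidates: frozenset[str] = field(default_factory=frozenset)
    name: str = "model"

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def rxn_idx(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    @property
    def biomass_idx(self) -> int:
        return self.rxn_idx(self.biomass_rxn)

    @property
    def glucose_idx(self) -> int:
        return self.rxn_idx(self.glucose_rxn)

    @property
    def target_idx(self) -> int:
        return self.rxn_idx(self.target_rxn)

    def exchange_reactions(self) -> frozenset[str]:
        """Reactions whose stoichiometric column has a single nonzero entry.

        These move mass across the system boundary (uptakes, secretions,
        drains); by default they are not knockout candidates.
        """
        nnz = np.diff(self.S.indptr)
        return frozenset(r for j, r in enumerate(self.reaction_ids) if nnz[j] == 1)

    # -- validation ----------------------------------------------------------

    def validate(self, spec: ProblemSpec | None = None) -> None:
        if len(set(self.reaction_ids)) != self.n_reactions:
            raise ModelValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != self.n_metabolites:
            raise ModelValidationError("duplicate metabolite ids")
        if self.S.shape != (self.n_metabolites, self.n_reactions):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected "
                f"({self.n_metabolites}, {self.n_reactions})"
            )
        if self.lb.shape != (self.n_reactions,) or self.ub.shape != (self.n_reactions,):
            raise ModelValidationError("bounds length does not match reaction count")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            raise ModelValidationError(
                f"lb > ub for reaction {self.reaction_ids[bad[0]]!r}"
            )
        designated = {self.biomass_rxn, self.glucose_rxn, self.target_rxn}
        if len(designated) != 3:
            raise ModelValidationError(
                "biomass, glucose and target reactions must be pairwise distinct"
            )
        for r in designated:
            if r not in self._rxn_index:
                raise ModelValidationError(f"designated reaction {r!r} not in model")
        forbidden = designated & set(self.knockout_candidates)
        if forbidden:
            raise ModelValidationError(
                f"designated reactions may not be knockout candidates: {sorted(forbidden)}"
            )
        unknown = set(self.knockout_candidates) - set(self.reaction_ids)
        if unknown:
            raise ModelValidationError(f"unknown candidate reactions: {sorted(unknown)}")
        if spec is not None:
            g = self.glucose_idx
            if not (self.lb[g] - 1e-12 <= spec.v_glc_uptake <= self.ub[g] + 1e-12):
                raise ModelValidationError(
                    "glucose uptake rate lies outside the glucose reaction's bounds"
                )

    def with_bounds(self, lb: np.ndarray, ub: np.ndarray) -> "MetabolicNetwork":
        return replace(self, lb=np.asarray(lb, float), ub=np.asarray(ub, float))

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(write_model_string(self).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# plain-text dialect
# ---------------------------------------------------------------------------

_ARROW = re.compile(r"\s*(<->|<=>|->|=>)\s*")


def _parse_side(side: str) -> list[tuple[float, str]]:
    terms = []
    side = side.strip()
    if not side:
        return terms
    for chunk in side.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split()
        if len(parts) == 1:
            terms.append((1.0, parts[0]))
        elif len(parts) == 2:
            terms.append((float(parts[0]), parts[1]))
        else:
            raise ModelValidationError(f"cannot parse equation term {chunk!r}")
    return terms


def _parse_equation(eq: str) -> dict[str, float]:
    m = _ARROW.search(eq)
    if m is None:
        raise ModelValidationError(f"equation {eq!r} has no arrow")
    lhs, rhs = eq[: m.start()], eq[m.end() :]
    coeffs: dict[str, float] = {}
    for c, met in _parse_side(lhs):
        coeffs[met] = coeffs.get(met, 0.0) - c
    for c, met in _parse_side(rhs):
        coeffs[met] = coeffs.get(met, 0.0) + c
    return {m: c for m, c in coeffs.items() if c != 0.0}


def _format_equation(coeffs: dict[str, float]) -> str:
    def side(items):
        out = []
        for met, c in items:
            out.append(met if c == 1.0 else f"{c:.12g} {met}")
        return " + ".join(out)

    lhs = [(m, -c) for m, c in coeffs.items() if c < 0]
    rhs = [(m, c) for m, c in coeffs.items() if c > 0]
    return f"{side(lhs)} -> {side(rhs)}"


def read_model(
    path,
    format: str = "plain",
    *,
    biomass: str | None = None,
    glucose: str | None = None,
    target: str | None = None,
    candidate_policy: "CandidatePolicy | None" = None,
) -> MetabolicNetwork:
    """Read a model from disk.

    ``format='plain'`` reads the TSV dialect (designated reactions come from
    the ``biomass``/``glucose``/``target`` flags in the file unless overridden
    by keyword).  ``format='sbml'`` reads SBML L3/FBC through cobrapy; the
    three designated reactions must then be given by keyword (biomass defaults
    to the model objective when unambiguous).
    """
    if format == "plain":
        with open(path) as fh:
            net = read_model_string(fh.read())
    elif format == "sbml":
        net = _read_sbml(path, biomass=biomass)
    else:
        raise ValueError(f"unknown model format {format!r}")
    if biomass:
        net.biomass_rxn = biomass
    if glucose:
        net.glucose_rxn = glucose
    if target:
        net.target_rxn = target
    if candidate_policy is not None:
        net.knockout_candidates = candidate_knockouts(net, candidate_policy)
    elif not net.knockout_candidates:
        net.knockout_candidates = candidate_knockouts(net, CandidatePolicy())
    net.validate()
    return net


def _read_sbml(path, *, biomass: str | None) -> MetabolicNetwork:
    from cobra.io import read_sbml_model  # heavyweight import kept local

    model = read_sbml_model(str(path))
    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    midx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(model.reactions):
        for met, c in r.metabolites.items():
            rows.append(midx[met.id])
            cols.append(j)
            vals.append(float(c))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rxns)))
    lb = np.array([r.lower_bound for r in model.reactions], float)
    ub = np.array([r.upper_bound for r in model.reactions], float)
    if biomass is None:
        obj = [r.id for r in model.reactions if r.objective_coefficient]
        biomass = obj[0] if len(obj) == 1 else "?"
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=S,
        lb=lb,
        ub=ub,
        biomass_rxn=biomass,
        glucose_rxn="?",
        target_rxn="?",
        name=model.id or "sbml_model",
    )


def read_model_string(text: str) -> MetabolicNetwork:
    """Parse the TSV dialect from a string."""
    mets: list[str] = []
    met_seen: set[str] = set()
    rxns, lbs, ubs = [], [], []
    coeff_rows: list[dict[str, float]] = []
    flags_per_rxn: list[set[str]] = []
    name = "model"
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.lower().startswith("# model:"):
                name = line.split(":", 1)[1].strip()
            elif line.lower().startswith("# metabolites:"):
                for met in line.split(":", 1)[1].split():
                    if met not in met_seen:
                        met_seen.add(met)
                        mets.append(met)
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ModelValidationError(f"malformed model line: {raw!r}")
        rid, eq, lb, ub = parts[0], parts[1], float(parts[2]), float(parts[3])
        flags = set(f.strip() for f in parts[4].split(",") if f.strip()) if len(parts) > 4 else set()
        coeffs = _parse_equation(eq)
        for met in coeffs:
            if met not in met_seen:
                met_seen.add(met)
                mets.append(met)
        rxns.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        coeff_rows.append(coeffs)
        flags_per_rxn.append(flags)

    midx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    for j, coeffs in enumerate(coeff_rows):
        for met, c in coeffs.items():
            rows.append(midx[met])
            cols.append(j)
            vals.append(c)
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rxns)))

    def _find(flag: str) -> str:
        hits = [r for r, fl in zip(rxns, flags_per_rxn) if flag in fl]
        if len(hits) != 1:
            raise ModelValidationError(
                f"model must designate exactly one {flag!r} reaction, found {len(hits)}"
            )
        return hits[0]

    no_ko = {r for r, fl in zip(rxns, flags_per_rxn) if "no_knockout" in fl}
    net = MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=S,
        lb=np.array(lbs),
        ub=np.array(ubs),
        biomass_rxn=_find("biomass"),
        glucose_rxn=_find("glucose"),
        target_rxn=_find("target"),
        name=name,
    )
    net.knockout_candidates = candidate_knockouts(
        net, CandidatePolicy(deny=frozenset(no_ko))
    )
    return net


def write_model_string(net: MetabolicNetwork) -> str:
    """Serialize to the TSV dialect (exact round-trip of S, bounds, flags)."""
    lines = [
        f"# model: {net.name}",
        "# metabolites: " + " ".join(net.metabolite_ids),
        "# reaction_id\tequation\tlb\tub\tflags",
    ]
    exch = net.exchange_reactions()
    for j, rid in enumerate(net.reaction_ids):
        col = net.S.getcol(j).tocoo()
        coeffs = {net.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}
        flags = []
        if rid == net.biomass_rxn:
            flags.append("biomass")
        if rid == net.glucose_rxn:
            flags.append("glucose")
        if rid == net.target_rxn:
            flags.append("target")
        if rid in exch:
            flags.append("exchange")
        if (
            rid not in net.knockout_candidates
            and rid not in {net.biomass_rxn, net.glucose_rxn, net.target_rxn}
            and rid not in exch
        ):
            flags.append("no_knockout")
        lines.append(
            f"{rid}\t{_format_equation(coeffs)}\t{net.lb[j]:.17g}\t{net.ub[j]:.17g}\t"
            + ",".join(flags)
        )
    return "\n".join(lines) + "\n"


def write_model(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_model_string(net))


# ---------------------------------------------------------------------------
# knockout-candidate policy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidatePolicy:
    """Which reactions may be knocked out.

    Designated reactions (biomass, glucose, target) are always excluded.
    ``exclude_exchanges`` drops boundary reactions; ``allow``/``deny`` are
    explicit id lists applied last.
    """

    exclude_exchanges: bool = True
    allow: frozenset[str] | None = None
    deny: frozenset[str] = frozenset()


def candidate_knockouts(
    net: MetabolicNetwork, policy: CandidatePolicy | None = None
) -> frozenset[str]:
    policy = policy or CandidatePolicy()
    known = set(net.reaction_ids)
    for rid in (policy.allow or set()) | set(policy.deny):
        if rid not in known:
            raise ModelValidationError(f"candidate policy references unknown reaction {rid!r}")
    cands = set(net.reaction_ids)
    cands -= {net.biomass_rxn, net.glucose_rxn, net.target_rxn}
    if policy.exclude_exchanges:
        cands -= net.exchange_reactions()
    if policy.allow is not None:
        cands &= set(policy.allow)
    cands -= set(policy.deny)
    return frozenset(cands)


# ---------------------------------------------------------------------------
# synthetic fixture generator
# ---------------------------------------------------------------------------


def generate_toy_network(
    n_internal: int,
    seed: int,
    *,
    uptake: float = 10.0,
    min_biomass: float = 1.0,
    max_retries: int = 20,
) -> MetabolicNetwork:
    """Generate a small mass-conserving network with branched pathways.

    The fixed backbone routes a substrate A either through a growth branch
    (A -> B -> D, with D feeding the biomass drain) or through a production
    branch (A -> g C + (1-g) D, C -> P, with P secreted as the target).
    Growth-maximizing wild types use the B branch exclusively, so deleting a
    growth-branch reaction reroutes flux toward the target — the phenotype
    the knockout optimizer must discover.  ``n_internal - 4`` additional
    internal conversions (some reversible) are drawn at random to create
    alternate routes; every reaction conserves unit mass, so no
    flux-generating loops can arise.

    Deterministic for a given ``(n_internal, seed)``.  Feasibility (an FBA
    optimum with biomass >= ``min_biomass`` at the fixed uptake) is verified
    by LP; on the rare failing draw the generator retries with a derived
    sub-seed and raises after ``max_retries``.
    """
    if n_internal < 4:
        raise ValueError("n_internal must be >= 4")
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        net = _build_toy(n_internal, rng, uptake)
        spec = ProblemSpec(v_glc_uptake=uptake, v_biom_target=min_biomass, K=0)
        try:
            net.validate(spec)
        except ModelValidationError:
            continue
        if _fba_feasible(net, spec):
            return net
    raise RuntimeError(
        f"could not generate a feasible toy network for seed {seed} "
        f"after {max_retries} attempts"
    )


def _build_toy(n_internal: int, rng: np.random.Generator, uptake: float) -> MetabolicNetwork:
    big = 3.0 * uptake
    g = rng.choice([0.5, 0.6, 0.75])
    d1 = rng.choice([1.0, 2.0])

    mets = ["A", "B", "C", "D", "P"]
    # (id, {met: coeff}, lb, ub)
    reactions: list[tuple[str, dict[str, float], float, float]] = [
        ("GLC_IN", {"A": 1.0}, 0.0, 2.0 * uptake),
        ("R_AB", {"A": -1.0, "B": 1.0}, 0.0, big),
        ("R_BD", {"B": -1.0, "D": 1.0}, 0.0, big),
        ("R_AC", {"A": -1.0, "C": g, "D": 1.0 - g}, 0.0, big),
        ("R_CP", {"C": -1.0, "P": 1.0}, 0.0, big),
        ("BIOMASS", {"D": -d1}, 0.0, big),
        ("EX_P", {"P": -1.0}, 0.0, big),
    ]
    internal_pool = ["B", "C", "D"]
    sinks = ["B", "C", "D", "P"]
    existing = {rid for rid, *_ in reactions}
    n_extra = n_internal - 4
    k = 0
    guard = 0
    while k < n_extra and guard < 200:
        guard += 1
        src = rng.choice(internal_pool)
        dst = rng.choice(sinks)
        if dst == src:
            continue
        rid = f"R{k + 1}_{src}{dst}"
        if rid in existing:
            continue
        coeffs = {src: -1.0, dst: 1.0}
        if rng.random() < 0.35 and dst != "P":
            # split product: conserve unit mass across two sinks
            alt = rng.choice([m for m in sinks if m not in (src, dst)])
            h = rng.choice([0.5, 0.75])
            coeffs = {src: -1.0, dst: h, alt: 1.0 - h}
        lb = -big if (rng.random() < 0.25 and "P" not in coeffs) else 0.0
        reactions.append((rid, coeffs, lb, big))
        existing.add(rid)
        k += 1

    rxn_ids = [r[0] for r in reactions]
    midx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    for j, (_, coeffs, _, _) in enumerate(reactions):
        for met, c in coeffs.items():
            rows.append(midx[met])
            cols.append(j)
            vals.append(c)
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rxn_ids)))
    net = MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rxn_ids,
        S=S,
        lb=np.array([r[2] for r in reactions]),
        ub=np.array([r[3] for r in reactions]),
        biomass_rxn="BIOMASS",
        glucose_rxn="GLC_IN",
        target_rxn="EX_P",
        name=f"toy_n{n_internal}",
    )
    net.knockout_candidates = candidate_knockouts(net, CandidatePolicy())
    return net


def _fba_feasible(net: MetabolicNetwork, spec: ProblemSpec) -> bool:
    from momaknock.steady_state import InfeasibleModelError, solve_fba

    try:
        w = solve_fba(net, spec)
    except InfeasibleModelError:
        return False
    return bool(w[net.biomass_rxn] >= spec.v_biom_target - 1e-9)
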