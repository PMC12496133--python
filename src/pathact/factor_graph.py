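"""Per-sample ternary factor graphs over a pathway network.

Every pathway entity carries a hidden ternary *activity* state
(repressed -1, normal 0, activated +1).  Proteins whose gene appears in
the supplied omic observations additionally carry *dna* and *rna*
states, chained dna -> rna -> activity so that copy number perturbs
transcription and transcription perturbs activity.  Pathway
interactions wire entities together through regulation factors:

* transcript-level edges enter the target's rna variable (or its
  activity variable when the target has no rna layer);
* protein-level edges enter the target's activity variable;
* ``component`` edges make a complex the minimum of its sign-adjusted
  members (a complex needs all components);
* ``member`` edges make a family the maximum of its members (any member
  can act for the family).

A regulation factor puts probability ``1 - eps`` on the child matching
the deterministic combination of its parents (vote / min / max) and
``eps/2`` on each other state.  An observation factor puts ``1 - eta``
on the hidden state matching the observed one.  Parentless, unobserved
variables get uniform priors.

Inference is sum-product belief propagation: exact on acyclic graphs
(flooding without damping converges to the exact marginals there) and
damped loopy BP otherwise.  ``exact_posteriors`` provides a brute-force
enumeration oracle for small graphs.  The inferred pathway level (IPL)
of an entity is ``log10(p_activated / p_repressed)`` from its activity
marginal — positive when activation is more likely than repression.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pathway_io import (
    PathwayNetwork,
    MEMBERSHIP_RELATIONS,
    PROTEIN_RELATIONS,
    TRANSCRIPT_RELATIONS,
)

__all__ = [
    "Var",
    "InferenceOptions",
    "FactorNode",
    "FactorGraph",
    "PosteriorTable",
    "EMResult",
    "build_factor_graph",
    "expected_state",
    "infer_posteriors",
    "exact_posteriors",
    "compute_ipl",
    "infer_cohort_ipls",
    "fit_parameters_em",
]

#: variable id: (entity name, layer)
Var = tuple[str, str]

LAYERS = ("dna", "rna", "activity")
STATES = (-1, 0, 1)  # index 0, 1, 2
IPL_FLOOR = 1e-300
MAX_PARENTS = 9  # factor tables are dense 3^(k+1) arrays


@dataclass
class InferenceOptions:
    """Knobs for graph construction, BP, and EM.

    epsilon is the regulation mismatch probability, eta the observation
    noise probability.  ``membership_rules=False`` falls back to vote
    combination everywhere.  The EM tolerance/cap (1e-9 / 1e4) are also
    reused as the BP message tolerance and sweep cap.
    """

    epsilon: float = 0.1
    eta: float = 0.1
    membership_rules: bool = True
    em: bool = False
    em_tol: float = 1e-9
    em_max_iter: int = 10_000
    damping: float = 0.5
    bp_tol: float = 1e-9
    max_sweeps: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.epsilon < 1 and 0 < self.eta < 1):
            raise ValueError("epsilon and eta must be in (0, 1)")
        if self.bp_tol <= 0 or self.em_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_sweeps < 1 or self.em_max_iter < 1:
            raise ValueError("iteration caps must be >= 1")
        if not (0 <= self.damping < 1):
            raise ValueError("damping must be in [0, 1)")


@dataclass(frozen=True)
class FactorNode:
    """One factor: kind in {prior, observation, regulation}.

    For regulation factors the scope is (child, parent1, ...) with
    per-parent signs and a combination rule; observation factors record
    the observed ternary value.
    """

    kind: str
    scope: tuple[Var, ...]
    signs: tuple[int, ...] = ()
    rule: str = ""
    observed: int | None = None


@dataclass
class FactorGraph:
    """Bipartite variable/factor graph for one sample."""

    variables: list[Var]
    factors: list[FactorNode]
    sample_id: str | None = None
    n_ignored_observations: int = 0

    def validate(self) -> None:
        vset = set(self.variables)
        in_scope: set[Var] = set()
        for f in self.factors:
            for v in f.scope:
                if v not in vset:
                    raise ValueError(f"factor scope var {v} not declared")
                in_scope.add(v)
        orphans = vset - in_scope
        if orphans:
            raise ValueError(f"variables outside every factor scope: {orphans}")


@dataclass
class PosteriorTable:
    """Per-variable marginals (p_repressed, p_normal, p_activated)."""

    probs: dict[Var, np.ndarray]
    converged: bool = True
    n_sweeps: int = 0

    def activity(self, entity: str) -> np.ndarray:
        return self.probs[(entity, "activity")]

    def entities(self) -> list[str]:
        return sorted({v[0] for v in self.probs if v[1] == "activity"})


# ---------------------------------------------------------------------------
# deterministic combination core
# ---------------------------------------------------------------------------

def expected_state(
    parent_states: Sequence[int], signs: Sequence[int], rule: str
) -> int:
    """Deterministic child state for given sign-adjusted parent states.

    vote: sign of the signed sum (0 on ties); min/max: extremum of the
    sign-adjusted states (AND/OR semantics for complexes/families).
    """
    if len(parent_states) == 0:
        raise ValueError("expected_state needs at least one parent")
    if len(parent_states) != len(signs):
        raise ValueError("parent_states and signs must have equal length")
    adj = [s * x for s, x in zip(signs, parent_states)]
    if rule == "vote":
        return int(np.sign(sum(adj)))
    if rule == "min":
        return int(min(adj))
    if rule == "max":
        return int(max(adj))
    raise ValueError(f"unknown combination rule {rule!r}")


def _match_mask(signs: tuple[int, ...], rule: str) -> np.ndarray:
    """Boolean (3,)*(k+1) mask: child (axis 0) equals expected(parents)."""
    k = len(signs)
    combos = np.array(list(itertools.product(STATES, repeat=k)), dtype=int)
    adj = combos * np.asarray(signs)[None, :]
    if rule == "vote":
        exp = np.sign(adj.sum(axis=1))
    elif rule == "min":
        exp = adj.min(axis=1)
    elif rule == "max":
        exp = adj.max(axis=1)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    child = np.array(STATES)[:, None]  # (3, 3^k)
    mask = child == exp[None, :]
    return mask.reshape((3,) + (3,) * k)


def _regulation_table(signs: tuple[int, ...], rule: str, eps: float) -> np.ndarray:
    mask = _match_mask(signs, rule)
    return np.where(mask, 1.0 - eps, eps / 2.0)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def _observed_gene_universe(net: PathwayNetwork, *columns) -> set[str]:
    proteins = set(net.proteins())
    genes: set[str] = set()
    for col in columns:
        if col is not None:
            genes.update(str(g) for g in col.index)
    return genes & proteins


def _count_ignored(net: PathwayNetwork, *columns) -> int:
    """Non-missing observations whose gene is absent from the network."""
    proteins = set(net.proteins())
    n = 0
    for col in columns:
        if col is None:
            continue
        outside = [g for g in col.index if str(g) not in proteins]
        if outside:
            block = col.loc[outside]
            n += int(np.asarray(block.notna()).sum())
    return n


@dataclass
class _Structure:
    """Network-level wiring shared by every sample of a cohort."""

    variables: list[Var]
    var_index: dict[Var, int]
    # regulation factors: (child_idx, parent_idxs, signs, rule)
    regulations: list[tuple[int, tuple[int, ...], tuple[int, ...], str]]
    prior_vars: list[int]
    # observation slots: (var_idx, omic in {cna, rna}, gene)
    obs_slots: list[tuple[int, str, str]]


def _build_structure(
    net: PathwayNetwork,
    layered_genes: set[str],
    opts: InferenceOptions,
) -> _Structure:
    variables: list[Var] = []
    var_index: dict[Var, int] = {}

    def add_var(v: Var) -> int:
        if v not in var_index:
            var_index[v] = len(variables)
            variables.append(v)
        return var_index[v]

    for name in sorted(net.entities):
        if name in layered_genes:
            for layer in LAYERS:
                add_var((name, layer))
        else:
            add_var((name, "activity"))

    # collect sign-adjusted parents per child variable, tagged by relation class
    parents: dict[int, list[tuple[int, int, str]]] = {}

    def add_parent(child: Var, parent: Var, sign: int, kind: str) -> None:
        if child == parent:
            # a self-regulation edge would place one variable twice in a
            # factor scope; flag and drop it rather than mis-wire the factor
            warnings.warn(
                f"self-regulation on {child[0]} dropped from the factor graph",
                stacklevel=3,
            )
            return
        parents.setdefault(var_index[child], []).append(
            (var_index[parent], sign, kind)
        )

    # central-dogma chain for layered proteins
    for g in sorted(layered_genes):
        add_parent((g, "rna"), (g, "dna"), +1, "regulatory")
        add_parent((g, "activity"), (g, "rna"), +1, "regulatory")

    for it in net.interactions:
        src = (it.source, "activity")
        if it.relation in TRANSCRIPT_RELATIONS:
            tgt_layer = "rna" if it.target in layered_genes else "activity"
            add_parent((it.target, tgt_layer), src, it.sign, "regulatory")
        elif it.relation in PROTEIN_RELATIONS:
            add_parent((it.target, "activity"), src, it.sign, "regulatory")
        elif it.relation in MEMBERSHIP_RELATIONS:
            add_parent((it.target, "activity"), src, it.sign, it.relation)
        else:  # pragma: no cover - closed vocabulary
            raise AssertionError(it.relation)

    regulations: list[tuple[int, tuple[int, ...], tuple[int, ...], str]] = []
    for child_idx in sorted(parents):
        plist = parents[child_idx]
        if len(plist) > MAX_PARENTS:
            raise ValueError(
                f"variable {variables[child_idx]} has {len(plist)} parents; "
                f"dense factor tables support at most {MAX_PARENTS}"
            )
        kinds = {kind for _, _, kind in plist}
        if not opts.membership_rules:
            rule = "vote"
        elif "component" in kinds:
            rule = "min"
        elif "member" in kinds:
            rule = "max"
        else:
            rule = "vote"
        pidx = tuple(p for p, _, _ in plist)
        signs = tuple(s for _, s, _ in plist)
        regulations.append((child_idx, pidx, signs, rule))

    children = {c for c, _, _, _ in regulations}
    prior_vars = [i for i in range(len(variables)) if i not in children]

    obs_slots = []
    for g in sorted(layered_genes):
        obs_slots.append((var_index[(g, "dna")], "cna", g))
        obs_slots.append((var_index[(g, "rna")], "rna", g))
    return _Structure(variables, var_index, regulations, prior_vars, obs_slots)


def build_factor_graph(
    net: PathwayNetwork,
    cna: pd.Series | None,
    rna: pd.Series | None,
    opts: InferenceOptions | None = None,
    sample_id: str | None = None,
) -> FactorGraph:
    """Factor graph for one sample's ternary CNA/RNA observation columns.

    Proteins whose gene appears in either observation index get the
    three-layer chain; observation factors attach only where the state
    is non-missing.  Observations for genes absent from the network are
    ignored with a warning (counted on the returned graph).
    """
    opts = opts or InferenceOptions()
    layered = _observed_gene_universe(net, cna, rna)
    n_ignored = _count_ignored(net, cna, rna)
    if n_ignored:
        warnings.warn(
            f"{n_ignored} observation(s) for genes absent from the network "
            "were ignored",
            stacklevel=2,
        )
    st = _build_structure(net, layered, opts)

    factors: list[FactorNode] = []
    for child_idx, pidx, signs, rule in st.regulations:
        scope = (st.variables[child_idx],) + tuple(st.variables[i] for i in pidx)
        factors.append(
            FactorNode(kind="regulation", scope=scope, signs=signs, rule=rule)
        )
    for i in st.prior_vars:
        factors.append(FactorNode(kind="prior", scope=(st.variables[i],)))
    for var_idx, omic, gene in st.obs_slots:
        col = cna if omic == "cna" else rna
        if col is None or gene not in col.index:
            continue
        val = col.loc[gene]
        if pd.isna(val):
            continue
        factors.append(
            FactorNode(
                kind="observation",
                scope=(st.variables[var_idx],),
                observed=int(val),
            )
        )
    fg = FactorGraph(
        variables=list(st.variables),
        factors=factors,
        sample_id=sample_id,
        n_ignored_observations=n_ignored,
    )
    fg.validate()
    return fg


# ---------------------------------------------------------------------------
# belief propagation engine (batched over samples)
# ---------------------------------------------------------------------------

def _obs_unary(states: np.ndarray, eta: float) -> np.ndarray:
    """(B,) ternary/NaN observations -> (B, 3) local potentials."""
    B = states.shape[0]
    out = np.ones((B, 3))
    seen = ~np.isnan(states)
    if seen.any():
        idx = (states[seen] + 1).astype(int)
        block = np.full((seen.sum(), 3), eta / 2.0)
        block[np.arange(len(idx)), idx] = 1.0 - eta
        out[seen] = block
    return out


def _fg_to_engine(fg: FactorGraph, opts: InferenceOptions):
    """Split an explicit graph into regulation structure + unary locals."""
    var_index = {v: i for i, v in enumerate(fg.variables)}
    V = len(fg.variables)
    local = np.ones((V, 1, 3))
    regs: list[tuple[tuple[int, ...], tuple[int, ...], str]] = []
    for f in fg.factors:
        if f.kind == "regulation":
            idxs = tuple(var_index[v] for v in f.scope)
            regs.append((idxs, f.signs, f.rule))
        elif f.kind == "prior":
            local[var_index[f.scope[0]]] *= 1.0 / 3.0
        elif f.kind == "observation":
            s = np.array([float(f.observed)])
            local[var_index[f.scope[0]], :, :] *= _obs_unary(s, opts.eta)
        else:
            raise ValueError(f"unknown factor kind {f.kind!r}")
    return regs, local


def _is_acyclic(n_vars: int, regs) -> bool:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n_vars))
    for fi, (idxs, _, _) in enumerate(regs):
        fnode = ("f", fi)
        for v in set(idxs):
            g.add_edge(fnode, v)
        if len(set(idxs)) < len(idxs):
            return False  # repeated variable in one scope forms a cycle
    return nx.is_forest(g)


class _BPResult:
    __slots__ = ("beliefs", "msgs", "converged", "n_sweeps")

    def __init__(self, beliefs, msgs, converged, n_sweeps):
        self.beliefs = beliefs
        self.msgs = msgs
        self.converged = converged
        self.n_sweeps = n_sweeps


def _run_bp(
    regs: list[tuple[tuple[int, ...], tuple[int, ...], str]],
    local: np.ndarray,
    opts: InferenceOptions,
) -> _BPResult:
    """Synchronous (flooding) sum-product over the regulation factors.

    ``local`` is (V, B, 3): the product of each variable's unary
    potentials, batched over B samples.  On acyclic graphs damping is
    dropped, which makes flooding converge to the exact marginals.
    """
    V, B, _ = local.shape
    tables = [
        _regulation_table(signs, rule, opts.epsilon) for _, signs, rule in regs
    ]
    if not regs:
        beliefs = local / local.sum(axis=2, keepdims=True)
        return _BPResult(beliefs, [], True, 0)

    damping = 0.0 if _is_acyclic(V, regs) else opts.damping

    # message bookkeeping: per factor, per scope position, a (B, 3) array
    msgs = [
        [np.full((B, 3), 1.0 / 3.0) for _ in idxs] for (idxs, _, _) in regs
    ]
    incoming: dict[int, list[tuple[int, int]]] = {v: [] for v in range(V)}
    for fi, (idxs, _, _) in enumerate(regs):
        for pos, v in enumerate(idxs):
            incoming[v].append((fi, pos))

    letters = "abcdefghijkl"
    ein: list[list[str]] = []
    for idxs, _, _ in regs:
        k = len(idxs)
        subs = letters[:k]
        per_factor = []
        for j in range(k):
            ins = [subs] + ["z" + subs[i] for i in range(k) if i != j]
            per_factor.append(",".join(ins) + "->z" + subs[j])
        ein.append(per_factor)

    converged = False
    n_sweeps = 0
    for sweep in range(opts.max_sweeps):
        n_sweeps = sweep + 1
        # variable beliefs under current messages
        P = local.copy()
        for fi, (idxs, _, _) in enumerate(regs):
            for pos, v in enumerate(idxs):
                P[v] *= msgs[fi][pos]
        P /= np.maximum(P.sum(axis=2, keepdims=True), IPL_FLOOR)

        delta = 0.0
        new_msgs = []
        for fi, (idxs, _, _) in enumerate(regs):
            T = tables[fi]
            k = len(idxs)
            vmsgs = []
            for pos, v in enumerate(idxs):
                m = P[v] / np.maximum(msgs[fi][pos], IPL_FLOOR)
                m /= np.maximum(m.sum(axis=1, keepdims=True), IPL_FLOOR)
                vmsgs.append(m)
            outs = []
            for j in range(k):
                operands = [T] + [vmsgs[i] for i in range(k) if i != j]
                out = np.einsum(ein[fi][j], *operands)
                out /= np.maximum(out.sum(axis=1, keepdims=True), IPL_FLOOR)
                if damping > 0:
                    out = damping * msgs[fi][j] + (1.0 - damping) * out
                delta = max(delta, float(np.abs(out - msgs[fi][j]).max()))
                outs.append(out)
            new_msgs.append(outs)
        msgs = new_msgs
        if delta < opts.bp_tol:
            converged = True
            break

    beliefs = local.copy()
    for fi, (idxs, _, _) in enumerate(regs):
        for pos, v in enumerate(idxs):
            beliefs[v] *= msgs[fi][pos]
    beliefs /= np.maximum(beliefs.sum(axis=2, keepdims=True), IPL_FLOOR)
    return _BPResult(beliefs, msgs, converged, n_sweeps)


def _factor_beliefs(regs, tables, msgs, local, beliefs):
    """Joint belief over each regulation factor's scope (for EM / Bethe)."""
    out = []
    letters = "abcdefghijkl"
    for fi, (idxs, _, _) in enumerate(regs):
        T = tables[fi]
        k = len(idxs)
        subs = letters[:k]
        vmsgs = []
        for pos, v in enumerate(idxs):
            m = beliefs[v] / np.maximum(msgs[fi][pos], IPL_FLOOR)
            m /= np.maximum(m.sum(axis=1, keepdims=True), IPL_FLOOR)
            vmsgs.append(m)
        spec = ",".join([subs] + ["z" + c for c in subs]) + "->z" + subs
        bf = np.einsum(spec, T, *vmsgs)
        bf /= np.maximum(
            bf.reshape(bf.shape[0], -1).sum(axis=1), IPL_FLOOR
        ).reshape((-1,) + (1,) * k)
        out.append(bf)
    return out


def infer_posteriors(
    fg: FactorGraph, opts: InferenceOptions | None = None
) -> PosteriorTable:
    """Sum-product marginals for one sample's graph.

    Exact on acyclic graphs; damped loopy BP otherwise.  Non-convergence
    within the sweep cap is reported on the result, not raised.
    """
    opts = opts or InferenceOptions()
    regs, local = _fg_to_engine(fg, opts)
    res = _run_bp(regs, local, opts)
    if not res.converged:
        warnings.warn(
            f"loopy BP did not converge within {opts.max_sweeps} sweeps",
            stacklevel=2,
        )
    probs = {v: res.beliefs[i, 0, :].copy() for i, v in enumerate(fg.variables)}
    return PosteriorTable(probs=probs, converged=res.converged, n_sweeps=res.n_sweeps)


def exact_posteriors(
    fg: FactorGraph,
    max_vars: int = 12,
    opts: InferenceOptions | None = None,
) -> PosteriorTable:
    """Marginals by full enumeration of the 3^n joint table (test oracle).

    Independent of the message-passing path: multiplies every factor
    table into a dense joint and sums it out.  Refuses graphs above
    ``max_vars`` variables.
    """
    opts = opts or InferenceOptions()
    n = len(fg.variables)
    if n > max_vars:
        raise ValueError(
            f"exact enumeration refused: {n} variables > max_vars={max_vars}"
        )
    var_index = {v: i for i, v in enumerate(fg.variables)}
    joint = np.ones((3,) * n)
    for f in fg.factors:
        if f.kind == "regulation":
            T = _regulation_table(f.signs, f.rule, opts.epsilon)
        elif f.kind == "prior":
            T = np.full(3, 1.0 / 3.0)
        elif f.kind == "observation":
            T = np.full(3, opts.eta / 2.0)
            T[int(f.observed) + 1] = 1.0 - opts.eta
        else:
            raise ValueError(f.kind)
        axes = tuple(var_index[v] for v in f.scope)
        if len(set(axes)) != len(axes):
            raise ValueError("factor scope repeats a variable")
        T_full_shape = [3 if i in axes else 1 for i in range(n)]
        order = np.argsort(axes)
        T_sorted = np.transpose(T, axes=tuple(order)) if T.ndim > 1 else T
        joint = joint * T_sorted.reshape(T_full_shape)
    Z = joint.sum()
    probs = {}
    for v, i in var_index.items():
        marg = joint.sum(axis=tuple(j for j in range(n) if j != i))
        probs[v] = marg / Z
    return PosteriorTable(probs=probs, converged=True, n_sweeps=0)


def compute_ipl(post: PosteriorTable, floor: float = IPL_FLOOR) -> pd.Series:
    """Inferred pathway level per entity from its activity marginal.

    IPL = log10((p_activated + floor) / (p_repressed + floor)); the sign
    defines the downstream pathway state.
    """
    vals = {}
    for (name, layer), p in post.probs.items():
        if layer == "activity":
            vals[name] = float(np.log10((p[2] + floor) / (p[0] + floor)))
    return pd.Series(vals).sort_index()


# ---------------------------------------------------------------------------
# cohort inference (one structure, batched evidence)
# ---------------------------------------------------------------------------

def infer_cohort_ipls(
    net: PathwayNetwork,
    cna_states: pd.DataFrame | None,
    rna_states: pd.DataFrame | None,
    opts: InferenceOptions | None = None,
) -> tuple[pd.DataFrame, dict]:
    """IPLs for every entity x sample of a cohort.

    Builds the network wiring once and runs BP with the per-sample
    observation potentials batched, which is equivalent to running
    ``build_factor_graph`` + ``infer_posteriors`` per sample.
    """
    opts = opts or InferenceOptions()
    samples: list[str] = []
    for df in (cna_states, rna_states):
        if df is not None:
            for c in df.columns:
                if c not in samples:
                    samples.append(str(c))
    if not samples:
        raise ValueError("no samples in the supplied state matrices")

    layered = _observed_gene_universe(net, cna_states, rna_states)
    st = _build_structure(net, layered, opts)
    V, B = len(st.variables), len(samples)
    local = np.ones((V, B, 3))
    for i in st.prior_vars:
        local[i] *= 1.0 / 3.0
    for var_idx, omic, gene in st.obs_slots:
        df = cna_states if omic == "cna" else rna_states
        if df is None or gene not in df.index:
            continue
        row = df.loc[gene].reindex(samples).to_numpy(dtype=float)
        local[var_idx] *= _obs_unary(row, opts.eta)

    regs = [
        ((child,) + pidx, signs, rule)
        for child, pidx, signs, rule in st.regulations
    ]
    res = _run_bp(regs, local, opts)

    act_rows = []
    act_names = []
    for i, (name, layer) in enumerate(st.variables):
        if layer == "activity":
            act_names.append(name)
            p = res.beliefs[i]  # (B, 3)
            act_rows.append(np.log10((p[:, 2] + IPL_FLOOR) / (p[:, 0] + IPL_FLOOR)))
    ipl = pd.DataFrame(np.vstack(act_rows), index=act_names, columns=samples)
    ipl = ipl.sort_index()
    info = {
        "converged": res.converged,
        "n_sweeps": res.n_sweeps,
        "n_ignored_observations": _count_ignored(net, cna_states, rna_states),
        "n_variables": V,
        "n_samples": B,
    }
    return ipl, info


# ---------------------------------------------------------------------------
# EM for shared (epsilon, eta)
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    epsilon: float
    eta: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    hit_cap: bool = False


def _bethe_loglik(regs, tables, msgs, local, beliefs) -> float:
    """Bethe free-energy estimate of log P(evidence); exact on trees."""
    fbeliefs = _factor_beliefs(regs, tables, msgs, local, beliefs)
    V, B, _ = local.shape
    ll = np.zeros(B)
    degree = np.zeros(V, dtype=int)
    for idxs, _, _ in regs:
        for v in idxs:
            degree[v] += 1
    safe = lambda x: np.log(np.maximum(x, IPL_FLOOR))  # noqa: E731
    for fi, (idxs, _, _) in enumerate(regs):
        bf = fbeliefs[fi]
        T = tables[fi]
        k = len(idxs)
        flat = bf.reshape(B, -1)
        ll += (flat * (safe(T).reshape(1, -1) - safe(flat))).sum(axis=1)
    for v in range(V):
        b = beliefs[v]
        # combined unary potential term
        ll += (b * safe(local[v])).sum(axis=1)
        ll -= (b * safe(b)).sum(axis=1)
        ll += degree[v] * (b * safe(b)).sum(axis=1)
    return float(ll.sum())


def fit_parameters_em(
    graphs: Iterable[FactorGraph], opts: InferenceOptions | None = None
) -> EMResult:
    """EM for the shared regulation/observation noise (epsilon, eta).

    E-step runs BP per graph; M-step re-estimates epsilon from expected
    regulation mismatches and eta from expected observation mismatches.
    Stops when the log-likelihood change drops below ``em_tol`` or at
    the iteration cap; the trace is reported (monotone on acyclic
    graphs, where the likelihood is exact).
    """
    opts = opts or InferenceOptions()
    graphs = list(graphs)
    if not any(
        f.kind == "observation" for fg in graphs for f in fg.factors
    ):
        raise ValueError("EM requires at least one observation across the graphs")

    eps, eta = opts.epsilon, opts.eta
    trace: list[float] = []
    hit_cap = True
    n_iter = 0
    for it in range(opts.em_max_iter):
        n_iter = it + 1
        cur = InferenceOptions(
            epsilon=eps,
            eta=eta,
            membership_rules=opts.membership_rules,
            damping=opts.damping,
            bp_tol=opts.bp_tol,
            max_sweeps=opts.max_sweeps,
        )
        ll = 0.0
        mis_reg = 0.0
        n_reg = 0
        mis_obs = 0.0
        n_obs = 0
        for fg in graphs:
            regs, local = _fg_to_engine(fg, cur)
            res = _run_bp(regs, local, cur)
            tables = [
                _regulation_table(signs, rule, cur.epsilon)
                for _, signs, rule in regs
            ]
            ll += _bethe_loglik(regs, tables, res.msgs, local, res.beliefs)
            fbeliefs = _factor_beliefs(regs, tables, res.msgs, local, res.beliefs)
            for fi, (idxs, signs, rule) in enumerate(regs):
                mask = _match_mask(signs, rule)
                match_p = (fbeliefs[fi] * mask[None, ...]).reshape(
                    fbeliefs[fi].shape[0], -1
                ).sum(axis=1)
                mis_reg += float((1.0 - match_p).sum())
                n_reg += fbeliefs[fi].shape[0]
            var_index = {v: i for i, v in enumerate(fg.variables)}
            for f in fg.factors:
                if f.kind == "observation":
                    b = res.beliefs[var_index[f.scope[0]], 0, :]
                    mis_obs += 1.0 - float(b[int(f.observed) + 1])
                    n_obs += 1
        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < opts.em_tol:
            hit_cap = False
            break
        if n_reg:
            eps = float(np.clip(mis_reg / n_reg, 1e-6, 1 - 1e-6))
        if n_obs:
            eta = float(np.clip(mis_obs / n_obs, 1e-6, 1 - 1e-6))
    return EMResult(
        epsilon=eps, eta=eta, loglik_trace=trace, n_iter=n_iter, hit_cap=hit_cap
    )
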