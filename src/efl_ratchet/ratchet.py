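"""The elongation-factor ratchet: gene gain/loss dynamics with lethal states.

A lineage's gene content is a subset of {eEF1A, eEF1Balpha, EFL}.  Because
aminoacyl-tRNA delivery is essential, only contents that support translation
are viable: either EFL is present (it recharges without a GEF), or both
eEF1A and its exchange factor eEF1Balpha are.  Five of the eight subsets are
viable.  Gene loss proceeds at a per-gene rate ``loss_rate`` (lambda); EFL —
and only EFL — can additionally be (re)gained by horizontal transfer at rate
``hgt_rate`` (h) while absent.  Neither eEF1A nor eEF1Balpha has a gain
channel: once either is lost in the presence of EFL the ancestral
eEF1A:eEF1Balpha state is unreachable.  That irreversible step is the pawl of
the ratchet; a positive HGT rate makes the ratchet processive, re-arming it
in eEF1A+eEF1Balpha lineages.

Lethality is modelled as *rejection* by default: loss mutations that would
leave a lineage without any functional elongation system are purged by
selection and never fix, so the embedded Markov chain simply has no flux into
inviable states.  An alternative ``extinct`` policy lets such events occur
and kills the lineage — exploratory only, and excluded from the matrix-based
machinery.

An optional two-step divergence mode interposes a DIVERGENT (detectable but
nonfunctional) level between intact and absent, mirroring observed genes
caught mid-decay.

The module provides exact stochastic simulation along a phylogeny
(Gillespie waiting times per branch), the matching master-equation
propagator, pruning likelihoods for tip observations, and maximum-likelihood
recovery of (lambda, h).
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

__all__ = [
    "EEF1A",
    "EEF1BA",
    "EFL",
    "GENES",
    "GENE_NAMES",
    "ALL_STATES",
    "VIABLE_STATES",
    "viable",
    "state_name",
    "RatchetModel",
    "rate_matrix",
    "Event",
    "SimulatedHistory",
    "simulate",
    "simulate_branch",
    "propagate",
    "HistorySummary",
    "summarize",
    "tip_likelihood",
    "FitResult",
    "fit_rates",
]

# gene-content states are 3-bit subsets of {eEF1A, eEF1Balpha, EFL}
EEF1A, EEF1BA, EFL = 1, 2, 4
GENES = (EEF1A, EEF1BA, EFL)
GENE_NAMES = {EEF1A: "eEF1A", EEF1BA: "eEF1Ba", EFL: "EFL"}

ALL_STATES = tuple(range(8))


def viable(state: int) -> bool:
    """A gene content supports translation iff EFL is present, or both
    eEF1A and eEF1Balpha are."""
    return bool(state & EFL) or (state & (EEF1A | EEF1BA)) == (EEF1A | EEF1BA)


VIABLE_STATES = tuple(s for s in ALL_STATES if viable(s))  # (3, 4, 5, 6, 7)
_VIDX = {s: i for i, s in enumerate(VIABLE_STATES)}


def state_name(state: int) -> str:
    if state == 0:
        return "none"
    return "+".join(GENE_NAMES[g] for g in GENES if state & g)


@dataclass
class RatchetModel:
    """Rates and policy for the gain/loss process.

    loss_rate may be a single per-gene rate or a {gene: rate} mapping; rates
    are per unit branch length (branch lengths set the clock — the model has
    no absolute time unit).  Defaults are placeholders, not estimates: the
    survey data constrain no absolute rates.
    """

    loss_rate: float | dict[int, float] = 0.1
    hgt_rate: float = 0.0
    divergence_mode: str = "one_step"  # or "two_step"
    divergence_rate: float | None = None
    lethal_policy: str = "reject"  # or "extinct"
    root_state: int = EEF1A | EEF1BA | EFL

    def __post_init__(self) -> None:
        if self.divergence_mode not in ("one_step", "two_step"):
            raise ValueError(f"unknown divergence_mode {self.divergence_mode!r}")
        if self.lethal_policy not in ("reject", "extinct"):
            raise ValueError(f"unknown lethal_policy {self.lethal_policy!r}")
        if self.divergence_mode == "two_step" and self.divergence_rate is None:
            raise ValueError("two_step mode requires divergence_rate")
        for g in GENES:
            if self.gene_loss_rate(g) < 0:
                raise ValueError("loss rates must be >= 0")
        if self.hgt_rate < 0:
            raise ValueError("hgt_rate must be >= 0")
        if not viable(self.initial_state() if self.divergence_mode == "one_step"
                      else _two_step_functional(self.initial_state())):
            raise ValueError(f"root state {self.root_state} is not viable")

    def gene_loss_rate(self, gene: int) -> float:
        if isinstance(self.loss_rate, dict):
            return float(self.loss_rate.get(gene, 0.0))
        return float(self.loss_rate)

    def initial_state(self):
        """Root state in the model's native encoding."""
        if self.divergence_mode == "one_step":
            return self.root_state
        return tuple(2 if self.root_state & g else 0 for g in GENES)

    # ---- state-space interface (shared by simulate / matrix builders) ----

    def states(self) -> list:
        if self.divergence_mode == "one_step":
            return list(VIABLE_STATES)
        out = []
        for a in (0, 1, 2):
            for b in (0, 1, 2):
                for e in (0, 1, 2):
                    s = (a, b, e)
                    if viable(_two_step_functional(s)):
                        out.append(s)
        return out

    def transitions(self, state, include_lethal: bool = False):
        """Outgoing moves as (target, rate, kind, gene) tuples.

        Under rejection semantics moves into inviable states are absent;
        ``include_lethal`` re-adds them (for the extinct policy).
        """
        moves = []
        if self.divergence_mode == "one_step":
            for g in GENES:
                if state & g:
                    tgt = state & ~g
                    if viable(tgt) or include_lethal:
                        moves.append((tgt, self.gene_loss_rate(g), "loss", g))
            if not state & EFL and self.hgt_rate > 0:
                moves.append((state | EFL, self.hgt_rate, "gain", EFL))
            return moves
        # two_step: per-gene levels 2 (intact) -> 1 (divergent) -> 0 (absent)
        for i, g in enumerate(GENES):
            lvl = state[i]
            if lvl == 2:
                tgt = state[:i] + (1,) + state[i + 1 :]
                if viable(_two_step_functional(tgt)) or include_lethal:
                    moves.append((tgt, self.divergence_rate, "divergence", g))
            elif lvl == 1:
                tgt = state[:i] + (0,) + state[i + 1 :]
                moves.append((tgt, self.gene_loss_rate(g), "loss", g))
        if state[2] == 0 and self.hgt_rate > 0:
            moves.append((state[:2] + (2,), self.hgt_rate, "gain", EFL))
        return moves


def _two_step_functional(s: tuple) -> int:
    """Bitmask of genes that are intact (level 2) in a two-step state."""
    return sum(g for g, lvl in zip(GENES, s) if lvl == 2)


def rate_matrix(model: RatchetModel):
    """Generator matrix Q over viable states (rejection semantics).

    Returns (Q, states): Q[i, j] is the rate from states[i] to states[j];
    rows sum to zero.  Defined only for lethal_policy="reject" — under the
    extinct policy the process is not a Markov chain on the viable states.
    """
    if model.lethal_policy != "reject":
        raise ValueError("rate_matrix is defined only for lethal_policy='reject'")
    states = model.states()
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    q = np.zeros((n, n))
    for s in states:
        for tgt, rate, _, _ in model.transitions(s):
            q[idx[s], idx[tgt]] += rate
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q, states


@dataclass
class Event:
    branch: str
    time: float  # absolute time from the root
    kind: str  # "loss" | "gain" | "divergence" | "lethal"
    gene: int
    from_state: object
    to_state: object

    @property
    def gene_name(self) -> str:
        return GENE_NAMES[self.gene]


@dataclass
class SimulatedHistory:
    tree: dendropy.Tree
    model: RatchetModel
    events: list[Event]
    tip_states: dict  # tip label -> state (None for extinct lineages)
    seed: int

    def events_by_branch(self) -> dict[str, list[Event]]:
        out: dict[str, list[Event]] = {}
        for ev in self.events:
            out.setdefault(ev.branch, []).append(ev)
        return out


def _branch_id(node) -> str:
    """Stable branch identifier: the sorted tip labels of the clade below.

    Topology-preserving edits elsewhere in the tree leave this id — and hence
    the branch's random stream — unchanged.
    """
    tips = sorted(
        lf.taxon.label if lf.taxon else str(id(lf)) for lf in node.leaf_iter()
    )
    return "|".join(tips)


def _branch_rng(seed: int, branch: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(branch.encode())])


def simulate_branch(model: RatchetModel, state, t: float, rng, branch: str = "", t0: float = 0.0):
    """Gillespie simulation of one branch: (end_state, events).

    Waiting times are exponential in the total outgoing rate of the current
    state; an end state of None means the lineage went extinct (possible only
    under lethal_policy="extinct").
    """
    include_lethal = model.lethal_policy == "extinct"
    events: list[Event] = []
    elapsed = 0.0
    while True:
        moves = model.transitions(state, include_lethal=include_lethal)
        total = sum(r for _, r, _, _ in moves)
        if total <= 0:
            return state, events
        elapsed += rng.exponential(1.0 / total)
        if elapsed >= t:
            return state, events
        weights = np.array([r for _, r, _, _ in moves]) / total
        tgt, _, kind, gene = moves[rng.choice(len(moves), p=weights)]
        dead = include_lethal and not _is_viable_state(model, tgt)
        events.append(
            Event(branch, t0 + elapsed, "lethal" if dead else kind, gene, state, tgt)
        )
        if dead:
            return None, events
        state = tgt


def _is_viable_state(model: RatchetModel, state) -> bool:
    if model.divergence_mode == "one_step":
        return viable(state)
    return viable(_two_step_functional(state))


def simulate(model: RatchetModel, tree: dendropy.Tree, seed: int) -> SimulatedHistory:
    """One realization of the ratchet process along a tree.

    Children inherit their parent's end state; each branch draws from its own
    random stream derived from (seed, branch id), so the realization is
    deterministic given the seed and unaffected by reordering of unrelated
    clades.  Branch lengths must be positive (the root edge may be absent).
    """
    tree = tree.clone(depth=1)
    root = tree.seed_node
    start: dict = {root: (model.initial_state(), 0.0)}
    events: list[Event] = []
    tip_states: dict = {}
    for node in tree.preorder_node_iter():
        state, t0 = start[node]
        if node is not root:
            if node.edge.length is None or node.edge.length <= 0:
                raise ValueError(
                    f"branch above {_branch_id(node)!r} has nonpositive length"
                )
            if state is None:  # extinct ancestor
                end, t1 = None, t0 + node.edge.length
            else:
                bid = _branch_id(node)
                end, evs = simulate_branch(
                    model, state, node.edge.length, _branch_rng(seed, bid), bid, t0
                )
                events.extend(evs)
                t1 = t0 + node.edge.length
        else:
            end, t1 = state, t0
        if node.is_leaf():
            tip_states[node.taxon.label] = end
        else:
            for child in node.child_nodes():
                start[child] = (end, t1)
    events.sort(key=lambda e: (e.time, e.branch))
    return SimulatedHistory(tree=tree, model=model, events=events, tip_states=tip_states, seed=seed)


def propagate(model: RatchetModel, dist, t: float) -> np.ndarray:
    """Master-equation propagation of a state distribution along time t.

    dist is over ``model.states()`` (in that order) and must sum to 1; the
    return distribution does too (scaling-and-squaring matrix exponential).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    dist = np.asarray(dist, dtype=float)
    q, states = rate_matrix(model)
    if dist.shape != (len(states),):
        raise ValueError(f"distribution must have length {len(states)}")
    if not math.isclose(dist.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("distribution must sum to 1")
    out = dist @ expm(q * t)
    return np.clip(out, 0.0, None)


@dataclass
class HistorySummary:
    tip_state_freqs: dict
    n_tips: int
    n_extinct: int
    replacement_events: int  # eEF1A losses that occurred with EFL present
    co_maintained_tips: int  # tips carrying both EFL and eEF1A
    reversal_events: int  # gains of a gene previously lost on the same lineage
    efl_tip_fraction: float


def _has_gene(model: RatchetModel, state, gene: int, include_divergent: bool = True) -> bool:
    if state is None:
        return False
    if model.divergence_mode == "one_step":
        return bool(state & gene)
    lvl = state[GENES.index(gene)]
    return lvl == 2 or (include_divergent and lvl == 1)


def summarize(history: SimulatedHistory) -> HistorySummary:
    """Tip-state frequencies and ratchet event counts for one history.

    A *replacement* is an eEF1A loss (or divergence) while EFL is carried; a
    *reversal* is any gain of a gene that had already been lost on the same
    root-to-tip path — impossible for eEF1A/eEF1Balpha by construction, and
    impossible for EFL when the HGT rate is zero.
    """
    model = history.model
    freqs: dict = {}
    n_ext = 0
    co = 0
    for state in history.tip_states.values():
        key = "extinct" if state is None else state
        freqs[key] = freqs.get(key, 0) + 1
        if state is None:
            n_ext += 1
            continue
        if _has_gene(model, state, EFL) and _has_gene(model, state, EEF1A):
            co += 1

    repl = sum(
        1
        for ev in history.events
        if ev.gene == EEF1A
        and ev.kind in ("loss", "divergence", "lethal")
        and _has_gene(model, ev.from_state, EFL)
    )

    by_branch = history.events_by_branch()
    reversals = 0

    def walk(node, lost: frozenset):
        nonlocal reversals
        if node.parent_node is not None:
            for ev in by_branch.get(_branch_id(node), []):
                if ev.kind == "gain":
                    if ev.gene in lost:
                        reversals += 1
                        lost = lost - {ev.gene}
                elif ev.kind in ("loss", "lethal"):
                    lost = lost | {ev.gene}
        for child in node.child_nodes():
            walk(child, lost)

    walk(history.tree.seed_node, frozenset())

    n_tips = len(history.tip_states)
    efl_tips = sum(
        1 for s in history.tip_states.values() if s is not None and _has_gene(model, s, EFL)
    )
    return HistorySummary(
        tip_state_freqs=freqs,
        n_tips=n_tips,
        n_extinct=n_ext,
        replacement_events=repl,
        co_maintained_tips=co,
        reversal_events=reversals,
        efl_tip_fraction=efl_tips / n_tips if n_tips else 0.0,
    )


# ---------------------------------------------------------------------------
# likelihood machinery (one_step, rejection semantics)
# ---------------------------------------------------------------------------


def _compatible_states(model: RatchetModel, obs, divergent_as: str) -> list:
    """States consistent with one tip observation.

    An observation is a full state (int / two-step tuple) or a per-gene dict
    with tokens present / absent / divergent / '?' (unknown).
    """
    states = model.states()
    if not isinstance(obs, dict):
        if obs not in states:
            raise ValueError(f"observed state {obs!r} is not a viable model state")
        return [obs]
    name_to_gene = {v.lower(): k for k, v in GENE_NAMES.items()}
    name_to_gene.update({"eef1balpha": EEF1BA, "eef1bα": EEF1BA})
    spec: dict[int, str] = {}
    for key, tok in obs.items():
        gene = key if key in GENES else name_to_gene[str(key).lower()]
        spec[gene] = str(tok).lower()
    two_step = model.divergence_mode == "two_step"
    out = []
    for s in states:
        ok = True
        for gene, tok in spec.items():
            if tok in ("?", "unknown"):
                continue
            if two_step:
                # native three-level observation
                want = {"present": 2, "divergent": 1, "absent": 0}[tok]
                ok = s[GENES.index(gene)] == want
            else:
                if tok == "divergent":
                    tok = divergent_as
                ok = (tok == "present") == bool(s & gene)
            if not ok:
                break
        if ok:
            out.append(s)
    return out


def tip_likelihood(
    model: RatchetModel,
    tree: dendropy.Tree | Sequence[dendropy.Tree],
    tip_states: dict,
    divergent_as: str = "absent",
) -> float:
    """Log-likelihood of tip observations under the ratchet CTMC (pruning).

    Post-order pruning with a matrix exponential per branch; the root is
    fixed at the model's root state.  Partial observations (per-gene tokens
    with unknowns) are summed over their compatible states.  Returns -inf for
    impossible data.

    ``tree`` may be a sequence of trees — independent clades, each starting
    from the root state, e.g. replicate lineages sampled across a radiation —
    in which case their log-likelihoods add and ``tip_states`` covers all
    tips (labels must be unique across the forest).
    """
    if not isinstance(tree, dendropy.Tree):
        total = 0.0
        for subtree in tree:
            labels = {lf.taxon.label for lf in subtree.leaf_node_iter()}
            total += tip_likelihood(
                model, subtree, {k: v for k, v in tip_states.items() if k in labels},
                divergent_as,
            )
            if total == -math.inf:
                break
        return total
    q, states = rate_matrix(model)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    pmat_cache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        if t not in pmat_cache:
            pmat_cache[t] = expm(q * t)
        return pmat_cache[t]

    tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for label in tip_states:
        if label not in tree_tips:
            raise KeyError(f"tip {label!r} not in tree")
    missing = tree_tips - set(tip_states)
    if missing:
        raise KeyError(f"no observation for tip(s) {sorted(missing)}")

    log_scale = 0.0
    partial: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(n)
            for s in _compatible_states(model, tip_states[node.taxon.label], divergent_as):
                vec[idx[s]] = 1.0
        else:
            vec = np.ones(n)
            for child in node.child_nodes():
                t = child.edge.length
                if t is None or t < 0:
                    raise ValueError("tree branches need nonnegative lengths")
                vec = vec * (pmat(t) @ partial[child])
        m = vec.max()
        if m <= 0.0:
            return -math.inf
        log_scale += math.log(m)
        partial[node] = vec / m
    root_vec = partial[tree.seed_node]
    p_root = root_vec[idx[model.initial_state()]]
    if p_root <= 0.0:
        return -math.inf
    return log_scale + math.log(p_root)


@dataclass
class FitResult:
    loss_rate: float
    hgt_rate: float
    log_likelihood: float
    grid: "np.ndarray" = field(repr=False, default=None)
    grid_loss: "np.ndarray" = field(repr=False, default=None)
    grid_hgt: "np.ndarray" = field(repr=False, default=None)
    degenerate: bool = False
    message: str = ""


def fit_rates(
    tree: dendropy.Tree | Sequence[dendropy.Tree],
    tip_states: dict,
    bounds: tuple = ((1e-3, 10.0), (1e-3, 10.0)),
    n_grid: int = 8,
    root_state: int = EEF1A | EEF1BA | EFL,
    divergent_as: str = "absent",
    seed: int | None = None,
) -> FitResult:
    """Maximum-likelihood (loss_rate, hgt_rate) from tip presence/absence.

    A log-spaced profile grid locates the basin; a Nelder-Mead refinement in
    log-parameter space polishes the optimum.  Deterministic given settings
    (the seed is recorded for provenance only — nothing here is stochastic).
    ``tree`` may be a forest of independent clades (see tip_likelihood);
    replicate clades are what make the HGT rate well identified — a single
    tree is a single draw of the deep gain/loss history.
    """
    trees = [tree] if isinstance(tree, dendropy.Tree) else list(tree)
    n_tips = sum(1 for t in trees for _ in t.leaf_node_iter())
    if n_tips < 10:
        warnings.warn(f"fit_rates on {n_tips} tips: estimates will be unstable")

    (lo_l, hi_l), (lo_h, hi_h) = bounds
    grid_loss = np.geomspace(lo_l, hi_l, n_grid)
    grid_hgt = np.geomspace(lo_h, hi_h, n_grid)

    def loglik(lam: float, h: float) -> float:
        model = RatchetModel(loss_rate=lam, hgt_rate=h, root_state=root_state)
        return tip_likelihood(model, trees, tip_states, divergent_as=divergent_as)

    grid = np.array([[loglik(l, h) for h in grid_hgt] for l in grid_loss])
    finite = grid[np.isfinite(grid)]
    if finite.size == 0 or float(finite.max() - finite.min()) < 1e-9:
        warnings.warn("flat likelihood surface: degenerate fit")
        i, j = 0, 0
        return FitResult(
            loss_rate=float(grid_loss[i]),
            hgt_rate=float(grid_hgt[j]),
            log_likelihood=float(grid[i, j]),
            grid=grid,
            grid_loss=grid_loss,
            grid_hgt=grid_hgt,
            degenerate=True,
            message="flat likelihood surface",
        )
    i, j = np.unravel_index(np.nanargmax(np.where(np.isfinite(grid), grid, -np.inf)), grid.shape)

    def neg(x: np.ndarray) -> float:
        lam, h = np.exp(x)
        ll = loglik(lam, h)
        return -ll if math.isfinite(ll) else 1e12

    res = minimize(
        neg,
        x0=np.log([grid_loss[i], grid_hgt[j]]),
        method="Nelder-Mead",
        bounds=[(math.log(lo_l), math.log(hi_l)), (math.log(lo_h), math.log(hi_h))],
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
    )
    lam, h = np.exp(res.x)
    return FitResult(
        loss_rate=float(lam),
        hgt_rate=float(h),
        log_likelihood=float(-res.fun),
        grid=grid,
        grid_loss=grid_loss,
        grid_hgt=grid_hgt,
        degenerate=False,
        message=res.message,
    )
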