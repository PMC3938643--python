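"""Independent oracles used across the test suite.

Everything here is deliberately brute-force: exact rational enumeration for
the 2x2 test, explicit state-sum marginalization for tree likelihoods, and
event-log replay for simulated histories.  None of it shares code with the
implementation paths it checks (beyond the generator-matrix definition,
which is the model itself).
"""

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
from scipy.linalg import expm

from efl_ratchet import ratchet


@lru_cache(maxsize=None)
def _hypergeom_pmfs(n: int, r1: int, c1: int):
    """Exact point probabilities for all 2x2 tables with margins (r1, n-r1 | c1)."""
    r2 = n - r1
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    return {
        a: Fraction(comb(r1, a) * comb(r2, c1 - a), denom) for a in range(lo, hi + 1)
    }


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration with exact rationals."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    pmfs = _hypergeom_pmfs(n, r1, c1)
    obs = pmfs[a]
    return sum((p for p in pmfs.values() if p <= obs), Fraction(0))


def brute_force_tip_loglik(model, tree, tip_states) -> float:
    """Likelihood by explicit summation over all internal-node states."""
    q, states = ratchet.rate_matrix(model)
    idx = {s: i for i, s in enumerate(states)}
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf() and nd is not tree.seed_node]
    leaves = [nd for nd in nodes if nd.is_leaf()]
    pmats = {
        nd: expm(q * nd.edge.length) for nd in nodes if nd is not tree.seed_node
    }
    root_idx = idx[model.initial_state()]
    total = 0.0
    assignments = [[s] for s in states]

    def rec(i, chosen):
        nonlocal total
        if i == len(internal):
            assign = dict(zip(internal, chosen))
            assign[tree.seed_node] = states[root_idx]
            prob = 1.0
            for nd in internal + leaves:
                parent_state = assign[nd.parent_node]
                if nd.is_leaf():
                    obs = tip_states[nd.taxon.label]
                    compatible = (
                        [obs] if not isinstance(obs, dict) else None
                    )
                    if compatible is not None:
                        prob *= pmats[nd][idx[parent_state], idx[obs]]
                    else:
                        prob *= sum(
                            pmats[nd][idx[parent_state], idx[s]]
                            for s in ratchet._compatible_states(model, obs, "absent")
                        )
                else:
                    prob *= pmats[nd][idx[parent_state], idx[assign[nd]]]
            total += prob
            return
        for s in states:
            rec(i + 1, chosen + [s])

    rec(0, [])
    return float(np.log(total)) if total > 0 else float("-inf")


def replay_history(history) -> dict:
    """Recompute tip states by replaying the event log from the root state."""
    by_branch = history.events_by_branch()
    tips = {}

    def walk(node, state):
        if node.parent_node is not None:
            for ev in sorted(by_branch.get(ratchet._branch_id(node), []),
                             key=lambda e: e.time):
                assert ev.from_state == state, "event log inconsistent"
                state = None if ev.kind == "lethal" else ev.to_state
                if state is None:
                    break
        if node.is_leaf():
            tips[node.taxon.label] = state
        else:
            for child in node.child_nodes():
                walk(child, state)

    walk(history.tree.seed_node, history.model.initial_state())
    return tips
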