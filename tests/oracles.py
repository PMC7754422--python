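"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — plain
Floyd–Warshall, scalar probability formulas, exhaustive enumeration and
truncated-horizon expectimax — and shares no code path with the package
implementation it cross-checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

INF = float("inf")


# ---------------------------------------------------------------- graphs


def floyd_warshall(n: int, edges) -> list[list[float]]:
    dist = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for i, j in edges:
        dist[i][j] = dist[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


def closeness_oracle(n: int, edges, node: int) -> float:
    dist = floyd_warshall(n, edges)[node]
    reach = [d for d in dist if d < INF]
    total = sum(reach)
    return (len(reach) - 1) / total if total > 0 else 0.0


def centralization_oracle(n: int, edges) -> float:
    c = [closeness_oracle(n, edges, i) for i in range(n)]
    denom = (n - 1) * (n - 2) / (2 * n - 3)
    return sum(max(c) - ci for ci in c) / denom


# ------------------------------------------------------------- nestedness


def supports_form_chain(inc: np.ndarray) -> bool:
    """Perfect nestedness: site supports totally ordered by inclusion."""
    rows = [frozenset(np.flatnonzero(r)) for r in inc]
    for a, b in itertools.combinations(rows, 2):
        if not (a <= b or b <= a):
            return False
    return True


# --------------------------------------------------------------- dynamics


def node_triple_oracle(state, intervened, p_d, p_r, dev_strengths, res_strengths):
    """Scalar per-node kernel; strengths are lists over D / R neighbours."""
    if state == 1:
        return (0.0, 1.0, 0.0)
    if state == 2:
        return (0.0, 0.0, 1.0)
    stay_d = 1.0 - p_d
    for u in dev_strengths:
        stay_d *= 1.0 - u
    q_d = 1.0 - stay_d
    if not intervened:
        return (1.0 - q_d, q_d, 0.0)
    stay_r = 1.0 - p_r
    for u in res_strengths:
        stay_r *= 1.0 - u
    q_r = 1.0 - stay_r
    return ((1.0 - q_r) * (1.0 - q_d), (1.0 - q_r) * q_d, q_r)


def joint_distribution_oracle(states, action, edges, p_d, p_r, u_d, u_r):
    """Exhaustive joint one-step kernel over all 3^n successors.

    ``u_d`` / ``u_r`` are homogeneous strengths; ``states`` is the joint
    pre-step vector; returns {successor tuple: probability}.
    """
    n = len(states)
    nbrs = {i: [] for i in range(n)}
    for a, b in edges:
        nbrs[a].append(b)
        nbrs[b].append(a)
    triples = []
    for i in range(n):
        dev = [u_d for j in nbrs[i] if states[j] == 1]
        res = [u_r for j in nbrs[i] if states[j] == 2]
        triples.append(node_triple_oracle(states[i], action == i + 1, p_d, p_r, dev, res))
    out = {}
    for nxt in itertools.product((0, 1, 2), repeat=n):
        p = 1.0
        for i in range(n):
            p *= triples[i][nxt[i]]
        if p > 0.0:
            out[nxt] = p
    return out


# ----------------------------------------------------------------- planner


def species_covered(states, incidence) -> int:
    present = np.zeros(incidence.shape[1], dtype=bool)
    for i, s in enumerate(states):
        if s == 2:
            present |= incidence[i].astype(bool)
    return int(present.sum())


def finite_horizon_value_oracle(
    edges, incidence, p_d, p_r, u_d, u_r, gamma, cost, horizon
):
    """Optimal truncated-horizon value at every joint state, by expectimax.

    Reward accrues on the pre-transition state; one intervention (or no-op)
    per step.  Returns {state tuple: value}.  The truncation error is at
    most ``gamma**horizon * r_max / (1 - gamma)``.
    """
    n = incidence.shape[0]
    inc = np.asarray(incidence)

    @lru_cache(maxsize=None)
    def value(states, t):
        if t == 0:
            return 0.0
        best = -INF
        base = species_covered(states, inc)
        for action in range(n + 1):
            r = base - (cost if action else 0.0)
            dist = joint_distribution_oracle(states, action, edges, p_d, p_r, u_d, u_r)
            ev = sum(p * value(nxt, t - 1) for nxt, p in dist.items())
            best = max(best, r + gamma * ev)
        return best

    return {
        s: value(s, horizon) for s in itertools.product((0, 1, 2), repeat=n)
    }


def finite_horizon_policy_value_oracle(
    policy, edges, incidence, p_d, p_r, u_d, u_r, gamma, cost, horizon
):
    """Truncated-horizon value of a fixed state-indexed policy (same scheme)."""
    n = incidence.shape[0]
    inc = np.asarray(incidence)

    def encode(states):
        return sum(s * 3**i for i, s in enumerate(states))

    @lru_cache(maxsize=None)
    def value(states, t):
        if t == 0:
            return 0.0
        action = int(policy[encode(states)])
        r = species_covered(states, inc) - (cost if action else 0.0)
        dist = joint_distribution_oracle(states, action, edges, p_d, p_r, u_d, u_r)
        return r + gamma * sum(p * value(nxt, t - 1) for nxt, p in dist.items())

    return {s: value(s, horizon) for s in itertools.product((0, 1, 2), repeat=n)}
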