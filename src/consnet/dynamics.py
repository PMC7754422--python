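"""Stochastic state dynamics of actors on the network.

Every actor/site is in one of three states — available (A), developed (D)
or reserved (R); D and R are absorbing.  An available actor develops with
an independent-cascade hazard combining its intrinsic propensity ``p_d``
with the influence of already-developed neighbours, and (only when targeted
by an intervention) reserves with the analogous hazard built from ``p_r``
and reserved neighbours:

    q_d = 1 - (1 - p_d) * prod_j (1 - u_d,ij)   over developed neighbours j
    q_r = 1 - (1 - p_r) * prod_j (1 - u_r,ij)   over reserved neighbours j

With homogeneous strengths the products collapse to ``(1-u_d)^n_d`` and
``(1-u_r)^n_r``.  When both latent events fire in an intervened step the
reserve event takes precedence (the intervention actively facilitates it):
P(A->R) = q_r, P(A->D) = (1-q_r) q_d, P(A->A) = (1-q_r)(1-q_d).  Without an
intervention p_r and u_r are inactive, so reservation is impossible.

All nodes update synchronously: every per-node kernel is conditioned on the
same pre-step joint state, as in standard cascade models of behaviour
spread.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import IntEnum
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .planner import DecisionModel

__all__ = [
    "NodeState",
    "BehaviorParams",
    "NeighborhoodContext",
    "TransitionTriple",
    "node_transition_distribution",
    "neighborhood_context",
    "system_transition_distribution",
    "simulate_trajectory",
]


class NodeState(IntEnum):
    """Three-state actor/site status; the integer codes are the base-3 digits."""

    AVAILABLE = 0
    DEVELOPED = 1
    RESERVED = 2


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioural probabilities shared by all actors.

    ``p_d`` / ``p_r``: intrinsic (network-independent) develop / reserve
    propensities per step; ``u_d`` / ``u_r``: default link strengths used
    when constructing homogeneous networks (per-link values on an
    :class:`~consnet.networks.ActorNetwork` override them).
    """

    p_d: float = 0.2
    p_r: float = 0.2
    u_d: float = 0.0
    u_r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_d", "p_r", "u_d", "u_r"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class NeighborhoodContext:
    """Influence context of one available node given the joint state.

    ``developed_stay`` = prod (1 - u_d,ij) over developed neighbours;
    ``reserved_stay`` = prod (1 - u_r,ij) over reserved neighbours;
    ``intervened`` marks whether this node is the intervention target.
    """

    developed_stay: float
    reserved_stay: float
    intervened: bool = False

    def __post_init__(self) -> None:
        for name in ("developed_stay", "reserved_stay"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class TransitionTriple:
    """One-step distribution (P_AA, P_AD, P_AR) for a single node."""

    p_aa: float
    p_ad: float
    p_ar: float

    def __post_init__(self) -> None:
        probs = (self.p_aa, self.p_ad, self.p_ar)
        if min(probs) < -1e-12 or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"invalid transition triple {probs}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_aa, self.p_ad, self.p_ar])


def node_transition_distribution(
    state: NodeState,
    ctx: NeighborhoodContext,
    params: BehaviorParams,
) -> TransitionTriple:
    """Per-node transition kernel; developed and reserved are absorbing."""
    if state == NodeState.DEVELOPED:
        return TransitionTriple(0.0, 1.0, 0.0)
    if state == NodeState.RESERVED:
        return TransitionTriple(0.0, 0.0, 1.0)
    q_d = 1.0 - (1.0 - params.p_d) * ctx.developed_stay
    if not ctx.intervened:
        return TransitionTriple(1.0 - q_d, q_d, 0.0)
    q_r = 1.0 - (1.0 - params.p_r) * ctx.reserved_stay
    return TransitionTriple((1.0 - q_r) * (1.0 - q_d), (1.0 - q_r) * q_d, q_r)


def neighborhood_context(
    states: Sequence[int],
    node: int,
    network,
    intervened: bool,
) -> NeighborhoodContext:
    """Read one node's influence context from the joint pre-step state."""
    ud = network.strength_matrix("u_d")
    ur = network.strength_matrix("u_r")
    dev_stay = 1.0
    res_stay = 1.0
    for j in network.neighbors(node):
        if states[j] == NodeState.DEVELOPED:
            dev_stay *= 1.0 - ud[node, j]
        elif states[j] == NodeState.RESERVED:
            res_stay *= 1.0 - ur[node, j]
    return NeighborhoodContext(dev_stay, res_stay, intervened)


def _node_triples(
    states: Sequence[int], action: int, model: "DecisionModel"
) -> list[np.ndarray]:
    triples = []
    for i in range(model.network.n_nodes):
        ctx = neighborhood_context(states, i, model.network, intervened=(action == i + 1))
        triples.append(
            node_transition_distribution(NodeState(states[i]), ctx, model.params).as_array()
        )
    return triples


def system_transition_distribution(
    state: int, action: int, model: "DecisionModel"
) -> dict[int, float]:
    """Joint one-step distribution as a sparse map ``next-state code -> prob``.

    Reference product-measure construction: the joint probability of a
    successor is the product of per-node kernel probabilities, every kernel
    conditioned on the pre-transition joint state, with the intervened flag
    set only on the targeted node.  Exponential in the number of available
    nodes; intended for small systems and as the oracle for the planner's
    vectorized transition matrices.
    """
    from .planner import decode_state, encode_state

    n = model.network.n_nodes
    if not (0 <= action <= n):
        raise ValueError(f"action {action} invalid for {n} nodes")
    states = decode_state(state, n)
    triples = _node_triples(states, action, model)
    supports = [np.flatnonzero(t > 0.0) for t in triples]
    out: dict[int, float] = {}
    for combo in itertools.product(*supports):
        p = 1.0
        for i, digit in enumerate(combo):
            p *= triples[i][digit]
        out[encode_state(list(combo))] = out.get(encode_state(list(combo)), 0.0) + p
    return out


def simulate_trajectory(
    model: "DecisionModel",
    policy,
    horizon: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, float]]:
    """Simulate one trajectory under a state-indexed policy.

    ``policy`` maps an encoded state to an action (an array indexed by state
    code or any callable/indexable).  Updates are synchronous: all nodes
    draw their next state from kernels conditioned on the same pre-step
    state.  Returns ``[(state, action, reward), ...]`` of length
    ``horizon``; the reward is accrued on the pre-transition state.
    """
    from .planner import decode_state, encode_state, reward

    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    n = model.network.n_nodes
    s = encode_state([NodeState.AVAILABLE] * n)
    out = []
    for _ in range(horizon):
        a = int(policy[s]) if hasattr(policy, "__getitem__") else int(policy(s))
        out.append((s, a, reward(s, a, model)))
        states = decode_state(s, n)
        triples = _node_triples(states, a, model)
        nxt = [int(rng.choice(3, p=t)) for t in triples]
        s = encode_state(nxt)
    return out
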