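"""Exact factored-MDP planner for sequencing conservation interventions.

The joint state of an ``n``-node network is the vector of node states,
encoded as a base-3 integer (node 0 least significant; A=0, D=1, R=2), so
the state space has ``3^n`` codes.  At each step the decision maker either
does nothing (action 0) or targets one actor ``i`` (action ``i+1``) for an
intervention.  The reward is the number of species represented in at least
one reserved site of the *pre-transition* state, less a notional cost ``c``
whenever an intervention is made.  Value iteration on the full state space
returns the optimal infinite-horizon discounted value; greedy extraction
and exact linear-system policy evaluation complete the toolkit.

The joint transition kernel factorizes over nodes, so per-action transition
matrices are assembled as elementwise products of per-node factor matrices
and stored sparse.  The exact method is exponential in ``n``; networks with
more than 8 nodes are refused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dynamics import BehaviorParams, NodeState
from .networks import ActorNetwork
from .species import SpeciesDistribution

__all__ = [
    "DecisionModel",
    "PlannerError",
    "ValueIterationResult",
    "MAX_EXACT_NODES",
    "encode_state",
    "decode_state",
    "all_state_digits",
    "reward",
    "reward_vector",
    "build_transition_matrices",
    "value_iteration",
    "q_values",
    "greedy_policy",
    "evaluate_policy_exact",
]

MAX_EXACT_NODES = 8

# Action ties are broken toward no-op, then the lowest node index; two Q
# values closer than this are treated as tied.
_TIE_TOL = 1e-9


class PlannerError(RuntimeError):
    """Raised on solver failure (non-convergence, oversized network, ...)."""


@dataclass(frozen=True)
class DecisionModel:
    """Network + species + behaviour + economic parameters: the full MDP.

    ``discount`` is the per-step factor gamma in (0, 1);
    ``intervention_cost`` is the notional cost ``c`` of one intervention in
    species-representation units.  The species site count must equal the
    network node count (site i belongs to actor i).
    """

    network: ActorNetwork
    species: SpeciesDistribution
    params: BehaviorParams
    discount: float = 0.95
    intervention_cost: float = 0.1

    def __post_init__(self) -> None:
        if self.species.n_sites != self.network.n_nodes:
            raise ValueError(
                f"species matrix has {self.species.n_sites} sites but the "
                f"network has {self.network.n_nodes} nodes"
            )
        if not (0.0 < self.discount < 1.0):
            raise ValueError("discount must lie in (0, 1)")
        if self.intervention_cost < 0.0:
            raise ValueError("intervention cost must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    @property
    def n_states(self) -> int:
        return 3 ** self.network.n_nodes

    @property
    def n_actions(self) -> int:
        return self.network.n_nodes + 1


def encode_state(states: Sequence[int]) -> int:
    """Encode per-node states as a base-3 integer, node 0 least significant."""
    code = 0
    for i, s in enumerate(states):
        if s not in (0, 1, 2):
            raise ValueError(f"invalid node state {s}")
        code += int(s) * 3**i
    return code


def decode_state(code: int, n: int) -> list[int]:
    """Inverse of :func:`encode_state` for an ``n``-node system."""
    if not (0 <= code < 3**n):
        raise ValueError(f"state code {code} out of range for {n} nodes")
    return [(code // 3**i) % 3 for i in range(n)]


def all_state_digits(n: int) -> np.ndarray:
    """(3^n, n) array of per-node state digits for every encoded state."""
    codes = np.arange(3**n)
    return np.stack([(codes // 3**i) % 3 for i in range(n)], axis=1)


def reward_vector(model: DecisionModel) -> np.ndarray:
    """Species represented in reserves, per encoded state (cost excluded)."""
    digits = all_state_digits(model.n_nodes)
    reserved = digits == NodeState.RESERVED
    covered = reserved @ model.species.incidence.astype(np.int64)  # (S, n_species)
    return (covered > 0).sum(axis=1).astype(float)


def reward(state: int, action: int, model: DecisionModel) -> float:
    """Reward of one (state, action) pair, accrued on the pre-transition state."""
    digits = np.array(decode_state(state, model.n_nodes))
    covered = (model.species.incidence[digits == NodeState.RESERVED].sum(axis=0) > 0).sum()
    cost = model.intervention_cost if action != 0 else 0.0
    return float(covered) - cost


def _node_factors(model: DecisionModel, digits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node kernels across all states: (no-op, intervened), each (n, S, 3)."""
    n = model.n_nodes
    s_count = digits.shape[0]
    ud = model.network.strength_matrix("u_d")
    ur = model.network.strength_matrix("u_r")
    p_d, p_r = model.params.p_d, model.params.p_r
    noop = np.empty((n, s_count, 3))
    intervened = np.empty((n, s_count, 3))
    for i in range(n):
        dev_stay = np.ones(s_count)
        res_stay = np.ones(s_count)
        for j in model.network.neighbors(i):
            dev_stay *= np.where(digits[:, j] == NodeState.DEVELOPED, 1.0 - ud[i, j], 1.0)
            res_stay *= np.where(digits[:, j] == NodeState.RESERVED, 1.0 - ur[i, j], 1.0)
        q_d = 1.0 - (1.0 - p_d) * dev_stay
        q_r = 1.0 - (1.0 - p_r) * res_stay
        for arr, qr in ((noop, np.zeros(s_count)), (intervened, q_r)):
            from_a = np.stack([(1 - qr) * (1 - q_d), (1 - qr) * q_d, qr], axis=1)
            arr[i] = from_a
            # absorbing rows overwrite the A-state kernel where needed
            dev_mask = digits[:, i] == NodeState.DEVELOPED
            res_mask = digits[:, i] == NodeState.RESERVED
            arr[i][dev_mask] = (0.0, 1.0, 0.0)
            arr[i][res_mask] = (0.0, 0.0, 1.0)
    return noop, intervened


def build_transition_matrices(model: DecisionModel) -> list[sp.csr_matrix]:
    """Sparse (3^n, 3^n) transition matrix per action, index = ActionId.

    The joint kernel is the product measure of per-node kernels conditioned
    on the pre-transition joint state; entry (s, s') is the elementwise
    product over nodes of the per-node probability of reaching s'-digit i.
    Assembled in row chunks to bound dense intermediates.
    """
    n = model.n_nodes
    if n > MAX_EXACT_NODES:
        raise PlannerError(
            f"exact planning materializes 3^n states; {n} nodes exceeds the "
            f"supported maximum of {MAX_EXACT_NODES}"
        )
    digits = all_state_digits(n)
    s_count = digits.shape[0]
    noop, intervened = _node_factors(model, digits)
    chunk = max(1, min(s_count, 2**21 // s_count + 1))
    mats: list[sp.csr_matrix] = []
    for action in range(n + 1):
        blocks = []
        for start in range(0, s_count, chunk):
            stop = min(start + chunk, s_count)
            block = np.ones((stop - start, s_count))
            for i in range(n):
                factor = intervened[i] if action == i + 1 else noop[i]
                block *= factor[start:stop][:, digits[:, i]]
            blocks.append(sp.csr_matrix(block))
        mat = sp.vstack(blocks, format="csr")
        mat.eliminate_zeros()
        mats.append(mat)
    return mats


@dataclass(frozen=True)
class ValueIterationResult:
    """Converged value function with solver diagnostics."""

    values: np.ndarray
    iterations: int
    residual: float

    def __getitem__(self, state: int) -> float:
        return float(self.values[state])


def _reward_matrix(model: DecisionModel) -> np.ndarray:
    base = reward_vector(model)
    r = np.tile(base[:, None], (1, model.n_actions))
    r[:, 1:] -= model.intervention_cost
    return r


def value_iteration(
    model: DecisionModel,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    mats: list[sp.csr_matrix] | None = None,
) -> ValueIterationResult:
    """Solve the MDP by value iteration to sup-norm Bellman residual ``tol``.

    Being a gamma-contraction the backup converges geometrically; failure
    to reach ``tol`` within ``max_iter`` sweeps raises :class:`PlannerError`
    with the last residual reported.
    """
    if mats is None:
        mats = build_transition_matrices(model)
    r = _reward_matrix(model)
    gamma = model.discount
    stacked = sp.vstack(mats, format="csr")  # ((n+1) * S, S)
    s_count, n_actions = model.n_states, model.n_actions
    v = np.zeros(s_count)
    for it in range(1, max_iter + 1):
        q = r + gamma * (stacked @ v).reshape(n_actions, s_count).T
        v_new = q.max(axis=1)
        residual = float(np.abs(v_new - v).max())
        v = v_new
        if residual <= tol:
            return ValueIterationResult(v, it, residual)
    raise PlannerError(
        f"value iteration did not reach tol={tol} in {max_iter} sweeps "
        f"(last residual {residual:.3e})"
    )


def q_values(
    model: DecisionModel,
    values: np.ndarray,
    mats: list[sp.csr_matrix] | None = None,
) -> np.ndarray:
    """(S, n_actions) one-step backup of a value function."""
    if mats is None:
        mats = build_transition_matrices(model)
    r = _reward_matrix(model)
    backed = np.stack([m @ values for m in mats], axis=1)
    return r + model.discount * backed


def greedy_policy(
    model: DecisionModel,
    values: "np.ndarray | ValueIterationResult",
    mats: list[sp.csr_matrix] | None = None,
) -> np.ndarray:
    """Greedy action per state; ties go to no-op, then the lowest node index."""
    v = values.values if isinstance(values, ValueIterationResult) else np.asarray(values)
    q = q_values(model, v, mats)
    best = q.max(axis=1)
    return np.argmax(q >= best[:, None] - _TIE_TOL, axis=1)


def evaluate_policy_exact(
    model: DecisionModel,
    policy: np.ndarray,
    mats: list[sp.csr_matrix] | None = None,
) -> np.ndarray:
    """Exact value of a stationary policy via the linear fixed point.

    Solves ``(I - gamma * P_pi) V = R_pi`` directly; for gamma < 1 the
    system is strictly diagonally dominant and always solvable.
    """
    policy = np.asarray(policy, dtype=int)
    if policy.shape != (model.n_states,) or (policy < 0).any() or (
        policy >= model.n_actions
    ).any():
        raise ValueError("policy must assign a valid action to every state")
    if mats is None:
        mats = build_transition_matrices(model)
    s_count = model.n_states
    rows = []
    order = []
    for a in range(model.n_actions):
        mask = policy == a
        if mask.any():
            rows.append(mats[a][mask])
            order.append(np.flatnonzero(mask))
    p_pi = sp.vstack(rows, format="csr")
    perm = np.empty(s_count, dtype=int)
    perm[np.concatenate(order)] = np.arange(s_count)
    p_pi = p_pi[perm]
    r_pi = _reward_matrix(model)[np.arange(s_count), policy]
    lhs = sp.eye(s_count, format="csc") - model.discount * p_pi.tocsc()
    return spla.spsolve(lhs, r_pi)
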