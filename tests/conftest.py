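import numpy as np
import pytest

from consnet.dynamics import BehaviorParams
from consnet.networks import ActorNetwork
from consnet.planner import DecisionModel
from consnet.species import SpeciesDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20200905)


def make_model(
    n_nodes,
    edges,
    incidence,
    p_d=0.2,
    p_r=0.2,
    u_d=0.5,
    u_r=0.5,
    gamma=0.8,
    cost=0.1,
):
    """Small decision model with homogeneous link strengths."""
    net = ActorNetwork.from_links(n_nodes, edges, u_r=u_r, u_d=u_d)
    dist = SpeciesDistribution(incidence=np.asarray(incidence, dtype=np.int8))
    params = BehaviorParams(p_d=p_d, p_r=p_r, u_d=u_d, u_r=u_r)
    return DecisionModel(
        network=net, species=dist, params=params, discount=gamma, intervention_cost=cost
    )


@pytest.fixture
def two_node_model():
    return make_model(2, [(0, 1)], [[1, 0], [0, 1]])


@pytest.fixture
def three_node_star_model():
    # node 0 is the hub; species concentrated off-hub
    incidence = [[1, 0, 0], [1, 1, 0], [0, 1, 1]]
    return make_model(3, [(0, 1), (0, 2)], incidence, u_d=0.8, u_r=0.8)
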