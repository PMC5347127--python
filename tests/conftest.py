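import warnings
from collections import Counter
from itertools import combinations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pccorrnet as pcn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


# ---------------------------------------------------------------------------
# independent oracles

def mwu_two_sided_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of assignments.

    p = P(|U - n1*n2/2| >= |U_obs - n1*n2/2|) under the permutation null.
    Assumes no ties.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    ranks_x = [pooled.index(v) for v in x]
    # U = (sum of 0-based pooled positions of x) - n1(n1-1)/2
    u_obs = sum(ranks_x) - n1 * (n1 - 1) // 2
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    count = total = 0
    for comb in combinations(range(n1 + n2), n1):
        u = sum(comb) - n1 * (n1 - 1) // 2
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


def bh_step_up_oracle(pvals):
    """Reference Benjamini-Hochberg step-up, executed literally."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return np.clip(adj, 0.0, 1.0)


# ---------------------------------------------------------------------------
# shared pipeline helper and fixtures

def run_pccorr(matrix, labels, cutoff=0.5):
    """Full-data PC-corr network via automatic PC selection.

    Returns (net, selection, pcc); net is None when no candidate component
    separates the groups.
    """
    sel = pcn.select_discriminative_pc(matrix, labels)
    if not sel.significant:
        return None, sel, None
    pca = pcn.fit_pca(matrix, sel.best.centering, k=sel.best.pc_index)
    nl = pcn.process_loadings(
        pca.loading_vector(sel.best.pc_index), matrix.feature_names
    )
    pcc = pcn.build_pccorr_matrix(matrix, nl)
    net = pcn.threshold_network(pcc, cutoff, data=matrix, labels=labels)
    return net, sel, pcc


@pytest.fixture(scope="session")
def and_gate_data():
    return pcn.generate(pcn.scenario_presets("and_gate", seed=1))


@pytest.fixture
def tiny_matrix():
    return pcn.OmicMatrix(
        [[1.0, 2.0, 0.5], [2.0, 4.0, 0.4], [3.0, 6.0, 0.9], [4.0, 8.0, 0.1]],
        ["s1", "s2", "s3", "s4"],
        ["f1", "f2", "f3"],
    )


def frustration_fixture():
    """3-node network: one frustrated positive edge between opposite-sign
    nodes, one correct positive edge, one correct negative edge."""
    names = ["n1", "n2", "n3"]
    v = np.array([1.0, 0.9, -0.95])
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.6   # (+,+) positive: fine
    W[0, 2] = W[2, 0] = 0.6   # (+,-) positive: frustrated
    W[1, 2] = W[2, 1] = -0.6  # (+,-) negative: fine
    return pcn.PCCorrMatrix(W, None, v, names)
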