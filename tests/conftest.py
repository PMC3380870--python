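"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized code paths: the
marginal score enumerates all (S+1)^E sparse attachments explicitly, and the
expected-complete-log-posterior maximizer enumerates all 2^(S(S-1)) graphs.
"""

import itertools

import numpy as np
import pytest

from mceminem.model import (
    AttachmentPrior,
    EdgePrior,
    LogOdds,
    SignalsGraph,
)


def enumerate_graphs(n_signals):
    """All binary unit-diagonal S x S adjacencies."""
    S = n_signals
    off = [(k, s) for k in range(S) for s in range(S) if k != s]
    for bits in itertools.product((0, 1), repeat=len(off)):
        adj = np.eye(S, dtype=np.int8)
        for (k, s), b in zip(off, bits):
            adj[k, s] = b
        yield adj


def brute_force_log_posterior(adj, R, nu, ep):
    """log sum over all joint sparse attachments of P(D|G,Theta) P(Theta), plus edge prior.

    Explicit enumeration over the (S+1)^E product space; the null target
    contributes exp(0) = 1.
    """
    E, S = R.shape
    total = 0.0
    for assignment in itertools.product(range(S + 1), repeat=E):
        term = 1.0
        for e, t in enumerate(assignment):
            if t == S:  # null node
                term *= nu[e, S]
            else:
                w = sum(adj[k, t] * R[e, k] for k in range(S))
                term *= nu[e, t] * np.exp(w)
        total += term
    prior = 0.0
    for k in range(S):
        for s in range(S):
            if k != s:
                prior += np.log(ep[k, s]) if adj[k, s] else np.log1p(-ep[k, s])
    return np.log(total) + prior


def expected_complete_log_posterior(adj, omega, R, ep):
    """Q(Gamma | omega) up to attachment-prior constants: linear part + edge prior."""
    E, S = R.shape
    q = 0.0
    for e in range(E):
        for s in range(S):
            w = sum(adj[k, s] * R[e, k] for k in range(S))
            q += omega[e, s] * w
    for k in range(S):
        for s in range(S):
            if k != s:
                q += np.log(ep[k, s]) if adj[k, s] else np.log1p(-ep[k, s])
    return q


def random_instance(rng, n_signals=None, n_effects=None, scale=2.0):
    """A random (graph, log-odds, prior, edge-prior) tuple for property tests."""
    S = n_signals or int(rng.integers(2, 4))
    E = n_effects or int(rng.integers(1, 5))
    adj = rng.integers(0, 2, size=(S, S)).astype(np.int8)
    np.fill_diagonal(adj, 1)
    g = SignalsGraph(adj)
    r = LogOdds(rng.normal(0, scale, size=(E, S)), None, g.labels)
    nu = rng.dirichlet(np.ones(S + 1), size=E)
    ep = rng.uniform(0.1, 0.9, size=(S, S))
    return g, r, AttachmentPrior(nu), EdgePrior(ep)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
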