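"""Mode-hopping Metropolis-Hastings over NEM signals graphs.

The chain's underlying state is a *raw* graph.  Proposals flip a few
off-diagonal adjacency entries of the raw graph (a symmetric proposal), each
proposal is mapped to its "nearest" local maximum by EM, and the Hastings
ratio is evaluated on the *mapped* graphs.  The recorded series of mapped
graphs is then approximately a sample from the structure posterior restricted
to the set of EM local maxima; this approximation is validated empirically in
the test suite against exhaustive enumeration on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .em import EMResult, _run_em_arrays, run_em
from .model import (
    AttachmentPrior,
    EdgePrior,
    LogOdds,
    NEMWorkspace,
    SignalsGraph,
    _workspace,
)

__all__ = ["ChainState", "ChainTrace", "propose", "mode_hop_step", "run_chain"]


@dataclass
class ChainState:
    """Current chain state: the raw graph and its EM image."""

    raw: SignalsGraph
    mapped: EMResult
    rng_state: object = None


@dataclass
class ChainTrace:
    """Recorded mode-hopping samples (mapped graphs with their scores)."""

    samples: list = field(default_factory=list)
    acceptance_count: int = 0
    length: int = 0

    @property
    def acceptance_rate(self):
        return self.acceptance_count / self.length if self.length else float("nan")

    def best(self):
        """Highest-scoring sampled (graph, score) pair; first occurrence on ties."""
        if not self.samples:
            raise ValueError("empty trace")
        return max(self.samples, key=lambda gs: gs[1])

    def edge_frequencies(self):
        """Per-edge sample frequency matrix over the recorded mapped graphs."""
        if not self.samples:
            raise ValueError("empty trace")
        acc = np.zeros_like(self.samples[0][0].adjacency, dtype=float)
        for g, _ in self.samples:
            acc += g.adjacency
        return acc / len(self.samples)


def _flip_positions(n_signals, n_flips, rng):
    S = n_signals
    n_off = S * (S - 1)
    if n_flips < 1:
        raise ValueError("n_flips must be >= 1")
    if n_flips > n_off:
        raise ValueError(f"n_flips={n_flips} exceeds the {n_off} off-diagonal entries")
    flat = rng.choice(n_off, size=n_flips, replace=False)
    # map 0..S(S-1)-1 onto off-diagonal (row, col) pairs
    rows = flat // (S - 1)
    rem = flat % (S - 1)
    cols = rem + (rem >= rows)
    return rows, cols


def propose(g: SignalsGraph, n_flips: int, rng: np.random.Generator) -> SignalsGraph:
    """Flip ``n_flips`` off-diagonal entries chosen uniformly without replacement.

    The proposal is symmetric and an involution for fixed flip positions; the
    diagonal is never touched.
    """
    if g.n_signals < 2:
        raise ValueError("proposals require at least 2 signals")
    rows, cols = _flip_positions(g.n_signals, n_flips, rng)
    adj = g.adjacency.copy()
    adj[rows, cols] = 1 - adj[rows, cols]
    return SignalsGraph(adj, list(g.labels))


def _accept(log_ratio: float, rng: np.random.Generator) -> bool:
    """Metropolis acceptance: always if log_ratio >= 0, else with prob exp(log_ratio)."""
    return log_ratio >= 0 or rng.random() < np.exp(log_ratio)


def mode_hop_step(
    state: ChainState,
    r: LogOdds,
    nu: AttachmentPrior,
    ep: EdgePrior,
    n_flips: int = 1,
    rng: np.random.Generator = None,
) -> ChainState:
    """One Metropolis step with EM-mapped proposal.

    The symmetric proposal makes the Hastings ratio the posterior ratio of the
    mapped graphs.  On rejection the state is returned unchanged.
    """
    rng = np.random.default_rng() if rng is None else rng
    proposal = propose(state.raw, n_flips, rng)
    mapped = run_em(proposal, r, nu, ep)
    if _accept(mapped.score - state.mapped.score, rng):
        return ChainState(raw=proposal, mapped=mapped, rng_state=rng)
    return ChainState(raw=state.raw, mapped=state.mapped, rng_state=rng)


def run_chain(
    g0: SignalsGraph,
    r: LogOdds,
    nu: AttachmentPrior,
    ep: EdgePrior,
    n_steps: int = 20_000,
    burn_in: int = 10_000,
    thin: int = 10,
    n_flips: int = 1,
    seed=None,
    max_iter: int = 100,
) -> ChainTrace:
    """Run a mode-hopping chain and record mapped graphs after burn-in.

    Bit-reproducible for a fixed ``seed``.  EM images of proposals are
    memoized per raw graph within the run, which makes long chains on small
    graph spaces cheap.
    """
    if not (n_steps > burn_in >= 0):
        raise ValueError("need n_steps > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ws = _workspace(g0, r, nu, ep)
    labels = list(g0.labels)

    em_cache = {}

    def em_map(adj):
        key = adj.tobytes()
        hit = em_cache.get(key)
        if hit is None:
            mapped_adj, score, _, _, _ = _run_em_arrays(ws, adj, max_iter)
            hit = (mapped_adj, score)
            em_cache[key] = hit
        return hit

    raw = g0.adjacency.astype(np.int8).copy()
    np.fill_diagonal(raw, 1)
    cur_mapped, cur_score = em_map(raw)

    trace = ChainTrace()
    graph_pool = {}  # intern sampled graphs: bytes -> SignalsGraph
    for step in range(n_steps):
        rows, cols = _flip_positions(ws.n_signals, n_flips, rng)
        prop = raw.copy()
        prop[rows, cols] = 1 - prop[rows, cols]
        prop_mapped, prop_score = em_map(prop)
        if _accept(prop_score - cur_score, rng):
            raw = prop
            cur_mapped, cur_score = prop_mapped, prop_score
            trace.acceptance_count += 1
        trace.length += 1
        if step >= burn_in and (step - burn_in) % thin == 0:
            key = cur_mapped.tobytes()
            g = graph_pool.get(key)
            if g is None:
                g = SignalsGraph(cur_mapped.copy(), labels)
                graph_pool[key] = g
            trace.samples.append((g, cur_score))
    return trace
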