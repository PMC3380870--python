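"""Synthetic NEM benchmark: random ground truths, the alpha/beta log-odds noise
model, baseline learners and edge-recovery metrics.

The noise model mimics an optimal binary test with type-I error ``alpha`` and
type-II error ``beta``: every data cell carries one of two log-odds values,
``log((1-beta)/alpha)`` ("effect called") or ``log(beta/(1-alpha))`` ("no
effect called").  Cells with a true predicted effect are called with
probability ``1-beta``; cells without with probability ``alpha``.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ebayes import MCEMiNEMConfig, init_prior, run_mc_eminem
from .em import run_em
from .mcmc import _accept, _flip_positions
from .model import (
    NULL_TARGET,
    AttachmentPrior,
    EdgePrior,
    EffectsAttachment,
    LogOdds,
    NEMWorkspace,
    SignalsGraph,
    predict_effects,
)

__all__ = [
    "SimScenario",
    "GroundTruth",
    "sample_nem",
    "generate_logodds",
    "evaluate_edges",
    "prior_l1",
    "posterior_quantile",
    "fit_em_only",
    "fit_random_sampling",
    "fit_exhaustive",
    "run_benchmark",
    "summarize_benchmark",
]


@dataclass
class SimScenario:
    """Parameters of one simulation setting.

    ``n_edges`` defaults to ``round(1.5 * n_signals)``, a sparse hierarchical
    regime; ``null_fraction`` is the share of effects attached to the null
    node (uninformative genes).
    """

    n_signals: int = 11
    n_effects: int = 1000
    n_edges: int = None
    alpha: float = 0.05
    beta: float = 0.1
    null_fraction: float = 0.2
    seed: int = None

    def __post_init__(self):
        if self.n_edges is None:
            self.n_edges = min(
                round(1.5 * self.n_signals),
                self.n_signals * (self.n_signals - 1) // 2,
            )
        if not (self.n_signals >= 1 and self.n_effects >= 0):
            raise ValueError("need n_signals >= 1 and n_effects >= 0")
        if not 0 <= self.n_edges <= self.n_signals * (self.n_signals - 1):
            raise ValueError("n_edges out of range")
        if self.n_edges > self.n_signals * (self.n_signals - 1) // 2:
            raise ValueError("n_edges exceeds the acyclic maximum S(S-1)/2")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1 and self.alpha + self.beta < 1):
            raise ValueError("need 0 < alpha, beta and alpha + beta < 1")
        if not 0 <= self.null_fraction <= 1:
            raise ValueError("null_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """A simulated NEM: signals graph, attachment, and the deterministic prior."""

    graph: SignalsGraph
    attachment: EffectsAttachment
    prior_star: AttachmentPrior


def sample_nem(scenario: SimScenario, rng: np.random.Generator) -> GroundTruth:
    """Draw a random ground-truth NEM.

    The signals graph is a random acyclic orientation: a uniform random node
    order, then exactly ``n_edges`` of the order-compatible pairs chosen
    uniformly; unit diagonal added.  Each effect attaches uniformly at random
    to a signal, except for ``round(null_fraction * E)`` effects (chosen at
    random) that attach to the null node.
    """
    S, E = scenario.n_signals, scenario.n_effects
    order = rng.permutation(S)
    pairs = list(itertools.combinations(range(S), 2))  # positions in `order`
    chosen = rng.choice(len(pairs), size=scenario.n_edges, replace=False) if pairs else []
    adj = np.eye(S, dtype=np.int8)
    for idx in np.atleast_1d(chosen):
        i, j = pairs[int(idx)]
        adj[order[i], order[j]] = 1
    graph = SignalsGraph(adj)

    targets = rng.integers(0, S, size=E)
    n_null = int(round(scenario.null_fraction * E))
    if n_null:
        null_idx = rng.choice(E, size=n_null, replace=False)
        targets[null_idx] = NULL_TARGET
    attachment = EffectsAttachment(targets, None, graph.labels)
    prior_star = AttachmentPrior.deterministic(attachment, S)
    return GroundTruth(graph, attachment, prior_star)


def logodds_values(alpha: float, beta: float):
    """The two log-odds levels of the optimal-test noise model (positive, negative)."""
    return float(np.log((1 - beta) / alpha)), float(np.log(beta / (1 - alpha)))


def generate_logodds(
    truth: GroundTruth, alpha: float, beta: float, rng: np.random.Generator
) -> LogOdds:
    """Two-valued noisy log-odds matrix for a ground-truth NEM.

    A cell with a true predicted effect (``F[k, e] = 1``) takes the positive
    value with probability ``1 - beta``; a cell without takes it with
    probability ``alpha``; otherwise the negative value.
    """
    pos, neg = logodds_values(alpha, beta)
    F = predict_effects(truth.graph, truth.attachment).T  # E x S
    u = rng.random(F.shape)
    p_call = np.where(F == 1, 1 - beta, alpha)
    values = np.where(u < p_call, pos, neg)
    return LogOdds(values, truth.attachment.effect_labels, truth.graph.labels)


def evaluate_edges(estimated: SignalsGraph, truth: SignalsGraph):
    """Edge-wise (sensitivity, specificity) over off-diagonal positions.

    Sensitivity is ``nan`` when the true graph has no off-diagonal edges.
    """
    if estimated.labels != truth.labels:
        raise ValueError("label mismatch between estimated and true graphs")
    off = ~np.eye(truth.n_signals, dtype=bool)
    est, tru = estimated.adjacency[off], truth.adjacency[off]
    tp = int(((est == 1) & (tru == 1)).sum())
    fn = int(((est == 0) & (tru == 1)).sum())
    tn = int(((est == 0) & (tru == 0)).sum())
    fp = int(((est == 1) & (tru == 0)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec


def prior_l1(nu: AttachmentPrior, truth: GroundTruth) -> float:
    """Mean per-effect L1 distance to the true deterministic prior, scaled to [0, 1].

    The maximum gene-wise L1 distance between two stochastic vectors is 2, so
    the mean L1 distance is divided by 2.
    """
    star = truth.prior_star.values
    if nu.values.shape != star.shape:
        raise ValueError("prior dimensions do not match the ground truth")
    return float(np.abs(nu.values - star).sum(axis=1).mean() / 2.0)


def posterior_quantile(
    truth_graph: SignalsGraph,
    r: LogOdds,
    nu: AttachmentPrior,
    ep: EdgePrior,
    n_random: int = 5000,
    rng: np.random.Generator = None,
) -> float:
    """Fraction of uniformly random graphs scoring strictly below the true graph."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    ws = NEMWorkspace(r.values, nu.values, ep.values)
    S = truth_graph.n_signals
    ref = ws.score(truth_graph.adjacency)
    below = 0
    for _ in range(n_random):
        adj = rng.integers(0, 2, size=(S, S), dtype=np.int8)
        np.fill_diagonal(adj, 1)
        if ws.score(adj) < ref:
            below += 1
    return below / n_random


# ---------------------------------------------------------------------------
# baseline learners
# ---------------------------------------------------------------------------


def _prepare(r: LogOdds, edge_prior: float, do_filter: bool = True):
    from .model import filter_effects

    r_fit = filter_effects(r)[0] if do_filter else r
    nu = init_prior(r_fit)
    ep = EdgePrior.uniform(r.n_signals, edge_prior)
    return r_fit, nu, ep


def fit_em_only(r: LogOdds, edge_prior: float = 0.5, max_iter: int = 100) -> SignalsGraph:
    """Single EM run from the identity graph with the data-driven prior (no MCMC)."""
    r_fit, nu, ep = _prepare(r, edge_prior)
    g0 = SignalsGraph.identity(r.n_signals, list(r.signal_labels))
    return run_em(g0, r_fit, nu, ep, max_iter=max_iter).graph


def fit_random_sampling(
    r: LogOdds, n_steps: int, seed=None, edge_prior: float = 0.5
) -> SignalsGraph:
    """Budget-matched random-search baseline without EM mapping.

    A plain Metropolis random walk over signals graphs (single off-diagonal
    flips, acceptance by the marginal posterior ratio of the *raw* graphs,
    data-driven attachment prior) run for ``n_steps`` steps; the best-scoring
    visited graph is returned.  This matches the step budget of the
    mode-hopping sampler while using none of its EM machinery.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_fit, nu, ep = _prepare(r, edge_prior)
    ws = NEMWorkspace(r_fit.values, nu.values, ep.values)
    S = r.n_signals
    adj = np.eye(S, dtype=np.int8)
    score = ws.score(adj)
    best_adj, best_score = adj, score
    for _ in range(n_steps):
        rows, cols = _flip_positions(S, 1, rng)
        prop = adj.copy()
        prop[rows, cols] = 1 - prop[rows, cols]
        s = ws.score(prop)
        if _accept(s - score, rng):
            adj, score = prop, s
            if s > best_score:
                best_adj, best_score = prop, s
    return SignalsGraph(best_adj, list(r.signal_labels))


def fit_exhaustive(r: LogOdds, edge_prior: float = 0.5) -> SignalsGraph:
    """Exact MAP over all unit-diagonal binary graphs (S <= 4 only)."""
    S = r.n_signals
    if S > 4:
        raise ValueError("exhaustive search is limited to S <= 4")
    r_fit, nu, ep = _prepare(r, edge_prior)
    ws = NEMWorkspace(r_fit.values, nu.values, ep.values)
    off = [(k, s) for k in range(S) for s in range(S) if k != s]
    best_adj, best_score = None, -np.inf
    for bits in itertools.product((0, 1), repeat=len(off)):
        adj = np.eye(S, dtype=np.int8)
        for (k, s), b in zip(off, bits):
            adj[k, s] = b
        sc = ws.score(adj)
        if sc > best_score:
            best_adj, best_score = adj, sc
    return SignalsGraph(best_adj, list(r.signal_labels))


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

_METHODS = ("mc_eminem", "em_only", "random_sampling", "exhaustive")


def _fit_method(method, r, scenario, chain_config: MCEMiNEMConfig, seed):
    if method == "mc_eminem":
        cfg = MCEMiNEMConfig(**{**chain_config.__dict__, "seed": seed})
        return run_mc_eminem(r, cfg).final_graph
    if method == "em_only":
        return fit_em_only(r, chain_config.edge_prior, chain_config.max_iter)
    if method == "random_sampling":
        budget = chain_config.rounds * chain_config.n_steps
        return fit_random_sampling(r, budget, seed, chain_config.edge_prior)
    if method == "exhaustive":
        if scenario.n_signals > 4:
            raise ValueError("exhaustive method requested for S > 4")
        return fit_exhaustive(r, chain_config.edge_prior)
    raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")


def run_benchmark(
    scenarios,
    methods=("mc_eminem", "em_only", "random_sampling"),
    n_replicates: int = 10,
    seed: int = None,
    chain_config: MCEMiNEMConfig = None,
) -> pd.DataFrame:
    """Simulate, fit and score every scenario x method x replicate combination.

    Returns a tidy table with one row per fit: scenario parameters, method,
    replicate, edge sensitivity/specificity against the true graph, and
    runtime in seconds.  Fully seeded.  Replicate seeds are shared across
    scenarios (common random numbers): scenarios that differ only in the
    noise level see the same ground truths and monotonically coupled noise,
    which makes across-noise comparisons paired.
    """
    for m in methods:
        if m not in _METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {_METHODS}")
    chain_config = chain_config or MCEMiNEMConfig(
        n_steps=3000, burn_in=1000, thin=5, rounds=3
    )
    scenarios = list(scenarios)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_replicates)
    rows = []
    for scen in scenarios:
        for rep in range(n_replicates):
            data_rng = np.random.default_rng(rep_seeds[rep])
            truth = sample_nem(scen, data_rng)
            r = generate_logodds(truth, scen.alpha, scen.beta, data_rng)
            fit_seed = int(rep_seeds[rep].generate_state(1)[0] % (2**31))
            for method in methods:
                t0 = time.perf_counter()
                est = _fit_method(method, r, scen, chain_config, fit_seed)
                dt = time.perf_counter() - t0
                sens, spec = evaluate_edges(est, truth.graph)
                rows.append(
                    dict(
                        n_signals=scen.n_signals,
                        n_effects=scen.n_effects,
                        n_edges=scen.n_edges,
                        alpha=scen.alpha,
                        beta=scen.beta,
                        null_fraction=scen.null_fraction,
                        method=method,
                        replicate=rep,
                        sensitivity=sens,
                        specificity=spec,
                        runtime_s=dt,
                    )
                )
    return pd.DataFrame(rows)


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of sensitivity/specificity per scenario x method."""
    g = df.groupby(["n_signals", "alpha", "beta", "method"], as_index=False)
    out = g.agg(
        sensitivity_mean=("sensitivity", "mean"),
        sensitivity_se=("sensitivity", "sem"),
        specificity_mean=("specificity", "mean"),
        specificity_se=("specificity", "sem"),
        runtime_mean_s=("runtime_s", "mean"),
        n=("replicate", "size"),
    )
    return out


def plot_benchmark(df: pd.DataFrame, path):
    """Sensitivity-per-scenario panel plot (one frame per noise level)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize_benchmark(df)
    betas = sorted(summary["beta"].unique())
    fig, axes = plt.subplots(1, len(betas), figsize=(3 * len(betas), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, beta in zip(axes, betas):
        sub = summary[summary["beta"] == beta]
        ax.bar(sub["method"], sub["sensitivity_mean"], yerr=sub["sensitivity_se"])
        ax.set_title(f"beta = {beta}")
        ax.set_ylim(0, 1.05)
        ax.tick_params(axis="x", rotation=45)
    axes[0].set_ylabel("edge sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
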