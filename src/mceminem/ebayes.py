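"""Empirical Bayes estimation of the attachment prior around the MCMC sampler.

The attachment prior ``nu`` is initialized from the data (the attachment
posterior under the identity signals graph with a uniform base prior), a
mode-hopping chain samples signals graphs given ``nu``, and ``nu`` is replaced
by the average attachment posterior over the sampled graphs.  Sampling and
re-estimation alternate until the prior stops changing.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .mcmc import ChainTrace, run_chain
from .model import (
    NULL_TARGET,
    AttachmentPrior,
    AttachmentPosterior,
    EdgePrior,
    EffectsAttachment,
    LogOdds,
    NEMWorkspace,
    SignalsGraph,
    filter_effects,
)

__all__ = [
    "MCEMiNEMConfig",
    "MCEMiNEMResult",
    "init_prior",
    "update_prior",
    "run_mc_eminem",
]


def init_prior(r: LogOdds) -> AttachmentPrior:
    """Data-driven attachment prior: softmax of each effect's log-odds row.

    ``nu[e, .]`` is the row-normalization of
    ``(exp(R[e, 1]), ..., exp(R[e, S]), exp(0))`` — the attachment posterior
    under the identity signals graph with a uniform base prior.  Computed in
    log space so large log-odds cannot overflow.
    """
    E, S = r.values.shape
    A = np.column_stack([r.values, np.zeros(E)])
    m = A.max(axis=1, keepdims=True)
    expA = np.exp(A - m)
    return AttachmentPrior(expA / expA.sum(axis=1, keepdims=True))


def update_prior(trace: ChainTrace, r: LogOdds, nu_old: AttachmentPrior) -> AttachmentPrior:
    """Average attachment posterior over the sampled graphs.

    Approximates the posterior over attachments given the data with the
    signals graph integrated out along the chain; rows are stochastic by
    construction.  Distinct sampled graphs are evaluated once and weighted by
    their sample counts.
    """
    if not trace.samples:
        raise ValueError("cannot update the prior from an empty trace")
    ws = NEMWorkspace(r.values, nu_old.values, np.full((r.n_signals,) * 2, 0.5))
    counts = {}
    for g, _ in trace.samples:
        key = g.adjacency.tobytes()
        if key in counts:
            counts[key][1] += 1
        else:
            counts[key] = [g.adjacency, 1]
    acc = np.zeros_like(nu_old.values)
    for adj, n in counts.values():
        acc += n * ws.omega(adj)
    acc /= len(trace.samples)
    acc /= acc.sum(axis=1, keepdims=True)  # guard rounding drift
    return AttachmentPrior(acc)


@dataclass
class MCEMiNEMConfig:
    """Settings for the full empirical Bayes run.

    ``edge_prior`` is the per-edge Bernoulli probability; values below 0.5 act
    as a sparsity weight.  ``rounds`` bounds the number of sample/re-estimate
    alternations; convergence is declared when the largest elementwise prior
    change drops below ``tol``.
    """

    n_steps: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    n_flips: int = 1
    rounds: int = 5
    tol: float = 1e-3
    edge_prior: float = 0.5
    max_iter: int = 100
    filter: bool = True
    seed: int = None

    @classmethod
    def from_file(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class MCEMiNEMResult:
    """Outcome of a full run.

    ``final_graph`` is the highest-scoring sampled local maximum of the last
    round, ``attachment`` the per-effect MAP target under the final prior
    (over the effects retained by pre-filtering), and ``rounds`` the
    (ChainTrace, AttachmentPrior) pair of every empirical Bayes round.
    """

    final_graph: SignalsGraph
    final_prior: AttachmentPrior
    attachment: EffectsAttachment
    rounds: list = field(default_factory=list)
    converged: bool = False
    score: float = float("nan")
    kept_effects: np.ndarray = None
    filtered_effect_labels: list = field(default_factory=list)
    config: MCEMiNEMConfig = None

    def full_attachment(self, all_effect_labels) -> EffectsAttachment:
        """Attachment over the full input effect set; filtered effects -> null."""
        kept = {lab: t for lab, t in zip(self.attachment.effect_labels, self.attachment.targets)}
        targets = np.array(
            [kept.get(lab, NULL_TARGET) for lab in all_effect_labels], dtype=int
        )
        return EffectsAttachment(targets, list(all_effect_labels), self.final_graph.labels)


def run_mc_eminem(r: LogOdds, config: MCEMiNEMConfig = None) -> MCEMiNEMResult:
    """Full pipeline: pre-filter, data-driven prior, alternate MCMC and prior updates.

    Fully seeded through ``config.seed``: identical seeds give bit-identical
    results.  Each round's chain starts from the previous round's best graph
    (round 1 from the identity graph).
    """
    config = config or MCEMiNEMConfig()
    if config.filter:
        r_fit, kept = filter_effects(r)
    else:
        r_fit, kept = r, np.arange(r.n_effects)
    filtered_labels = [
        lab for i, lab in enumerate(r.effect_labels) if i not in set(kept.tolist())
    ]
    S = r.n_signals
    ep = EdgePrior.uniform(S, config.edge_prior)
    nu = init_prior(r_fit)
    if r_fit.n_effects == 0:
        warnings.warn("no effects left after filtering; returning the empty model")
    ss = np.random.SeedSequence(config.seed)
    round_seeds = ss.spawn(max(config.rounds, 1))

    g0 = SignalsGraph.identity(S, list(r.signal_labels))
    rounds = []
    converged = False
    best_graph, best_score = g0, float("nan")
    for rnd in range(config.rounds):
        trace = run_chain(
            g0,
            r_fit,
            nu,
            ep,
            n_steps=config.n_steps,
            burn_in=config.burn_in,
            thin=config.thin,
            n_flips=config.n_flips,
            seed=np.random.default_rng(round_seeds[rnd]),
            max_iter=config.max_iter,
        )
        nu_new = update_prior(trace, r_fit, nu)
        rounds.append((trace, nu_new))
        best_graph, best_score = trace.best()
        g0 = best_graph
        delta = float(np.abs(nu_new.values - nu.values).max()) if nu.values.size else 0.0
        nu = nu_new
        if delta < config.tol:
            converged = True
            break

    ws = NEMWorkspace(r_fit.values, nu.values, ep.values)
    omega = AttachmentPosterior(ws.omega(best_graph.adjacency)) if r_fit.n_effects else None
    if omega is not None:
        attachment = omega.argmax_attachment(list(r_fit.effect_labels), best_graph.labels)
    else:
        attachment = EffectsAttachment(np.empty(0, dtype=int), [], best_graph.labels)
    return MCEMiNEMResult(
        final_graph=best_graph,
        final_prior=nu,
        attachment=attachment,
        rounds=rounds,
        converged=converged,
        score=best_score,
        kept_effects=kept,
        filtered_effect_labels=filtered_labels,
        config=config,
    )
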