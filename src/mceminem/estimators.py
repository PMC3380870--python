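"""Scikit-learn style estimators for NEM structure learning.

``X`` is the effects-by-signals log-odds matrix (one row per effect gene, one
column per perturbation); a :class:`pandas.DataFrame` contributes its index
and columns as labels.  Both estimators are unsupervised structure learners:
``fit`` stores the inferred signals graph and effects attachment as fitted
attributes, in the style of clustering estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import ebayes
from .em import run_em
from .model import (
    AttachmentPosterior,
    EdgePrior,
    LogOdds,
    NEMWorkspace,
    SignalsGraph,
    filter_effects,
    log_posterior,
    predict_effects,
)

__all__ = ["EMiNEM", "MCEMiNEM"]


def _as_log_odds(X) -> LogOdds:
    if isinstance(X, LogOdds):
        return X
    if isinstance(X, pd.DataFrame):
        return LogOdds(
            X.to_numpy(dtype=float),
            list(X.index.astype(str)),
            list(X.columns.astype(str)),
        )
    return LogOdds(np.asarray(X, dtype=float))


class EMiNEM(BaseEstimator):
    """Single-run EM maximization of the NEM structure posterior.

    Starts from the identity signals graph with the data-driven attachment
    prior and iterates the closed-form edge-wise update to a local maximum.

    Parameters
    ----------
    edge_prior : float in (0, 1), default 0.5
        Per-edge Bernoulli prior; values below 0.5 penalize dense graphs.
    max_iter : int, default 100
        Iteration cap; convergence typically takes a handful of updates.
    filter : bool, default True
        Drop effects without any strictly positive log-odds entry before
        fitting.

    Attributes
    ----------
    graph_ : SignalsGraph
        The EM fixed point.
    adjacency_ : ndarray of shape (S, S)
    score_ : float
        Marginal log posterior at the fixed point (up to a constant).
    trajectory_ : list of float
        Monotone score trajectory of the run.
    attachment_ : EffectsAttachment
        MAP attachment of the retained effects under the final posterior.
    n_iter_ : int
    """

    def __init__(self, edge_prior=0.5, max_iter=100, filter=True):
        self.edge_prior = edge_prior
        self.max_iter = max_iter
        self.filter = filter

    def fit(self, X, y=None):
        r = _as_log_odds(X)
        r_fit, kept = filter_effects(r) if self.filter else (r, np.arange(r.n_effects))
        nu = ebayes.init_prior(r_fit)
        ep = EdgePrior.uniform(r.n_signals, self.edge_prior)
        g0 = SignalsGraph.identity(r.n_signals, list(r.signal_labels))
        res = run_em(g0, r_fit, nu, ep, max_iter=self.max_iter)
        self.graph_ = res.graph
        self.adjacency_ = res.graph.adjacency
        self.score_ = res.score
        self.trajectory_ = res.trajectory
        self.n_iter_ = res.n_iterations
        self.kept_effects_ = kept
        ws = NEMWorkspace(r_fit.values, nu.values, ep.values)
        omega = AttachmentPosterior(ws.omega(res.graph.adjacency))
        self.attachment_posterior_ = omega
        self.attachment_ = omega.argmax_attachment(
            list(r_fit.effect_labels), res.graph.labels
        )
        return self

    def score(self, X, y=None):
        """Marginal log posterior of the fitted graph on ``X`` (data-driven prior)."""
        r = _as_log_odds(X)
        nu = ebayes.init_prior(r)
        ep = EdgePrior.uniform(r.n_signals, self.edge_prior)
        return log_posterior(self.graph_, r, nu, ep)

    def predict_effects_matrix(self):
        """Binary S x E prediction matrix of the fitted model."""
        return predict_effects(self.graph_, self.attachment_)


class MCEMiNEM(BaseEstimator):
    """Full NEM learner: EM-mapped mode-hopping MCMC with an empirical Bayes prior.

    Alternates mode-hopping sampling of signals graphs with re-estimation of
    the attachment prior from the averaged attachment posteriors of the
    sampled graphs.  Deterministic for a fixed ``random_state``.

    Parameters mirror :class:`~mceminem.ebayes.MCEMiNEMConfig`; see there for
    semantics and defaults.

    Attributes
    ----------
    graph_ : SignalsGraph
        Highest-scoring sampled local maximum of the final round.
    adjacency_ : ndarray of shape (S, S)
    prior_ : AttachmentPrior
        Final empirical Bayes attachment prior (retained effects).
    attachment_ : EffectsAttachment
        Per-effect MAP attachment under the final prior.
    score_ : float
    rounds_ : list of (ChainTrace, AttachmentPrior)
    converged_ : bool
    result_ : MCEMiNEMResult
        The complete result object.
    """

    def __init__(
        self,
        n_steps=20_000,
        burn_in=10_000,
        thin=10,
        n_flips=1,
        rounds=5,
        tol=1e-3,
        edge_prior=0.5,
        max_iter=100,
        filter=True,
        random_state=None,
    ):
        self.n_steps = n_steps
        self.burn_in = burn_in
        self.thin = thin
        self.n_flips = n_flips
        self.rounds = rounds
        self.tol = tol
        self.edge_prior = edge_prior
        self.max_iter = max_iter
        self.filter = filter
        self.random_state = random_state

    def _config(self):
        return ebayes.MCEMiNEMConfig(
            n_steps=self.n_steps,
            burn_in=self.burn_in,
            thin=self.thin,
            n_flips=self.n_flips,
            rounds=self.rounds,
            tol=self.tol,
            edge_prior=self.edge_prior,
            max_iter=self.max_iter,
            filter=self.filter,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        r = _as_log_odds(X)
        res = ebayes.run_mc_eminem(r, self._config())
        self.result_ = res
        self.graph_ = res.final_graph
        self.adjacency_ = res.final_graph.adjacency
        self.prior_ = res.final_prior
        self.attachment_ = res.attachment
        self.score_ = res.score
        self.rounds_ = res.rounds
        self.converged_ = res.converged
        return self

    def score(self, X, y=None):
        """Marginal log posterior of the fitted graph on ``X`` under the fitted prior."""
        r = _as_log_odds(X)
        r_fit = filter_effects(r)[0] if self.filter else r
        ep = EdgePrior.uniform(r.n_signals, self.edge_prior)
        return log_posterior(self.graph_, r_fit, self.prior_, ep)

    def predict_effects_matrix(self):
        """Binary S x E prediction matrix of the fitted model."""
        return predict_effects(self.graph_, self.attachment_)
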