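"""Core nested effects model (NEM) data types and scoring.

A NEM explains a perturbation screen with two graphs: a *signals graph*
``Gamma`` (binary adjacency over the perturbed entities, unit diagonal) and an
*effects attachment* ``Theta`` assigning each observed effect gene to exactly
one signal or to a virtual *null node*.  The model predicts an effect of gene
``e`` under perturbation of signal ``k`` exactly if there is a two-step path
``k -> s -> e``, i.e. ``Gamma[k, s] = 1`` for the signal ``s`` that ``e`` is
attached to.  Effects on the null node are predicted always inactive, which
implements feature selection inside the model.

The data enter as a log-odds matrix ``R`` (effects x perturbations): ``R[e, k]``
is the log ratio of the evidence that effect ``e`` changed versus stayed
unchanged when signal ``k`` was perturbed.  The marginal structure score used
throughout the package integrates the attachment out under a row-stochastic
attachment prior ``nu``::

    log P(Gamma | D) =  sum_e log( sum_s nu[e, s] * exp(sum_k Gamma[k, s] * R[e, k])
                                   + nu[e, null] )
                      + sum_{k != s} log P(gamma_ks)            (+ const)

with edge-wise independent Bernoulli priors on the off-diagonal entries of
``Gamma``.  All arithmetic is carried out in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

NULL_TARGET = -1
"""Sentinel index for attachment to the null node."""

__all__ = [
    "NULL_TARGET",
    "SignalsGraph",
    "EffectsAttachment",
    "LogOdds",
    "AttachmentPrior",
    "AttachmentPosterior",
    "EdgePrior",
    "predict_effects",
    "log_posterior",
    "attachment_posterior",
    "filter_effects",
    "merge_indistinguishable",
]


def _as_labels(labels, n, prefix):
    if labels is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")
    return labels


@dataclass
class SignalsGraph:
    """Binary S x S adjacency over the perturbed entities, unit diagonal.

    ``adjacency[k, s] = 1`` means that perturbing ``k`` also perturbs ``s``
    (and hence the effects attached to ``s``).  The diagonal is fixed at 1:
    perturbing a signal always perturbs itself.
    """

    adjacency: np.ndarray
    labels: list = None

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1] or adj.shape[0] < 1:
            raise ValueError("adjacency must be a square matrix with S >= 1")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if not (np.diag(adj) == 1).all():
            raise ValueError("adjacency must have unit diagonal")
        self.adjacency = adj.astype(np.int8)
        self.labels = _as_labels(self.labels, adj.shape[0], "s")

    @property
    def n_signals(self):
        return self.adjacency.shape[0]

    @classmethod
    def identity(cls, n_signals, labels=None):
        return cls(np.eye(n_signals, dtype=np.int8), labels)

    def copy(self):
        return SignalsGraph(self.adjacency.copy(), list(self.labels))

    def __eq__(self, other):
        return (
            isinstance(other, SignalsGraph)
            and self.labels == other.labels
            and np.array_equal(self.adjacency, other.adjacency)
        )

    def edges(self):
        """Off-diagonal edges as (source_label, target_label) pairs."""
        out = []
        for k in range(self.n_signals):
            for s in range(self.n_signals):
                if k != s and self.adjacency[k, s]:
                    out.append((self.labels[k], self.labels[s]))
        return out


@dataclass
class EffectsAttachment:
    """Sparse attachment of each effect to one signal or the null node.

    ``targets[e]`` is the 0-based signal index, or :data:`NULL_TARGET` (-1)
    for the null node.
    """

    targets: np.ndarray
    effect_labels: list = None
    signal_labels: list = None

    def __post_init__(self):
        t = np.asarray(self.targets, dtype=int)
        if t.ndim != 1:
            raise ValueError("targets must be one-dimensional")
        self.targets = t
        self.effect_labels = _as_labels(self.effect_labels, t.size, "e")
        if self.signal_labels is not None:
            self.signal_labels = [str(x) for x in self.signal_labels]
            if t.size and (t.max(initial=NULL_TARGET) >= len(self.signal_labels)):
                raise ValueError("attachment target out of range")
        if t.size and t.min(initial=0) < NULL_TARGET:
            raise ValueError("attachment target out of range")

    @property
    def n_effects(self):
        return self.targets.size

    def target_labels(self, null_label="null"):
        names = []
        for t in self.targets:
            names.append(null_label if t == NULL_TARGET else self.signal_labels[t])
        return names

    def as_matrix(self, n_signals):
        """Dense 0/1 attachment matrix Theta of shape (S, E); null columns are zero."""
        theta = np.zeros((n_signals, self.n_effects), dtype=np.int8)
        attached = self.targets != NULL_TARGET
        theta[self.targets[attached], np.flatnonzero(attached)] = 1
        return theta


@dataclass
class LogOdds:
    """E x S matrix of per-effect, per-perturbation log-odds evidence."""

    values: np.ndarray
    effect_labels: list = None
    signal_labels: list = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("log-odds values must be a 2-d matrix")
        if not np.isfinite(v).all():
            raise ValueError("log-odds values must be finite")
        self.values = v
        self.effect_labels = _as_labels(self.effect_labels, v.shape[0], "e")
        self.signal_labels = _as_labels(self.signal_labels, v.shape[1], "s")

    @property
    def n_effects(self):
        return self.values.shape[0]

    @property
    def n_signals(self):
        return self.values.shape[1]


def _check_rows_stochastic(v, what):
    if (v < 0).any():
        raise ValueError(f"{what} entries must be nonnegative")
    if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9, rtol=0):
        raise ValueError(f"{what} rows must sum to 1")


@dataclass
class AttachmentPrior:
    """Row-stochastic E x (S+1) prior over attachment targets.

    Columns 0..S-1 are the signals (in the order of the companion
    :class:`LogOdds` / :class:`SignalsGraph` labels); column S is the null node.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("attachment prior must be E x (S+1) with S >= 1")
        _check_rows_stochastic(v, "attachment prior")
        self.values = v

    @property
    def n_signals(self):
        return self.values.shape[1] - 1

    @classmethod
    def uniform(cls, n_effects, n_signals):
        return cls(np.full((n_effects, n_signals + 1), 1.0 / (n_signals + 1)))

    @classmethod
    def deterministic(cls, attachment: EffectsAttachment, n_signals):
        """Unit-row prior putting all mass on each effect's attachment target."""
        v = np.zeros((attachment.n_effects, n_signals + 1))
        cols = np.where(attachment.targets == NULL_TARGET, n_signals, attachment.targets)
        v[np.arange(attachment.n_effects), cols] = 1.0
        return cls(v)


@dataclass
class AttachmentPosterior:
    """Row-stochastic E x (S+1) E-step responsibilities over attachment targets."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("attachment posterior must be E x (S+1)")
        _check_rows_stochastic(v, "attachment posterior")
        self.values = v

    def argmax_attachment(self, effect_labels=None, signal_labels=None):
        """Per-effect MAP attachment; ties go to the lexicographically smallest label."""
        E, cols = self.values.shape
        S = cols - 1
        signal_labels = _as_labels(signal_labels, S, "s")
        order_names = list(signal_labels) + ["null"]
        targets = np.empty(E, dtype=int)
        for e in range(E):
            row = self.values[e]
            top = np.flatnonzero(row >= row.max() - 1e-12)
            j = min(top, key=lambda i: order_names[i])
            targets[e] = NULL_TARGET if j == S else j
        return EffectsAttachment(targets, effect_labels, signal_labels)


@dataclass
class EdgePrior:
    """Edge-wise independent Bernoulli prior on off-diagonal entries of Gamma.

    Probabilities must lie strictly inside (0, 1) so every edge has finite
    log-odds.  The diagonal of Gamma is fixed at 1 and is ignored here.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("edge prior must be a square matrix")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not ((v[off] > 0) & (v[off] < 1)).all():
            raise ValueError("off-diagonal edge prior entries must be strictly in (0, 1)")
        self.values = v

    @property
    def n_signals(self):
        return self.values.shape[0]

    @classmethod
    def uniform(cls, n_signals, p=0.5):
        """Constant per-edge prior; p < 0.5 acts as a sparsity weight."""
        return cls(np.full((n_signals, n_signals), float(p)))


# ---------------------------------------------------------------------------
# numerical workspace shared by the scoring, EM and MCMC code paths
# ---------------------------------------------------------------------------


class NEMWorkspace:
    """Pre-computed quantities for repeated scoring of graphs on fixed data.

    Holds ``R``, ``log(nu)`` and the edge-prior log terms so that scoring a
    candidate adjacency costs one (E x S) @ (S x S) product plus a row-wise
    log-sum-exp.  Used internally by the EM and MCMC drivers; the public
    functions below build a throwaway workspace per call.
    """

    def __init__(self, r_values, nu_values, ep_values):
        R = np.asarray(r_values, dtype=float)
        nu = np.asarray(nu_values, dtype=float)
        ep = np.asarray(ep_values, dtype=float)
        E, S = R.shape
        if nu.shape != (E, S + 1):
            raise ValueError(
                f"attachment prior shape {nu.shape} does not match log-odds ({E} x {S})"
            )
        if ep.shape != (S, S):
            raise ValueError("edge prior dimensions do not match the log-odds matrix")
        if (nu.sum(axis=1) <= 0).any():
            raise ValueError("attachment prior has an all-zero row")
        self.R = R
        self.n_effects = E
        self.n_signals = S
        with np.errstate(divide="ignore"):
            log_nu = np.log(nu)
        self.log_nu_sig = log_nu[:, :S]
        self.log_nu_null = log_nu[:, S]
        off = ~np.eye(S, dtype=bool)
        self.offdiag = off
        logit = np.zeros((S, S))
        logit[off] = np.log(ep[off]) - np.log1p(-ep[off])
        self.edge_logit = logit
        self.edge_const = np.log1p(-ep[off]).sum()

    def _terms(self, adj):
        """Per-target log weights: A[:, :S] for signals, A[:, S] for null."""
        A = np.empty((self.n_effects, self.n_signals + 1))
        np.matmul(self.R, adj, out=A[:, : self.n_signals])
        A[:, : self.n_signals] += self.log_nu_sig
        A[:, self.n_signals] = self.log_nu_null
        return A

    @staticmethod
    def _lse_rows(A):
        m = A.max(axis=1)
        return m + np.log(np.exp(A - m[:, None]).sum(axis=1))

    def edge_prior_term(self, adj):
        return float((adj * self.edge_logit)[self.offdiag].sum()) + self.edge_const

    def score(self, adj):
        """Marginal log posterior of ``adj`` (up to a Gamma-independent constant)."""
        att = self._lse_rows(self._terms(adj)).sum()
        if not np.isfinite(att):
            raise ValueError("non-finite log posterior; check inputs")
        return float(att) + self.edge_prior_term(adj)

    def omega(self, adj):
        """E-step responsibilities omega for the given adjacency."""
        A = self._terms(adj)
        A -= self._lse_rows(A)[:, None]
        return np.exp(A)

    def score_and_omega(self, adj):
        A = self._terms(adj)
        lse = self._lse_rows(A)
        att = lse.sum()
        if not np.isfinite(att):
            raise ValueError("non-finite log posterior; check inputs")
        return float(att) + self.edge_prior_term(adj), np.exp(A - lse[:, None])

    def em_step(self, adj):
        """Closed-form M-step: edge (k,s) present iff its linear coefficient is > 0."""
        omega = self.omega(adj)
        return self.em_step_from_omega(omega)

    def em_step_from_omega(self, omega):
        M = self.R.T @ omega[:, : self.n_signals]  # M[k, s] = sum_e R[e,k] omega[e,s]
        new = ((M + self.edge_logit) > 0).astype(np.int8)
        np.fill_diagonal(new, 1)
        return new


def _workspace(g, r, nu, ep):
    if g.n_signals != r.n_signals:
        raise ValueError("signals graph and log-odds dimensions disagree")
    if g.labels != r.signal_labels:
        raise ValueError("signals graph and log-odds labels disagree")
    return NEMWorkspace(r.values, nu.values, ep.values)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def predict_effects(g: SignalsGraph, a: EffectsAttachment) -> np.ndarray:
    """Binary S x E prediction matrix F of the NEM (Gamma, Theta).

    ``F[k, e] = 1`` iff effect ``e`` is attached to a signal ``s`` with
    ``Gamma[k, s] = 1`` (a two-step path k -> s -> e).  Effects attached to
    the null node yield all-zero columns.  Equals the indicator of
    ``Gamma @ Theta >= 1``.
    """
    if a.signal_labels is not None and list(a.signal_labels) != list(g.labels):
        raise ValueError("attachment and signals graph labels disagree")
    S = g.n_signals
    F = np.zeros((S, a.n_effects), dtype=np.int8)
    attached = a.targets != NULL_TARGET
    F[:, attached] = g.adjacency[:, a.targets[attached]]
    return F


def log_posterior(
    g: SignalsGraph, r: LogOdds, nu: AttachmentPrior, ep: EdgePrior
) -> float:
    """Marginal log posterior of the signals graph, attachments integrated out.

    Defined up to an additive constant that is fixed for fixed ``(r, nu, ep)``;
    only score differences between graphs are meaningful.
    """
    return _workspace(g, r, nu, ep).score(g.adjacency)


def attachment_posterior(
    g: SignalsGraph, r: LogOdds, nu: AttachmentPrior
) -> AttachmentPosterior:
    """E-step posterior over attachment targets given the signals graph.

    ``omega[e, s] propto nu[e, s] * exp(sum_k Gamma[k, s] R[e, k])`` for
    signals and ``omega[e, null] propto nu[e, null]``; rows normalized, all in
    log space.
    """
    ws = NEMWorkspace(r.values, nu.values, np.full((r.n_signals,) * 2, 0.5))
    if g.n_signals != r.n_signals or g.labels != r.signal_labels:
        raise ValueError("signals graph and log-odds labels disagree")
    return AttachmentPosterior(ws.omega(g.adjacency))


def filter_effects(r: LogOdds):
    """Drop effects whose log-odds row has no strictly positive entry.

    Attaching such a gene to any signal can never increase the posterior, so
    it is removed before estimation.  Returns the reduced :class:`LogOdds` and
    the array of retained original row indices.
    """
    keep = np.flatnonzero((r.values > 0).any(axis=1))
    if keep.size == 0:
        warnings.warn("all effects filtered out; model has no informative effects")
    reduced = LogOdds(
        r.values[keep].reshape(keep.size, r.n_signals),
        [r.effect_labels[i] for i in keep],
        list(r.signal_labels),
    )
    return reduced, keep


def merge_indistinguishable(g: SignalsGraph, r: LogOdds):
    """Merge signals connected by bi-directional edges into single nodes.

    A mutual edge pair ``Gamma[i, j] = Gamma[j, i] = 1`` means the two signals
    are indistinguishable in terms of their intervention effects; the relation
    is closed transitively (union-find).  Merged node labels concatenate the
    member labels, the merged log-odds column is the row-wise mean of member
    columns, and the merged adjacency row/column is the element-wise OR over
    members.  Returns ``(merged_graph, merged_logodds, report)`` where report
    maps each merged label to its member labels.
    """
    if g.labels != r.signal_labels:
        raise ValueError("signals graph and log-odds labels disagree")
    S = g.n_signals
    parent = list(range(S))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    adj = g.adjacency
    for i in range(S):
        for j in range(i + 1, S):
            if adj[i, j] and adj[j, i]:
                parent[find(i)] = find(j)

    groups = {}
    for i in range(S):
        groups.setdefault(find(i), []).append(i)
    # stable order: by first member index
    ordered = sorted(groups.values(), key=lambda m: m[0])

    S2 = len(ordered)
    new_labels = ["".join(g.labels[i] for i in members) for members in ordered]
    new_adj = np.zeros((S2, S2), dtype=np.int8)
    for a, mem_a in enumerate(ordered):
        for b, mem_b in enumerate(ordered):
            new_adj[a, b] = int(adj[np.ix_(mem_a, mem_b)].any())
    np.fill_diagonal(new_adj, 1)
    new_r = np.column_stack(
        [r.values[:, members].mean(axis=1) for members in ordered]
    )
    report = {
        lab: [g.labels[i] for i in members]
        for lab, members in zip(new_labels, ordered)
    }
    merged_g = SignalsGraph(new_adj, new_labels)
    merged_r = LogOdds(new_r, list(r.effect_labels), new_labels)
    return merged_g, merged_r, report
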