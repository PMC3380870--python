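"""Downstream grouping and multi-seed consensus of fitted NEMs.

Attached effect genes are grouped by their attachment target and by the
direction of their expression change across the perturbations in which the
model predicts an effect; with S' signal nodes this yields up to 2*S' groups,
the input shape expected by gene set enrichment tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ebayes import MCEMiNEMResult
from .model import NULL_TARGET, SignalsGraph

__all__ = ["EffectGroup", "group_effects", "consensus"]

logger = logging.getLogger(__name__)


@dataclass
class EffectGroup:
    """Effects attached to one signal with a common direction of regulation."""

    signal: str
    direction: str  # "up" | "down"
    members: list = field(default_factory=list)


def group_effects(result: MCEMiNEMResult, direction_matrix) -> list:
    """Partition attached effects into (signal x direction) groups.

    ``direction_matrix`` gives the sign of the expression change of each
    effect under each perturbation (E x S, rows aligned with the result's
    attachment; a DataFrame is reindexed by label).  An effect's direction is
    the sign of the mean entry over the perturbations with a predicted effect
    (``F[k, e] = 1``).  Zero net sign means the direction is undecidable: the
    effect is excluded from both groups and logged.  Null-attached effects
    carry no predicted effects and are excluded by construction.
    """
    att = result.attachment
    graph = result.final_graph
    if isinstance(direction_matrix, pd.DataFrame):
        direction_matrix = direction_matrix.reindex(
            index=att.effect_labels, columns=graph.labels
        ).to_numpy()
    D = np.asarray(direction_matrix, dtype=float)
    if D.shape != (att.n_effects, graph.n_signals):
        raise ValueError("direction matrix must be E x S aligned with the attachment")

    groups = {}
    for e, target in enumerate(att.targets):
        if target == NULL_TARGET:
            continue
        predicted = graph.adjacency[:, target] == 1  # perturbations k with an effect
        net = D[e, predicted].mean()
        if net == 0 or np.isnan(net):
            logger.info(
                "effect %s has zero net direction; excluded from grouping",
                att.effect_labels[e],
            )
            continue
        key = (graph.labels[target], "up" if net > 0 else "down")
        groups.setdefault(key, []).append(att.effect_labels[e])
    return [
        EffectGroup(signal=s, direction=d, members=m)
        for (s, d), m in sorted(groups.items())
    ]


def groups_to_frame(groups) -> pd.DataFrame:
    """Tab-writable long table: one row per (signal, direction, effect)."""
    rows = [
        {"signal": g.signal, "direction": g.direction, "effect": e}
        for g in groups
        for e in g.members
    ]
    return pd.DataFrame(rows, columns=["signal", "direction", "effect"])


def consensus(results: list):
    """Per-edge sample frequency across independent runs, plus the modal graph.

    The modal graph keeps the edges present in more than half of the runs.
    Permutation-invariant in the input order.
    """
    if len(results) < 2:
        raise ValueError("consensus needs at least 2 results")
    graphs = [
        res.final_graph if isinstance(res, MCEMiNEMResult) else res for res in results
    ]
    labels = graphs[0].labels
    for g in graphs[1:]:
        if g.labels != labels:
            raise ValueError("all results must share identical signal labels")
    freq = np.mean([g.adjacency for g in graphs], axis=0)
    modal_adj = (freq > 0.5).astype(np.int8)
    np.fill_diagonal(modal_adj, 1)
    return freq, SignalsGraph(modal_adj, list(labels))
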