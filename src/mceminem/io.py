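"""Tab-separated text I/O for the NEM data structures.

All formats are plain TSV with row/column labels: log-odds matrices carry
signal labels in the first row and effect labels in the first column;
adjacencies are labelled square matrices; attachments are two-column
(signal, effect) tables; traces are one row per recorded sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    NULL_TARGET,
    EffectsAttachment,
    LogOdds,
    SignalsGraph,
)

__all__ = [
    "read_log_odds",
    "write_log_odds",
    "read_adjacency",
    "write_adjacency",
    "write_edge_list",
    "to_dot",
    "write_attachment",
    "read_attachment",
    "write_trace",
    "write_edge_frequencies",
]


def read_log_odds(path) -> LogOdds:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LogOdds(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)))


def write_log_odds(r: LogOdds, path):
    pd.DataFrame(r.values, index=r.effect_labels, columns=r.signal_labels).to_csv(
        path, sep="\t"
    )


def read_adjacency(path) -> SignalsGraph:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = list(df.columns.astype(str))
    if list(df.index.astype(str)) != labels:
        raise ValueError("adjacency row and column labels disagree")
    return SignalsGraph(df.to_numpy(dtype=int), labels)


def write_adjacency(g: SignalsGraph, path):
    pd.DataFrame(g.adjacency, index=g.labels, columns=g.labels).to_csv(path, sep="\t")


def write_edge_list(g: SignalsGraph, path):
    """Off-diagonal edges, one 'source<TAB>target' line each."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for src, dst in g.edges():
            fh.write(f"{src}\t{dst}\n")


def to_dot(g: SignalsGraph, name="signals") -> str:
    lines = [f"digraph {name} {{"]
    for lab in g.labels:
        lines.append(f'  "{lab}";')
    for src, dst in g.edges():
        lines.append(f'  "{src}" -> "{dst}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_attachment(a: EffectsAttachment, path, include_null=False, null_label="null"):
    """Two-column (signal, effect) table; null-attached effects optional."""
    with open(path, "w") as fh:
        fh.write("signal\teffect\n")
        for lab, t in zip(a.effect_labels, a.targets):
            if t == NULL_TARGET:
                if include_null:
                    fh.write(f"{null_label}\t{lab}\n")
            else:
                fh.write(f"{a.signal_labels[t]}\t{lab}\n")


def read_attachment(path, signal_labels, null_label="null") -> EffectsAttachment:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    idx = {lab: i for i, lab in enumerate(signal_labels)}
    targets, effects = [], []
    for sig, eff in zip(df["signal"].astype(str), df["effect"].astype(str)):
        effects.append(eff)
        targets.append(NULL_TARGET if sig == null_label else idx[sig])
    return EffectsAttachment(np.array(targets, dtype=int), effects, list(signal_labels))


def write_trace(trace, path):
    """Sampled chain states: step index, score, flattened adjacency bits."""
    with open(path, "w") as fh:
        fh.write("sample\tscore\tadjacency_bits\n")
        for i, (g, score) in enumerate(trace.samples):
            bits = "".join(map(str, g.adjacency.ravel().tolist()))
            fh.write(f"{i}\t{score:.6f}\t{bits}\n")


def write_edge_frequencies(freq, labels, path):
    pd.DataFrame(freq, index=labels, columns=labels).to_csv(path, sep="\t")
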