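"""Neuronal correlation matrix and ensemble detection.

Pairwise Pearson correlations of dF/F traces give each neuron a mean
correlation (mean of the off-diagonal entries in its row). Ensembles are
found by network analysis on the thresholded correlation graph: neurons
are nodes, edges connect pairs with r above a threshold (default 0.3),
and the connected components of size >= 2 are the ensembles; singletons
stay unassigned (label -1). A deterministic greedy-modularity refinement
of the components is available behind a flag for graphs where components
merge distinct groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx


@dataclass
class CorrelationGraph:
    """Correlation structure and ensemble assignment of a neuron field."""

    r: np.ndarray                 # N x N Pearson matrix (NaN rows = excluded)
    mean_correlation: np.ndarray  # per neuron, off-diagonal mean
    valid: np.ndarray             # False for constant (excluded) traces
    threshold: float | None = None
    labels: np.ndarray | None = None      # ensemble id per neuron, -1 = none
    n_ensembles: int | None = None


def correlation_matrix(traces: np.ndarray) -> CorrelationGraph:
    """Pairwise Pearson correlations of an N x T trace matrix.

    Constant traces have undefined correlations; they are flagged invalid
    and their rows/columns set to NaN (and excluded from every mean).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2 or traces.shape[1] < 3:
        raise ValueError("need at least 2 neurons and 3 time points")
    valid = traces.std(axis=1) > 0
    n = traces.shape[0]
    r = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(traces[valid])
        r[np.ix_(valid, valid)] = sub
    r[np.arange(n), np.arange(n)] = np.where(valid, 1.0, np.nan)
    off = r.copy()
    off[np.arange(n), np.arange(n)] = np.nan
    mean_corr = np.full(n, np.nan)
    has_any = (~np.isnan(off)).any(axis=1)
    mean_corr[has_any] = np.nanmean(off[has_any], axis=1)
    return CorrelationGraph(r=r, mean_correlation=mean_corr, valid=valid)


def detect_ensembles(graph: CorrelationGraph, threshold: float = 0.3,
                     refine: bool = False) -> CorrelationGraph:
    """Assign neurons to ensembles from the thresholded correlation graph.

    Edges connect valid pairs with r > threshold; ensembles are the
    connected components with at least two members, numbered 0, 1, ... in
    order of their smallest neuron index. With ``refine=True`` each
    component is further split by greedy modularity maximization
    (deterministic: fixed node order, no randomness).
    """
    r = graph.r
    n = r.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(np.nan_to_num(r, nan=-np.inf) > threshold, 1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))

    groups: list[set[int]] = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        if refine and len(comp) > 2:
            sub = g.subgraph(comp)
            parts = nx.community.greedy_modularity_communities(sub)
            groups.extend(set(p) for p in parts if len(p) >= 2)
        else:
            groups.append(set(comp))
    groups.sort(key=min)
    labels = np.full(n, -1, dtype=int)
    for k, members in enumerate(groups):
        labels[list(members)] = k
    return CorrelationGraph(r=r, mean_correlation=graph.mean_correlation,
                            valid=graph.valid, threshold=threshold,
                            labels=labels, n_ensembles=len(groups))
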