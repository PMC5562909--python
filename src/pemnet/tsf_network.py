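"""Time-series-fusion (TSF) kinetic network among metastable patterns.

Transitions are counted at a fixed lag along each trajectory's label
series — never across trajectory boundaries, since the runs are an
ensemble of uncoupled simulations.  Row-normalised counts give the
transition probability matrix; thresholding the symmetrised off-diagonal
probabilities yields an undirected graph whose connected components and
articulation (cut) vertices expose obligatory intermediate patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TransitionModel",
    "PopulationSeries",
    "count_transitions",
    "transition_probabilities",
    "population_timeseries",
    "build_graph",
    "stationary_distribution",
    "merge_counts",
]


@dataclass
class TransitionModel:
    """Lag-``lag`` transition counts and row-stochastic probabilities."""

    counts: np.ndarray          # (k, k) non-negative ints
    probabilities: np.ndarray   # (k, k); zero rows left as zeros
    zero_rows: np.ndarray       # bool flags for rows with no observations
    lag: int

    @property
    def k(self) -> int:
        return self.counts.shape[0]


@dataclass
class PopulationSeries:
    """Fraction of trajectories in each pattern at each time."""

    times: np.ndarray        # fs
    populations: np.ndarray  # (n_times, k), rows on the simplex
    n_defined: np.ndarray    # trajectories contributing at each time


def count_transitions(
    label_series: Sequence[np.ndarray] | Mapping[str, np.ndarray],
    k: int,
    lag: int = 1,
) -> TransitionModel:
    """Accumulate ordered (t, t+lag) label pairs over all trajectories.

    ``label_series`` is a sequence (or mapping by trajectory id) of
    per-trajectory label arrays.  Series no longer than ``lag``
    contribute nothing.  Total counts equal sum over trajectories of
    max(len - lag, 0).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if isinstance(label_series, Mapping):
        items = list(label_series.items())
    else:
        items = [(str(i), s) for i, s in enumerate(label_series)]
    counts = np.zeros((k, k), dtype=np.int64)
    for tid, series in items:
        s = np.asarray(series, dtype=int)
        if s.size and (s.min() < 0 or s.max() >= k):
            bad = int(np.flatnonzero((s < 0) | (s >= k))[0])
            raise ValueError(
                f"trajectory {tid}, frame {bad}: label {s[bad]} outside 0..{k - 1}"
            )
        if len(s) <= lag:
            continue
        np.add.at(counts, (s[:-lag], s[lag:]), 1)
    probs, zero = transition_probabilities(counts)
    return TransitionModel(counts=counts, probabilities=probs,
                           zero_rows=zero, lag=lag)


def transition_probabilities(
    counts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalise a count matrix; all-zero rows are flagged, not imputed."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("counts must be square")
    if np.any(c < 0):
        raise ValueError("negative transition count")
    row_sums = c.sum(axis=1)
    zero = row_sums == 0
    probs = np.zeros_like(c)
    nz = ~zero
    probs[nz] = c[nz] / row_sums[nz, None]
    return probs, zero


def population_timeseries(
    label_series: Sequence[np.ndarray],
    k: int,
    times: Sequence[np.ndarray] | None = None,
) -> PopulationSeries:
    """Per-time pattern populations over an ensemble of trajectories.

    Trajectories are aligned on a common grid: if ``times`` is omitted the
    grid is the frame index converted through position (series may have
    unequal lengths; each contributes while it is defined).  Population of
    pattern i at time t is the fraction of trajectories defined at t that
    are in pattern i; rows always sum to 1 over the defined set.
    """
    if not label_series:
        raise ValueError("no trajectories")
    arrs = [np.asarray(s, dtype=int) for s in label_series]
    if times is None:
        n_times = max(len(s) for s in arrs)
        grid = np.arange(n_times, dtype=float)
    else:
        grid = np.unique(np.concatenate([np.asarray(t, float) for t in times]))
        n_times = len(grid)
        index_of = {t: i for i, t in enumerate(grid)}
    pops = np.zeros((n_times, k))
    ndef = np.zeros(n_times, dtype=int)
    for j, s in enumerate(arrs):
        if times is None:
            rows = np.arange(len(s))
        else:
            rows = np.array([index_of[t] for t in np.asarray(times[j], float)])
        np.add.at(pops, (rows, s), 1)
        np.add.at(ndef, rows, 1)
    defined = ndef > 0
    pops[defined] /= ndef[defined, None]
    return PopulationSeries(
        times=grid[defined], populations=pops[defined],
        n_defined=ndef[defined],
    )


def stationary_distribution(probabilities: np.ndarray) -> np.ndarray:
    """Stationary distribution: leading left eigenvector, normalised.

    Requires an irreducible row-stochastic matrix for uniqueness; for a
    reducible chain the returned vector is one stationary solution.
    """
    p = np.asarray(probabilities, dtype=float)
    w, v = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def build_graph(
    probabilities: np.ndarray, edge_threshold: float = 0.0
) -> tuple[nx.Graph, list[set[int]], list[int]]:
    """Undirected pattern graph from a transition-probability matrix.

    Edge (i, j), i != j, exists iff max(P[i,j], P[j,i]) >= threshold (and
    is positive); self-transitions never create edges.  Returns the graph
    (edge weight = symmetrised probability), its connected components and
    its articulation vertices sorted ascending.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("probability matrix must be square")
    if not 0.0 <= edge_threshold <= 1.0:
        raise ValueError(f"edge_threshold {edge_threshold} outside [0, 1]")
    k = p.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            w = max(p[i, j], p[j, i])
            if w > 0 and w >= edge_threshold:
                g.add_edge(i, j, weight=float(w))
    components = [set(c) for c in nx.connected_components(g)]
    cut_vertices = sorted(nx.articulation_points(g))
    return g, components, cut_vertices


def merge_counts(counts: np.ndarray, mapping: Mapping[int, int]) -> np.ndarray:
    """Aggregate a count matrix under a pattern-merge mapping.

    Merged pattern ids are renumbered compactly in ascending order of the
    representative label.
    """
    reps = sorted(set(mapping.values()))
    idx = {r: i for i, r in enumerate(reps)}
    out = np.zeros((len(reps), len(reps)), dtype=counts.dtype)
    k = counts.shape[0]
    for i in range(k):
        for j in range(k):
            out[idx[mapping[i]], idx[mapping[j]]] += counts[i, j]
    return out


# ---------------------------------------------------------------------------
# Tabular / graph export
# ---------------------------------------------------------------------------

def matrix_to_frame(m: np.ndarray, prefix: str = "pattern_") -> pd.DataFrame:
    labels = [f"{prefix}{i}" for i in range(m.shape[0])]
    return pd.DataFrame(m, index=labels, columns=labels)


def populations_to_frame(ps: PopulationSeries) -> pd.DataFrame:
    df = pd.DataFrame(
        ps.populations,
        columns=[f"pattern_{i}" for i in range(ps.populations.shape[1])],
    )
    df.insert(0, "time_fs", ps.times)
    df["n_defined"] = ps.n_defined
    return df
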