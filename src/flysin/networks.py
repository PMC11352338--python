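"""Directed weighted network metrics and the random-network null model.

Metrics
-------
Four measures are computed on each social interaction network, under either
edge weight (interaction ``count`` or total ``duration_s``).  Strong ties are
short: the path distance of an edge is ``1/weight``.

* global efficiency — mean over ordered node pairs of the inverse shortest
  path distance (unreachable pairs contribute 0);
* local clustering — the directed weighted generalization of Fagiolo
  (geometric mean of triangle weights over a total-degree denominator,
  weights rescaled by the graph maximum);
* betweenness centrality — fraction of shortest paths through a node,
  normalized by (n−1)(n−2);
* closeness centrality — inverse mean incoming distance with the
  Wasserman–Faust reachability correction for disconnected graphs
  (``harmonic`` variant switchable).

Null model
----------
Chimeric "random networks" are assembled by drawing ``group_size`` flies
from different recordings of the same experimental group, overlaying their
trajectories in the common arena frame, and re-running interaction detection
as if they had been co-housed.  Interactions found there reflect spatial
coincidence only, so observed metrics are normalized as
``z = (observed − mean(null)) / sd(null)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .interaction import InteractionCriteria, build_network, detect_events_arrays, tracks_to_arrays

__all__ = [
    "NullModelSpec",
    "MetricZScore",
    "write_graphml",
    "read_graphml",
    "METRICS",
    "WEIGHT_MODES",
    "global_efficiency",
    "local_clustering",
    "betweenness",
    "closeness",
    "recording_summary",
    "build_random_networks",
    "zscore",
    "zscore_table",
]

METRICS = ("global_efficiency", "clustering_coefficient",
           "betweenness_centrality", "closeness_centrality")
WEIGHT_MODES = ("count", "duration")

_WEIGHT_ATTR = {"count": "count", "duration": "duration_s"}


@dataclass(frozen=True)
class NullModelSpec:
    """How many chimeric networks to build and from how many flies each."""

    n_random_networks: int = 10_000
    group_size: int = 12
    all_distinct_recordings: bool = False

    def __post_init__(self):
        if self.n_random_networks < 1:
            raise ValueError("n_random_networks must be >= 1")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")


@dataclass(frozen=True)
class MetricZScore:
    """An observed metric normalized against its random-network null."""

    metric_name: str
    weight_mode: str
    level: str  # "global" or "local"
    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_null: int
    undefined: bool = False


def write_graphml(g: nx.DiGraph, path) -> None:
    """GraphML export (node ids and both edge weights preserved)."""
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.DiGraph:
    """GraphML import; node labels are restored to integer fly ids."""
    g = nx.read_graphml(path)
    if not g.is_directed():
        raise ValueError("social interaction networks are directed")
    return nx.relabel_nodes(g, {u: int(u) for u in g.nodes})


def _distance_graph(g: nx.DiGraph, weight_mode: str) -> nx.DiGraph:
    attr = _WEIGHT_ATTR[weight_mode]
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        w = d[attr]
        if w <= 0:
            raise ValueError("edge weights must be positive")
        h.add_edge(u, v, dist=1.0 / w, w=w)
    return h


def global_efficiency(g: nx.DiGraph, weight_mode: str = "count") -> float:
    """Mean inverse shortest-path distance over ordered node pairs."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    h = _distance_graph(g, weight_mode)
    total = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(h, weight="dist"):
        for v, d in dists.items():
            if d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def local_clustering(g: nx.DiGraph, weight_mode: str = "count") -> dict:
    """Per-node directed weighted clustering (Fagiolo); degree<2 nodes score 0."""
    h = _distance_graph(g, weight_mode)
    return nx.clustering(h, weight="w")


def betweenness(g: nx.DiGraph, weight_mode: str = "count") -> dict:
    """Per-node shortest-path betweenness, normalized by (n−1)(n−2)."""
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    h = _distance_graph(g, weight_mode)
    return nx.betweenness_centrality(h, weight="dist", normalized=True)


def closeness(g: nx.DiGraph, weight_mode: str = "count",
              variant: str = "wasserman_faust") -> dict:
    """Per-node closeness on incoming distances.

    ``wasserman_faust`` (default) scales by the reachable fraction so that
    disconnected graphs stay comparable; ``harmonic`` sums inverse distances
    (normalized by n−1).
    """
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    h = _distance_graph(g, weight_mode)
    if variant == "wasserman_faust":
        return nx.closeness_centrality(h, distance="dist", wf_improved=True)
    if variant == "harmonic":
        n = h.number_of_nodes()
        c = nx.harmonic_centrality(h, distance="dist")
        return {u: v / (n - 1) for u, v in c.items()}
    raise ValueError("variant must be 'wasserman_faust' or 'harmonic'")


def recording_summary(g: nx.DiGraph,
                      weight_modes: Sequence[str] = WEIGHT_MODES) -> dict:
    """One scalar per (metric, weight_mode) for a recording.

    Global efficiency is inherently global; the three local metrics are
    summarized by their mean over nodes (per-node values are available from
    the individual metric functions).
    """
    out = {}
    for mode in weight_modes:
        out[("global_efficiency", mode)] = global_efficiency(g, mode)
        for name, fn in (("clustering_coefficient", local_clustering),
                         ("betweenness_centrality", betweenness),
                         ("closeness_centrality", closeness)):
            vals = fn(g, mode)
            out[(name, mode)] = float(np.mean(list(vals.values())))
    return out


def _recording_arrays(recordings):
    """Cache (pos, heading, present) per recording, on each one's own grid."""
    return [tracks_to_arrays(tracks) for tracks in recordings]


def build_random_networks(recordings: Sequence[Sequence],
                          spec: NullModelSpec,
                          criteria: InteractionCriteria,
                          frame_rate_hz: float,
                          rng: np.random.Generator | int | None = None,
                          _arrays=None) -> list[nx.DiGraph]:
    """Chimeric null networks from flies pooled across recordings.

    Each network draws ``spec.group_size`` (recording, fly) pairs uniformly
    without replacement from the pool — never all from a single recording
    (all-distinct-recordings available via the spec flag) — overlays their
    trajectories on the common frame grid, and re-runs event detection.
    Sampling is with replacement across networks.
    """
    rng = np.random.default_rng(rng)
    if len(recordings) < 2:
        raise ValueError("need >= 2 recordings in the group for the null model")
    arrays = _arrays if _arrays is not None else _recording_arrays(recordings)
    pool = [(ri, fi) for ri, arr in enumerate(arrays) for fi in range(arr[1].shape[1])]
    if spec.all_distinct_recordings and len(recordings) < spec.group_size:
        raise ValueError("all_distinct_recordings needs >= group_size recordings")
    if len(pool) < spec.group_size:
        raise ValueError("pool smaller than group_size")
    n_frames = min(arr[1].shape[0] for arr in arrays)
    nets = []
    for _ in range(spec.n_random_networks):
        while True:
            idx = rng.choice(len(pool), size=spec.group_size, replace=False)
            recs = [pool[i][0] for i in idx]
            if spec.all_distinct_recordings:
                if len(set(recs)) == spec.group_size:
                    break
            elif len(set(recs)) > 1:
                break
        pos = np.stack([arrays[pool[i][0]][0][:n_frames, pool[i][1]] for i in idx], axis=1)
        heading = np.stack([arrays[pool[i][0]][1][:n_frames, pool[i][1]] for i in idx], axis=1)
        present = np.stack([arrays[pool[i][0]][2][:n_frames, pool[i][1]] for i in idx], axis=1)
        events = detect_events_arrays(pos, heading, present, criteria, frame_rate_hz)
        nets.append(build_network(events, spec.group_size, recording_id="null"))
    return nets


def zscore(observed: float, null_values: Iterable[float],
           metric_name: str = "", weight_mode: str = "", level: str = "global") -> MetricZScore:
    """Normalize an observed metric against its null sample.

    sd uses the n−1 denominator.  A degenerate null (sd = 0) gives z = 0 when
    the observation equals the null mean and is flagged undefined otherwise.
    """
    null = np.asarray(list(null_values), dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    if null.size < 2:
        raise ValueError("need >= 2 null values")
    mu = float(np.mean(null))
    sd = float(np.std(null, ddof=1))
    if sd > 0:
        z, undef = (observed - mu) / sd, False
    elif observed == mu:
        z, undef = 0.0, False
    else:
        z, undef = np.nan, True
    return MetricZScore(metric_name, weight_mode, level, float(observed),
                        mu, sd, z, int(null.size), undef)


def zscore_table(observed_graphs: Sequence[nx.DiGraph],
                 null_graphs: Sequence[nx.DiGraph],
                 weight_modes: Sequence[str] = WEIGHT_MODES) -> pd.DataFrame:
    """Tidy z-score table for a set of recordings against one null sample.

    Columns: recording, genotype, metric, weight_mode, level, observed,
    null_mean, null_sd, z, n_null.
    """
    null_summaries = [recording_summary(g, weight_modes) for g in null_graphs]
    rows = []
    for g in observed_graphs:
        obs = recording_summary(g, weight_modes)
        for key, val in obs.items():
            metric, mode = key
            null_vals = [s[key] for s in null_summaries]
            zs = zscore(val, null_vals, metric, mode,
                        level="global" if metric == "global_efficiency" else "local")
            rows.append(
                {
                    "recording": g.graph.get("recording_id", ""),
                    "genotype": g.graph.get("genotype", ""),
                    "metric": metric,
                    "weight_mode": mode,
                    "level": zs.level,
                    "observed": zs.observed,
                    "null_mean": zs.null_mean,
                    "null_sd": zs.null_sd,
                    "z": zs.z,
                    "n_null": zs.n_null,
                }
            )
    return pd.DataFrame(rows)
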