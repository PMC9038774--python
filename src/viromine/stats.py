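"""Abundance normalisation, diversity, UPGMA and network statistics.

TPM (transcripts per kilobase per million) length-normalises read counts so
every sample sums to 10^6, making gene abundances comparable across samples
with different sequencing depths. Alpha diversity follows the vegan-style
conventions: natural-log Shannon, Gini-Simpson (1 - sum p_i^2), Pielou
evenness H/ln(S), bias-corrected Chao1 and the abundance-based coverage
estimator (ACE) with rare cutoff 10. Beta diversity is Bray-Curtis, samples
are clustered by UPGMA (average linkage, deterministic smallest-id
tie-break), and gene-sharing graphs are summarised by density, average
clustering coefficient and average neighbour count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha

from .params import Parameters

__all__ = ["NetworkStats", "tpm", "alpha_diversity", "bray_curtis",
           "upgma", "network_stats"]


def tpm(counts: pd.DataFrame, lengths_bp: Mapping[str, float],
        params: Parameters | None = None) -> pd.DataFrame:
    """Per-sample TPM: 1e6 * (c_i/L_i) / sum_j (c_j/L_j).

    ``counts`` is samples x features. All-zero samples yield all-zero rows
    with a warning instead of NaNs.
    """
    params = params or Parameters()
    missing = [f for f in counts.columns if f not in lengths_bp]
    if missing:
        raise KeyError(f"no length for feature(s) {missing[:5]}")
    lens = np.array([lengths_bp[f] for f in counts.columns], dtype=float)
    if (lens <= 0).any():
        raise ValueError("feature lengths must be positive")
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative count encountered")
    rate = values / lens
    totals = rate.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero sample(s) in TPM input",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = params.tpm_scale * rate / totals
    out[zero, :] = 0.0
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def _ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator with gamma^2 floored at 0.

    Degenerate cases: no rare taxa -> observed richness; sample coverage
    estimate of zero (all rare individuals are singletons) -> bias-corrected
    Chao1 as documented fallback.
    """
    counts = counts[counts > 0]
    s_obs = counts.size
    rare = counts[counts <= rare_threshold]
    s_abund = s_obs - rare.size
    if rare.size == 0:
        return float(s_obs)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == f1:  # coverage estimate 0; ACE undefined
        return float(skbio_alpha.chao1(counts.astype(int), bias_corrected=True))
    c_ace = 1.0 - f1 / n_rare
    top = sum(i * (i - 1) * int((rare == i).sum())
              for i in range(1, rare_threshold + 1))
    gamma2 = max(0.0, (rare.size / c_ace) * top / (n_rare * (n_rare - 1)) - 1.0)
    return s_abund + rare.size / c_ace + (f1 / c_ace) * gamma2


def alpha_diversity(counts: pd.DataFrame,
                    params: Parameters | None = None) -> pd.DataFrame:
    """Per-sample richness, Chao1, ACE, Shannon, Gini-Simpson and Pielou.

    ``counts`` must be integer counts (Chao1/ACE rely on singleton and
    doubleton frequencies). All-zero samples get NaN for every index, with a
    warning; Pielou is NaN when richness <= 1.
    """
    params = params or Parameters()
    values = counts.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError("alpha diversity requires integer counts")
    values = np.round(values).astype(np.int64)
    if (values < 0).any():
        raise ValueError("negative count encountered")
    rows = []
    for i, sample in enumerate(counts.index):
        v = values[i]
        total = int(v.sum())
        if total == 0:
            warnings.warn(f"sample {sample}: all-zero counts, indices undefined",
                          stacklevel=2)
            rows.append(dict.fromkeys(
                ["richness", "chao1", "ace", "shannon", "simpson", "pielou"],
                np.nan))
            continue
        richness = int((v > 0).sum())
        base = params.shannon_base if params.shannon_base else math.e
        h = float(skbio_alpha.shannon(v, base=base))
        rows.append({
            "richness": richness,
            "chao1": float(skbio_alpha.chao1(v, bias_corrected=True)),
            "ace": _ace(v.astype(float)),
            "shannon": h,
            "simpson": float(skbio_alpha.simpson(v)),
            "pielou": h / math.log(richness, base) if richness > 1 else np.nan,
        })
    return pd.DataFrame(rows, index=counts.index)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i). A pair of all-zero samples
    has no defined dissimilarity; it is reported as 0 with a warning.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundance encountered")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(values, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s); dissimilarity set to 0",
                      stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def upgma(dissimilarity: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) agglomeration serialized as newick with
    branch lengths; node heights are half the merge dissimilarity.

    Ties between candidate pairs are broken deterministically by the smallest
    member sample id (then the second-smallest). Input must be a symmetric
    zero-diagonal matrix.
    """
    d = dissimilarity.to_numpy(dtype=float)
    ids = list(dissimilarity.index)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("UPGMA requires a symmetric dissimilarity matrix")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("UPGMA requires a zero diagonal")
    if len(ids) == 1:
        return f"{ids[0]};"
    # active cluster state: newick fragment, height, size, sorted member ids
    clusters: dict[int, dict] = {
        i: {"nwk": str(ids[i]), "height": 0.0, "size": 1, "members": (str(ids[i]),)}
        for i in range(len(ids))
    }
    dist: dict[frozenset, float] = {
        frozenset((i, j)): float(d[i, j])
        for i in range(len(ids)) for j in range(i + 1, len(ids))
    }
    next_id = len(ids)
    while len(clusters) > 1:
        def sort_key(pair):
            a, b = sorted(pair, key=lambda c: clusters[c]["members"])
            key = sorted(clusters[a]["members"] + clusters[b]["members"])
            return (dist[pair], key)
        pair = min(dist, key=sort_key)
        a, b = sorted(pair, key=lambda c: clusters[c]["members"])
        h = dist[pair] / 2.0
        ca, cb = clusters.pop(a), clusters.pop(b)
        merged = {
            "nwk": (f"({ca['nwk']}:{h - ca['height']:.10g},"
                    f"{cb['nwk']}:{h - cb['height']:.10g})"),
            "height": h,
            "size": ca["size"] + cb["size"],
            "members": tuple(sorted(ca["members"] + cb["members"])),
        }
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        # inter-cluster distance = unweighted mean over all cross-member pairs
        idx = {str(s): i for i, s in enumerate(ids)}
        mem_m = [idx[m] for m in merged["members"]]
        for c in clusters:
            mem_c = [idx[m] for m in clusters[c]["members"]]
            dist[frozenset((next_id, c))] = float(
                np.mean([d[x, y] for x in mem_m for y in mem_c]))
        clusters[next_id] = merged
        next_id += 1
    root = next(iter(clusters.values()))
    return root["nwk"] + ";"


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    density: float | None
    avg_clustering_coefficient: float | None
    avg_neighbors: float | None
    n_dropped: int = 0  # self-loops / duplicate edges removed


def network_stats(edges: Iterable[tuple[str, str]],
                  nodes: Iterable[str] | None = None) -> NetworkStats:
    """Summary statistics of a simple undirected graph.

    Self-loops and duplicate edges are dropped (counted in ``n_dropped``).
    Density = 2E / (N(N-1)); average neighbours = 2E / N; the clustering
    coefficient averages over all nodes, counting degree-<2 nodes as 0
    (Cytoscape NetworkAnalyzer convention).
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    dropped = 0
    for u, v in edges:
        if u == v or g.has_edge(u, v):
            dropped += 1
            continue
        g.add_edge(u, v)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        return NetworkStats(n, e, None, None, None, dropped)
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        density=2 * e / (n * (n - 1)),
        avg_clustering_coefficient=float(nx.average_clustering(g)),
        avg_neighbors=2 * e / n,
        n_dropped=dropped,
    )
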