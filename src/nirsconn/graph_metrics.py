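"""Binary-graph topology metrics, threshold sweep, and small-world analysis.

Metrics on an undirected simple graph with adjacency a_ij:

* clustering coefficient  C = (1/n) sum_i 2 t_i / (k_i (k_i - 1)),
  t_i = triangles at node i; nodes with k_i < 2 contribute 0.
* global efficiency       E_glob = (1/(N(N-1))) sum_{i != j} 1/d_ij,
  with 1/inf = 0 for disconnected pairs.
* characteristic path length  L_p = mean shortest-path length over
  *connected* ordered pairs only (disconnected pairs excluded).
* local efficiency        E_loc,i = global efficiency of the subgraph
  induced by i's neighbours; nodes with k_i < 2 contribute 0.
* betweenness centrality  B_h = (1/((n-1)(n-2))) sum over ordered pairs
  (i, j), i != j != h, of the fraction of shortest i-j paths through h.

Networks are built from a correlation matrix either by an absolute
correlation cut (r > 0.7) or by a density (sparsity) threshold T that keeps
the floor(T * 231) strongest edges; the sweep T = 0.1..0.9 yields
per-threshold profiles whose area under the curve (trapezoid over T) is the
per-subject scalar used in nodal group comparisons.

Small-worldness sigma = gamma / lambda compares clustering and path length
against matched random networks generated by Maslov-Sneppen
degree-preserving double-edge swaps (default 100 nulls, 10 swaps per edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import BinaryNetwork, ConnectivityMatrix
from .edge_stats import paired_t
from .errors import InvalidInputError, InvalidParameterError

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def density_threshold(mat: ConnectivityMatrix, T: float) -> BinaryNetwork:
    """Keep the floor(T * n_pairs) strongest off-diagonal edges.

    Ties at the cut are broken by ascending (i, j) lexicographic order, so
    the construction is deterministic; edge sets are nested across T.
    """
    if not 0.0 < T < 1.0:
        raise InvalidParameterError("density threshold T must be in (0, 1)")
    n = mat.n_channels
    iu = np.triu_indices(n, k=1)
    vals = mat.values[iu]
    n_keep = int(np.floor(T * vals.size))
    adj = np.zeros((n, n), dtype=np.int8)
    if n_keep > 0:
        order = np.lexsort((iu[1], iu[0], -vals))  # strongest first, lexicographic ties
        keep = order[:n_keep]
        adj[iu[0][keep], iu[1][keep]] = 1
        adj = adj + adj.T
    return BinaryNetwork(adj, threshold_used=T, thresholding_mode="density")


# ---------------------------------------------------------------------------
# scalar and nodal metrics
# ---------------------------------------------------------------------------

def clustering_coefficient(net: BinaryNetwork) -> float:
    """Mean clustering coefficient; degree < 2 nodes contribute 0."""
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(g, count_zeros=True))


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over all ordered pairs (1/inf = 0)."""
    g = net.to_networkx()
    if g.number_of_nodes() < 2:
        return 0.0
    return float(nx.global_efficiency(g))


def char_path_length(net: BinaryNetwork) -> float:
    """Mean shortest-path length over connected pairs only; NaN if no edges."""
    g = net.to_networkx()
    total = 0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    if count == 0:
        return float("nan")
    return total / count


def local_efficiency(net: BinaryNetwork) -> tuple[float, np.ndarray]:
    """(mean, nodal) local efficiency.

    Nodal value = global efficiency of the subgraph induced by the node's
    neighbours; nodes with fewer than 2 neighbours score 0.
    """
    g = net.to_networkx()
    nodal = np.zeros(net.n_nodes)
    for v in g.nodes():
        nbrs = list(g[v])
        if len(nbrs) < 2:
            continue
        nodal[v] = nx.global_efficiency(g.subgraph(nbrs))
    return float(nodal.mean()) if net.n_nodes else 0.0, nodal


def betweenness(net: BinaryNetwork, ordered_pairs: bool = True) -> np.ndarray:
    """Normalized betweenness centrality per node.

    The default normalizer (n-1)(n-2) counts ordered pairs; for an undirected
    graph this coincides with the conventional normalized centrality.  With
    ``ordered_pairs=False`` the halved (unordered) convention is returned.
    """
    g = net.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=True)
    out = np.array([bc[v] for v in range(net.n_nodes)])
    return out if ordered_pairs else out / 2.0


# ---------------------------------------------------------------------------
# random nulls and small-worldness
# ---------------------------------------------------------------------------

def rewire_preserving_degree(net: BinaryNetwork, n_swap_per_edge: int = 10,
                             seed: int | None = None) -> BinaryNetwork:
    """Maslov-Sneppen double-edge-swap randomization.

    Preserves every node's degree exactly; no self-loops or multi-edges.
    Graphs too small or too constrained to swap are returned as copies with
    the ``degenerate`` flag set.
    """
    g = net.to_networkx()
    m = g.number_of_edges()
    if m < 2:
        return BinaryNetwork(net.adjacency.copy(), net.threshold_used,
                             net.thresholding_mode, degenerate=True)
    degenerate = False
    try:
        nx.double_edge_swap(g, nswap=n_swap_per_edge * m,
                            max_tries=100 * n_swap_per_edge * m, seed=seed)
    except nx.NetworkXError:
        # includes graphs with < 4 nodes and swap-exhausted graphs (e.g. K3)
        degenerate = True
    return BinaryNetwork.from_networkx(g, net.n_nodes, net.threshold_used,
                                       net.thresholding_mode, degenerate=degenerate)


@dataclass
class SmallWorldResult:
    gamma: float
    lambda_: float
    sigma: float
    Cnet: float
    Lnet: float
    Cran: float
    Lran: float
    n_null: int = 100
    null_seed: int = 0
    undefined: bool = False


def small_worldness(net: BinaryNetwork, n_null: int = 100,
                    seed: int = 0, n_swap_per_edge: int = 10) -> SmallWorldResult:
    """gamma = C/C_ran, lambda = L/L_ran, sigma = gamma/lambda against
    ``n_null`` degree-preserving random networks.

    ``undefined`` is set when the null clustering vanishes (degenerate
    sparse graphs); sigma is then NaN.
    """
    cnet = clustering_coefficient(net)
    lnet = char_path_length(net)
    rng = np.random.default_rng(seed)
    cs = np.empty(n_null)
    ls = np.empty(n_null)
    for k in range(n_null):
        null = rewire_preserving_degree(net, n_swap_per_edge,
                                        seed=int(rng.integers(0, 2**31 - 1)))
        cs[k] = clustering_coefficient(null)
        ls[k] = char_path_length(null)
    cran = float(cs.mean())
    lran = float(np.nanmean(ls)) if np.any(np.isfinite(ls)) else float("nan")
    if cran == 0 or not np.isfinite(lran) or lran == 0 or not np.isfinite(lnet):
        return SmallWorldResult(float("nan"), float("nan"), float("nan"),
                                cnet, lnet, cran, lran, n_null, seed, undefined=True)
    gamma = cnet / cran
    lam = lnet / lran
    sigma = gamma / lam if lam != 0 else float("nan")
    return SmallWorldResult(gamma, lam, sigma, cnet, lnet, cran, lran, n_null, seed)


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class GraphMetricProfile:
    """Per-threshold metric curves for one connectivity matrix."""

    thresholds: np.ndarray
    cnet: np.ndarray
    eglobal: np.ndarray
    eloc: np.ndarray
    lp: np.ndarray            # NaN where undefined (no edges)
    nodal_bc: np.ndarray      # (n_thresholds, n_nodes)
    nodal_eloc: np.ndarray    # (n_thresholds, n_nodes)
    subject_id: str = ""
    session: str = ""

    def _auc(self, y: np.ndarray) -> float:
        """Trapezoid AUC over T, normalized by the T-span actually used.

        NaN points are dropped and the normalization renormalized so that a
        constant curve c has AUC exactly c.
        """
        t = np.asarray(self.thresholds, dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 2:
            return float(y[ok][0]) if ok.sum() == 1 else float("nan")
        t, y = t[ok], y[ok]
        return float(np.trapezoid(y, t) / (t[-1] - t[0]))

    def auc(self, metric: str) -> float:
        return self._auc(getattr(self, metric))

    def auc_nodal(self, metric: str) -> np.ndarray:
        curves = getattr(self, metric)  # (n_thresh, n_nodes)
        return np.array([self._auc(curves[:, v]) for v in range(curves.shape[1])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "Cnet": self.cnet,
            "Eglobal": self.eglobal,
            "Eloc": self.eloc,
            "Lp": self.lp,
        })


def metric_sweep(mat: ConnectivityMatrix,
                 thresholds=DEFAULT_THRESHOLDS) -> GraphMetricProfile:
    """Density-threshold the matrix at each T and compute all metrics."""
    thresholds = np.asarray(thresholds, dtype=float)
    nt = thresholds.size
    n = mat.n_channels
    prof = GraphMetricProfile(
        thresholds=thresholds,
        cnet=np.zeros(nt), eglobal=np.zeros(nt), eloc=np.zeros(nt),
        lp=np.zeros(nt), nodal_bc=np.zeros((nt, n)), nodal_eloc=np.zeros((nt, n)),
        subject_id=mat.subject_id, session=mat.session,
    )
    for k, T in enumerate(thresholds):
        net = density_threshold(mat, T)
        prof.cnet[k] = clustering_coefficient(net)
        prof.eglobal[k] = global_efficiency(net)
        mean_eloc, nodal_eloc = local_efficiency(net)
        prof.eloc[k] = mean_eloc
        prof.nodal_eloc[k] = nodal_eloc
        prof.lp[k] = char_path_length(net)
        prof.nodal_bc[k] = betweenness(net)
    return prof


def nodal_group_comparison(profiles_pre: list[GraphMetricProfile],
                           profiles_post: list[GraphMetricProfile],
                           metric: str = "nodal_bc",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-node paired t-tests on AUC-over-sweep nodal values.

    ``metric`` is "nodal_bc"/"betweenness" or "nodal_eloc" (nodal local
    efficiency).  Flags are uncorrected at ``alpha`` (per-node presentation).
    """
    if metric == "betweenness":
        metric = "nodal_bc"
    if metric not in ("nodal_bc", "nodal_eloc"):
        raise InvalidParameterError("metric must be 'betweenness'/'nodal_bc' or 'nodal_eloc'")
    if len(profiles_pre) != len(profiles_post) or not profiles_pre:
        raise InvalidInputError("need equal, non-empty paired profile lists")
    pre = np.stack([p.auc_nodal(metric) for p in profiles_pre])    # (subjects, nodes)
    post = np.stack([p.auc_nodal(metric) for p in profiles_post])
    n_nodes = pre.shape[1]
    rows = []
    for v in range(n_nodes):
        t, p = paired_t(pre[:, v], post[:, v])
        rows.append({
            "channel": f"CH{v + 1:02d}",
            "mean_pre": pre[:, v].mean(),
            "mean_post": post[:, v].mean(),
            "t": t,
            "p": p,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)
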