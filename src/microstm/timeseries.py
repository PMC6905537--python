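"""Temporal subcommunity dynamics via topic-correlation-graph clustering.

Topics whose posterior frequencies co-vary across samples form edges of an
undirected correlation graph; its connected components ("topic clusters")
are interpreted as community regimes.  Cluster frequencies tracked over the
day covariate, with 80% uncertainty bands from posterior theta draws,
expose regime shifts; a change day is a day whose dominant cluster differs
from the previous day's.  A Bray-Curtis / Ward hierarchical clustering of
the raw table is provided as the conventional comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .stm_core import StmFit, sample_theta_all, sample_tokens

__all__ = [
    "CorrelationGraph", "EventTimeline",
    "topic_correlation_graph", "cluster_day_frequencies", "detect_events",
    "taxa_by_cluster", "hierarchical_cluster",
]


@dataclass
class CorrelationGraph:
    """Topic-to-topic correlation graph and its connected components."""

    graph: nx.Graph
    cutoff: float
    clusters: list          # list of sorted topic-index lists, multi-topic first
    singletons: list        # topics with no edge ("misc")

    @property
    def cluster_labels(self) -> list[str]:
        return [f"cluster{j + 1}" for j in range(len(self.clusters))] + (
            ["misc"] if self.singletons else [])

    def membership(self) -> dict[int, str]:
        out = {}
        for j, members in enumerate(self.clusters):
            for t in members:
                out[t] = f"cluster{j + 1}"
        for t in self.singletons:
            out[t] = "misc"
        return out

    def edge_list(self):
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


@dataclass
class EventTimeline:
    """Per-day posterior cluster frequencies with uncertainty bands."""

    days: np.ndarray
    labels: list
    mean: np.ndarray     # days x clusters
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_draws: int
    change_days: list = field(default_factory=list)


def topic_correlation_graph(
    fit: StmFit,
    cutoff: float = 0.05,
    n_draws: int = 500,
    seed: int = 0,
) -> CorrelationGraph:
    """Threshold the correlations of topic frequencies into a graph.

    Correlations are computed between topic columns over posterior theta
    draws pooled across samples (capturing both the logistic-normal
    covariance and covariate-induced co-occurrence); an edge joins two
    topics when their correlation exceeds ``cutoff``.  Clusters are the
    connected components with >= 2 topics; edgeless topics form "misc".
    """
    if fit.K < 2:
        raise ValueError("need at least 2 topics")
    if cutoff >= 1:
        raise ValueError("cutoff must be < 1")
    thetas = sample_theta_all(fit, n_draws, seed=seed)      # (draws, M, K)
    pooled = thetas.reshape(-1, fit.K)
    corr = np.corrcoef(pooled, rowvar=False)
    G = nx.Graph()
    G.add_nodes_from(range(fit.K))
    for a in range(fit.K):
        for b in range(a + 1, fit.K):
            if corr[a, b] > cutoff:
                G.add_edge(a, b, weight=float(corr[a, b]))
    comps = [sorted(c) for c in nx.connected_components(G)]
    clusters = sorted([c for c in comps if len(c) > 1])
    singletons = sorted(t for c in comps if len(c) == 1 for t in c)
    return CorrelationGraph(graph=G, cutoff=cutoff, clusters=clusters,
                            singletons=singletons)


def cluster_day_frequencies(
    fit: StmFit,
    graph: CorrelationGraph,
    day: np.ndarray,
    n_draws: int = 200,
    seed: int = 0,
    level: float = 0.80,
) -> EventTimeline:
    """Posterior frequency of each topic cluster as a function of day.

    Theta draws map linearly to cluster frequencies (sum of member topics,
    misc topics pooled into one band); samples sharing a day are pooled by
    averaging.  Days without samples remain gaps (no interpolation).
    """
    day = np.asarray(day, dtype=float)
    if day.shape[0] != fit.M:
        raise ValueError("day must provide one value per sample")
    if np.any(~np.isfinite(day)):
        raise ValueError("missing day value(s)")
    member_sets = list(graph.clusters) + ([graph.singletons] if graph.singletons else [])
    labels = graph.cluster_labels
    thetas = sample_theta_all(fit, n_draws, seed=seed)          # (draws, M, K)
    cf = np.stack([thetas[:, :, ms].sum(axis=2) for ms in member_sets], axis=2)
    udays = np.unique(day)
    nD, nC = len(udays), len(member_sets)
    mean = np.empty((nD, nC))
    lower = np.empty((nD, nC))
    upper = np.empty((nD, nC))
    a = (1 - level) / 2
    for i, d in enumerate(udays):
        sel = cf[:, day == d, :].mean(axis=1)    # pooled over same-day samples
        mean[i] = sel.mean(axis=0)
        lower[i] = np.quantile(sel, a, axis=0)
        upper[i] = np.quantile(sel, 1 - a, axis=0)
    tl = EventTimeline(days=udays, labels=labels, mean=mean, lower=lower,
                       upper=upper, level=level, n_draws=n_draws)
    tl.change_days = detect_events(tl)
    return tl


def detect_events(timeline: EventTimeline, min_dominance: float = 0.5) -> list:
    """Days where the dominant topic cluster changes.

    The dominant cluster of a day is the argmax of the posterior mean
    frequencies, required to reach ``min_dominance``; a day failing the
    requirement inherits the previous day's dominant cluster, so brief
    mixed states do not spawn spurious events.
    """
    if timeline.mean.size == 0:
        raise ValueError("empty timeline")
    events = []
    current = None
    for i, d in enumerate(timeline.days):
        j = int(np.argmax(timeline.mean[i]))
        if timeline.mean[i, j] < min_dominance:
            dom = current
        else:
            dom = j
        if current is not None and dom is not None and dom != current:
            events.append(d)
        if dom is not None:
            current = dom
    return events


def taxa_by_cluster(
    fit: StmFit,
    graph: CorrelationGraph,
    taxonomy: dict[str, tuple],
    rank: str = "family",
    n_draws: int = 20,
    tokens_per_draw: int = 500,
    seed: int = 0,
):
    """Frequency of taxa among simulated tokens, conditional on cluster.

    Tokens are simulated per sample (z from posterior theta draws, OTUs
    from beta); each token's topic maps to its cluster and its OTU to the
    taxon at ``rank``.  Rows (clusters) sum to 1; a cluster that received
    no tokens yields a NaN row rather than silent zeros.
    """
    from .io_prep import RANKS

    if rank not in RANKS:
        raise ValueError(f"rank {rank!r} not available; expected one of {RANKS}")
    ri = RANKS.index(rank)
    member = graph.membership()
    labels = graph.cluster_labels
    lab_index = {l: j for j, l in enumerate(labels)}
    taxa = sorted({taxonomy[o][ri] for o in fit.vocabulary if o in taxonomy})
    missing = [o for o in fit.vocabulary if o not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy missing for OTUs: {missing[:5]}")
    tax_index = {t: j for j, t in enumerate(taxa)}
    counts = np.zeros((len(labels), len(taxa)))
    rng = np.random.default_rng(seed)
    from .stm_core import sample_theta

    for m in range(fit.M):
        ths = sample_theta(fit, m, n_draws, seed=int(rng.integers(2 ** 31)))
        for i in range(n_draws):
            draw = sample_tokens(fit, ths[i], tokens_per_draw,
                                 seed=int(rng.integers(2 ** 31)), draw_index=i)
            for z, o in zip(draw.z, draw.w_sim):
                counts[lab_index[member[int(z)]], tax_index[taxonomy[o][ri]]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), np.nan)
    import pandas as pd
    return pd.DataFrame(freq, index=labels, columns=taxa)


def hierarchical_cluster(
    m: np.ndarray,
    n_clusters: int,
    distance: str = "bray-curtis",
    linkage_method: str = "ward",
    normalize: bool = False,
) -> np.ndarray:
    """Ward hierarchical clustering on Bray-Curtis dissimilarities.

    BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i) on the (possibly normalized)
    rows; Ward linkage applies the Lance-Williams update directly to the
    dissimilarity (the common ecology convention, though BC is not
    Euclidean); the tree is cut at ``n_clusters``.  With ``normalize``,
    each row is divided by its geometric mean (library-size correction) and
    each feature is then centered and scaled.
    """
    if distance != "bray-curtis" or linkage_method != "ward":
        raise ValueError("only bray-curtis distance with ward linkage is supported")
    m = np.asarray(m, dtype=float)
    if n_clusters > m.shape[0]:
        raise ValueError("n_clusters must be <= number of observations")
    if normalize:
        gm = np.exp(np.mean(np.log(m + 1.0), axis=1, keepdims=True))
        m = m / gm
        sd = m.std(axis=0, ddof=0)
        m = (m - m.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    elif np.any(m < 0):
        raise ValueError("Bray-Curtis is undefined for negative entries")
    d = pdist(m, metric="braycurtis")
    d = np.nan_to_num(d)     # identical all-zero rows give 0/0
    tree = linkage(d, method="ward")
    return fcluster(tree, t=n_clusters, criterion="maxclust")
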