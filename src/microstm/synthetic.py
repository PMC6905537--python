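"""Synthetic data generators mirroring the pipeline's generative assumptions.

Every generator is a pure function of its parameters and seed: amplicon
count tables are drawn from the logistic-normal topic model (eta ~
N(Gamma' x, Sigma), theta = softmax(eta, 0), tokens ~ Mult(theta' beta)),
pathway count tables from the negative-binomial interaction model, and
gene-content tables from a sparse copy-number process with a nested KEGG-like
three-level hierarchy.  These emulate the statistical structure the models
assume -- they do not emulate chimeras, primer bias, or phylogenetic
correlation between OTUs in real surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_prep import OtuTable, DesignMatrix

__all__ = [
    "SyntheticDataset",
    "generate_stm_dataset",
    "generate_gene_content",
    "generate_pathway_counts",
    "generate_regime_timeseries",
]


@dataclass
class SyntheticDataset:
    """A drawn OTU table with the ground truth that generated it."""

    table: OtuTable
    theta: np.ndarray  # M x K true mixed memberships
    beta: np.ndarray   # K x V true topics-over-OTUs
    gamma: np.ndarray  # P x (K-1) covariate coefficients
    sigma: np.ndarray  # (K-1) x (K-1) covariance
    design: DesignMatrix | None
    seed: int
    params: dict = field(default_factory=dict)
    regime_labels: np.ndarray | None = None  # per-day regime index, if temporal


def _softmax_ref(eta: np.ndarray) -> np.ndarray:
    """softmax([eta, 0]) along the last axis (K-th coordinate pinned at 0)."""
    full = np.concatenate([eta, np.zeros(eta.shape[:-1] + (1,))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def _dirichlet_rows(rng, K: int, V: int, concentration: float) -> np.ndarray:
    beta = rng.dirichlet(np.full(V, concentration), size=K)
    beta = np.maximum(beta, 1e-12)
    return beta / beta.sum(axis=1, keepdims=True)


def generate_stm_dataset(
    M: int,
    V: int,
    K: int,
    X: DesignMatrix | None = None,
    gamma: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    library_sizes: np.ndarray | None = None,
    seed: int = 0,
    beta: np.ndarray | None = None,
    beta_concentration: float = 0.1,
) -> SyntheticDataset:
    """Draw an OTU table from the covariate-aware logistic-normal topic model.

    Per sample m: eta_m ~ N(Gamma' x_m, Sigma) in K-1 dimensions,
    theta_m = softmax(eta_m, 0); each of N_m tokens draws a topic
    z ~ Mult(theta_m) and an OTU w ~ Mult(beta_z).  Unless supplied, beta
    rows come from a sparse symmetric Dirichlet (concentration 0.1,
    microbiome-like), and library sizes N_m are log-normal with median 1e4,
    mimicking amplicon depth variation.
    """
    rng = np.random.default_rng(seed)
    Km1 = K - 1
    if sigma is None:
        sigma = 0.5 * np.eye(Km1)
    sigma = np.asarray(sigma, dtype=float)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as e:
        raise ValueError("sigma must be positive definite") from e
    if X is None:
        Xm = np.ones((M, 1))
        P = 1
    else:
        Xm = X.X
        P = X.P
        if Xm.shape[0] != M:
            raise ValueError("design matrix rows must equal M")
    if gamma is None:
        gamma = np.zeros((P, Km1))
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (P, Km1):
        raise ValueError(f"gamma must be {P} x {Km1}")

    if beta is None:
        beta = _dirichlet_rows(rng, K, V, beta_concentration)
    else:
        beta = np.asarray(beta, dtype=float)
    mu = Xm @ gamma
    eta = mu + rng.standard_normal((M, Km1)) @ chol.T
    theta = _softmax_ref(eta)

    if library_sizes is None:
        library_sizes = np.round(np.exp(rng.normal(np.log(1e4), 0.3, size=M))).astype(int)
    library_sizes = np.asarray(library_sizes).astype(int)

    counts = np.zeros((M, V))
    for m in range(M):
        nz = rng.multinomial(library_sizes[m], theta[m])
        for k in np.nonzero(nz)[0]:
            counts[m] += rng.multinomial(nz[k], beta[k])

    sample_ids = [f"S{m:04d}" for m in range(M)]
    otu_ids = [f"OTU{v:04d}" for v in range(V)]
    taxonomy = {
        o: ("Bacteria", f"Phylum{v % 5}", f"Class{v % 7}", f"Order{v % 11}",
            f"Family{v % 13}", f"Genus{v % 17}", f"Species{v}")
        for v, o in enumerate(otu_ids)
    }
    metadata = pd.DataFrame(index=pd.Index(sample_ids))
    if X is not None:
        for j, (name, transform, _src) in enumerate(X.column_spec):
            if transform != "intercept":
                metadata[name] = Xm[:, j]
    table = OtuTable(counts, sample_ids, otu_ids, taxonomy, metadata)
    return SyntheticDataset(
        table=table, theta=theta, beta=beta, gamma=gamma, sigma=sigma,
        design=X, seed=seed,
        params=dict(M=M, V=V, K=K, beta_concentration=beta_concentration),
    )


# ---------------------------------------------------------------------------


def generate_gene_content(
    V: int,
    G: int,
    n_level3: int = 12,
    n_level2: int = 4,
    copy_range: tuple[int, int] = (1, 5),
    multimap_prob: float = 0.0,
    seed: int = 0,
    density: float = 0.3,
):
    """Sparse reference OTU x gene-family copy-number table with hierarchy.

    Each gene family receives one level-3 pathway parent (two with
    probability ``multimap_prob``); level-3 categories nest under
    ``n_level2`` level-2 names, all under one level-1 root, mirroring the
    KEGG Orthology hierarchy shape.
    """
    from .topic_functions import GeneContentTable

    if n_level2 > n_level3:
        raise ValueError("n_level2 must be <= n_level3")
    lo, hi = int(copy_range[0]), int(copy_range[1])
    if hi < lo:
        raise ValueError("empty copy_range")
    rng = np.random.default_rng(seed)
    content = np.where(
        rng.random((V, G)) < density,
        rng.integers(lo, hi + 1, size=(V, G)),
        0,
    ).astype(float)
    # every gene present in at least one reference OTU
    empty = np.where(content.sum(axis=0) == 0)[0]
    for g in empty:
        content[rng.integers(0, V), g] = rng.integers(lo, hi + 1)
    otu_ids = [f"OTU{v:04d}" for v in range(V)]
    gene_ids = [f"K{g:05d}" for g in range(G)]
    level3 = [f"L3_{i:02d}" for i in range(n_level3)]
    parent2 = {l3: f"L2_{i % n_level2}" for i, l3 in enumerate(level3)}
    hierarchy: dict[str, set] = {}
    for g, gid in enumerate(gene_ids):
        picks = [level3[rng.integers(0, n_level3)]]
        if multimap_prob > 0 and rng.random() < multimap_prob:
            alt = level3[rng.integers(0, n_level3)]
            if alt != picks[0]:
                picks.append(alt)
        hierarchy[gid] = {("Metabolism", parent2[l3], l3) for l3 in picks}
    copy16s = {o: float(rng.integers(1, 8)) for o in otu_ids}
    return GeneContentTable(content=content, otu_ids=otu_ids, gene_ids=gene_ids,
                            hierarchy=hierarchy, copy16s=copy16s)


def generate_pathway_counts(
    K: int,
    C: int,
    mu: float,
    topic_effects: np.ndarray | None = None,
    pathway_effects: np.ndarray | None = None,
    interactions: dict[tuple[int, int], float] | None = None,
    lam: float = 10.0,
    seed: int = 0,
):
    """Draw a K x C table from the NB interaction model.

    y_{k,c} ~ NB with mean exp(mu + b_k + b_c + b_{k,c}) and dispersion
    ``lam`` (variance = mean + mean^2/lam).

    Returns (y, truth) where truth records the generating parameters.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    rng = np.random.default_rng(seed)
    bk = np.zeros(K) if topic_effects is None else np.asarray(topic_effects, float)
    bc = np.zeros(C) if pathway_effects is None else np.asarray(pathway_effects, float)
    bkc = np.zeros((K, C))
    for (k, c), v in (interactions or {}).items():
        bkc[k, c] = v
    mean = np.exp(mu + bk[:, None] + bc[None, :] + bkc)
    # NB2 as gamma-Poisson: rate ~ Gamma(shape=lam, scale=mean/lam)
    rate = rng.gamma(shape=lam, scale=mean / lam)
    y = rng.poisson(rate)
    truth = dict(mu=mu, topic_effects=bk, pathway_effects=bc,
                 interactions=bkc, lam=lam)
    return y.astype(int), truth


# ---------------------------------------------------------------------------


def generate_regime_timeseries(
    n_days: int,
    switch_days: list[int],
    cluster_topic_map: dict[str, list[int]] | None = None,
    base_params: dict | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Daily samples whose dominant topic cluster switches at planted days.

    Regime r (delimited by ``switch_days``) puts high logistic-normal prior
    mass on its designated topic cluster so that the cluster's expected
    summed frequency exceeds 0.7; a rare "exposure" topic spikes on the
    first switch day, emulating the transient taxon marking the onset of an
    infection.  Topics occupy mostly-disjoint OTU blocks so that refitting
    can recover them.
    """
    switch_days = sorted(int(d) for d in switch_days)
    if any(d < 1 or d > n_days for d in switch_days) or len(set(switch_days)) != len(switch_days):
        raise ValueError("switch_days must be strictly increasing within [1, n_days]")
    p = dict(V=80, library_size=3000, eta_scale=0.25, active_mean=1.6,
             inactive_mean=-2.5, cluster_noise=1.0,
             within_block=40.0, outside_block=0.05)
    p.update(base_params or {})
    n_regimes = len(switch_days) + 1
    if cluster_topic_map is None:
        cluster_topic_map = {f"regime{r}": [2 * r, 2 * r + 1] for r in range(n_regimes)}
    clusters = list(cluster_topic_map.items())
    if len(clusters) < n_regimes:
        raise ValueError("need at least one topic cluster per regime")
    n_core = max(t for _name, ts in clusters for t in ts) + 1
    K = n_core + 1          # +1 exposure topic
    exposure_topic = n_core
    V = int(p["V"])
    rng = np.random.default_rng(seed)

    # block-structured topics: each topic concentrates on its own OTU slice
    beta = np.full((K, V), p["outside_block"])
    bounds = np.linspace(0, V, K + 1).astype(int)
    for k in range(K):
        beta[k, bounds[k]:bounds[k + 1]] = p["within_block"]
    beta = np.apply_along_axis(rng.dirichlet, 1, beta * 1.0)
    beta = np.maximum(beta, 1e-12)
    beta /= beta.sum(axis=1, keepdims=True)

    days = np.arange(1, n_days + 1)
    regime = np.searchsorted(switch_days, days, side="right")  # day < first switch -> 0
    Km1 = K - 1
    # the exposure topic is the logistic-normal reference (eta = 0), so it
    # keeps a small background share; the active cluster's topics share a
    # day-level activity term, which makes members of a subcommunity rise
    # and fall together (positive co-occurrence) on top of the regime shifts
    cluster_of = np.full(K, -1)
    for ci, (_name, ts) in enumerate(clusters):
        for t in ts:
            cluster_of[t] = ci
    mu = np.full((n_days, Km1), float(p["inactive_mean"]))
    u = float(p["cluster_noise"]) * rng.standard_normal((n_days, len(clusters)))
    for t in range(Km1):
        ci = cluster_of[t]
        if ci >= 0:
            mu[:, t] += u[:, ci]
    for d in range(n_days):
        for t in clusters[regime[d]][1]:
            if t < Km1:
                mu[d, t] += float(p["active_mean"]) - float(p["inactive_mean"])
    if switch_days:
        d0 = switch_days[0] - 1
        mu[d0, :] = mu[d0, :] - 3.0  # exposure topic (reference, eta=0) spikes
    eta = mu + float(p["eta_scale"]) * rng.standard_normal((n_days, Km1))
    theta = _softmax_ref(eta)

    N = int(p["library_size"])
    counts = np.zeros((n_days, V))
    for m in range(n_days):
        nz = rng.multinomial(N, theta[m])
        for k in np.nonzero(nz)[0]:
            counts[m] += rng.multinomial(nz[k], beta[k])

    sample_ids = [f"D{d:03d}" for d in days]
    otu_ids = [f"OTU{v:04d}" for v in range(V)]
    taxonomy = {}
    for v, o in enumerate(otu_ids):
        block = min(int(np.searchsorted(bounds, v, side="right")) - 1, K - 1)
        taxonomy[o] = ("Bacteria", f"Phylum{block}", f"Class{block}",
                       f"Order{block}", f"Family{block}", f"Genus{block}", f"Species{v}")
    metadata = pd.DataFrame({"day": days}, index=pd.Index(sample_ids))
    table = OtuTable(counts, sample_ids, otu_ids, taxonomy, metadata)
    ds = SyntheticDataset(
        table=table, theta=theta, beta=beta,
        gamma=np.zeros((1, Km1)), sigma=np.eye(Km1), design=None, seed=seed,
        params=dict(n_days=n_days, switch_days=switch_days, K=K,
                    exposure_topic=exposure_topic,
                    cluster_topic_map=dict(cluster_topic_map), **p),
        regime_labels=regime,
    )
    return ds
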