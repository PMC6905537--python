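"""Covariate-aware correlated topic model fit by variational EM.

The model: each sample m carries covariates x_m; its topic proportions are
logistic-normal, eta_m ~ N(Gamma' x_m, Sigma) in K-1 dimensions with the
K-th coordinate pinned at 0 and theta_m = softmax([eta_m, 0]).  Each token
(read) draws a topic z ~ Mult(theta_m) and an OTU w ~ Mult(beta_z), with
beta the K x V topics-over-OTUs matrix.

Inference is a semi-collapsed variational EM: token-level topic assignments
are collapsed, leaving per-sample objectives

    f_m(eta) = sum_v c_{mv} log(theta' beta_{.v}) - (1/2)(eta - mu_m)' Sigma^{-1} (eta - mu_m)

maximized by batched Newton steps; the variational posterior on eta_m is the
Gaussian N(eta_hat_m, H_m^{-1}) with H_m the negative Hessian at the mode
(a Laplace-style family).  The M-step updates beta from the collapsed token
responsibilities, Gamma by ridge regression of eta_hat on X, and Sigma from
the posterior second moments with optional shrinkage toward its diagonal.
Counts may be fractional (16S copy-number normalization); they enter the
E-step sufficient statistics as fractional token weights, unrounded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_prep import OtuTable, DesignMatrix

__all__ = [
    "StmConfig", "StmFit", "PosteriorDraw",
    "fit_stm", "refit_theta", "heldout_likelihood",
    "sample_theta", "sample_tokens",
    "permutation_test_sample_effect", "residual_dispersion",
    "save_fit", "load_fit",
]

_BETA_FLOOR = 1e-12


@dataclass
class StmConfig:
    """Hyper-parameters of the topic-model fit.

    K is the number of topics (chosen a priori, >= 2).  ``sigma_prior_weight``
    shrinks the estimated topic covariance toward its diagonal (keeps it
    positive definite at small M); ``gamma_prior_sd`` is the ridge prior
    standard deviation on the covariate coefficients.  ``sigma_max`` caps the
    eigenvalues of the topic covariance: without a proper scale prior the
    logistic normal degenerates (topics absent from a sample drive their
    natural parameter to -inf and the covariance diverges); a log-odds
    standard deviation of 4 already spans topic frequencies from ~0 to ~1.
    """

    K: int
    max_em_iter: int = 500
    rel_tol: float = 1e-5
    seed: int = 0
    init: str = "spectral"          # or "random"
    sigma_prior_weight: float = 0.05
    gamma_prior_sd: float = 5.0
    sigma_max: float = 16.0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.max_em_iter < 1:
            raise ValueError("max_em_iter must be >= 1")
        if self.init not in ("spectral", "random"):
            raise ValueError("init must be 'spectral' or 'random'")
        if not 0 <= self.sigma_prior_weight <= 1:
            raise ValueError("sigma_prior_weight must be in [0, 1]")


@dataclass
class StmFit:
    """A fitted topic model (variational posterior summaries)."""

    theta: np.ndarray          # M x K, rows sum to 1
    beta: np.ndarray           # K x V, rows sum to 1
    gamma: np.ndarray          # P x (K-1)
    sigma: np.ndarray          # (K-1) x (K-1), SPD
    eta_mean: np.ndarray       # M x (K-1) variational Gaussian means
    eta_cov: np.ndarray        # M x (K-1) x (K-1) variational covariances
    elbo_trace: list
    config: StmConfig
    vocabulary: list
    sample_ids: list
    converged: bool = True
    column_spec: list = field(default_factory=list)  # design columns used

    @property
    def K(self) -> int:
        return self.beta.shape[0]

    @property
    def V(self) -> int:
        return self.beta.shape[1]

    @property
    def M(self) -> int:
        return self.theta.shape[0]


@dataclass
class PosteriorDraw:
    """One simulated token set: topic assignments z and OTU draws w."""

    theta_draw: np.ndarray
    z: np.ndarray              # topic index per token (0-based)
    w_sim: list                # OTU id per token
    draw_index: int = 0


# ---------------------------------------------------------------------------
# E-step: batched Newton optimization of the per-sample eta posteriors
# ---------------------------------------------------------------------------


def _softmax_ref(eta: np.ndarray) -> np.ndarray:
    full = np.concatenate([eta, np.zeros(eta.shape[:-1] + (1,))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def _doc_objective(eta, C, logB_cols, mu, sigma_inv):
    """f_m(eta) for every sample (vectorized); higher is better."""
    theta = _softmax_ref(eta)
    pi = theta @ np.exp(logB_cols)
    pi = np.maximum(pi, 1e-300)
    ll = np.einsum("mv,mv->m", C, np.log(pi))
    d = eta - mu
    quad = 0.5 * np.einsum("mi,ij,mj->m", d, sigma_inv, d)
    return ll - quad, theta, pi


def _estep(C, beta, mu, sigma_inv, eta0, max_newton=60, grad_tol=1e-7):
    """Batched Newton ascent of f_m(eta); returns mode, covariance, bound parts.

    Returns (eta_hat, theta_hat, eta_cov, logdet_cov, f_vals).
    """
    M, V = C.shape
    K = beta.shape[0]
    Km1 = K - 1
    N = C.sum(axis=1)
    eta = eta0.copy()
    logB = np.log(np.maximum(beta, _BETA_FLOOR))
    f, theta, pi = _doc_objective(eta, C, logB, mu, sigma_inv)
    eye = np.eye(Km1)
    for _ in range(max_newton):
        R = C / pi                                  # M x V
        A = R @ beta.T                              # M x K
        nhat = theta * A                            # M x K, responsibilities' totals
        g_full = nhat - N[:, None] * theta          # M x K
        grad = g_full[:, :Km1] - (eta - mu) @ sigma_inv
        gmax = np.abs(grad).max(axis=1)
        active = gmax > grad_tol
        if not active.any():
            break
        # likelihood Hessian: diag(nhat) - B'diag(c/pi^2)B*theta theta' - N(diag(th)-th th')
        C2 = C / (pi * pi)
        T = np.einsum("mv,iv,jv->mij", C2, beta, beta, optimize=True)
        outer_t = theta[:, :, None] * theta[:, None, :]
        BB = outer_t * T
        H = (np.einsum("mk,kl->mkl", nhat, np.eye(K))
             - BB
             - N[:, None, None] * (np.einsum("mk,kl->mkl", theta, np.eye(K)) - outer_t))
        Hneg = sigma_inv[None, :, :] - H[:, :Km1, :Km1]
        # eigenvalue-clamped solve: guarantees an ascent direction even when
        # the Hessian is momentarily indefinite away from the mode
        w_eig, U = np.linalg.eigh(Hneg[active])
        w_eig = np.maximum(w_eig, 1e-8)
        gU = np.einsum("mij,mi->mj", U, grad[active])
        step = np.zeros_like(eta)
        step[active] = np.einsum("mij,mj->mi", U, gU / w_eig)
        # backtracking line search on active docs
        scale = np.ones(M)
        for _bt in range(25):
            eta_try = eta + (scale[:, None] * step) * active[:, None]
            f_try, theta_try, pi_try = _doc_objective(eta_try, C, logB, mu, sigma_inv)
            bad = active & (f_try < f - 1e-12)
            if not bad.any():
                break
            scale[bad] *= 0.5
        improved = active & (f_try >= f)
        eta[improved] = eta_try[improved]
        f2, theta, pi = _doc_objective(eta, C, logB, mu, sigma_inv)
        if np.max(np.abs(f2 - f)) < 1e-10 * (1 + np.abs(f2).max()):
            f = f2
            break
        f = f2
    # final covariance = inverse negative Hessian at the mode
    R = C / pi
    A = R @ beta.T
    nhat = theta * A
    C2 = C / (pi * pi)
    T = np.einsum("mv,iv,jv->mij", C2, beta, beta, optimize=True)
    outer_t = theta[:, :, None] * theta[:, None, :]
    H = (np.einsum("mk,kl->mkl", nhat, np.eye(K))
         - outer_t * T
         - N[:, None, None] * (np.einsum("mk,kl->mkl", theta, np.eye(K)) - outer_t))
    Hneg = sigma_inv[None, :, :] - H[:, :Km1, :Km1]
    # covariance = eigen-clamped inverse of the negative Hessian at the mode
    w_eig, U = np.linalg.eigh(Hneg)
    w_eig = np.maximum(w_eig, 1e-8)
    eta_cov = np.einsum("mij,mj,mkj->mik", U, 1.0 / w_eig, U)
    logdet = -np.log(w_eig).sum(axis=1)
    return eta, theta, eta_cov, logdet, f


def _projection_eta(C, beta):
    """Deterministic data-driven start: column-normalized topic loads."""
    Bn = beta / np.maximum(beta.sum(axis=0, keepdims=True), 1e-12)
    theta_p = C @ Bn.T + 1e-3
    theta_p /= theta_p.sum(axis=1, keepdims=True)
    eta_p = np.log(theta_p[:, :-1]) - np.log(theta_p[:, -1:])
    return np.clip(eta_p, -8, 8)


def _estep_best(C, beta, mu, sigma_inv, extra_start=None):
    """E-step from several deterministic starts, best mode per sample.

    The per-sample objective can be multimodal; running Newton from the
    zero vector and from a count-projection start (plus an optional extra
    start) and keeping the best mode makes the converged eta a pure,
    reproducible function of (counts, beta, Gamma, Sigma).
    """
    starts = [np.zeros((C.shape[0], beta.shape[0] - 1)), _projection_eta(C, beta)]
    if extra_start is not None:
        starts.append(extra_start)
    best = None
    for eta0 in starts:
        res = _estep(C, beta, mu, sigma_inv, eta0)
        if best is None:
            best = list(res)
        else:
            win = res[4] > best[4]
            for i in range(5):
                best[i] = np.where(
                    win.reshape((-1,) + (1,) * (best[i].ndim - 1)), res[i], best[i])
    return tuple(best)


def _bound(f_vals, logdet_cov, sigma, M, Km1):
    """Approximate evidence lower bound (up to data-independent constants)."""
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    return float(f_vals.sum() + 0.5 * logdet_cov.sum()
                 - 0.5 * M * logdet_sigma + 0.5 * M * Km1)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _init_params(C, K, cfg):
    M, V = C.shape
    rng = np.random.default_rng(cfg.seed)
    if cfg.init == "spectral":
        # deterministic NMF (NNDSVD init) on the relative-abundance matrix:
        # an anchor-free spectral-style start that is identical for any
        # row order of C up to the corresponding row order of W.
        from sklearn.decomposition import NMF
        totals = C.sum(axis=1, keepdims=True)
        rel = C / np.maximum(totals, 1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nmf = NMF(n_components=K, init="nndsvda", max_iter=250,
                      random_state=0, tol=1e-5)
            W = nmf.fit_transform(rel)
        Hf = nmf.components_
        beta = np.maximum(Hf, _BETA_FLOOR)
        beta = beta / beta.sum(axis=1, keepdims=True)
        theta0 = np.maximum(W, 1e-8)
        theta0 = theta0 / theta0.sum(axis=1, keepdims=True)
        eta0 = np.log(theta0[:, :-1]) - np.log(theta0[:, -1:])
        eta0 = np.clip(eta0, -8, 8)
    else:
        beta = rng.dirichlet(np.ones(V), size=K)
        beta = np.maximum(beta, _BETA_FLOOR)
        beta /= beta.sum(axis=1, keepdims=True)
        eta0 = np.zeros((M, K - 1))
    return beta, eta0


# ---------------------------------------------------------------------------
# main fit
# ---------------------------------------------------------------------------


def fit_stm(t: OtuTable, X: DesignMatrix | None = None, cfg: StmConfig | None = None) -> StmFit:
    """Fit the structural topic model to an OTU table.

    ``X`` is the sample-level design matrix (intercept-only when absent).
    Convergence is declared when the relative change of the variational
    objective between EM iterations falls below ``cfg.rel_tol``; the same
    seed and inputs reproduce the fit bit-identically.
    """
    if cfg is None:
        raise ValueError("cfg is required")
    C = np.asarray(t.counts, dtype=float)
    M, V = C.shape
    K = cfg.K
    n_pos = int((C.sum(axis=1) > 0).sum())
    if n_pos < M:
        raise ValueError("every sample must have positive total count")
    if K >= n_pos:
        raise ValueError(f"K={K} must be < number of samples with positive counts ({n_pos})")
    if X is None:
        Xm = np.ones((M, 1))
        column_spec = [("intercept", "intercept", "")]
    else:
        if X.X.shape[0] != M:
            raise ValueError("design matrix rows do not align with the table")
        Xm = X.X
        column_spec = list(X.column_spec)
        if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            raise ValueError("design matrix is rank-deficient")
    P = Xm.shape[1]
    Km1 = K - 1

    beta, eta = _init_params(C, K, cfg)
    gamma = np.zeros((P, Km1))
    sigma = np.eye(Km1)
    ridge = 1.0 / cfg.gamma_prior_sd ** 2
    XtX = Xm.T @ Xm

    elbo_trace: list[float] = []
    converged = False
    eta0_first = eta
    for it in range(cfg.max_em_iter):
        sigma_inv = np.linalg.inv(sigma)
        mu = Xm @ gamma
        # deterministic multi-start E-step (spectral start only helps the
        # first iteration): the converged eta is a pure function of
        # (counts, beta, Gamma, Sigma), so refitting reproduces it exactly
        eta, theta, eta_cov, logdet_cov, f_vals = _estep_best(
            C, beta, mu, sigma_inv, extra_start=eta0_first if it == 0 else None)
        bound = _bound(f_vals, logdet_cov, sigma, M, Km1)
        if elbo_trace:
            prev = elbo_trace[-1]
            rel = (bound - prev) / max(abs(prev), 1.0)
            if bound < prev - 1e-6 * max(abs(prev), 1.0):
                # the Laplace bound can dip once near a fixed point;
                # stop without recording the decreasing step
                converged = True
                break
            elbo_trace.append(bound)
            if abs(rel) < cfg.rel_tol:
                converged = True
                break
        else:
            elbo_trace.append(bound)
        # ---- M-step ----
        pi = np.maximum(theta @ beta, 1e-300)
        beta = beta * (theta.T @ (C / pi))
        beta = np.maximum(beta, _BETA_FLOOR)
        beta /= beta.sum(axis=1, keepdims=True)
        pen = ridge * np.eye(P)
        pen[0, 0] = 0.0  # intercept unpenalized
        gamma = np.linalg.solve(XtX + pen, Xm.T @ eta)
        resid = eta - Xm @ gamma
        S = (eta_cov.sum(axis=0) + resid.T @ resid) / M
        w = cfg.sigma_prior_weight
        sigma = (1 - w) * S + w * np.diag(np.diag(S))
        sigma = 0.5 * (sigma + sigma.T)
        w_sig, U_sig = np.linalg.eigh(sigma)
        sigma = (U_sig * np.clip(w_sig, 1e-8, cfg.sigma_max)) @ U_sig.T
    if not converged:
        warnings.warn("fit_stm: EM iteration cap reached before convergence")

    theta = _softmax_ref(eta)
    return StmFit(
        theta=theta, beta=beta, gamma=gamma, sigma=sigma,
        eta_mean=eta, eta_cov=eta_cov, elbo_trace=elbo_trace, config=cfg,
        vocabulary=list(t.otu_ids), sample_ids=list(t.sample_ids),
        converged=converged, column_spec=column_spec,
    )


def refit_theta(fit: StmFit, t_new: OtuTable, X_new: DesignMatrix | None = None) -> StmFit:
    """Estimate theta for new samples with beta, Gamma, Sigma held fixed.

    OTUs absent from the fit's vocabulary are dropped with a warning; the
    remaining columns are aligned to the fit's vocabulary order.
    """
    vocab_index = {o: j for j, o in enumerate(fit.vocabulary)}
    keep = [o for o in t_new.otu_ids if o in vocab_index]
    if not keep:
        raise ValueError("no overlap between the new table's OTUs and the fit vocabulary")
    if len(keep) < len(t_new.otu_ids):
        warnings.warn(
            f"refit_theta: dropping {len(t_new.otu_ids) - len(keep)} OTUs "
            "absent from the fitted vocabulary")
    M = t_new.shape[0]
    C = np.zeros((M, fit.V))
    src = {o: j for j, o in enumerate(t_new.otu_ids)}
    for o in keep:
        C[:, vocab_index[o]] = t_new.counts[:, src[o]]
    if C.sum(axis=1).min() <= 0:
        raise ValueError("a new sample has no counts on the fitted vocabulary")
    if X_new is None:
        mu = np.tile(fit.gamma[0], (M, 1)) if fit.gamma.shape[0] >= 1 else np.zeros((M, fit.K - 1))
    else:
        if X_new.X.shape[1] != fit.gamma.shape[0]:
            raise ValueError("X_new columns do not match the fitted design")
        mu = X_new.X @ fit.gamma
    sigma_inv = np.linalg.inv(fit.sigma)
    eta, theta, eta_cov, logdet_cov, f_vals = _estep_best(C, fit.beta, mu, sigma_inv)
    return StmFit(
        theta=theta, beta=fit.beta, gamma=fit.gamma, sigma=fit.sigma,
        eta_mean=eta, eta_cov=eta_cov,
        elbo_trace=[_bound(f_vals, logdet_cov, fit.sigma, M, fit.K - 1)],
        config=fit.config, vocabulary=list(fit.vocabulary),
        sample_ids=list(t_new.sample_ids), converged=True,
        column_spec=list(fit.column_spec),
    )


# ---------------------------------------------------------------------------
# predictive scoring and posterior simulation
# ---------------------------------------------------------------------------


def heldout_likelihood(
    fit: StmFit,
    heldout: OtuTable,
    X_heldout: DesignMatrix | None = None,
    frac_heldout_tokens: float = 0.5,
    seed: int = 0,
    beta: np.ndarray | None = None,
) -> float:
    """Document-completion held-out log-likelihood (mean per token).

    Per held-out sample, a random subset of tokens (binomial thinning of the
    rounded counts at ``frac_heldout_tokens``) is scored under theta' beta,
    where theta is re-estimated from the remaining tokens with the fitted
    topics held fixed.  ``beta`` overrides the fitted topics for baseline
    comparisons (e.g. a uniform distribution over the vocabulary).
    """
    if not 0 < frac_heldout_tokens < 1:
        raise ValueError("frac_heldout_tokens must be in (0, 1)")
    rng = np.random.default_rng(seed)
    C = np.round(np.asarray(heldout.counts, dtype=float)).astype(int)
    if np.any((C > 0).sum(axis=1) < 2):
        raise ValueError("every held-out sample needs >= 2 distinct OTUs")
    C_score = rng.binomial(C, frac_heldout_tokens)
    C_train = C - C_score
    # guard: keep at least one training token per sample
    empty = C_train.sum(axis=1) == 0
    for m in np.where(empty)[0]:
        j = int(np.argmax(C_score[m]))
        C_train[m, j] += 1
        C_score[m, j] -= 1
    train_tab = OtuTable(C_train.astype(float), list(heldout.sample_ids),
                         list(heldout.otu_ids), dict(heldout.taxonomy),
                         heldout.metadata.copy())
    sub = refit_theta(fit, train_tab, X_heldout)
    B = fit.beta if beta is None else np.asarray(beta, dtype=float)
    # theta rows of sub align with heldout samples; vocabulary = fit vocabulary
    vocab_index = {o: j for j, o in enumerate(fit.vocabulary)}
    M = C_score.shape[0]
    Cs = np.zeros((M, fit.V))
    for jo, o in enumerate(heldout.otu_ids):
        if o in vocab_index:
            Cs[:, vocab_index[o]] = C_score[:, jo]
    mix = np.maximum(sub.theta @ B, 1e-300)
    tot = Cs.sum()
    if tot == 0:
        raise ValueError("no held-out tokens were drawn; increase counts or frac")
    return float((Cs * np.log(mix)).sum() / tot)


def sample_theta(fit: StmFit, m: int, n_draws: int, seed: int = 0) -> np.ndarray:
    """Draw theta for sample m from its variational Gaussian posterior.

    Returns an (n_draws, K) array of simplex rows: eta ~ N(eta_mean[m],
    eta_cov[m]) pushed through softmax with the K-th coordinate at 0.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be > 0")
    if not 0 <= m < fit.M:
        raise ValueError(f"sample index {m} out of range")
    rng = np.random.default_rng(seed)
    L = _cov_factor(fit.eta_cov[m])
    eta = fit.eta_mean[m] + rng.standard_normal((n_draws, fit.K - 1)) @ L.T
    return _softmax_ref(eta)


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor that tolerates singular (even zero) covariance."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(cov)
        return U @ np.diag(np.sqrt(np.maximum(w, 0)))


def sample_theta_all(fit: StmFit, n_draws: int, seed: int = 0) -> np.ndarray:
    """(n_draws, M, K) posterior theta draws for every sample (one seed)."""
    rng = np.random.default_rng(seed)
    Km1 = fit.K - 1
    out = np.empty((n_draws, fit.M, fit.K))
    for m in range(fit.M):
        L = _cov_factor(fit.eta_cov[m])
        eta = fit.eta_mean[m] + rng.standard_normal((n_draws, Km1)) @ L.T
        out[:, m, :] = _softmax_ref(eta)
    return out


def sample_tokens(fit: StmFit, theta_draw: np.ndarray, n_tokens: int,
                  seed: int = 0, draw_index: int = 0) -> PosteriorDraw:
    """Simulate tokens: z ~ Mult(theta_draw), w ~ Mult(beta_z)."""
    if n_tokens <= 0:
        raise ValueError("n_tokens must be > 0")
    theta_draw = np.asarray(theta_draw, dtype=float)
    if theta_draw.shape != (fit.K,) or abs(theta_draw.sum() - 1) > 1e-6:
        raise ValueError("theta_draw must be a length-K simplex vector")
    rng = np.random.default_rng(seed)
    z = rng.choice(fit.K, size=n_tokens, p=theta_draw)
    w_idx = np.empty(n_tokens, dtype=int)
    for k in range(fit.K):
        mask = z == k
        n_k = int(mask.sum())
        if n_k:
            w_idx[mask] = rng.choice(fit.V, size=n_k, p=fit.beta[k])
    w_sim = [fit.vocabulary[j] for j in w_idx]
    return PosteriorDraw(theta_draw=theta_draw, z=z, w_sim=w_sim, draw_index=draw_index)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def permutation_test_sample_effect(
    t: OtuTable,
    X: DesignMatrix,
    covariate: str,
    cfg: StmConfig,
    n_perm: int = 25,
    seed: int = 0,
    n_effect_draws: int = 100,
):
    """Permutation null for per-topic covariate effects.

    Each permutation shuffles the covariate's values across samples, refits
    the topic model, and records the per-topic mean effect coefficient.
    Returns a dict with the observed coefficients (length K) and the null
    coefficient matrix (n_perm x K).
    """
    from .topic_effects import estimate_topic_effects

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cols = X.columns_for(covariate)
    rng = np.random.default_rng(seed)

    def _coefs(Xd, fit_seed, eff_seed):
        cfg_p = StmConfig(**{**asdict(cfg), "seed": fit_seed})
        fit = fit_stm(t, Xd, cfg_p)
        eff = estimate_topic_effects(fit, Xd, covariate,
                                     n_draws=n_effect_draws, seed=eff_seed)
        return np.array([e.point for e in eff])

    observed = _coefs(X, cfg.seed, seed)
    null = np.empty((n_perm, cfg.K))
    for p in range(n_perm):
        perm = rng.permutation(X.X.shape[0])
        Xp = DesignMatrix(X.X.copy(), list(X.column_spec), list(X.sample_ids))
        Xp.X[:, cols] = X.X[np.ix_(perm, cols)]
        null[p] = _coefs(Xp, cfg.seed, seed + 1 + p)
    return {"observed": observed, "null": null, "covariate": covariate}


def residual_dispersion(fit: StmFit, t: OtuTable) -> float:
    """Multinomial Pearson chi^2 / df against the fitted means.

    Expected count e_{mv} = N_m (theta_m' beta)_v; the statistic sums
    (c - e)^2 / e over cells and divides by M (V - 1) residual degrees of
    freedom.  Values near 1 indicate the multinomial dispersion is adequate;
    values well above 1 indicate overdispersed residuals.
    """
    C = np.asarray(t.counts, dtype=float)
    if C.shape != (fit.M, fit.V):
        raise ValueError(f"table shape {C.shape} does not match fit ({fit.M}, {fit.V})")
    N = C.sum(axis=1, keepdims=True)
    E = N * (fit.theta @ fit.beta)
    mask = E > 1e-12
    chi2 = ((C - E) ** 2 / np.where(mask, E, 1.0))[mask].sum()
    df = C.shape[0] * (C.shape[1] - 1)
    return float(chi2 / df)


# ---------------------------------------------------------------------------
# serialization (single JSON archive, versioned)
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def save_fit(fit: StmFit, path) -> None:
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "config": asdict(fit.config),
        "vocabulary": fit.vocabulary,
        "sample_ids": fit.sample_ids,
        "column_spec": [list(c) for c in fit.column_spec],
        "converged": fit.converged,
        "elbo_trace": [float(x) for x in fit.elbo_trace],
        "theta": fit.theta.tolist(),
        "beta": fit.beta.tolist(),
        "gamma": fit.gamma.tolist(),
        "sigma": fit.sigma.tolist(),
        "eta_mean": fit.eta_mean.tolist(),
        "eta_cov": fit.eta_cov.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_fit(path) -> StmFit:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported fit archive version: {doc.get('schema_version')}")
    return StmFit(
        theta=np.array(doc["theta"]), beta=np.array(doc["beta"]),
        gamma=np.array(doc["gamma"]), sigma=np.array(doc["sigma"]),
        eta_mean=np.array(doc["eta_mean"]), eta_cov=np.array(doc["eta_cov"]),
        elbo_trace=doc["elbo_trace"], config=StmConfig(**doc["config"]),
        vocabulary=doc["vocabulary"], sample_ids=doc["sample_ids"],
        converged=doc["converged"],
        column_spec=[tuple(c) for c in doc["column_spec"]],
    )
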