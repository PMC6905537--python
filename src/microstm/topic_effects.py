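"""Relating topics to sample covariates.

Implements the method of composition for topic-sample-effects (uncertainty
from both the topic-frequency posterior and the regression coefficients),
the "high-ranking topic" call (95% uncertainty interval excluding 0), the
posterior simulation that assigns OTUs to effect groups, and negative-
binomial regression of group abundance profiles on clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_prep import OtuTable, DesignMatrix
from .stm_core import StmFit, sample_theta_all

__all__ = [
    "EffectEstimate", "GroupFrequencies",
    "estimate_topic_effects", "high_ranking_topics",
    "posterior_group_frequencies", "select_group_otus",
    "group_abundance_series", "abundance_covariate_regression",
    "bonferroni",
]

_LOGIT_CLAMP = 1e-6


@dataclass
class EffectEstimate:
    """Per-topic covariate effect with an uncertainty interval."""

    topic: int
    point: float
    lower: float
    upper: float
    level: float
    covariate: str
    n_draws: int


@dataclass
class GroupFrequencies:
    """F_n(g)*: per-OTU frequency of winning each topic group."""

    freqs: dict          # group label -> np.ndarray over OTUs
    otu_ids: list
    groups: list
    R: int
    I: int
    seed: int

    def frame(self):
        import pandas as pd
        return pd.DataFrame({g: self.freqs[g] for g in self.groups},
                            index=self.otu_ids)


def _logit(p):
    p = np.clip(p, _LOGIT_CLAMP, 1 - _LOGIT_CLAMP)
    return np.log(p / (1 - p))


def estimate_topic_effects(
    fit: StmFit,
    X: DesignMatrix,
    covariate: str,
    n_draws: int = 500,
    level: float = 0.95,
    seed: int = 0,
) -> list[EffectEstimate]:
    """Topic-sample-effects by the method of composition.

    For each of ``n_draws`` iterations: draw theta for every sample from its
    variational posterior, regress each topic's logit-transformed frequency
    on X by OLS, then draw the coefficient vector from its asymptotic normal
    sampling distribution.  The effect of a multi-column covariate (spline /
    polynomial / multi-level indicator) is summarized as the mean of its
    column coefficients.  Interval = empirical quantiles of the pooled
    coefficient draws at (1-level)/2 and 1-(1-level)/2.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cols = X.columns_for(covariate)
    Xm = X.X
    if Xm.shape[0] != fit.M:
        raise ValueError("design matrix rows do not align with the fit")
    for j in cols:
        if np.ptp(Xm[:, j]) == 0:
            raise ValueError(f"covariate {covariate!r} is constant")
    rng = np.random.default_rng(seed)
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    pinv = XtX_inv @ Xm.T
    P = Xm.shape[1]
    Ldec = np.linalg.cholesky(XtX_inv + 1e-14 * np.eye(P))
    thetas = sample_theta_all(fit, n_draws, seed=seed)   # (n_draws, M, K)
    draws = np.empty((n_draws, fit.K))
    dof = max(fit.M - P, 1)
    for i in range(n_draws):
        Y = _logit(thetas[i])                            # M x K
        coef = pinv @ Y                                  # P x K
        resid = Y - Xm @ coef
        s2 = (resid ** 2).sum(axis=0) / dof              # per-topic sigma^2
        noise = (Ldec @ rng.standard_normal((P, fit.K))) * np.sqrt(s2)[None, :]
        coef_draw = coef + (noise if n_draws > 1 else 0.0)
        draws[i] = coef_draw[cols].mean(axis=0)
    alpha = (1 - level) / 2
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1 - alpha, axis=0)
    pt = draws.mean(axis=0)
    out = []
    for k in range(fit.K):
        lower = min(lo[k], pt[k])
        upper = max(hi[k], pt[k])
        out.append(EffectEstimate(topic=k, point=float(pt[k]), lower=float(lower),
                                  upper=float(upper), level=level,
                                  covariate=covariate, n_draws=n_draws))
    return out


def high_ranking_topics(effects: list[EffectEstimate]) -> dict[int, str]:
    """Call topics whose uncertainty interval excludes 0.

    Returns topic -> 'positive' | 'negative' | 'none' (exhaustive).
    """
    groups = {}
    for e in effects:
        if e.lower > 0:
            groups[e.topic] = "positive"
        elif e.upper < 0:
            groups[e.topic] = "negative"
        else:
            groups[e.topic] = "none"
    return groups


def posterior_group_frequencies(
    fit: StmFit,
    groups: dict[int, str],
    R: int = 1000,
    I: int = 100,
    tokens_per_draw: np.ndarray | None = None,
    seed: int = 0,
    library_sizes: np.ndarray | None = None,
) -> GroupFrequencies:
    """Posterior simulation assigning each OTU to the topic group that most
    often generates it.

    Per outer iteration r: for every sample, draw I theta samples from the
    variational posterior; for each, simulate tokens z ~ Mult(theta),
    w ~ Mult(beta_z); accumulate f_n(g) = tokens of OTU n generated by a
    topic in group g.  The winning group per OTU (argmax of f_n(g), ties
    broken uniformly at random) scores 1 that iteration; F_n(g)* is the mean
    over the R iterations.  ``tokens_per_draw`` defaults to each sample's
    observed (rounded) library size.
    """
    if R <= 0 or I <= 0:
        raise ValueError("R and I must be > 0")
    missing = [k for k in range(fit.K) if k not in groups]
    if missing:
        raise ValueError(f"groups must cover every topic; missing {missing}")
    labels = sorted(set(groups.values()))
    group_of = np.array([labels.index(groups[k]) for k in range(fit.K)])
    nG = len(labels)
    if tokens_per_draw is None:
        if library_sizes is None:
            raise ValueError("supply tokens_per_draw or library_sizes")
        tokens = np.maximum(np.round(np.asarray(library_sizes)).astype(int), 1)
    else:
        tokens = np.broadcast_to(np.asarray(tokens_per_draw, dtype=int), (fit.M,)).copy()
        if np.any(tokens <= 0):
            raise ValueError("tokens_per_draw must be positive")
    from .stm_core import _cov_factor

    rng = np.random.default_rng(seed)
    wins = np.zeros((fit.V, nG))
    Km1 = fit.K - 1
    chols = [_cov_factor(fit.eta_cov[m]) for m in range(fit.M)]
    for _r in range(R):
        f = np.zeros((fit.V, nG))
        for m in range(fit.M):
            eta = fit.eta_mean[m] + rng.standard_normal((I, Km1)) @ chols[m].T
            full = np.concatenate([eta, np.zeros((I, 1))], axis=1)
            full -= full.max(axis=1, keepdims=True)
            th = np.exp(full)
            th /= th.sum(axis=1, keepdims=True)
            for i in range(I):
                nz = rng.multinomial(tokens[m], th[i])
                for k in np.nonzero(nz)[0]:
                    f[:, group_of[k]] += rng.multinomial(nz[k], fit.beta[k])
        top = f.max(axis=1, keepdims=True)
        is_top = f >= top            # ties all marked
        n_top = is_top.sum(axis=1)
        pick = np.empty(fit.V, dtype=int)
        for n in range(fit.V):
            cand = np.nonzero(is_top[n])[0]
            pick[n] = cand[0] if len(cand) == 1 else rng.choice(cand)
        wins[np.arange(fit.V), pick] += 1
    F = wins / R
    return GroupFrequencies(
        freqs={g: F[:, j] for j, g in enumerate(labels)},
        otu_ids=list(fit.vocabulary), groups=labels, R=R, I=I, seed=seed)


def select_group_otus(freqs: GroupFrequencies, threshold: float = 0.99) -> dict[str, set]:
    """OTUs whose winning-group frequency strictly exceeds the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out: dict[str, set] = {}
    for g in freqs.groups:
        sel = {o for o, F in zip(freqs.otu_ids, freqs.freqs[g]) if F > threshold}
        if sel:
            out[g] = sel
    return out


def group_abundance_series(t: OtuTable, group_otus: dict[str, set]) -> dict[str, np.ndarray]:
    """Per-sample relative abundance of each group's OTU profile."""
    totals = t.library_sizes()
    if np.any(totals <= 0):
        raise ValueError("every sample needs a positive library size")
    col = {o: j for j, o in enumerate(t.otu_ids)}
    out = {}
    for g, otus in group_otus.items():
        unknown = [o for o in otus if o not in col]
        if unknown:
            raise ValueError(f"unknown OTU id(s) in group {g!r}: {sorted(unknown)[:5]}")
        idx = [col[o] for o in otus]
        out[g] = (t.counts[:, idx].sum(axis=1) / totals) if idx else np.zeros(t.shape[0])
    return out


def _fit_nb(y, X, offset):
    """NB regression with log link; falls back to NB-GLM if MLE stalls."""
    import statsmodels.api as sm

    try:
        mod = sm.NegativeBinomial(y, X, offset=offset)
        res = mod.fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)):
            return res.params[:X.shape[1]], res.predict()
    except Exception:
        pass
    glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=1.0), offset=offset)
    res = glm.fit()
    return np.asarray(res.params), np.asarray(res.fittedvalues)


def abundance_covariate_regression(
    abundance: np.ndarray,
    covariate: np.ndarray,
    library_sizes: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
):
    """NB regression of a profile's counts on a numeric covariate.

    Log link with log library-size offset.  Returns (slope, permutation
    p-value, R^2): the p-value is the add-one proportion of permutations
    with |slope| at least the observed; R^2 is the squared correlation of
    fitted and observed counts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.round(np.asarray(abundance, dtype=float)).astype(int)
    x = np.asarray(covariate, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    X = np.column_stack([np.ones_like(x), x])
    offset = np.log(lib)
    rng = np.random.default_rng(seed)
    params, fitted = _fit_nb(y, X, offset)
    slope = float(params[1])
    r = np.corrcoef(fitted, y)[0, 1] if np.std(fitted) > 0 else 0.0
    r2 = float(r ** 2)
    exceed = 0
    for _p in range(n_perm):
        xp = rng.permutation(x)
        Xp = np.column_stack([np.ones_like(x), xp])
        params_p, _ = _fit_nb(y, Xp, offset)
        if abs(params_p[1]) >= abs(slope):
            exceed += 1
    pval = (exceed + 1) / (n_perm + 1)
    return slope, float(pval), r2


def bonferroni(pvalues) -> np.ndarray:
    """Family-wise Bonferroni adjustment for multiple tested profiles."""
    p = np.asarray(list(pvalues), dtype=float)
    return np.minimum(p * len(p), 1.0)
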