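"""Disease-status modeling and metabolite biomarker discovery.

The five-point canopy health score is recoded to a healthy/diseased binary
(scores 4–5 vs 1–3).  Single metabolites — or chemodiversity indices of a
metabolite subset — are tested as predictors of the log odds of being
healthy in a random-intercept logistic regression that controls for the
individual inbreeding coefficient (F), temperature at collection (Tcol)
and a random effect of collection site; the model is fit by
Laplace-approximate maximum likelihood with Wald tests on the fixed
effects.  Interaction terms between the focal predictor and the covariates
are deliberately not included.

Biomarker ranking uses a bagged classification-tree ensemble with
out-of-bag permutation importance (mean decrease in accuracy): each tree
is scored on its out-of-bag samples before and after permuting one
metabolite's values, and the accuracy drops are averaged over trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MixedLogisticFit",
    "BiomarkerRanking",
    "recode_health",
    "logistic_mixed",
    "rf_biomarkers",
    "subset_chemodiv_models",
    "DIVERSITY_INDICES",
]

DIVERSITY_INDICES = ["S", "H", "D1", "D2", "E", "BP"]


def recode_health(score: int) -> int:
    """Binary disease state from the 1–5 canopy score: 4–5 healthy, 1–3 diseased."""
    if score not in (1, 2, 3, 4, 5):
        raise ValueError(f"health score must be an integer in 1..5, got {score!r}")
    return int(score >= 4)


@dataclass
class MixedLogisticFit:
    coef: pd.DataFrame  # term, estimate, se, z, p
    site_sd: float
    loglik: float
    converged: bool
    n_used: int

    def term(self, name: str) -> pd.Series:
        return self.coef.set_index("term").loc[name]


def _laplace_negloglik(params, y, x, site_idx, n_sites, fixed_sigma):
    """Negative Laplace-approximate marginal log-likelihood.

    Inner step: per-site Newton maximization of the conditional posterior
    of the scalar random intercept.
    """
    q = x.shape[1]
    beta = params[:q]
    sigma = fixed_sigma if fixed_sigma is not None else np.exp(params[q])
    eta_fixed = x @ beta
    total = 0.0
    for s in range(n_sites):
        rows = site_idx == s
        ef = eta_fixed[rows]
        ys = y[rows]
        if sigma < 1e-8:
            mu = expit(ef)
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            total += float(ys @ np.log(mu) + (1 - ys) @ np.log(1 - mu))
            continue
        b = 0.0
        for _ in range(50):
            mu = expit(ef + b)
            grad = float((ys - mu).sum()) - b / sigma**2
            hess = float((mu * (1 - mu)).sum()) + 1.0 / sigma**2
            step = grad / hess
            b += step
            if abs(step) < 1e-10:
                break
        mu = np.clip(expit(ef + b), 1e-12, 1 - 1e-12)
        ll_cond = float(ys @ np.log(mu) + (1 - ys) @ np.log(1 - mu))
        hess = float((mu * (1 - mu)).sum()) + 1.0 / sigma**2
        total += ll_cond - b**2 / (2 * sigma**2) - 0.5 * np.log(sigma**2 * hess)
    return -total


def _numerical_hessian(f, x0, eps=1e-5):
    k = len(x0)
    h = np.zeros((k, k))
    f0 = f(x0)
    steps = eps * np.maximum(1.0, np.abs(x0))
    for i in range(k):
        for j in range(i, k):
            xpp = x0.copy(); xpp[i] += steps[i]; xpp[j] += steps[j]
            xpm = x0.copy(); xpm[i] += steps[i]; xpm[j] -= steps[j]
            xmp = x0.copy(); xmp[i] -= steps[i]; xmp[j] += steps[j]
            xmm = x0.copy(); xmm[i] -= steps[i]; xmm[j] -= steps[j]
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4 * steps[i] * steps[j])
    return h


def logistic_mixed(
    y: pd.Series,
    focal: pd.Series,
    covariates: pd.DataFrame | None,
    site: pd.Series,
    focal_name: str = "focal",
    site_sd: float | None = None,
) -> MixedLogisticFit:
    """Random-intercept logistic regression of binary health on a focal predictor.

    ``covariates`` typically carries F and Tcol.  ``site_sd`` fixes the
    random-intercept SD (0 gives ordinary logistic regression); by default
    it is estimated.  Raises on a constant focal predictor or complete
    separation.
    """
    samples = y.index
    yv = y.to_numpy(dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    fv = focal.reindex(samples).to_numpy(dtype=float)
    if np.ptp(fv) == 0:
        raise ValueError(f"focal predictor '{focal_name}' is constant: no information")
    f1, f0 = fv[yv == 1], fv[yv == 0]
    if len(f1) and len(f0) and (f1.min() > f0.max() or f1.max() < f0.min()):
        raise ValueError(f"complete separation on focal predictor '{focal_name}'")

    cols = [np.ones(len(yv)), fv]
    names = ["intercept", focal_name]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates.reindex(samples)[c].to_numpy(dtype=float))
            names.append(c)
    x = np.column_stack(cols)
    ok = ~np.isnan(x).any(axis=1) & ~np.isnan(yv)
    x, yv = x[ok], yv[ok]
    sites_used = site.reindex(samples)[ok]
    site_codes, _ = pd.factorize(sites_used)
    n_sites = site_codes.max() + 1
    if n_sites < 2 and site_sd is None:
        raise ValueError("need >= 2 sites to estimate a site random effect")

    q = x.shape[1]
    x0 = np.zeros(q + (0 if site_sd is not None else 1))
    if site_sd is None:
        x0[q:] = np.log(0.5)

    def obj(p):
        return _laplace_negloglik(p, yv, x, site_codes, n_sites, site_sd)

    res = minimize(obj, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    params = res.x
    hess = _numerical_hessian(obj, params)
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov)[:q], 0, None))
        converged = bool(res.success or np.linalg.norm(res.jac[:q]) < 1e-3)
    except np.linalg.LinAlgError:
        ses = np.full(q, np.nan)
        converged = False
    if np.any(ses == 0) or np.any(~np.isfinite(ses)):
        converged = False
    beta = params[:q]
    z = np.divide(beta, ses, out=np.full(q, np.nan), where=ses > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame({"term": names, "estimate": beta, "se": ses, "z": z, "p": p})
    sd_hat = site_sd if site_sd is not None else float(np.exp(params[q]))
    return MixedLogisticFit(coef, sd_hat, -float(res.fun), converged, int(ok.sum()))


@dataclass
class BiomarkerRanking:
    importance: pd.DataFrame  # metabolite, importance, rank, direction
    selected: list  # top-k metabolite ids

    def rank_of(self, metabolite) -> int:
        return int(self.importance.set_index("metabolite").loc[metabolite, "rank"])


def rf_biomarkers(
    log_abundance: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 1000,
    seed: int = 0,
    top_k: int = 12,
    max_features: str | float = "sqrt",
) -> BiomarkerRanking:
    """Rank metabolites by out-of-bag permutation importance of a bagged forest.

    ``log_abundance`` is samples × metabolites.  Importance of a metabolite
    is the mean (over trees) decrease in out-of-bag accuracy after
    permuting its values; direction is the sign of the healthy-minus-
    diseased mean log abundance.  The top ``top_k`` metabolites form the
    selected biomarker set.
    """
    x = log_abundance.to_numpy(dtype=float)
    yv = y.reindex(log_abundance.index).to_numpy(dtype=int)
    classes = np.unique(yv)
    if len(classes) < 2:
        raise ValueError("both health classes must be present")
    n, p = x.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    counts = np.zeros(p)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(0, 2**31 - 1))
        ).fit(x[boot], yv[boot])
        base_acc = (tree.predict(x[oob]) == yv[oob]).mean()
        x_oob = x[oob]
        perm = rng.permutation(len(oob))
        for j in range(p):
            xp = x_oob.copy()
            xp[:, j] = xp[perm, j]
            drops[j] += base_acc - (tree.predict(xp) == yv[oob]).mean()
            counts[j] += 1
    importance = np.divide(drops, counts, out=np.zeros(p), where=counts > 0)
    healthy_mean = x[yv == 1].mean(axis=0)
    diseased_mean = x[yv == 0].mean(axis=0)
    df = pd.DataFrame({
        "metabolite": log_abundance.columns,
        "importance": importance,
        "direction": np.sign(healthy_mean - diseased_mean).astype(int),
    })
    df = df.sort_values(["importance", "metabolite"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, p + 1)
    selected = df["metabolite"].head(top_k).tolist()
    return BiomarkerRanking(df, selected)


def subset_chemodiv_models(
    abundance: pd.DataFrame,
    subset: list,
    metadata: pd.DataFrame,
    covariate_cols: tuple = ("F", "tcol"),
    site_col: str = "subpopulation",
    response_col: str = "health_binary",
) -> dict:
    """Fit one mixed logistic model per chemodiversity index of a metabolite subset.

    Indices (S, H, D1, D2, E, BP) are recomputed from the subset only
    (renormalized within it) and substituted as the focal predictor.  An
    index constant across samples — richness with no dropout, for instance —
    is skipped with a reason string instead of a fit.
    """
    from .chemodiversity import subset_diversity

    if len(subset) < 2:
        raise ValueError("subset needs >= 2 metabolites")
    profiles = subset_diversity(abundance, subset)
    samples = profiles.index.intersection(metadata.index)
    y = metadata.loc[samples, response_col].astype(int)
    cov = metadata.loc[samples, list(covariate_cols)]
    site = metadata.loc[samples, site_col]
    out = {}
    for index_name in DIVERSITY_INDICES:
        vals = profiles.loc[samples, index_name]
        usable = vals.notna()
        if usable.sum() < 10 or np.ptp(vals[usable].to_numpy(dtype=float)) == 0:
            out[index_name] = f"skipped: index {index_name} constant or undefined"
            continue
        try:
            out[index_name] = logistic_mixed(
                y[usable], vals[usable], cov[usable], site[usable],
                focal_name=index_name,
            )
        except ValueError as exc:
            out[index_name] = f"skipped: {exc}"
    return out
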