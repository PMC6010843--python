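"""Distance-based congruence analyses.

DAPC (PCA dimension reduction followed by linear discriminant analysis,
with prior-free cluster number chosen by BIC over k-means solutions),
pairwise ANOSIM R between subpopulations, and one-tailed full/partial
Mantel permutation tests with bootstrap confidence intervals — the toolkit
for asking whether genetically similar subpopulations are also chemically
and environmentally similar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "DapcResult",
    "dapc",
    "anosim_r",
    "anosim_pairwise",
    "mantel",
    "subpop_distance_matrices",
]


def _check_distance_matrix(d: pd.DataFrame, name: str = "distance matrix"):
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(a, a.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(a), 0):
        raise ValueError(f"{name} must have a zero diagonal")
    if (a < -1e-12).any():
        raise ValueError(f"{name} must be nonnegative")
    return a


@dataclass
class DapcResult:
    retained_pcs: int
    coordinates: pd.DataFrame  # sample × discriminant axes (empty when K == 1)
    assignments: pd.Series
    memberships: pd.DataFrame  # posterior membership probabilities
    bic_by_k: pd.Series | None  # prior-free mode only
    chosen_k: int


def _cluster_bic(scores: np.ndarray, labels: np.ndarray) -> float:
    """BIC of a hard-assignment spherical Gaussian mixture on PC scores.

    Uses the full mixture log-likelihood (including the mixing-proportion
    term) with a pooled spherical variance.  A WSS-only criterion with a
    K*ln(n) penalty always rewards splitting a Gaussian cloud — the
    within-cluster variance genuinely drops by a constant factor per split
    — so it cannot recover K = 1 on unstructured data; the mixing term
    n_k ln(n_k/n) supplies the missing cost of a split.
    """
    n, d = scores.shape
    k = len(np.unique(labels))
    wss_k = {c: float(((scores[labels == c] - scores[labels == c].mean(axis=0)) ** 2
                       ).sum()) for c in np.unique(labels)}
    sigma2 = max(sum(wss_k.values()) / (d * max(n - k, 1)), 1e-300)
    ll = 0.0
    for c, wss in wss_k.items():
        nk = int((labels == c).sum())
        ll += (nk * np.log(nk / n) - nk * d / 2 * np.log(2 * np.pi * sigma2)
               - wss / (2 * sigma2))
    n_params = k * d + k  # centroids + mixing weights + shared variance
    return -2 * ll + n_params * np.log(n)


def _retain_pcs(explained_ratio: np.ndarray, n: int, target: float = 0.90) -> int:
    cum = np.cumsum(explained_ratio)
    k = int(np.searchsorted(cum, target) + 1)
    return max(1, min(k, max(n // 3, 1), len(explained_ratio)))


def dapc(
    data: pd.DataFrame,
    groups: pd.Series | None = None,
    n_pcs: int | None = None,
    k_max: int | None = None,
    seed: int = 0,
) -> DapcResult:
    """Discriminant analysis of principal components.

    Variables are autoscaled, PCA retains ``n_pcs`` components (default:
    the smallest number explaining >= 90% of variance, capped at n/3), and
    a linear discriminant analysis is fit on the PC scores.  With ``groups``
    given, those define the classes; without, k-means solutions over
    K = 1..k_max are scored by a hard-assignment mixture BIC and the
    arg-min K defines the clusters.
    """
    x = data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two entities")
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    max_pcs = min(n - 1, x.shape[1])
    if n_pcs is not None and n_pcs >= n:
        raise ValueError("n_pcs must be smaller than the number of entities")
    pca = PCA(n_components=max_pcs, random_state=seed)
    scores = pca.fit_transform(x)
    a = n_pcs if n_pcs is not None else _retain_pcs(pca.explained_variance_ratio_, n)
    scores = scores[:, :a]

    bic_by_k = None
    if groups is None:
        if k_max is None:
            k_max = max(1, min(20, n // 3))
        bics = {}
        labels_by_k = {}
        for k in range(1, k_max + 1):
            if k == 1:
                labels = np.zeros(n, dtype=int)
            else:
                labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(
                    scores).labels_
            bics[k] = _cluster_bic(scores, labels)
            labels_by_k[k] = labels
        bic_by_k = pd.Series(bics, name="BIC")
        chosen_k = int(bic_by_k.idxmin())
        labels = pd.Series(labels_by_k[chosen_k], index=data.index, name="cluster")
    else:
        labels = groups.reindex(data.index)
        chosen_k = labels.nunique()

    if chosen_k < 2:
        memberships = pd.DataFrame(1.0, index=data.index, columns=[0])
        coords = pd.DataFrame(index=data.index)
        return DapcResult(a, coords, labels, memberships, bic_by_k, chosen_k)

    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, labels.to_numpy())
    coords = pd.DataFrame(
        lda.transform(scores), index=data.index,
        columns=[f"LD{i + 1}" for i in range(min(chosen_k - 1, a))],
    )
    memberships = pd.DataFrame(
        lda.predict_proba(scores), index=data.index, columns=lda.classes_
    )
    assignments = pd.Series(lda.predict(scores), index=data.index, name="assignment")
    return DapcResult(a, coords, assignments, memberships, bic_by_k, chosen_k)


def anosim_r(d: np.ndarray, within_mask: np.ndarray) -> float:
    """ANOSIM R from a condensed distance vector and a within-group mask.

    R = (mean between-group rank - mean within-group rank) / (m(m-1)/4),
    with m the number of samples (equivalently, half the number of pooled
    pairs); ranks use mean ranks for ties.  The divisor makes R = 1 under
    complete separation and keeps R in [-1, 1].
    """
    ranks = rankdata(d)
    half_pairs = len(d) / 2.0
    rw = ranks[within_mask].mean()
    rb = ranks[~within_mask].mean()
    return float((rb - rw) / half_pairs)


def anosim_pairwise(
    d: pd.DataFrame,
    grouping: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
):
    """Pairwise ANOSIM between subpopulations from an inter-sample distance matrix.

    For every subpopulation pair the samples are restricted to that pair and
    the rank-based R statistic is computed, with a label-permutation p-value.
    Returns ``(R matrix, p matrix)`` as subpopulation × subpopulation frames.
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p-value")
    dist = _check_distance_matrix(d, "sample distance matrix")
    grouping = grouping.reindex(d.index)
    rng = np.random.default_rng(seed)
    groups = {k: np.asarray(v) for k, v in grouping.groupby(grouping).indices.items()}
    for k, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"subpopulation {k} has fewer than 2 samples")
    names = sorted(groups)
    r_mat = pd.DataFrame(0.0, index=names, columns=names)
    p_mat = pd.DataFrame(1.0, index=names, columns=names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            idx = np.concatenate([groups[names[i]], groups[names[j]]])
            labels = np.concatenate([
                np.zeros(len(groups[names[i]]), dtype=int),
                np.ones(len(groups[names[j]]), dtype=int),
            ])
            sub = dist[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            vec = sub[iu]
            ranks = rankdata(vec)
            m = len(vec)

            def r_of(lab):
                within = lab[iu[0]] == lab[iu[1]]
                return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

            r_obs = r_of(labels)
            count = 0
            lab = labels.copy()
            for _ in range(n_perm):
                rng.shuffle(lab)
                if r_of(lab) >= r_obs - 1e-12:
                    count += 1
            p = (count + 1) / (n_perm + 1)
            r_mat.iloc[i, j] = r_mat.iloc[j, i] = r_obs
            p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
    return r_mat, p_mat


def _upper(a: np.ndarray) -> np.ndarray:
    return a[np.triu_indices(a.shape[0], k=1)]


def _resid(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    x = np.c_[np.ones_like(c), c]
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def mantel(
    a: pd.DataFrame,
    b: pd.DataFrame,
    n_perm: int = 9999,
    n_boot: int = 500,
    conditioning: pd.DataFrame | None = None,
    seed: int = 0,
):
    """One-tailed (partial) Mantel test of Pearson's r between distance matrices.

    r is the Pearson correlation of the upper-triangle vectors; the partial
    variant correlates the residuals of both vectors after regressing each
    on the conditioning matrix's vector.  The p-value is the (count+1)/(n+1)
    proportion of row/column permutations of ``a`` with r >= observed; the
    CI is a percentile bootstrap over entities.

    Returns ``(r, p, (ci_low, ci_high))``.
    """
    if list(a.index) != list(b.index):
        raise ValueError("distance matrices must share entity ids in order")
    am = _check_distance_matrix(a, "a")
    bm = _check_distance_matrix(b, "b")
    cm = None
    if conditioning is not None:
        if list(conditioning.index) != list(a.index):
            raise ValueError("conditioning matrix entity mismatch")
        cm = _check_distance_matrix(conditioning, "conditioning")
    n = am.shape[0]
    va, vb = _upper(am), _upper(bm)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant distance vector: correlation undefined")

    vc = _upper(cm) if cm is not None else None

    def corr(x, y):
        return float(np.corrcoef(x, y)[0, 1])

    if vc is None:
        r_obs = corr(va, vb)
        vb_use = vb
    else:
        ra, rb = _resid(va, vc), _resid(vb, vc)
        r_obs = corr(ra, rb)
        vb_use = rb

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pa = _upper(am[np.ix_(perm, perm)])
        if vc is None:
            r_perm = corr(pa, vb_use)
        else:
            r_perm = corr(_resid(pa, vc), vb_use)
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)

    boot = []
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        ii, jj = np.meshgrid(take, take, indexing="ij")
        distinct = np.triu(take[:, None] != take[None, :], k=1)
        if distinct.sum() < 3:
            continue
        ba = am[ii, jj][distinct]
        bb = bm[ii, jj][distinct]
        if ba.std() == 0 or bb.std() == 0:
            continue
        if vc is None:
            boot.append(corr(ba, bb))
        else:
            bc = cm[ii, jj][distinct]
            boot.append(corr(_resid(ba, bc), _resid(bb, bc)))
    ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975))) if boot else (np.nan, np.nan)
    return r_obs, p, ci


def subpop_distance_matrices(
    metadata: pd.DataFrame,
    log_abundance: pd.DataFrame,
    genotypes,
    grouping: pd.Series | None = None,
    n_perm_anosim: int = 999,
    seed: int = 0,
) -> dict:
    """Aligned subpopulation-level distance matrices for congruence tests.

    Produces geographic (Euclidean on planar site coordinates), Tcol and
    Bio14 (Euclidean on site means), genetic (linearized Weir–Cockerham
    F_ST on the genotype panel) and metabolic (pairwise ANOSIM R from
    inter-sample Euclidean distances on log abundances, shifted to be
    nonnegative if any R < 0) matrices.
    """
    from scipy.spatial.distance import pdist, squareform

    from .popgen import pairwise_fst

    if grouping is None:
        grouping = metadata["subpopulation"]
    grouping = grouping.reindex(metadata.index)
    sites = metadata.groupby(grouping).agg(
        {"x": "mean", "y": "mean", "tcol": "mean", "bio14": "mean"}
    )
    if sites.isna().any().any():
        raise ValueError("missing site covariates for at least one subpopulation")
    names = list(sites.index)

    def euclid(cols):
        return pd.DataFrame(
            squareform(pdist(sites[cols].to_numpy())), index=names, columns=names
        )

    geographic = euclid(["x", "y"])
    tcol = euclid(["tcol"])
    bio14 = euclid(["bio14"])

    genetic = pairwise_fst(genotypes, grouping).loc[names, names]

    samp_d = pd.DataFrame(
        squareform(pdist(log_abundance.T.to_numpy())),
        index=log_abundance.columns, columns=log_abundance.columns,
    )
    r_mat, _ = anosim_pairwise(samp_d, grouping.reindex(log_abundance.columns),
                               n_perm=n_perm_anosim, seed=seed)
    r_mat = r_mat.loc[names, names]
    off = _upper(r_mat.to_numpy())
    if (off < 0).any():
        shift = -off.min()
        r_np = r_mat.to_numpy() + shift
        np.fill_diagonal(r_np, 0.0)
        r_mat = pd.DataFrame(r_np, index=names, columns=names)
    return {
        "geographic": geographic,
        "tcol": tcol,
        "bio14": bio14,
        "genetic": genetic,
        "metabolic": r_mat,
    }
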