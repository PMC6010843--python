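"""Metabolite–metabolite Gaussian graphical model and SNP–metabolite network.

In the study regime the number of metabolites (hundreds) exceeds the
number of samples, so the sample covariance is singular and classical
full-order partial correlations do not exist.  The estimator here shrinks
the sample correlation matrix toward the identity with the analytic
Schäfer–Strimmer/Ledoit–Wolf intensity, inverts the shrunk matrix, and
reads partial correlations off the precision matrix.  Edge significance
uses an empirical null: the z-transformed partial correlations are
overwhelmingly null, so their center and robust spread estimate the null
distribution, and Benjamini–Hochberg q-values select edges.

The integrated network fuses GGM edges (metabolite–metabolite, solid in
the study's display convention) with significant mixed-model association
edges (SNP–metabolite, dashed), annotating each association edge with the
covariate configurations under which it was significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PartialCorrelationGraph",
    "shrinkage_pcor",
    "integrate_network",
    "write_network",
]


@dataclass
class PartialCorrelationGraph:
    pcor: pd.DataFrame  # symmetric, unit diagonal
    edges: pd.DataFrame  # metabolite_a, metabolite_b, pcor, p, q
    shrinkage_lambda: float
    q_max: float = 0.05

    def adjacency(self) -> pd.DataFrame:
        ids = list(self.pcor.index)
        adj = pd.DataFrame(False, index=ids, columns=ids)
        for _, row in self.edges.iterrows():
            adj.loc[row["metabolite_a"], row["metabolite_b"]] = True
            adj.loc[row["metabolite_b"], row["metabolite_a"]] = True
        return adj


def _shrinkage_intensity(x: np.ndarray) -> float:
    """Analytic shrinkage of the correlation matrix toward the identity.

    lambda* = sum of estimated variances of the off-diagonal sample
    correlations divided by the sum of their squares, clamped to [0, 1].
    """
    n, p = x.shape
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = (xs.T @ xs) / (n - 1)
    # var(r_ij) via the empirical variance of the products w_kij = x_ki x_kj
    w_bar = r * (n - 1) / n
    var_sum = 0.0
    r2_sum = 0.0
    # accumulate column-blockwise to keep memory bounded
    for j in range(p):
        w = xs * xs[:, [j]]  # n × p products against variable j
        v = (n / (n - 1) ** 3) * ((w - w_bar[j]) ** 2).sum(axis=0)
        v[j] = 0.0
        var_sum += v.sum()
        rj2 = r[j] ** 2
        rj2[j] = 0.0
        r2_sum += rj2.sum()
    if r2_sum == 0:
        return 1.0
    return float(np.clip(var_sum / r2_sum, 0.0, 1.0))


def shrinkage_pcor(
    log_abundance: pd.DataFrame,
    q_max: float = 0.05,
    shrinkage_lambda: float | None = None,
) -> PartialCorrelationGraph:
    """Full-order partial correlations from a shrunk correlation matrix.

    ``log_abundance`` is samples × metabolites.  Zero-variance metabolites
    are dropped with a warning.  Edges are retained at BH q <= ``q_max``
    under the empirical-null z model.
    """
    if log_abundance.shape[0] < 3:
        raise ValueError("need at least 3 samples for partial correlations")
    x = log_abundance.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance metabolites")
    ids = [m for m, k in zip(log_abundance.columns, keep) if k]
    x = x[:, keep]
    n, p = x.shape

    lam = _shrinkage_intensity(x) if shrinkage_lambda is None else float(shrinkage_lambda)
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = (xs.T @ xs) / (n - 1)
    np.fill_diagonal(r, 1.0)
    r_shrunk = (1 - lam) * r + lam * np.eye(p)
    omega = np.linalg.inv(r_shrunk)
    d = 1.0 / np.sqrt(np.diag(omega))
    pcor = -(omega * d[:, None] * d[None, :])
    np.fill_diagonal(pcor, 1.0)

    iu = np.triu_indices(p, k=1)
    vals = pcor[iu]
    z = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
    # null model: unconnected pairs have z centered at 0.  The null scale is
    # the smaller of (a) a robust empirical estimate (valid when most pairs
    # are null, as in wide panels) and (b) the classical Fisher SE of a
    # full-order partial correlation, 1/sqrt(n - p - 1), defined only when
    # n exceeds p (and the binding estimate when true edges dominate the
    # empirical spread, as in small designed panels)
    scales = [float(np.median(np.abs(z)) / 0.6744898)]
    if n - p - 1 >= 2:
        scales.append(1.0 / np.sqrt(n - p - 1))
    scale = min(s for s in scales if s > 0) if any(s > 0 for s in scales) else 0.0
    if scale == 0:
        pv = np.ones_like(z)
    else:
        pv = 2 * stats.norm.sf(np.abs(z) / scale)
    order = np.argsort(pv)
    m = len(pv)
    q = np.empty(m)
    q[order] = np.minimum.accumulate((pv[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.clip(q, 0, 1)

    sel = q <= q_max
    edges = pd.DataFrame({
        "metabolite_a": [ids[i] for i in iu[0][sel]],
        "metabolite_b": [ids[j] for j in iu[1][sel]],
        "pcor": vals[sel],
        "p": pv[sel],
        "q": q[sel],
    }).sort_values("q", kind="mergesort").reset_index(drop=True)
    pcor_df = pd.DataFrame(pcor, index=ids, columns=ids)
    return PartialCorrelationGraph(pcor_df, edges, lam, q_max)


def integrate_network(
    ggm: PartialCorrelationGraph,
    gwa_results,
    feature_map: dict | None = None,
) -> nx.Graph:
    """Fuse the partial-correlation graph with significant association hits.

    ``gwa_results`` is either a single AssociationResult or a mapping of
    covariate-config name -> AssociationResult.  ``feature_map`` translates
    association trait ids (features) to metabolite group ids; identity when
    omitted.  Nodes are the metabolites participating in a retained GGM
    edge plus SNPs significantly associated with at least one of them; a
    SNP associated with >= 2 distinct metabolites is flagged
    ``multi_associated``.
    """
    if not isinstance(gwa_results, dict):
        gwa_results = {"": gwa_results}
    feature_map = feature_map or {}

    g = nx.Graph()
    ggm_metabolites = set(ggm.edges["metabolite_a"]) | set(ggm.edges["metabolite_b"])
    for m in sorted(ggm_metabolites):
        g.add_node(m, node_type="metabolite")
    for _, row in ggm.edges.iterrows():
        g.add_edge(row["metabolite_a"], row["metabolite_b"], edge_type="GGM",
                   weight=float(row["pcor"]), q=float(row["q"]))

    snp_partners: dict = {}
    for cfg, res in gwa_results.items():
        for _, row in res.significant().iterrows():
            met = feature_map.get(row["trait"], row["trait"])
            if met not in ggm_metabolites:
                continue
            snp = row["snp"]
            snp_partners.setdefault(snp, set()).add(met)
            if not g.has_node(snp):
                g.add_node(snp, node_type="SNP")
            if g.has_edge(snp, met):
                data = g[snp][met]
                configs = set(data["configs"].split("|")) if data["configs"] else set()
                configs.add(cfg or row["config"])
                data["configs"] = "|".join(sorted(configs))
                data["weight"] = max(data["weight"], float(-np.log10(row["p"])))
            else:
                g.add_edge(snp, met, edge_type="GWA",
                           weight=float(-np.log10(row["p"])),
                           configs=cfg or row["config"])
    for snp, partners in snp_partners.items():
        g.nodes[snp]["multi_associated"] = len(partners) >= 2
    return g


def write_network(g: nx.Graph, graphml_path, ggm_tsv_path, gwa_tsv_path) -> None:
    """Write GraphML plus separate GGM and GWA edge-list TSVs."""
    nx.write_graphml(g, graphml_path)
    ggm_rows, gwa_rows = [], []
    for u, v, data in g.edges(data=True):
        if data.get("edge_type") == "GGM":
            ggm_rows.append({"metabolite_a": u, "metabolite_b": v,
                             "pcor": data["weight"], "q": data.get("q")})
        else:
            gwa_rows.append({"snp": u if g.nodes[u]["node_type"] == "SNP" else v,
                             "metabolite": v if g.nodes[u]["node_type"] == "SNP" else u,
                             "neg_log10_p": data["weight"],
                             "configs": data.get("configs", "")})
    pd.DataFrame(ggm_rows, columns=["metabolite_a", "metabolite_b", "pcor", "q"]).to_csv(
        ggm_tsv_path, sep="\t", index=False)
    pd.DataFrame(gwa_rows, columns=["snp", "metabolite", "neg_log10_p", "configs"]).to_csv(
        gwa_tsv_path, sep="\t", index=False)
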