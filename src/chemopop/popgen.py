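"""Genotype QC and population-genetic statistics for biallelic SNP panels.

Covers the marker-side half of the pipeline: Hardy–Weinberg exact tests
(Levene–Haldane conditional distribution), SNP filtering, one-SNP-per-tag
panel selection, observed/expected heterozygosity, per-base nucleotide
diversity over GBS tags, rarefied allelic richness, method-of-moments
individual inbreeding coefficients, identity-by-state kinship, and the
Weir & Cockerham (1984) theta estimator of F_ST with the standard
theta/(1-theta) linearization.

Genotypes are minor-allele dosages in {0, 1, 2}; missing calls are NaN.
Missing data are excluded pairwise (no imputation) everywhere in this
module; the mixed-model association module mean-imputes instead, matching
the conventions of the tools each module emulates (PLINK vs EMMAX).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "read_dosage_tsv",
    "read_vcf",
    "hwe_exact",
    "filter_snps",
    "select_one_snp_per_tag",
    "heterozygosity",
    "nucleotide_diversity",
    "rarefied_allelic_richness",
    "allelic_richness_from_counts",
    "inbreeding_f",
    "ibs_matrix",
    "per_snp_fst",
    "pairwise_fst",
]

#: TSV columns that carry SNP metadata rather than sample dosages.
META_COLUMNS = ["snp_id", "tag_id", "pos_in_tag", "selection_class", "fst"]


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs dosage matrix with per-SNP tag metadata.

    Attributes
    ----------
    dosage
        ``(n_individuals, n_snps)`` float array over {0, 1, 2, NaN}.
    snp_meta
        DataFrame indexed by SNP id with columns ``tag_id``, ``pos_in_tag``
        (0-based offset within the assembled tag), ``selection_class``
        (``"neutral"`` or ``"outlier"``) and ``fst`` (per-SNP estimate, may
        be NaN for neutral tags).
    sample_ids
        Individual labels, aligned with dosage rows.
    tag_length
        Length in bases of the assembled sequencing tags (default 90 bp).
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list = field(default_factory=list)
    tag_length: int = 90

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise ValueError("dosage shape inconsistent with sample/snp id lists")
        vals = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if (self.snp_meta["pos_in_tag"] < 0).any() or (
            self.snp_meta["pos_in_tag"] >= self.tag_length
        ).any():
            raise ValueError("pos_in_tag must lie in [0, tag_length)")

    @property
    def snp_ids(self) -> list:
        return list(self.snp_meta.index)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = [self.snp_meta.index.get_loc(s) for s in snp_ids]
        return replace(
            self, dosage=self.dosage[:, idx], snp_meta=self.snp_meta.loc[list(snp_ids)].copy()
        )

    def to_tsv(self, path) -> None:
        df = self.snp_meta.reset_index().rename(columns={"index": "snp_id"})
        if "snp_id" not in df.columns:
            df.insert(0, "snp_id", self.snp_meta.index)
        dos = pd.DataFrame(self.dosage.T, columns=self.sample_ids)
        pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(
            path, sep="\t", index=False, na_rep="NA"
        )


def read_dosage_tsv(path, tag_length: int = 90) -> GenotypeMatrix:
    """Read a SNP × sample dosage TSV (metadata columns then one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "tag_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing metadata columns: {missing}")
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    meta = df[META_COLUMNS].set_index("snp_id")
    dosage = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(dosage, meta, sample_cols, tag_length=tag_length)


def read_vcf(path, tag_length: int = 90) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Tag id / position / selection class are taken from INFO fields TAG,
    POSTAG and SELCLASS when present, else derived from CHROM/POS with
    class "neutral".  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.array(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        tag = var.INFO.get("TAG", var.CHROM)
        pos = int(var.INFO.get("POSTAG", (var.POS - 1) % tag_length))
        sel = var.INFO.get("SELCLASS", "neutral")
        fst = var.INFO.get("FST", np.nan)
        meta_rows.append(
            {"snp_id": var.ID or f"{var.CHROM}_{var.POS}", "tag_id": str(tag),
             "pos_in_tag": pos, "selection_class": sel, "fst": float(fst) if fst is not None else np.nan}
        )
    meta = pd.DataFrame(meta_rows).set_index("snp_id")
    return GenotypeMatrix(np.array(rows).T, meta, samples, tag_length=tag_length)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def _log_het_prob(n_het: int, n: int, n_a: int) -> float:
    """Log conditional probability of n_het heterozygotes given allele counts.

    Levene–Haldane distribution: n diploids, n_a copies of the rarer allele.
    """
    n_hom_a = (n_a - n_het) // 2
    n_hom_b = n - n_het - n_hom_a
    return (
        gammaln(n + 1)
        - gammaln(n_hom_a + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_b + 1)
        + n_het * math.log(2)
        + gammaln(n_a + 1)
        + gammaln(2 * n - n_a + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact(n_aa_major: int, n_het: int, n_aa_minor: int) -> float:
    """Exact two-sided Hardy–Weinberg p-value for one biallelic locus.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count.  A monomorphic locus returns p = 1.
    """
    for c in (n_aa_major, n_het, n_aa_minor):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_aa_major + n_het + n_aa_minor
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = min(2 * n_aa_major + n_het, 2 * n_aa_minor + n_het)
    if n_a == 0:
        return 1.0
    # heterozygote count shares parity with the minor allele count
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.array([_log_het_prob(int(h), n, n_a) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.where(hets == n_het)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Filtering and panel selection
# ---------------------------------------------------------------------------

def _genotype_counts(col: np.ndarray):
    ok = ~np.isnan(col)
    g = col[ok]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def filter_snps(
    g: GenotypeMatrix,
    grouping: pd.Series,
    maf_min: float = 0.05,
    call_rate_min: float = 0.80,
    hwe_alpha: float = 0.05,
    min_subpop_n: int = 5,
):
    """Apply minor-allele-frequency, call-rate, and per-subpopulation HWE filters.

    A SNP is kept iff its MAF (over non-missing calls) is >= ``maf_min``, its
    call rate is >= ``call_rate_min``, and the HWE exact p-value is >=
    ``hwe_alpha`` in strictly more than half of the subpopulations with at
    least ``min_subpop_n`` genotyped individuals.

    Returns ``(filtered GenotypeMatrix, report DataFrame)`` where the report
    counts removals per filter (a SNP failing several filters is counted
    under each).
    """
    grouping = grouping.reindex(g.sample_ids)
    if grouping.isna().any():
        raise ValueError("every sample needs a subpopulation assignment")
    groups = {k: np.asarray(v) for k, v in grouping.groupby(grouping).indices.items()}

    keep = np.ones(g.n_snps, dtype=bool)
    fails = {"maf": 0, "call_rate": 0, "hwe": 0}
    for j in range(g.n_snps):
        col = g.dosage[:, j]
        ok = ~np.isnan(col)
        call_rate = ok.mean()
        if ok.sum() == 0:
            keep[j] = False
            fails["call_rate"] += 1
            continue
        p = col[ok].mean() / 2.0
        maf = min(p, 1 - p)
        if maf < maf_min:
            keep[j] = False
            fails["maf"] += 1
        if call_rate < call_rate_min:
            keep[j] = False
            fails["call_rate"] += 1
        n_pass = n_eligible = 0
        for idx in groups.values():
            sub = col[idx]
            n0, n1, n2 = _genotype_counts(sub)
            if n0 + n1 + n2 < min_subpop_n:
                continue
            n_eligible += 1
            if hwe_exact(n0, n1, n2) >= hwe_alpha:
                n_pass += 1
        if n_eligible > 0 and not (n_pass > n_eligible / 2):
            keep[j] = False
            fails["hwe"] += 1
    report = pd.DataFrame(
        {"filter": list(fails), "n_removed": list(fails.values())}
    ).set_index("filter")
    report.loc["kept"] = int(keep.sum())
    out = replace(g, dosage=g.dosage[:, keep], snp_meta=g.snp_meta.iloc[keep].copy())
    return out, report


def select_one_snp_per_tag(g: GenotypeMatrix):
    """Thin each sequencing tag to a single SNP and split the panels.

    Neutral tags keep the SNP closest to the restriction cut site (minimal
    ``pos_in_tag``, ties by lexicographic id); outlier tags keep the SNP with
    the highest per-SNP F_ST (ties by minimal position).  A tag containing a
    mix of classes is treated as outlier.

    Returns ``(neutral_panel, association_panel)``: the association panel
    holds one SNP from every tag; the neutral panel is its neutral-tag subset.
    """
    chosen, chosen_class = [], {}
    meta = g.snp_meta
    for tag, sub in meta.groupby("tag_id", sort=True):
        classes = set(sub["selection_class"])
        cls = "outlier" if "outlier" in classes else "neutral"
        if cls == "neutral":
            sub = sub.sort_values(["pos_in_tag"], kind="mergesort")
            sub = sub.loc[sub["pos_in_tag"] == sub["pos_in_tag"].min()]
            pick = sorted(sub.index)[0]
        elif sub["fst"].isna().all():
            # no usable differentiation estimate (e.g. monomorphic in the
            # genotyped sample): fall back to the cut-site-proximity rule
            import warnings

            warnings.warn(f"outlier tag {tag} has no per-SNP fst; using position rule")
            sub = sub.sort_values(["pos_in_tag"], kind="mergesort")
            pick = sorted(sub.loc[sub["pos_in_tag"] == sub["pos_in_tag"].min()].index)[0]
        else:
            best = sub["fst"].max()
            cand = sub.loc[sub["fst"] == best]
            cand = cand.sort_values(["pos_in_tag"], kind="mergesort")
            pick = cand.index[0]
        chosen.append(pick)
        chosen_class[pick] = cls
    assoc = g.subset_snps(chosen)
    neutral_ids = [s for s in chosen if chosen_class[s] == "neutral"]
    neutral = g.subset_snps(neutral_ids)
    return neutral, assoc


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def _per_locus_he(col: np.ndarray):
    """Unbiased expected heterozygosity 2p(1-p) * 2n/(2n-1); NaN if < 2 calls."""
    ok = ~np.isnan(col)
    n = ok.sum()
    if n < 2:
        return np.nan
    p = col[ok].mean() / 2.0
    return 2 * p * (1 - p) * (2 * n) / (2 * n - 1)


def heterozygosity(
    g: GenotypeMatrix,
    grouping: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed and (unbiased) expected heterozygosity per subpopulation.

    Subpopulation values are means over loci; 95% CIs come from a
    nonparametric bootstrap over loci.
    """
    grouping = grouping.reindex(g.sample_ids)
    rng = np.random.default_rng(seed)
    rows = []
    for subpop, idx in grouping.groupby(grouping).indices.items():
        sub = g.dosage[np.asarray(idx), :]
        ho = np.array([
            np.nanmean(sub[:, j] == 1) if (~np.isnan(sub[:, j])).sum() >= 2 else np.nan
            for j in range(sub.shape[1])
        ])
        he = np.array([_per_locus_he(sub[:, j]) for j in range(sub.shape[1])])
        valid = ~np.isnan(ho) & ~np.isnan(he)
        ho, he = ho[valid], he[valid]
        boot_idx = rng.integers(0, len(ho), size=(n_boot, len(ho)))
        ho_b = ho[boot_idx].mean(axis=1)
        he_b = he[boot_idx].mean(axis=1)
        rows.append({
            "subpopulation": subpop,
            "Ho": ho.mean(), "Ho_ci_low": np.quantile(ho_b, 0.025), "Ho_ci_high": np.quantile(ho_b, 0.975),
            "He": he.mean(), "He_ci_low": np.quantile(he_b, 0.025), "He_ci_high": np.quantile(he_b, 0.975),
            "n_loci": len(ho),
        })
    return pd.DataFrame(rows).set_index("subpopulation")


def nucleotide_diversity(g: GenotypeMatrix, grouping: pd.Series) -> pd.DataFrame:
    """Per-subpopulation nucleotide diversity per base over the assembled tags.

    pi = sum over variable sites of unbiased 2pq divided by the total
    assayed sequence length (tag count × tag length) — the only sequence
    length information reduced-representation tags carry.
    """
    grouping = grouping.reindex(g.sample_ids)
    n_tags = g.snp_meta["tag_id"].nunique()
    denom = n_tags * g.tag_length
    rows = []
    for subpop, idx in grouping.groupby(grouping).indices.items():
        sub = g.dosage[np.asarray(idx), :]
        he = np.array([_per_locus_he(sub[:, j]) for j in range(sub.shape[1])])
        rows.append({"subpopulation": subpop, "pi": np.nansum(he) / denom})
    return pd.DataFrame(rows).set_index("subpopulation")


def allelic_richness_from_counts(counts, g: int) -> float:
    """Rarefied allelic richness of one locus from per-allele copy counts.

    Expected number of distinct alleles in a random subsample of ``g`` gene
    copies: sum over alleles of 1 - C(N - N_i, g)/C(N, g).
    """
    counts = np.asarray(counts, dtype=float)
    n_total = counts.sum()
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    if g > n_total:
        raise ValueError("rarefaction size exceeds available gene copies")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for ni in counts:
        if ni == 0:
            continue
        if n_total - ni < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_choose(n_total - ni, g) - log_choose(n_total, g))
    return float(total)


def rarefied_allelic_richness(
    g_mat: GenotypeMatrix, grouping: pd.Series, g: int | None = None
) -> pd.DataFrame:
    """Mean rarefied allelic richness per subpopulation over biallelic loci.

    ``g`` defaults to the smallest number of genotyped gene copies at any
    (locus, subpopulation) combination, so every locus can be rarefied to a
    common size.
    """
    grouping = grouping.reindex(g_mat.sample_ids)
    groups = {k: np.asarray(v) for k, v in grouping.groupby(grouping).indices.items()}
    copies = {
        k: 2 * (~np.isnan(g_mat.dosage[idx, :])).sum(axis=0) for k, idx in groups.items()
    }
    if g is None:
        g = int(min(c.min() for c in copies.values()))
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    rows = []
    for subpop, idx in groups.items():
        sub = g_mat.dosage[idx, :]
        vals = []
        for j in range(sub.shape[1]):
            col = sub[:, j]
            ok = ~np.isnan(col)
            n_copies = 2 * ok.sum()
            if n_copies < g:
                continue
            n_minor = col[ok].sum()
            vals.append(allelic_richness_from_counts([n_copies - n_minor, n_minor], g))
        rows.append({"subpopulation": subpop, "allelic_richness": float(np.mean(vals)), "g": g})
    return pd.DataFrame(rows).set_index("subpopulation")


def inbreeding_f(g: GenotypeMatrix, min_loci: int = 20) -> pd.DataFrame:
    """Method-of-moments inbreeding coefficient per individual.

    F = (O_hom - E_hom) / (L - E_hom) over the individual's non-missing
    loci, with E_hom computed from total-sample allele frequencies using the
    small-sample-corrected expected heterozygosity.  Individuals with fewer
    than ``min_loci`` genotyped loci are flagged unreliable.
    """
    p = np.nanmean(g.dosage, axis=0) / 2.0
    n_called = (~np.isnan(g.dosage)).sum(axis=0)
    exp_het = 2 * p * (1 - p) * (2 * n_called) / np.maximum(2 * n_called - 1, 1)
    rows = []
    for i, sid in enumerate(g.sample_ids):
        row = g.dosage[i, :]
        ok = ~np.isnan(row)
        L = int(ok.sum())
        o_hom = float((row[ok] != 1).sum())
        e_hom = float((1 - exp_het[ok]).sum())
        denom = L - e_hom
        f = (o_hom - e_hom) / denom if denom > 0 else np.nan
        rows.append({"sample_id": sid, "F": f, "n_loci": L, "reliable": L >= min_loci})
    return pd.DataFrame(rows).set_index("sample_id")


def ibs_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state similarity matrix (the mixed-model kinship proxy).

    Pairwise mean over shared non-missing loci of (2 - |d_i - d_j|)/2.
    """
    d = g.dosage
    n = g.n_samples
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(d[i]) & ~np.isnan(d[j])
            if not ok.any():
                raise ValueError(
                    f"samples {g.sample_ids[i]} and {g.sample_ids[j]} share no genotyped locus"
                )
            sim[i, j] = sim[j, i] = np.mean((2 - np.abs(d[i, ok] - d[j, ok])) / 2)
    return pd.DataFrame(sim, index=g.sample_ids, columns=g.sample_ids)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(cols_by_pop):
    """Per-locus Weir–Cockerham variance components (a, b, c).

    ``cols_by_pop``: list of 1-D dosage arrays (NaN = missing), one per
    subpopulation.  Returns NaN components when fewer than two
    subpopulations have >= 2 genotyped individuals.
    """
    ns, ps, hs = [], [], []
    for col in cols_by_pop:
        gt = col[~np.isnan(col)]
        if len(gt) < 2:
            continue
        ns.append(len(gt))
        ps.append(gt.mean() / 2.0)
        hs.append((gt == 1).mean())
    r = len(ns)
    if r < 2:
        return np.nan, np.nan, np.nan
    ns = np.asarray(ns, dtype=float)
    ps = np.asarray(ps)
    hs = np.asarray(hs)
    nbar = ns.mean()
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    pbar = (ns * ps).sum() / (r * nbar)
    s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (ns * hs).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def per_snp_fst(g: GenotypeMatrix, grouping: pd.Series) -> pd.Series:
    """Per-locus Weir–Cockerham theta over all subpopulations."""
    grouping = grouping.reindex(g.sample_ids)
    groups = [np.asarray(v) for v in grouping.groupby(grouping).indices.values()]
    out = np.full(g.n_snps, np.nan)
    for j in range(g.n_snps):
        a, b, c = _wc_components([g.dosage[idx, j] for idx in groups])
        denom = a + b + c
        if np.isfinite(denom) and denom != 0:
            out[j] = a / denom
    return pd.Series(out, index=g.snp_meta.index, name="fst")


def pairwise_fst(
    g: GenotypeMatrix,
    grouping: pd.Series,
    linearize: bool = True,
    cap: float = 100.0,
) -> pd.DataFrame:
    """Pairwise multilocus Weir–Cockerham theta between subpopulations.

    The multilocus estimate is the ratio-of-sums across loci.  When
    ``linearize`` is set, values are mapped through theta/(1-theta)
    (Rousset's linearization); negative multilocus estimates are truncated
    to 0 first, and theta = 1 maps to ``cap``.
    """
    grouping = grouping.reindex(g.sample_ids)
    groups = {k: np.asarray(v) for k, v in grouping.groupby(grouping).indices.items()}
    names = [k for k, idx in groups.items() if len(idx) >= 2]
    dropped = set(groups) - set(names)
    if dropped:
        import warnings

        warnings.warn(f"subpopulations with < 2 individuals excluded: {sorted(dropped)}")
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for ii in range(len(names)):
        for jj in range(ii + 1, len(names)):
            num = den = 0.0
            for k in range(g.n_snps):
                a, b, c = _wc_components(
                    [g.dosage[groups[names[ii]], k], g.dosage[groups[names[jj]], k]]
                )
                if np.isfinite(a):
                    num += a
                    den += a + b + c
            theta = num / den if den != 0 else 0.0
            if linearize:
                theta = max(theta, 0.0)
                if theta >= 1.0:
                    import warnings

                    warnings.warn("theta = 1 linearization capped")
                    val = cap
                else:
                    val = theta / (1 - theta)
            else:
                val = theta
            mat.iloc[ii, jj] = mat.iloc[jj, ii] = val
    return mat
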