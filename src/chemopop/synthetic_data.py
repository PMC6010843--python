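"""Synthetic cohort generator with recorded ground truth.

Emulates a field study of six tree subpopulations in three ecoregions
(~30 individuals each): a reduced-representation SNP panel with neutral and
outlier tags, an untargeted LC-MS metabolome in which each true metabolite
gives rise to several redundant peaks (isotopes/adducts/fragments), site
environmental covariates, and a disease state driven by biomarker
abundances plus inbreeding, temperature and site effects.

Every stochastic choice is recorded in :class:`SyntheticTruth`, so each
downstream stage of the pipeline is testable by parameter recovery:
F_ST against its generating value, the feature→metabolite grouping against
the true redundancy structure, the partial-correlation graph against the
planted latent-pathway support, association scans against planted
SNP→metabolite effects, and health models against the generating logistic
coefficients.

Population structure follows the Balding–Nichols model: subpopulation
allele frequencies are Beta((1-F)/F * p, (1-F)/F * (1-p)) draws around an
ancestral frequency p with F the target differentiation.  An optional
second (region) level of the same form places extra divergence between
ecoregions, giving genetic structure that mirrors geography.

The metabolite covariance is built from latent pathway factors, so the true
partial-correlation graph (within-pathway cliques) is known by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .lcms_features import FeatureTable
from .popgen import GenotypeMatrix, per_snp_fst

__all__ = [
    "DiseaseModel",
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_metabolome",
    "simulate_health",
    "simulate_cohort",
    "write_cohort",
]


@dataclass
class DiseaseModel:
    """Logistic disease-model coefficients on standardized predictors.

    Slopes act on z-scored log biomarker abundances, z-scored inbreeding F
    and z-scored Tcol; the site random intercept has SD ``site_sd``.

    The default slopes make the *relative* dominance of the first
    biomarker, not just its absolute level, predictive of health: a
    positive slope on the dominant member with mild negative slopes on its
    pathway partners.  With slopes on the dominant member alone, the
    shared pathway factor cancels out of the within-group abundance ratios
    and dominance indices of the biomarker group carry almost no health
    signal.
    """

    intercept: float = 1.2
    biomarker_slopes: tuple = (1.5, -0.5, -0.5)
    f_slope: float = -1.0
    tcol_slope: float = -0.5
    site_sd: float = 0.5


@dataclass
class CohortConfig:
    """Study-design and generative parameters of one synthetic cohort."""

    n_subpops: int = 6
    n_regions: int = 3
    individuals_per_subpop: int = 30
    # genotypes
    n_tags: int = 200
    snps_per_tag: int = 2
    fst_target: float = 0.05
    region_differentiation: float = 0.05  # extra Balding-Nichols F between regions
    outlier_tag_fraction: float = 0.15
    outlier_fst_boost: float = 4.0
    missing_rate: float = 0.03
    # metabolome
    n_metabolites: int = 377
    redundancy_factor: float = 7.4  # mean peaks per metabolite (377 -> ~2,785 features)
    n_latent_pathways: int = 20
    pathway_size_range: tuple = (3, 4)
    pathway_loading_range: tuple = (0.7, 1.0)
    noise_sd: float = 0.5
    baseline_log_mean: float = np.log(1e5)
    baseline_log_sd: float = 1.0
    env_effect_sizes: dict = field(default_factory=lambda: {"tcol": 0.5, "bio14": 0.3})
    env_affected_fraction: float = 0.3
    snp_effect_size: float = 0.8  # log-abundance per dosage unit; sized for
    # >=90% power at the Bonferroni level under the default cohort
    planted_snp_effects: list | None = None  # [(snp_id, metabolite_id, beta)]
    dropout_rate: float = 0.05
    rt_jitter: float = 0.5  # s, within-group RT scatter
    peak_noise_sd: float = 0.05  # log-scale independent noise of redundant peaks
    # health
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    n_biomarkers: int = 3
    dominant_biomarker_boost: float = 1.5  # extra log-baseline of biomarker 1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subpops", "n_regions", "individuals_per_subpop", "n_tags",
                     "snps_per_tag", "n_metabolites", "n_latent_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.fst_target < 1):
            raise ValueError("fst_target must lie in (0, 1)")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.redundancy_factor < 1:
            raise ValueError("redundancy_factor must be >= 1")
        if self.n_subpops % self.n_regions != 0:
            raise ValueError("n_subpops must be divisible by n_regions")

    @property
    def n_samples(self) -> int:
        return self.n_subpops * self.individuals_per_subpop

    def rngs(self):
        """Independent per-stage generators derived from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ["genotypes", "environment", "metabolome", "health"]
        return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for parameter recovery."""

    subpop_freqs: pd.DataFrame = None  # subpop × SNP allele frequencies
    complete_dosage: np.ndarray = None  # dosage before missingness masking
    ggm_adjacency: pd.DataFrame = None  # metabolite × metabolite bool, symmetric
    pathways: list = None  # list of metabolite-id lists
    snp_effects: list = None  # [(snp_id, metabolite_id, beta)]
    env_slopes: pd.DataFrame = None  # metabolite × covariate slopes
    biomarkers: list = None
    disease_model: DiseaseModel = None
    pathway_scores: pd.DataFrame = None  # sample × pathway latent scores
    metabolite_of_feature: dict = None  # feature_id -> metabolite_id
    metabolite_log_abundance: pd.DataFrame = None  # pre-dropout, metabolite × sample
    focal_scaling: dict = None  # mean/sd used to standardize health predictors

    def validate(self, snp_ids, metabolite_ids):
        snp_ids, metabolite_ids = set(snp_ids), set(metabolite_ids)
        for snp, met, _ in self.snp_effects:
            if snp not in snp_ids or met not in metabolite_ids:
                raise ValueError(f"planted effect references unknown ids: ({snp}, {met})")
        adj = self.ggm_adjacency.to_numpy()
        if not (adj == adj.T).all():
            raise ValueError("planted adjacency must be symmetric")


@dataclass
class SyntheticCohort:
    """Bundle of generated data plus truth."""

    config: CohortConfig
    genotypes: GenotypeMatrix
    features: FeatureTable
    metadata: pd.DataFrame  # indexed by sample id
    truth: SyntheticTruth


def _beta_draw(rng, p, f, size):
    """Balding–Nichols Beta draw around frequency p with differentiation f."""
    if f <= 0:
        return np.broadcast_to(p, size).copy()
    a = (1 - f) / f
    return rng.beta(a * p, a * (1 - p), size=size)


def simulate_genotypes(config: CohortConfig, rng=None):
    """Draw the SNP panel under (hierarchical) Balding–Nichols structure.

    Returns ``(GenotypeMatrix, SyntheticTruth)`` with subpopulation allele
    frequencies and the pre-missingness dosage recorded in the truth.  A
    ``outlier_tag_fraction`` of tags is generated with boosted
    differentiation and labeled "outlier"; per-SNP F_ST estimates are
    filled into the SNP metadata (needed for outlier-panel selection).
    """
    rng = rng if rng is not None else config.rngs()["genotypes"]
    n_snps = config.n_tags * config.snps_per_tag
    n_out_tags = int(round(config.outlier_tag_fraction * config.n_tags))
    outlier_tags = set(rng.choice(config.n_tags, size=n_out_tags, replace=False))

    p_anc = rng.uniform(0.1, 0.9, size=n_snps)
    tag_of_snp = np.repeat(np.arange(config.n_tags), config.snps_per_tag)
    f_snp = np.full(n_snps, config.fst_target)
    is_outlier = np.isin(tag_of_snp, list(outlier_tags))
    f_snp[is_outlier] = np.minimum(config.fst_target * config.outlier_fst_boost, 0.6)

    subpops = [f"SP{i + 1}" for i in range(config.n_subpops)]
    per_region = config.n_subpops // config.n_regions
    region_of_subpop = {
        sp: f"R{i // per_region + 1}" for i, sp in enumerate(subpops)
    }

    # region-level then subpopulation-level frequency draws
    f_reg = config.region_differentiation
    region_freqs = {
        reg: np.array([_beta_draw(rng, p_anc[j], f_reg, ())[()] if f_reg > 0 else p_anc[j]
                       for j in range(n_snps)])
        for reg in sorted(set(region_of_subpop.values()))
    }
    subpop_freqs = {}
    for sp in subpops:
        base = region_freqs[region_of_subpop[sp]]
        subpop_freqs[sp] = np.array(
            [_beta_draw(rng, base[j], f_snp[j], ())[()] for j in range(n_snps)]
        )

    sample_ids, dosage_rows = [], []
    for sp in subpops:
        freqs = subpop_freqs[sp]
        dos = rng.binomial(2, freqs, size=(config.individuals_per_subpop, n_snps))
        dosage_rows.append(dos)
        sample_ids.extend(f"{sp}_{k + 1:03d}" for k in range(config.individuals_per_subpop))
    complete = np.vstack(dosage_rows).astype(float)

    dosage = complete.copy()
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    snp_ids = [f"B{t + 1}_{pos}" for t, pos in zip(
        tag_of_snp,
        rng.integers(0, 90, size=n_snps),
    )]
    # ensure unique position labels per tag
    meta = pd.DataFrame({
        "snp_id": snp_ids,
        "tag_id": [f"T{t + 1:04d}" for t in tag_of_snp],
        "pos_in_tag": [int(s.split("_")[1]) for s in snp_ids],
        "selection_class": np.where(is_outlier, "outlier", "neutral"),
        "fst": np.nan,
    })
    # deduplicate snp ids (same tag, same random position)
    dupes = meta["snp_id"].duplicated(keep=False)
    if dupes.any():
        counters = meta.groupby("snp_id").cumcount()
        meta.loc[dupes, "snp_id"] = (
            meta.loc[dupes, "snp_id"] + "." + counters[dupes].astype(str)
        )
    meta = meta.set_index("snp_id")

    g = GenotypeMatrix(dosage, meta, sample_ids, tag_length=90)
    grouping = pd.Series(
        [s.rsplit("_", 1)[0] for s in sample_ids], index=sample_ids, name="subpopulation"
    )
    g.snp_meta["fst"] = per_snp_fst(g, grouping).to_numpy()

    truth = SyntheticTruth(
        subpop_freqs=pd.DataFrame(subpop_freqs, index=meta.index).T,
        complete_dosage=complete,
    )
    return g, truth


def simulate_environment(config: CohortConfig, sample_ids, rng=None) -> pd.DataFrame:
    """Site coordinates and environmental covariates per sample.

    Region centers sit far apart on an abstract planar grid; subpopulation
    sites are jittered around their region's center, so geographic distance
    mirrors the hierarchical genetic structure.  Tcol and Bio14 are
    site-level values (region gradient + site noise), confounded with
    subpopulation by construction — as in real collection campaigns.
    """
    rng = rng if rng is not None else config.rngs()["environment"]
    subpops = sorted({s.rsplit("_", 1)[0] for s in sample_ids},
                     key=lambda s: int(s[2:]))
    per_region = config.n_subpops // config.n_regions
    angles = 2 * np.pi * np.arange(config.n_regions) / config.n_regions
    centers = 100.0 * np.c_[np.cos(angles), np.sin(angles)]
    rows = []
    for i, sp in enumerate(subpops):
        reg = i // per_region
        x, y = centers[reg] + rng.normal(0, 8.0, size=2)
        tcol = 20.0 + 3.0 * reg + rng.normal(0, 1.0)
        bio14 = 40.0 - 6.0 * reg + rng.normal(0, 3.0)
        rows.append({"subpopulation": sp, "region": f"R{reg + 1}", "x": x, "y": y,
                     "tcol": tcol, "bio14": bio14})
    sites = pd.DataFrame(rows).set_index("subpopulation")
    meta = pd.DataFrame({"sample_id": sample_ids})
    meta["subpopulation"] = [s.rsplit("_", 1)[0] for s in sample_ids]
    meta = meta.join(sites, on="subpopulation").set_index("sample_id")
    return meta


def simulate_metabolome(config: CohortConfig, genotypes: GenotypeMatrix,
                        metadata: pd.DataFrame, truth: SyntheticTruth, rng=None):
    """Generate the metabolite layer and expand it into a redundant peak table.

    Log abundance of metabolite m in sample i:

        baseline_m + sum_k loading_mk * pathway_ki + sum planted SNP effects
        + env slopes * standardized covariates + N(0, noise_sd)

    Each metabolite is then expanded into ``1 + Poisson(redundancy_factor-1)``
    peaks sharing its retention time up to ``rt_jitter``, with near-perfectly
    correlated intensities and distinct m/z (adduct/isotope offsets); the
    parent [M-H]- peak is always the most intense.  Per-sample dropout zeros
    all peaks of an undetected metabolite.
    """
    rng = rng if rng is not None else config.rngs()["metabolome"]
    n_m, n_s = config.n_metabolites, len(genotypes.sample_ids)
    met_ids = [f"MET{m + 1:04d}" for m in range(n_m)]
    samples = list(genotypes.sample_ids)

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_m)

    # latent pathways -> true partial-correlation support (within-pathway cliques)
    lo, hi = config.pathway_size_range
    pathways, used = [], set()
    pool = list(range(n_m))
    rng.shuffle(pool)
    cursor = 0
    for _ in range(config.n_latent_pathways):
        size = int(rng.integers(lo, hi + 1))
        if cursor + size > n_m:
            break
        members = pool[cursor: cursor + size]
        cursor += size
        pathways.append(members)
        used.update(members)
    scores = rng.standard_normal((n_s, len(pathways)))
    loadings = np.zeros((n_m, len(pathways)))
    for k, members in enumerate(pathways):
        mag = rng.uniform(*config.pathway_loading_range, size=len(members))
        sign = rng.choice([1.0, -1.0], size=len(members), p=[0.8, 0.2])
        loadings[members, k] = mag * sign

    # biomarkers: leading members of the first pathway; the first one gets
    # its baseline raised above the largest of its group so it is the
    # dominant (most abundant) member in nearly all samples — without this
    # guarantee a partner can out-draw it and invert dominance indices
    n_bio = min(config.n_biomarkers, len(pathways[0])) if pathways else 0
    biomarkers = [met_ids[m] for m in pathways[0][:n_bio]] if pathways else []
    if biomarkers:
        group = pathways[0]
        baseline[group[0]] = (baseline[group].max()
                              + config.dominant_biomarker_boost)

    # planted SNP -> metabolite effects
    if config.planted_snp_effects is not None:
        snp_effects = list(config.planted_snp_effects)
    else:
        snp_ids = genotypes.snp_ids
        maf = np.nanmean(genotypes.dosage, axis=0) / 2
        common = [s for s, p in zip(snp_ids, maf) if 0.2 <= p <= 0.8]
        picks = rng.choice(len(common), size=min(2, len(common)), replace=False)
        snp_effects = []
        if len(picks) >= 1 and pathways:
            # one SNP planted on two pathway-linked metabolites
            pw = pathways[0]
            snp_effects.append((common[picks[0]], met_ids[pw[0]], config.snp_effect_size))
            if len(pw) > 1:
                snp_effects.append((common[picks[0]], met_ids[pw[1]], config.snp_effect_size))
        if len(picks) >= 2:
            free = [m for m in range(n_m) if m not in used]
            target = free[0] if free else n_m - 1
            snp_effects.append((common[picks[1]], met_ids[target], config.snp_effect_size))

    met_index = {m: i for i, m in enumerate(met_ids)}
    snp_index = {s: i for i, s in enumerate(genotypes.snp_ids)}
    for snp, met, _ in snp_effects:
        if snp not in snp_index or met not in met_index:
            raise ValueError(f"planted effect references unknown ids: ({snp}, {met})")

    # environmental slopes on a random subset of metabolites
    env_slopes = pd.DataFrame(0.0, index=met_ids, columns=list(config.env_effect_sizes))
    for cov, slope in config.env_effect_sizes.items():
        n_aff = int(round(config.env_affected_fraction * n_m))
        affected = rng.choice(n_m, size=n_aff, replace=False)
        signs = rng.choice([1.0, -1.0], size=n_aff)
        env_slopes.iloc[affected, env_slopes.columns.get_loc(cov)] = slope * signs

    env_z = {}
    for cov in config.env_effect_sizes:
        v = metadata.loc[samples, cov].to_numpy(dtype=float)
        env_z[cov] = (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)

    log_ab = np.tile(baseline[:, None], (1, n_s))
    log_ab += loadings @ scores.T
    for cov in config.env_effect_sizes:
        log_ab += env_slopes[cov].to_numpy()[:, None] * env_z[cov][None, :]
    complete_dosage = truth.complete_dosage
    for snp, met, beta in snp_effects:
        d = complete_dosage[:, snp_index[snp]]
        log_ab[met_index[met], :] += beta * d
    log_ab += rng.normal(0, config.noise_sd, size=log_ab.shape)

    met_log = pd.DataFrame(log_ab, index=met_ids, columns=samples)

    # true conditional-dependence support: within-pathway cliques
    adj = np.zeros((n_m, n_m), dtype=bool)
    for members in pathways:
        for a in members:
            for b in members:
                if a != b:
                    adj[a, b] = True
    ggm_adjacency = pd.DataFrame(adj, index=met_ids, columns=met_ids)

    # dropout: a metabolite undetected in a sample zeroes all its peaks
    detected = rng.random((n_m, n_s)) >= config.dropout_rate

    # expand into redundant peaks; RT on a shuffled grid keeps distinct
    # metabolites separated beyond typical grouping tolerances
    n_peaks = 1 + rng.poisson(max(config.redundancy_factor - 1.0, 0.0), size=n_m)
    rt_grid = np.linspace(90.0, 1170.0, n_m)
    spacing = rt_grid[1] - rt_grid[0] if n_m > 1 else 1080.0
    rt_assign = rng.permutation(rt_grid) + rng.uniform(
        -1, 1, size=n_m) * min(2.0, spacing / 4)
    neutral_mass = rng.uniform(120.0, 1500.0, size=n_m)
    offsets = np.array([1.00336, 2.00671, -18.0106, 46.0055, 35.9767, -46.0055,
                        18.0106, 60.0211, -60.0211, 3.01007])

    feat_ids, feat_mz, feat_rt, rows, met_of_feat = [], [], [], [], {}
    inten = np.exp(log_ab) * detected
    for m in range(n_m):
        parent_mz = neutral_mass[m] - 1.007276
        for pk in range(int(n_peaks[m])):
            if pk == 0:
                mz = parent_mz
                scale = np.ones(n_s)
            else:
                mz = parent_mz + offsets[(pk - 1) % len(offsets)] * (1 + (pk - 1) // len(offsets))
                scale = rng.uniform(0.1, 0.8) * np.exp(
                    rng.normal(0, config.peak_noise_sd, size=n_s))
            rt = rt_assign[m] + (rng.uniform(-config.rt_jitter, config.rt_jitter) if pk else 0.0)
            fid = f"M{mz:.0f}T{rt:.0f}"
            while fid in met_of_feat:
                fid += "x"
            feat_ids.append(fid)
            feat_mz.append(mz)
            feat_rt.append(max(rt, 0.0))
            rows.append(inten[m] * scale)
            met_of_feat[fid] = met_ids[m]

    features = FeatureTable(feat_ids, np.array(feat_mz), np.array(feat_rt),
                            np.vstack(rows), samples)

    truth.ggm_adjacency = ggm_adjacency
    truth.pathways = [[met_ids[m] for m in members] for members in pathways]
    truth.snp_effects = snp_effects
    truth.env_slopes = env_slopes
    truth.biomarkers = biomarkers
    truth.metabolite_of_feature = met_of_feat
    truth.metabolite_log_abundance = met_log
    truth.pathway_scores = pd.DataFrame(
        scores, index=samples, columns=[f"PW{k + 1}" for k in range(len(pathways))]
    )
    truth.validate(genotypes.snp_ids, met_ids)
    return features, truth


def simulate_health(config: CohortConfig, truth: SyntheticTruth,
                    metadata: pd.DataFrame, inbreeding: pd.Series, rng=None):
    """Draw binary health from the logistic disease model, then derive a 1-5 score.

    The ordinal score is obtained by quantile-binning the linear predictor
    within each binary class (diseased -> terciles 1/2/3, healthy -> halves
    4/5), so recoding scores {4,5} vs {1,2,3} reproduces the generated
    binary state exactly.
    """
    rng = rng if rng is not None else config.rngs()["health"]
    dm = config.disease_model
    samples = list(truth.metabolite_log_abundance.columns)

    def zscore(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)

    lin = np.full(len(samples), dm.intercept)
    scaling = {}
    for b, met in enumerate(truth.biomarkers):
        v = truth.metabolite_log_abundance.loc[met, samples].to_numpy()
        scaling[met] = {"mean": float(v.mean()), "sd": float(v.std())}
        slope = dm.biomarker_slopes[b] if b < len(dm.biomarker_slopes) else 0.0
        lin += slope * zscore(v)
    f_vals = inbreeding.reindex(samples).to_numpy(dtype=float)
    tcol = metadata.loc[samples, "tcol"].to_numpy(dtype=float)
    scaling["F"] = {"mean": float(f_vals.mean()), "sd": float(f_vals.std())}
    scaling["tcol"] = {"mean": float(tcol.mean()), "sd": float(tcol.std())}
    lin += dm.f_slope * zscore(f_vals) + dm.tcol_slope * zscore(tcol)

    sites = metadata.loc[samples, "subpopulation"]
    site_effects = {sp: rng.normal(0, dm.site_sd) for sp in sorted(sites.unique())}
    lin += np.array([site_effects[sp] for sp in sites])

    binary = (rng.random(len(samples)) < expit(lin)).astype(int)

    score = np.zeros(len(samples), dtype=int)
    for state, bins in ((0, [1, 2, 3]), (1, [4, 5])):
        idx = np.where(binary == state)[0]
        if len(idx) == 0:
            continue
        qs = np.linspace(0, 1, len(bins) + 1)[1:-1]
        cuts = np.quantile(lin[idx], qs) if len(qs) else np.array([])
        score[idx] = np.array(bins)[np.searchsorted(cuts, lin[idx], side="right")]

    truth.disease_model = dm
    truth.focal_scaling = scaling
    health = pd.DataFrame(
        {"health_binary": binary, "health_score": score,
         "site_effect": [site_effects[sp] for sp in sites]},
        index=samples,
    )
    return health


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Run all generator stages with per-stage substreams of the global seed."""
    from .popgen import inbreeding_f

    rngs = config.rngs()
    genotypes, truth = simulate_genotypes(config, rngs["genotypes"])
    metadata = simulate_environment(config, genotypes.sample_ids, rngs["environment"])
    features, truth = simulate_metabolome(config, genotypes, metadata, truth,
                                          rngs["metabolome"])
    f_est = inbreeding_f(genotypes)["F"]
    health = simulate_health(config, truth, metadata, f_est, rngs["health"])
    metadata = metadata.join(f_est.rename("F")).join(health)
    return SyntheticCohort(config, genotypes, features, metadata, truth)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort in the same text formats the real-data path reads."""
    from pathlib import Path

    from .lcms_features import write_feature_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "feature_table.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_feature_table(cohort.features, paths["features"])
    cohort.genotypes.to_tsv(paths["genotypes"])
    cohort.metadata.to_csv(paths["metadata"], sep="\t")
    truth = cohort.truth
    payload = {
        "pathways": truth.pathways,
        "snp_effects": [list(e) for e in truth.snp_effects],
        "biomarkers": truth.biomarkers,
        "disease_model": asdict(truth.disease_model),
        "metabolite_of_feature": truth.metabolite_of_feature,
        "focal_scaling": truth.focal_scaling,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
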