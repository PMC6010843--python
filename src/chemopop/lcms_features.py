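"""Aligned LC-MS peak-table processing.

Reads the tab-separated export dialect of an XCMS-style alignment (one row
per feature with m/z and retention time, one intensity column per sample),
screens for multivariate outlier samples with a PCA distance-to-model
(DModX) test, collapses redundant peaks (isotopes, adducts, in-source
fragments of one compound) into metabolite groups by retention-time
proximity and intensity correlation, annotates representatives by exact
mass under a deprotonated-ion assumption, and log-transforms intensities.

Intensity zeros are treated as "not detected" (below the detection limit),
not missing at random; this convention feeds the downstream richness index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "MetaboliteTable",
    "read_feature_table",
    "write_feature_table",
    "dmodx_outliers",
    "group_features",
    "annotate_by_mass",
    "log_transform",
]

#: Mass of a proton; the neutral mass of an [M-H]- ion is mz + PROTON_MASS.
PROTON_MASS = 1.007276


@dataclass
class FeatureTable:
    """Aligned peak table: features × samples with per-feature m/z and RT."""

    feature_ids: list
    mz: np.ndarray  # Da/e
    rt: np.ndarray  # seconds
    intensity: np.ndarray  # (n_features, n_samples), nonnegative
    sample_ids: list

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n_f, n_s = len(self.feature_ids), len(self.sample_ids)
        if len(set(self.feature_ids)) != n_f:
            dupes = pd.Series(self.feature_ids).value_counts()
            raise ValueError(
                f"duplicate feature ids: {list(dupes[dupes > 1].index)}"
            )
        if self.intensity.shape != (n_f, n_s):
            raise ValueError("intensity matrix shape inconsistent with id lists")
        if (self.mz <= 0).any():
            raise ValueError("m/z values must be positive")
        if (self.rt < 0).any():
            raise ValueError("retention times must be nonnegative")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be nonnegative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def drop_samples(self, sample_ids) -> "FeatureTable":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s not in drop]
        return FeatureTable(
            self.feature_ids, self.mz, self.rt, self.intensity[:, keep],
            [self.sample_ids[i] for i in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensity, index=self.feature_ids, columns=self.sample_ids)
        df.insert(0, "rt", self.rt)
        df.insert(0, "mz", self.mz)
        return df


@dataclass
class MetaboliteTable:
    """Redundant peaks collapsed into metabolite groups.

    ``abundance`` holds the representative peak's raw intensity per group;
    ``log_abundance`` is populated by :func:`log_transform`.
    """

    group_of: dict  # feature_id -> group_id
    representative: dict  # group_id -> feature_id
    abundance: pd.DataFrame  # group × sample raw intensity of representative
    log_abundance: pd.DataFrame | None = None
    annotation: dict = field(default_factory=dict)  # group_id -> [(name, mass, ppm)]

    @property
    def group_ids(self) -> list:
        return list(self.abundance.index)

    def members(self, group_id) -> list:
        return [f for f, g in self.group_of.items() if g == group_id]

    def write(self, abundance_path, sidecar_path) -> None:
        self.abundance.to_csv(abundance_path, sep="\t")
        with open(sidecar_path, "w") as fh:
            json.dump(
                {"group_of": self.group_of, "representative": self.representative},
                fh, indent=1,
            )


def read_feature_table(path, dialect: str = "xcms") -> FeatureTable:
    """Read an aligned peak table TSV (columns: feature id, mz, rt, samples...).

    Missing intensity cells are read as 0 with a logged count; non-numeric
    intensities and duplicate feature ids are hard errors.
    """
    if dialect != "xcms":
        raise ValueError(f"unknown feature-table dialect: {dialect}")
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    df[first] = df[first].astype(str)
    if df[first].duplicated().any():
        dupes = df[first][df[first].duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise ValueError(f"feature table missing required column '{col}'")
    sample_cols = [c for c in df.columns[1:] if c not in ("mz", "rt")]
    inten = df[sample_cols]
    n_missing = int(inten.isna().sum().sum())
    if n_missing:
        logger.info("read %d missing intensity cells as 0", n_missing)
        inten = inten.fillna(0.0)
    try:
        mat = inten.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in sample_cols:
            bad = pd.to_numeric(inten[col], errors="coerce").isna() & inten[col].notna()
            if bad.any():
                row = df[first][bad].iloc[0]
                raise ValueError(
                    f"non-numeric intensity at feature {row}, sample column {col}"
                ) from None
        raise
    return FeatureTable(df[first].tolist(), df["mz"].to_numpy(), df["rt"].to_numpy(),
                        mat, sample_cols)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def dmodx_outliers(
    table: FeatureTable,
    n_components: int = 3,
    alpha: float = 0.05,
    observed: np.ndarray | None = None,
) -> list:
    """Flag multivariate outlier samples by a PCA distance-to-model test.

    Features are autoscaled (zero mean, unit variance; constant features are
    excluded with a warning), a PCA with ``n_components`` is fit on samples,
    and each sample's normalized orthogonal residual distance

        DModX_i = sqrt(SS_resid_i / (K - A)) / s0

    (K features, A components, s0 the pooled residual standard deviation) is
    compared against the upper-``alpha`` critical value of an F distribution
    on the residual degrees of freedom.  Returns the flagged sample ids.

    ``observed`` (optional feature × sample boolean mask) restricts each
    sample's residual sum to measured cells: below-detection intensities
    that were filled or imputed otherwise enter as multi-sigma residuals
    and dominate the statistic.  With the mask, K becomes the per-sample
    observed count K_i.
    """
    n, a = table.n_samples, n_components
    if not (n > a >= 1):
        raise ValueError("need n_samples > n_components >= 1")
    x = table.intensity.T.astype(float)  # samples × features
    obs = (observed.T.astype(bool) if observed is not None
           else np.ones_like(x, dtype=bool))
    sd = x.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        logger.warning("excluding %d constant features from DModX scaling", const.sum())
        x = x[:, ~const]
        obs = obs[:, ~const]
        sd = sd[~const]
    x = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=a)
    scores = pca.fit_transform(x)
    resid = (x - scores @ pca.components_) * obs
    ss = (resid**2).sum(axis=1)
    k_i = obs.sum(axis=1)
    if (k_i <= a).any():
        raise ValueError("a sample has no more observed features than components")
    # pooled residual variance; the model consumes A components and the mean
    df_i = k_i - a
    df_total = (n - a - 1) * df_i.sum() / n
    s0_sq = ss.sum() / ((n - a - 1) / n * df_i.sum())
    dmodx_sq = ss / df_i / s0_sq
    crit = stats.f.ppf(1 - alpha, df_i, df_total)
    flagged = [table.sample_ids[i] for i in np.where(dmodx_sq > crit)[0]]
    return flagged


def group_features(
    table: FeatureTable, rt_tol: float = 5.0, cor_min: float = 0.75
) -> MetaboliteTable:
    """Collapse redundant peaks into metabolite groups.

    Two features are linked when their retention times differ by at most
    ``rt_tol`` seconds and the Pearson correlation of their intensities
    across samples is at least ``cor_min``; groups are the connected
    components of that graph.  Each group is represented by the member with
    the largest median intensity across samples (ties: larger mean, then
    lexicographically smallest id).
    """
    if rt_tol < 0:
        raise ValueError("rt_tol must be nonnegative")
    if not (-1 <= cor_min <= 1):
        raise ValueError("cor_min must lie in [-1, 1]")
    if table.n_samples < 2:
        raise ValueError("feature grouping needs >= 2 samples for correlations")

    order = np.argsort(table.rt, kind="mergesort")
    rt_sorted = table.rt[order]
    x = table.intensity.astype(float)
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    norms = np.sqrt((xc**2).sum(axis=1))

    rows, cols = [], []
    n = table.n_features
    for a_pos in range(n):
        i = order[a_pos]
        b_pos = a_pos + 1
        while b_pos < n and rt_sorted[b_pos] - rt_sorted[a_pos] <= rt_tol:
            j = order[b_pos]
            denom = norms[i] * norms[j]
            corr = float(xc[i] @ xc[j] / denom) if denom > 0 else 0.0
            if corr >= cor_min:
                rows.append(i)
                cols.append(j)
            b_pos += 1
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)

    med = np.median(x, axis=1)
    mean = x.mean(axis=1)
    group_of, representative = {}, {}
    rep_rows, group_ids = [], []
    for comp in range(n_comp):
        members = np.where(labels == comp)[0]
        # representative: max median, then max mean, then smallest id
        best = min(
            members,
            key=lambda m: (-med[m], -mean[m], str(table.feature_ids[m])),
        )
        gid = f"G{str(table.feature_ids[best])}"
        for m in members:
            group_of[str(table.feature_ids[m])] = gid
        representative[gid] = str(table.feature_ids[best])
        rep_rows.append(x[best])
        group_ids.append(gid)
    abundance = pd.DataFrame(np.vstack(rep_rows), index=group_ids, columns=table.sample_ids)
    return MetaboliteTable(group_of, representative, abundance)


def annotate_by_mass(
    metabolites: MetaboliteTable,
    table: FeatureTable,
    compound_db: pd.DataFrame,
    ppm_max: float = 10.0,
) -> MetaboliteTable:
    """Annotate group representatives by exact neutral mass ([M-H]- assumed).

    ``compound_db`` needs columns ``name`` and ``mass`` (monoisotopic neutral
    mass, Da).  A compound matches when |candidate_mass - mass|/mass * 1e6
    <= ``ppm_max`` (inclusive); matches are sorted by ppm error.  Empty match
    lists are valid.
    """
    if compound_db.empty:
        raise ValueError("compound database is empty")
    mz_of = dict(zip((str(f) for f in table.feature_ids), table.mz))
    db_mass = compound_db["mass"].to_numpy(dtype=float)
    db_name = compound_db["name"].tolist()
    annotation = {}
    for gid, rep in metabolites.representative.items():
        neutral = mz_of[rep] + PROTON_MASS
        ppm = np.abs(neutral - db_mass) / db_mass * 1e6
        # inclusive boundary; the slop absorbs cancellation error in the
        # neutral-mass difference, far below any chemically meaningful ppm
        inside = np.where(ppm <= ppm_max * (1 + 1e-9))[0]
        hits = sorted(
            ((db_name[i], float(db_mass[i]), float(ppm[i])) for i in inside),
            key=lambda t: t[2],
        )
        annotation[gid] = hits
    metabolites.annotation = annotation
    return metabolites


def impute_undetected(metabolites: MetaboliteTable, factor: float = 0.5) -> pd.DataFrame:
    """Natural-log abundances with not-detected zeros imputed.

    Zeros are below-detection events, not measurements; carrying them into
    correlation-based analyses as ln(0+1) = 0 creates ~5-sigma leverage
    points.  The standard remedy is to substitute ``factor`` times the
    metabolite's smallest detected intensity before taking logs.  Rows with
    no detected value at all are dropped.
    """
    x = metabolites.abundance.to_numpy(dtype=float).copy()
    keep = (x > 0).any(axis=1)
    x = x[keep]
    for i in range(x.shape[0]):
        row = x[i]
        row[row == 0] = factor * row[row > 0].min()
    return pd.DataFrame(np.log(x), index=metabolites.abundance.index[keep],
                        columns=metabolites.abundance.columns)


def log_transform(metabolites: MetaboliteTable, offset: float = 1.0) -> pd.DataFrame:
    """Natural-log transform of representative intensities: ln(x + offset)."""
    x = metabolites.abundance.to_numpy()
    if (x < 0).any():
        raise ValueError("negative intensity encountered")
    if (x == 0).any() and offset <= 0:
        raise ValueError("offset must be positive when zero intensities are present")
    logged = pd.DataFrame(
        np.log(x + offset), index=metabolites.abundance.index,
        columns=metabolites.abundance.columns,
    )
    metabolites.log_abundance = logged
    return logged
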