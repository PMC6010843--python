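"""Per-sample chemodiversity indices and their alpha/gamma decomposition.

Community-ecology diversity indices applied to a sample's metabolite
relative-abundance vector: richness ``S``, Shannon entropy ``H`` (nats),
Hill numbers ``D1 = exp(H)`` and ``D2 = 1/sum(p_i^2)``, Pielou evenness
``E = H/ln(S)`` and Berger–Parker dominance ``BP = max(p_i)``.

Indices are computed on raw intensities (relative abundances are
compositional on the raw scale, not the log scale); the log-transformed
matrix is reserved for association and network analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiversityProfile",
    "diversity_profile",
    "diversity_table",
    "alpha_gamma_richness",
    "subset_diversity",
]


@dataclass(frozen=True)
class DiversityProfile:
    """Diversity indices of one sample's metabolite abundance vector.

    ``E`` is undefined (NaN) when fewer than two metabolites are detected.
    A profile with ``S == 0`` (possible only for subset profiles where no
    subset member is detected) carries NaN for every abundance-based index.
    """

    sample_id: str
    S: int
    H: float
    D1: float
    D2: float
    E: float
    BP: float

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "S": self.S,
            "H": self.H,
            "D1": self.D1,
            "D2": self.D2,
            "E": self.E,
            "BP": self.BP,
        }


def _profile_from_vector(abund: np.ndarray, sample_id: str, detection_threshold: float) -> DiversityProfile:
    detected = abund > detection_threshold
    s = int(detected.sum())
    if s == 0:
        return DiversityProfile(sample_id, 0, math.nan, math.nan, math.nan, math.nan, math.nan)
    p = abund[detected].astype(float)
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    d1 = math.exp(h)
    d2 = float(1.0 / (p**2).sum())
    e = h / math.log(s) if s > 1 else math.nan
    bp = float(p.max())
    return DiversityProfile(sample_id, s, h, d1, d2, e, bp)


def diversity_profile(
    abundances,
    detection_threshold: float = 0.0,
    sample_id: str = "",
) -> DiversityProfile:
    """Compute all six indices for a single nonnegative abundance vector.

    Parameters
    ----------
    abundances
        Nonnegative metabolite intensities for one sample.
    detection_threshold
        Intensity strictly above which a metabolite counts as detected.
        The default 0 means any positive aligned peak counts.

    Raises
    ------
    ValueError
        If the vector is negative anywhere or has no detected metabolite.
    """
    abund = np.asarray(abundances, dtype=float)
    if abund.ndim != 1:
        raise ValueError("abundances must be a 1-D vector")
    if (abund < 0).any():
        raise ValueError("abundances must be nonnegative")
    if not (abund > detection_threshold).any():
        raise ValueError("empty metabolome: no abundance above the detection threshold")
    return _profile_from_vector(abund, sample_id, detection_threshold)


def diversity_table(
    abundance: pd.DataFrame, detection_threshold: float = 0.0
) -> pd.DataFrame:
    """Per-sample diversity profiles for a metabolite × sample intensity matrix.

    Returns a DataFrame indexed by sample id with columns S, H, D1, D2, E, BP.
    """
    rows = []
    for sample in abundance.columns:
        prof = diversity_profile(
            abundance[sample].to_numpy(), detection_threshold, sample_id=str(sample)
        )
        rows.append(prof.as_dict())
    return pd.DataFrame(rows).set_index("sample_id")


def alpha_gamma_richness(
    abundance: pd.DataFrame,
    grouping: pd.Series,
    detection_threshold: float = 0.0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Alpha (mean per-sample richness) and gamma (pooled richness) per subpopulation.

    Alpha richness is the average number of detected metabolites per sample
    within the subpopulation; gamma richness is the number of metabolites
    detected in at least one sample of the subpopulation.  A two-sided
    t-interval on alpha is reported when a subpopulation has >= 2 samples.
    """
    grouping = grouping.reindex(abundance.columns)
    if grouping.isna().any():
        missing = list(abundance.columns[grouping.isna()])
        raise ValueError(f"samples without subpopulation assignment: {missing}")
    detected = abundance.to_numpy() > detection_threshold
    out = []
    for subpop, cols in grouping.groupby(grouping).groups.items():
        idx = [abundance.columns.get_loc(c) for c in cols]
        per_sample_s = detected[:, idx].sum(axis=0).astype(float)
        alpha = float(per_sample_s.mean())
        gamma = int(detected[:, idx].any(axis=1).sum())
        n = len(idx)
        if n >= 2 and per_sample_s.std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + ci_level / 2, n - 1) * per_sample_s.std(ddof=1) / math.sqrt(n)
            lo, hi = alpha - half, alpha + half
        elif n >= 2:
            lo = hi = alpha
        else:
            lo = hi = math.nan
        out.append(
            {"subpopulation": subpop, "n_samples": n, "alpha": alpha,
             "alpha_ci_low": lo, "alpha_ci_high": hi, "gamma": gamma}
        )
    return pd.DataFrame(out).set_index("subpopulation")


def subset_diversity(
    abundance: pd.DataFrame,
    subset: list,
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Diversity profiles restricted to a metabolite subset, renormalized within it.

    Used to quantify dominance/evenness inside a candidate biomarker group
    (e.g. a partial-correlation-linked family of glycosides).  Samples where
    no subset member is detected get S = 0 and NaN indices.
    """
    if len(subset) == 0:
        raise ValueError("subset must be nonempty")
    unknown = [m for m in subset if m not in abundance.index]
    if unknown:
        raise KeyError(f"unknown metabolite ids in subset: {unknown}")
    sub = abundance.loc[subset]
    rows = []
    for sample in sub.columns:
        vec = sub[sample].to_numpy(dtype=float)
        if (vec < 0).any():
            raise ValueError("abundances must be nonnegative")
        rows.append(_profile_from_vector(vec, str(sample), detection_threshold).as_dict())
    return pd.DataFrame(rows).set_index("sample_id")
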