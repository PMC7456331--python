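"""Bray-Curtis dissimilarity, PCoA ordination and group similarity summaries.

Dissimilarities are computed on the rarefied counts directly; with equal
column sums this is identical to using relative abundances.  "Similarity"
throughout is 1 - dissimilarity.  PCoA uses Gower double-centering of
-d^2/2 and reports negative eigenvalues without correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .data_model import DesignError, FormatError, OtuTable, SampleDesign


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d_jk = sum|x_j - x_k| / sum(x_j + x_k)."""
    sums = table.sample_sums()
    if np.any(sums == 0):
        empty = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise FormatError(f"Bray-Curtis undefined for zero-sum samples: {empty}")
    d = pdist(table.counts.T.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA axes ordered by descending eigenvalue.

    ``coordinates`` has one row per sample and one column per strictly
    positive eigenvalue; ``eigenvalues`` includes the negative ones (which
    contribute no axis), and ``proportion_explained`` is taken over the
    positive eigenvalue sum only.
    """

    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


_EIG_TOL = 1e-10


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA requires at least 2 samples")
    a = -0.5 * d**2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigval, eigvec = np.linalg.eigh(centered)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = np.abs(eigval).max() if eigval.size else 1.0
    pos = eigval > _EIG_TOL * max(scale, 1.0)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    prop = eigval[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    return OrdinationResult(list(dm.ids), coords, eigval, prop)


@dataclass
class SimilaritySummary:
    label: str
    n_pairs: int
    mean_similarity: float
    sd_similarity: float
    similarities: np.ndarray


def resolve_pairs(
    design: SampleDesign,
    within: dict | None = None,
    group_a: dict | None = None,
    group_b: dict | None = None,
    sample_ids: list[str] | None = None,
) -> list[tuple[str, str]]:
    """Resolve a declarative pairing into explicit sample pairs.

    ``within`` selects one set of samples by factor values and pairs all
    unordered pairs within it; ``group_a``/``group_b`` select two disjoint
    sets and pair every cross combination.  Factor values are matched
    against the design columns (e.g. {"sample_type": "fish", "system":
    "FTS", "day": 8}).
    """

    def _select(spec: dict) -> list[str]:
        df = design.frame if sample_ids is None else design.frame.loc[sample_ids]
        mask = pd.Series(True, index=df.index)
        for col, val in spec.items():
            if col not in df.columns:
                raise DesignError(f"unknown factor {col!r} in pairing spec")
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= df[col].astype(str).isin([str(v) for v in vals])
        return df.index[mask].tolist()

    if within is not None:
        members = _select(within)
        return [(a, b) for i, a in enumerate(members) for b in members[i + 1:]]
    if group_a is None or group_b is None:
        raise DesignError("pairing needs either `within` or both `group_a` and `group_b`")
    sa, sb = _select(group_a), _select(group_b)
    overlap = set(sa) & set(sb)
    if overlap:
        raise DesignError(f"pairing groups overlap: {sorted(overlap)}")
    return [(a, b) for a in sa for b in sb]


def group_similarity_summary(
    dm: DistanceMatrix, pairs: list[tuple[str, str]], label: str = ""
) -> SimilaritySummary:
    """Mean and sd of Bray-Curtis similarity (1 - d) over an explicit pair set."""
    if not pairs:
        raise DesignError(f"empty pair set for comparison {label!r}")
    for a, b in pairs:
        if a == b:
            raise DesignError(f"pair ({a}, {b}) compares a sample with itself")
    sims = np.array([1.0 - dm[a, b] for a, b in pairs])
    return SimilaritySummary(
        label=label,
        n_pairs=len(pairs),
        mean_similarity=float(sims.mean()),
        sd_similarity=float(sims.std(ddof=1)) if len(sims) > 1 else 0.0,
        similarities=sims,
    )


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test; returns (t, Satterthwaite df, two-sided p).

    The degenerate case of zero variance in both samples with equal means
    is reported as t = 0, p = 1 instead of a division error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    # recompute Satterthwaite df explicitly (scipy exposes it only on newer APIs)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
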