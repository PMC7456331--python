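"""Permutational multivariate ANOVA (one- and two-way) and SIMPER.

One-way PERMANOVA partitions the total sum of squared distances

    SS_total = (1/N) * sum_{j<k} d_jk^2
    SS_within = sum_g (1/n_g) * sum_{j<k in g} d_jk^2

and tests pseudo-F = [SS_between/(a-1)] / [SS_within/(N-a)] by permuting
group labels.  When the number of distinct label arrangements is small the
null is enumerated exactly (p = #{F >= F_obs} / total); otherwise a seeded
Monte-Carlo sample is used with the (1 + B) / (1 + n_perm) convention so
that p is never 0.

The two-way crossed analysis uses sequential (Type I) sums of squares via
hat-matrix traces on the Gower-centred matrix, with unrestricted
permutation of the raw observations for every term.

SIMPER decomposes the average between-group Bray-Curtis dissimilarity into
per-taxon contributions: for each between-group sample pair the taxon-i
share is |x_ij - x_ik| / sum_s (x_sj + x_sk), averaged over pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .data_model import DesignError, OtuTable

EXACT_CAP = 10_000  # max label arrangements enumerated exactly
_F_TIE_TOL = 1e-12  # relative tolerance when counting F_perm >= F_obs


@dataclass
class PermanovaResult:
    term: str
    ss_total: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    pseudo_f: float
    n_permutations: int
    p_value: float
    exact: bool = False
    infinite_f: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PERMANOVA[{self.term}] F={self.pseudo_f:.4g} "
            f"df=({self.df_between},{self.df_within}) p={self.p_value:.4g}"
            f"{' (exact)' if self.exact else ''}"
        )


def _encode_labels(labels) -> tuple[np.ndarray, list]:
    labels = pd.Series(list(labels))
    levels = labels.unique().tolist()
    codes = labels.map({l: i for i, l in enumerate(levels)}).to_numpy()
    return codes, levels


def _ss_within_batch(codes: np.ndarray, d2: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """SS_within for a batch of label vectors, shape (B, N) -> (B,)."""
    out = np.zeros(codes.shape[0])
    for g, n_g in enumerate(sizes):
        mask = (codes == g).astype(float)
        out += np.einsum("bi,ij,bj->b", mask, d2, mask) / (2.0 * n_g)
    return out


def _n_arrangements(sizes: np.ndarray) -> int:
    n = int(sizes.sum())
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _enumerate_assignments(sizes: np.ndarray) -> np.ndarray:
    """All distinct assignments of a label multiset to N positions."""
    n = int(sizes.sum())
    results: list[np.ndarray] = []
    base = np.full(n, -1, dtype=np.int64)

    def rec(g: int, free: tuple[int, ...], current: np.ndarray) -> None:
        if g == len(sizes) - 1:
            filled = current.copy()
            filled[list(free)] = g
            results.append(filled)
            return
        for chosen in combinations(free, int(sizes[g])):
            nxt = current.copy()
            nxt[list(chosen)] = g
            rec(g + 1, tuple(i for i in free if i not in set(chosen)), nxt)

    rec(0, tuple(range(n)), base)
    return np.array(results)


def permanova_one_way(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
    exact_cap: int = EXACT_CAP,
    term: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a grouping factor."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    codes, levels = _encode_labels(labels)
    if len(codes) != n:
        raise DesignError(f"{len(codes)} labels for {n} samples")
    if len(levels) < 2:
        raise DesignError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = [levels[g] for g in np.where(sizes < 2)[0]]
        raise DesignError(f"groups of size < 2: {small}")
    a = len(levels)
    d2 = d**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = float(_ss_within_batch(codes[None, :], d2, sizes)[0])
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    infinite = ss_within <= _F_TIE_TOL * max(ss_total, 1.0)
    f_obs = math.inf if infinite else (ss_between / df_b) / (ss_within / df_w)

    def f_from_ssw(ssw: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return ((ss_total - ssw) / df_b) / (ssw / df_w)

    total_arr = _n_arrangements(sizes)
    if total_arr <= exact_cap:
        perms = _enumerate_assignments(sizes)
        f_perm = f_from_ssw(_ss_within_batch(perms, d2, sizes))
        thresh = f_obs - _F_TIE_TOL * abs(f_obs) if np.isfinite(f_obs) else math.inf
        p = float(np.sum(f_perm >= thresh)) / total_arr
        return PermanovaResult(
            term, ss_total, ss_between, ss_within, df_b, df_w,
            float(f_obs), total_arr, p, exact=True, infinite_f=infinite,
        )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    f_perm = f_from_ssw(_ss_within_batch(perms, d2, sizes))
    thresh = f_obs - _F_TIE_TOL * abs(f_obs) if np.isfinite(f_obs) else math.inf
    hits = int(np.sum(f_perm >= thresh))
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(
        term, ss_total, ss_between, ss_within, df_b, df_w,
        float(f_obs), n_perm, p, exact=False, infinite_f=infinite,
    )


# ---------------------------------------------------------------------------
# two-way crossed design


def _gower(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    return a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()


def _hat(x: np.ndarray) -> np.ndarray:
    # SVD-based projector: dummy codings are deliberately over-parameterised
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    u = u[:, :rank]
    return u @ u.T


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    return np.eye(n_levels)[codes]


def permanova_two_way(
    dm: DistanceMatrix,
    factor_a,
    factor_b,
    n_perm: int = 9999,
    seed: int | None = None,
    names: tuple[str, str] = ("A", "B"),
) -> list[PermanovaResult]:
    """Crossed two-factor PERMANOVA; returns results for A, B and A x B."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    ca, la = _encode_labels(factor_a)
    cb, lb = _encode_labels(factor_b)
    if len(ca) != n or len(cb) != n:
        raise DesignError("factor length does not match distance matrix")
    if len(la) < 2 or len(lb) < 2:
        single = names[0] if len(la) < 2 else names[1]
        raise DesignError(f"factor {single} has a single level")
    cells = pd.crosstab(pd.Series(ca), pd.Series(cb))
    cells = cells.reindex(index=range(len(la)), columns=range(len(lb)), fill_value=0)
    if (cells.to_numpy() == 0).any():
        i, j = np.argwhere(cells.to_numpy() == 0)[0]
        raise DesignError(f"empty design cell ({la[i]}, {lb[j]})")
    g = _gower(d)
    ones = np.ones((n, 1))
    xa, xb = _dummies(ca, len(la)), _dummies(cb, len(lb))
    xab = (xa[:, :, None] * xb[:, None, :]).reshape(n, -1)
    h_a = _hat(np.hstack([ones, xa]))
    h_ab = _hat(np.hstack([ones, xa, xb]))
    h_full = _hat(np.hstack([ones, xab]))
    df_a, df_b_ = len(la) - 1, len(lb) - 1
    df_int = df_a * df_b_
    df_res = n - len(la) * len(lb)
    if df_res < 1:
        raise DesignError("no residual degrees of freedom (need replication per cell)")

    def terms_for(gm: np.ndarray) -> np.ndarray:
        ss_tot = np.trace(gm)
        s_a = np.sum(h_a * gm)
        s_ab = np.sum(h_ab * gm)
        s_full = np.sum(h_full * gm)
        ss = np.array([s_a, s_ab - s_a, s_full - s_ab])
        ss_res = ss_tot - s_full
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / np.array([df_a, df_b_, df_int])) / (ss_res / df_res)
        return np.concatenate([ss, [ss_res, ss_tot], f])

    obs = terms_for(g)
    rng = np.random.default_rng(seed)
    f_obs = obs[5:8]
    hits = np.zeros(3)
    for _ in range(n_perm):
        p = rng.permutation(n)
        f_perm = terms_for(g[np.ix_(p, p)])[5:8]
        hits += f_perm >= f_obs - _F_TIE_TOL * np.abs(f_obs)
    pvals = (1 + hits) / (1 + n_perm)
    out = []
    term_names = [names[0], names[1], f"{names[0]}x{names[1]}"]
    dfs = [df_a, df_b_, df_int]
    for i, (tname, dfi) in enumerate(zip(term_names, dfs)):
        out.append(
            PermanovaResult(
                term=tname,
                ss_total=float(obs[4]),
                ss_between=float(obs[i]),
                ss_within=float(obs[3]),
                df_between=dfi,
                df_within=df_res,
                pseudo_f=float(f_obs[i]),
                n_permutations=n_perm,
                p_value=float(pvals[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# SIMPER


@dataclass
class SimperResult:
    taxon_ids: list[str]
    contributions: np.ndarray  # aligned with taxon_ids, descending
    percent: np.ndarray
    cumulative_percent: np.ndarray
    overall_dissimilarity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                "contribution": self.contributions,
                "percent": self.percent,
                "cumulative_percent": self.cumulative_percent,
            }
        ).set_index("taxon_id")


def simper(table: OtuTable, labels) -> SimperResult:
    """Per-taxon contributions to mean between-group Bray-Curtis dissimilarity."""
    codes, levels = _encode_labels(labels)
    if len(codes) != table.n_samples:
        raise DesignError(f"{len(codes)} labels for {table.n_samples} samples")
    if len(levels) != 2:
        raise DesignError(
            f"SIMPER requires exactly 2 groups, got {len(levels)}: {levels}"
        )
    x = table.counts.astype(float)
    ja = np.where(codes == 0)[0]
    jb = np.where(codes == 1)[0]
    contrib = np.zeros(table.n_taxa)
    n_pairs = len(ja) * len(jb)
    for j in ja:
        diff = np.abs(x[:, [j]] - x[:, jb])  # taxa x |B|
        denom = (x[:, [j]] + x[:, jb]).sum(axis=0)  # per-pair total
        contrib += (diff / denom).sum(axis=1)
    contrib /= n_pairs
    overall = float(contrib.sum())
    order = np.argsort(contrib)[::-1]
    contrib = contrib[order]
    pct = 100.0 * contrib / overall if overall > 0 else np.zeros_like(contrib)
    return SimperResult(
        taxon_ids=[table.taxon_ids[i] for i in order],
        contributions=contrib,
        percent=pct,
        cumulative_percent=np.cumsum(pct),
        overall_dissimilarity=overall,
    )
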