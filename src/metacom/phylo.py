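"""Phylogenetic community structure and turnover null models.

This module implements the phylogenetic side of community-assembly
inference:

* MNTD, the mean nearest taxon distance, and its standardised effect size
  against a taxa-label-shuffling null.  The nearest taxon index is
  NTI = -z, and NTI > 2 indicates phylogenetic clustering beyond chance,
  the signature of environmental selection.
* betaMNTD, the between-community analogue (mean distance of each taxon to
  its closest relative in the other community), and its z-score beta-NTI.
  Pairwise comparisons are classified into assembly processes with the
  conventional thresholds: beta-NTI < -2 -> homogeneous selection,
  beta-NTI > 2 -> heterogeneous selection, |beta-NTI| <= 2 -> stochastic
  assembly (drift, dispersal).

The null model shuffles taxon labels on the patristic distance matrix
(equivalently: permutes tip identities across the whole taxon pool) and
recomputes the statistic; moments are estimated by Monte Carlo or, for
small pools, by exhaustive enumeration of all label permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import dendropy
import numpy as np
import pandas as pd

from .data_model import DesignError, OtuTable

HOMOGENEOUS = "homogeneous_selection"
HETEROGENEOUS = "heterogeneous_selection"
STOCHASTIC = "stochastic"
PROCESS_LABELS = (HOMOGENEOUS, HETEROGENEOUS, STOCHASTIC)

#: |z| beyond which a pairwise comparison is attributed to selection
SELECTION_THRESHOLD = 2.0

ENUM_CAP = 5040  # 7! — largest pool enumerated exhaustively


class PhyloError(ValueError):
    """Raised for invalid phylogenetic inputs (negative lengths, missing tips)."""


@dataclass
class PhyloDistances:
    """Patristic (path-length) distance matrix over the taxa of a tree."""

    taxon_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxon_ids), len(self.taxon_ids)):
            raise PhyloError("matrix shape does not match taxon ids")
        if np.any(m < 0):
            raise PhyloError("negative patristic distances")
        if not np.allclose(m, m.T, atol=1e-12):
            raise PhyloError("matrix is not symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise PhyloError("diagonal must be zero")
        self.matrix = m

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def index_of(self, taxa) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in lookup]
        if missing:
            raise PhyloError(f"taxa absent from distance matrix: {missing[:5]}")
        return np.array([lookup[t] for t in taxa], dtype=np.intp)

    def subset(self, taxa) -> "PhyloDistances":
        """Restrict the matrix (and hence the null-model taxon pool) to ``taxa``."""
        idx = self.index_of(taxa)
        return PhyloDistances(list(taxa), self.matrix[np.ix_(idx, idx)])


def patristic_distances(tree: dendropy.Tree, clamp_negative: bool = False) -> PhyloDistances:
    """Pairwise path-length distances between all tips of a tree.

    Neighbour-joining trees can carry small negative branch lengths; these
    are rejected unless ``clamp_negative`` zeroes them (with adjustment of
    the distances implied).
    """
    neg = [
        e for e in tree.preorder_edge_iter()
        if e.length is not None and e.length < 0
    ]
    if neg:
        if not clamp_negative:
            raise PhyloError(
                f"{len(neg)} negative branch lengths; pass clamp_negative=True to zero them"
            )
        for e in neg:
            e.length = 0.0
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return PhyloDistances(ids, m)


# ---------------------------------------------------------------------------
# MNTD / NTI


def _mntd_from_indices(
    d: np.ndarray, idx: np.ndarray, weights: np.ndarray | None
) -> float:
    """MNTD of the community occupying matrix positions ``idx``.

    ``weights`` (relative abundances, summing to 1) switch on the
    abundance-weighted variant; None means the unweighted mean.
    """
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    mins = sub.min(axis=1)
    if weights is None:
        return float(mins.mean())
    return float(np.dot(weights, mins))


def mntd(community, pd_: PhyloDistances, abundance_weighted: bool = False) -> float:
    """Mean nearest taxon distance of one community.

    ``community`` is either a sequence of taxon ids (unweighted) or a
    mapping taxon id -> abundance.  Singleton communities have no nearest
    neighbour and raise.
    """
    if isinstance(community, dict):
        taxa = [t for t, v in community.items() if v > 0]
        abund = np.array([community[t] for t in taxa], dtype=float)
    else:
        taxa = list(community)
        abund = np.ones(len(taxa))
    if len(taxa) < 2:
        raise PhyloError("MNTD undefined for a community of < 2 taxa")
    idx = pd_.index_of(taxa)
    weights = abund / abund.sum() if abundance_weighted else None
    return _mntd_from_indices(pd_.matrix, idx, weights)


@dataclass
class SesResult:
    sample_id: str
    observed_mntd: float
    null_mean: float
    null_sd: float
    z: float | None
    nti: float | None
    n_null_runs: int
    degenerate: bool


def _null_permutations(
    pool_size: int, n_runs: int, seed, enum_cap: int
) -> tuple[np.ndarray, bool]:
    """Label permutations of the pool: exhaustive if small, else Monte Carlo."""
    if math.factorial(pool_size) <= enum_cap:
        perms = np.array(list(iter_permutations(range(pool_size))), dtype=np.intp)
        return perms, True
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(pool_size) for _ in range(n_runs)], dtype=np.intp)
    return perms, False


def ses_mntd(
    table: OtuTable,
    pd_: PhyloDistances,
    n_runs: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = False,
    enum_cap: int = ENUM_CAP,
) -> list[SesResult]:
    """Standardised effect size of MNTD per sample (taxa-labels null).

    For each sample the observed MNTD is compared with its distribution
    under random relabelling of the taxon pool (all taxa of ``pd_``);
    z = (obs - null mean) / null sd and NTI = -z.  Null sd of zero (e.g. a
    community spanning the whole pool) is flagged degenerate.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    pool_idx = pd_.index_of(table.taxon_ids)
    perms, exact = _null_permutations(pd_.n_taxa, n_runs, seed, enum_cap)
    results = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        present = np.where(col > 0)[0]
        if len(present) < 2:
            results.append(
                SesResult(sid, math.nan, math.nan, math.nan, None, None, 0, True)
            )
            continue
        idx = pool_idx[present]
        weights = None
        if abundance_weighted:
            weights = col[present] / col[present].sum()
        obs = _mntd_from_indices(pd_.matrix, idx, weights)
        nulls = np.array(
            [_mntd_from_indices(pd_.matrix, p[idx], weights) for p in perms]
        )
        mu, sd = float(nulls.mean()), float(nulls.std(ddof=1))
        if sd <= 1e-12 * max(abs(mu), 1.0):
            results.append(SesResult(sid, obs, mu, sd, None, None, len(perms), True))
        else:
            z = (obs - mu) / sd
            results.append(
                SesResult(sid, obs, mu, sd, z, -z, len(perms), False)
            )
    return results


def ses_mntd_frame(results: list[SesResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "mntd_obs": r.observed_mntd,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "NTI": r.nti,
                "n_null_runs": r.n_null_runs,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# betaMNTD / beta-NTI


def _beta_mntd_from_indices(
    d: np.ndarray,
    idx_j: np.ndarray,
    idx_k: np.ndarray,
    w_j: np.ndarray | None,
    w_k: np.ndarray | None,
) -> float:
    sub = d[np.ix_(idx_j, idx_k)]
    min_j = sub.min(axis=1)  # each taxon in j to its nearest in k
    min_k = sub.min(axis=0)
    if w_j is None:
        return 0.5 * (float(min_j.mean()) + float(min_k.mean()))
    return 0.5 * (float(np.dot(w_j, min_j)) + float(np.dot(w_k, min_k)))


def beta_mntd(
    sample_j,
    sample_k,
    pd_: PhyloDistances,
    abundance_weighted: bool = True,
) -> float:
    """Between-community mean nearest taxon distance.

    ``sample_j`` / ``sample_k`` are abundance vectors aligned with
    ``pd_.taxon_ids``.  A taxon shared by both communities contributes a
    nearest-neighbour distance of zero.
    """
    xj = np.asarray(sample_j, dtype=float)
    xk = np.asarray(sample_k, dtype=float)
    if xj.shape != (pd_.n_taxa,) or xk.shape != (pd_.n_taxa,):
        raise PhyloError("abundance vectors must align with the distance matrix taxa")
    idx_j, idx_k = np.where(xj > 0)[0], np.where(xk > 0)[0]
    if len(idx_j) == 0 or len(idx_k) == 0:
        raise PhyloError("betaMNTD undefined for an empty community")
    w_j = w_k = None
    if abundance_weighted:
        w_j = xj[idx_j] / xj[idx_j].sum()
        w_k = xk[idx_k] / xk[idx_k].sum()
    return _beta_mntd_from_indices(pd_.matrix, idx_j, idx_k, w_j, w_k)


def classify(z: float) -> str:
    """Map a beta-NTI value to its assembly-process label.

    The selection classes use strict inequalities, so |z| exactly at the
    threshold is classified stochastic.
    """
    if z < -SELECTION_THRESHOLD:
        return HOMOGENEOUS
    if z > SELECTION_THRESHOLD:
        return HETEROGENEOUS
    return STOCHASTIC


@dataclass
class BetaNtiSet:
    group: str
    pairs: list[tuple[str, str]]
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    beta_nti: np.ndarray  # NaN where degenerate
    labels: list[str | None]  # None where degenerate
    n_degenerate: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def fractions(self) -> dict[str, float]:
        valid = [l for l in self.labels if l is not None]
        if not valid:
            raise DesignError(f"all pairs degenerate in group {self.group!r}")
        return {p: valid.count(p) / len(valid) for p in PROCESS_LABELS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "sample_a": [a for a, _ in self.pairs],
                "sample_b": [b for _, b in self.pairs],
                "beta_mntd_obs": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "beta_NTI": self.beta_nti,
                "process": [l if l is not None else "degenerate" for l in self.labels],
            }
        )


def beta_nti(
    table: OtuTable,
    pd_: PhyloDistances,
    groups: dict[str, list[str]],
    n_runs: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = True,
    enum_cap: int = ENUM_CAP,
    pool: str = "table",
) -> list[BetaNtiSet]:
    """beta-NTI for every within-group sample pair, per group.

    ``groups`` maps a group label (conventionally system x day) to its
    member sample ids; every unordered pair within a group is evaluated
    against the taxa-label-shuffling null (one label permutation per null
    run, applied to all pairs).  ``pool`` chooses the null taxon pool:
    ``"table"`` shuffles labels across every taxon of ``pd_`` (the whole
    analysed table), ``"group"`` restricts the pool to taxa observed in
    the group's own samples.  Deterministic given ``seed``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if pool not in ("table", "group"):
        raise ValueError("pool must be 'table' or 'group'")
    col_of = {s: j for j, s in enumerate(table.sample_ids)}
    out = []
    ss = np.random.SeedSequence(seed)
    for (gname, members), child in zip(sorted(groups.items()), ss.spawn(len(groups))):
        if len(members) < 2:
            raise DesignError(f"group {gname!r} has fewer than 2 samples")
        missing = [m for m in members if m not in col_of]
        if missing:
            raise DesignError(f"group {gname!r} samples absent from table: {missing}")
        if pool == "group":
            present = table.counts[:, [col_of[s] for s in members]].sum(axis=1) > 0
            gtaxa = [t for t, p in zip(table.taxon_ids, present) if p]
        else:
            gtaxa = list(table.taxon_ids)
        gpd = pd_.subset(gtaxa)
        pool_idx = gpd.index_of(gtaxa)
        taxon_row = {t: r for t, r in zip(gtaxa, range(len(gtaxa)))}
        # per-sample present indices (positions in gpd) and weights
        comm = []
        for s in members:
            col = table.counts[:, col_of[s]]
            pres = np.where(col > 0)[0]
            if len(pres) == 0:
                raise DesignError(f"sample {s!r} is empty")
            rows = np.array(
                [taxon_row[table.taxon_ids[i]] for i in pres], dtype=np.intp
            )
            w = col[pres] / col[pres].sum() if abundance_weighted else None
            comm.append((pool_idx[rows], w))
        pairs = [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        pair_idx = [
            (i, j) for i in range(len(members)) for j in range(i + 1, len(members))
        ]
        obs = np.array(
            [
                _beta_mntd_from_indices(
                    gpd.matrix, comm[i][0], comm[j][0], comm[i][1], comm[j][1]
                )
                for i, j in pair_idx
            ]
        )
        perms, _ = _null_permutations(
            gpd.n_taxa, n_runs, child.generate_state(1)[0], enum_cap
        )
        nulls = np.empty((len(perms), len(pairs)))
        for r, p in enumerate(perms):
            for q, (i, j) in enumerate(pair_idx):
                nulls[r, q] = _beta_mntd_from_indices(
                    gpd.matrix, p[comm[i][0]], p[comm[j][0]], comm[i][1], comm[j][1]
                )
        mu = nulls.mean(axis=0)
        sd = nulls.std(axis=0, ddof=1)
        degenerate = sd <= 1e-12 * np.maximum(np.abs(mu), 1.0)
        z = np.full(len(pairs), np.nan)
        z[~degenerate] = (obs[~degenerate] - mu[~degenerate]) / sd[~degenerate]
        labels: list[str | None] = [
            None if deg else classify(zi) for zi, deg in zip(z, degenerate)
        ]
        out.append(
            BetaNtiSet(
                group=gname,
                pairs=pairs,
                observed=obs,
                null_mean=mu,
                null_sd=sd,
                beta_nti=z,
                labels=labels,
                n_degenerate=int(degenerate.sum()),
            )
        )
    return out


def process_fractions(sets: list[BetaNtiSet]) -> pd.DataFrame:
    """Per-group fractions of each assembly process plus mean beta-NTI."""
    rows = []
    for s in sets:
        frac = s.fractions()
        rows.append(
            {
                "group": s.group,
                **{p: frac[p] for p in PROCESS_LABELS},
                "mean_beta_NTI": float(np.nanmean(s.beta_nti)),
                "n_pairs": s.n_pairs,
                "n_degenerate": s.n_degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("group")
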