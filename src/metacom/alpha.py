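"""Per-sample alpha diversity: Hill numbers, evenness and Chao1 richness.

The Hill number of order ``a`` is the effective number of taxa

    D_a = exp(H_a),   H_a = (1 / (1 - a)) * ln( sum_i p_i^a )

over taxa with positive relative abundance p_i; the a -> 1 limit is the
exponential of Shannon entropy.  D0 is observed richness, and evenness is
defined as D1 / D0.  Chao1 extrapolates richness from singleton (F1) and
doubleton (F2) counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import OtuTable

_SHANNON_TOL = 1e-9


class DiversityError(ValueError):
    """Raised when diversity is undefined (e.g. an empty sample)."""


def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a vector")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise DiversityError("diversity undefined for an all-zero sample")
    p = x[x > 0] / total
    return p


def hill_number(counts, order: float) -> float:
    """Effective number of taxa D_a at diversity order ``a`` >= 0."""
    if order < 0:
        raise ValueError("order must be >= 0")
    p = _proportions(counts)
    if abs(order - 1.0) < _SHANNON_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** order) ** (1.0 / (1.0 - order)))


def evenness(counts) -> float:
    """D1 / D0, in (0, 1]; 1 for a perfectly even (or single-taxon) sample."""
    return hill_number(counts, 1.0) / hill_number(counts, 0.0)


def chao1(counts) -> float:
    """Chao1 richness estimate from integer counts.

    Classic form S_obs + F1^2 / (2 F2); when there are no doubletons the
    bias-corrected form S_obs + F1 (F1 - 1) / (2 (F2 + 1)) is used instead.
    """
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        if not np.all(np.mod(x, 1) == 0):
            raise ValueError("Chao1 requires integer counts")
        x = x.astype(np.int64)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    s_obs = int(np.sum(x > 0))
    if s_obs == 0:
        raise DiversityError("Chao1 undefined for an all-zero sample")
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


@dataclass
class AlphaResult:
    sample_id: str
    richness_D0: int
    hill: dict[float, float]
    evenness: float
    chao1: float
    F1: int
    F2: int


def alpha_table(table: OtuTable, orders=(0.0, 1.0, 2.0)) -> pd.DataFrame:
    """Per-sample diversity profile as a tidy DataFrame.

    Columns: D<a> for each requested order, evenness (D1/D0), chao1, F1, F2.
    """
    orders = list(orders)
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rec = {"sample_id": sid}
        for a in orders:
            rec[f"D{a:g}"] = hill_number(col, a)
        rec["evenness"] = evenness(col)
        rec["chao1"] = chao1(col)
        rec["F1"] = int(np.sum(col == 1))
        rec["F2"] = int(np.sum(col == 2))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("sample_id")
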