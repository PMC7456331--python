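"""Core data types and I/O for the metacommunity pipeline.

The central object is the :class:`OtuTable`, a taxa x samples matrix of
non-negative integer read counts, as produced by OTU clustering of 16S
amplicon reads and equal-depth subsampling.  Sample metadata live in a
:class:`SampleDesign` (sample type, rearing system, replicate tank, day
post hatching).  Phylogenies are plain :class:`dendropy.Tree` objects read
from Newick.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("metacom")

SAMPLE_TYPES = ("fish", "tank_water", "incoming_water", "feed")
SYSTEMS = ("FTS", "MMS", "RAS")

#: default subsampling depth: reads per sample after rarefaction
DEFAULT_DEPTH = 12100


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class DesignError(ValueError):
    """Raised when a sample grouping or factor specification is invalid."""


@dataclass
class OtuTable:
    """Taxa x samples table of non-negative integer counts.

    Parameters
    ----------
    taxon_ids : list of str
        Unique taxon (OTU) identifiers, one per row of ``counts``.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``counts``.
    counts : ndarray of int, shape (n_taxa, n_samples)
    taxonomy : dict, optional
        Map taxon_id -> lineage string (semicolon-delimited ranks).
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise FormatError(f"duplicate {kind} ids: {dupes}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        """Subset (and reorder) columns; taxonomy is carried over."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            list(self.taxon_ids), list(sample_ids), self.counts[:, idx], self.taxonomy
        )

    def drop_empty_taxa(self) -> "OtuTable":
        """Remove taxa whose total count is zero (keeps richness meaningful)."""
        keep = self.counts.sum(axis=1) > 0
        taxa = [t for t, k in zip(self.taxon_ids, keep) if k]
        return OtuTable(taxa, list(self.sample_ids), self.counts[keep], self.taxonomy)

    def relative_abundances(self) -> np.ndarray:
        sums = self.sample_sums().astype(float)
        if np.any(sums == 0):
            empty = [s for s, t in zip(self.sample_ids, sums) if t == 0]
            raise FormatError(f"zero-sum samples: {empty}")
        return self.counts / sums


@dataclass
class SampleDesign:
    """Per-sample experimental factors.

    Columns: ``sample_id`` (index), ``sample_type`` (fish / tank_water /
    incoming_water / feed), ``system`` (FTS / MMS / RAS water-treatment
    regime), ``tank`` (replicate rearing tank), ``day`` (days post hatching).
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "sample_type", "system", "tank", "day")

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise FormatError("design is missing the sample_id column")
        if missing := [c for c in self.REQUIRED[1:] if c not in df.columns]:
            raise FormatError(f"design is missing columns: {missing}")
        if df.index.duplicated().any():
            raise FormatError(
                f"duplicate sample ids in design: "
                f"{df.index[df.index.duplicated()].unique().tolist()}"
            )
        bad_type = sorted(set(df["sample_type"]) - set(SAMPLE_TYPES))
        if bad_type:
            raise FormatError(
                f"unknown sample_type values {bad_type}; expected one of {SAMPLE_TYPES}"
            )
        bad_sys = sorted(set(df["system"]) - set(SYSTEMS))
        if bad_sys:
            raise FormatError(
                f"unknown system values {bad_sys}; expected one of {SYSTEMS}"
            )
        df = df.copy()
        df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
        object.__setattr__(self, "frame", df)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def subset(self, sample_ids: list[str]) -> "SampleDesign":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise DesignError(f"samples absent from design: {missing}")
        return SampleDesign(self.frame.loc[sample_ids].copy())

    def labels(self, factor: str | list[str], sample_ids: list[str] | None = None) -> pd.Series:
        """Group label per sample for one factor or a factor combination."""
        factors = [factor] if isinstance(factor, str) else list(factor)
        for f in factors:
            if f not in self.frame.columns:
                raise DesignError(f"unknown factor {f!r}; design has {list(self.frame.columns)}")
        df = self.frame if sample_ids is None else self.frame.loc[sample_ids]
        if len(factors) == 1:
            return df[factors[0]].astype(str)
        return df[factors].astype(str).agg("|".join, axis=1)

    def groups(self, factor: str | list[str], sample_ids: list[str] | None = None) -> dict[str, list[str]]:
        lab = self.labels(factor, sample_ids)
        return {str(k): list(v.index) for k, v in lab.groupby(lab)}


# ---------------------------------------------------------------------------
# readers / writers


def read_otu_table(path, taxonomy_col: str = "taxonomy") -> OtuTable:
    """Read a tab-separated OTU table (rows = taxa, first column = taxon id).

    A trailing column named ``taxonomy`` (if present) is split off into the
    table's taxonomy map rather than treated as a sample.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample header {dupes}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    taxonomy = None
    if taxonomy_col in df.columns:
        taxonomy = df[taxonomy_col].to_dict()
        df = df.drop(columns=[taxonomy_col])
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: ragged or missing cell in row {row!r}")
    try:
        counts = df.astype(np.int64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer cell ({exc})") from exc
    if (counts < 0).any():
        bad = df.index[(counts < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative count in row {bad!r}")
    return OtuTable(df.index.tolist(), df.columns.tolist(), counts, taxonomy)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.to_dataframe()
    if table.taxonomy is not None:
        df = df.assign(taxonomy=[table.taxonomy.get(t, "") for t in table.taxon_ids])
    df.to_csv(path, sep="\t", index_label="#OTU_ID")


def read_design(path) -> SampleDesign:
    """Read the tab-separated sample metadata table."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    design.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path, allow_missing_lengths: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Edges without a length are an error unless ``allow_missing_lengths``
    (then they default to zero with a warning).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"{path}: unparseable Newick ({exc})") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate tip labels")
    n_missing = sum(
        1
        for e in tree.preorder_edge_iter()
        if e.length is None and e.head_node is not tree.seed_node
    )
    if n_missing:
        if not allow_missing_lengths:
            raise FormatError(
                f"{path}: {n_missing} edges lack branch lengths "
                "(pass allow_missing_lengths=True to default them to 0)"
            )
        warnings.warn(f"{n_missing} missing branch lengths defaulted to 0")
        for e in tree.preorder_edge_iter():
            if e.length is None:
                e.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# filtering and rarefaction


def filter_taxa_by_lineage(table: OtuTable, blacklist: list[str]) -> OtuTable:
    """Drop taxa whose lineage string contains any blacklist term.

    Matching is a case-insensitive substring test on the lineage, which is
    how whole high-level groups (e.g. Chloroplast, Archaea) are removed.
    Taxa left with zero total count are pruned afterwards.
    """
    if not blacklist:
        return table
    taxonomy = table.taxonomy or {}
    terms = [b.lower() for b in blacklist]
    removed = [
        t for t in table.taxon_ids
        if any(term in taxonomy.get(t, "").lower() for term in terms)
    ]
    if not removed:
        logger.info("lineage blacklist %s matched no taxa", blacklist)
        return table
    logger.info("removing %d blacklisted taxa: %s", len(removed), removed)
    keep = [t not in set(removed) for t in table.taxon_ids]
    out = OtuTable(
        [t for t, k in zip(table.taxon_ids, keep) if k],
        list(table.sample_ids),
        table.counts[np.asarray(keep)],
        {t: l for t, l in taxonomy.items() if t not in set(removed)} or None,
    )
    if out.n_taxa == 0:
        warnings.warn("lineage blacklist removed every taxon")
    return out.drop_empty_taxa() if out.n_taxa else out


def rarefy(table: OtuTable, depth: int = DEFAULT_DEPTH, seed: int | None = None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained column is a multivariate-hypergeometric draw of ``depth``
    reads from its counts; samples with fewer than ``depth`` reads are
    dropped with a warning.  Deterministic given ``seed``.  Taxa with zero
    total count afterwards are pruned.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    if not keep.any():
        raise FormatError(f"no sample reaches depth {depth} (max sum {sums.max()})")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} samples below depth {depth}: {dropped}")
    cols = []
    kept_ids = []
    for j, (sid, ok) in enumerate(zip(table.sample_ids, keep)):
        if not ok:
            continue
        col = table.counts[:, j]
        if col.sum() == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
        kept_ids.append(sid)
    out = OtuTable(
        list(table.taxon_ids), kept_ids, np.column_stack(cols), table.taxonomy
    )
    return out.drop_empty_taxa()
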