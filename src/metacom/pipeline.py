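"""Config-driven orchestration of the full analysis.

A single YAML/dict config names the inputs, the rarefaction depth and
blacklist, which groupings to test (PERMANOVA/SIMPER), the null-model
settings for NTI/beta-NTI, and the overlap/abundance screens.  Every
random stage takes an explicit seed, so a rerun with the same config and
inputs is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha, beta, permanova as ctests, phylo, screens
from .data_model import (
    DesignError,
    OtuTable,
    SampleDesign,
    filter_taxa_by_lineage,
    rarefy,
    read_design,
    read_otu_table,
    read_tree,
    write_otu_table,
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    otu_table: str
    design: str
    tree: str
    output_dir: str
    depth: int = 12100
    rarefy_seed: int = 1
    blacklist: list[str] = field(default_factory=list)
    groupings: list[dict] = field(default_factory=list)
    null_model: dict = field(default_factory=dict)
    overlap: dict | None = None
    screen: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.pop("inputs", {})
        return cls(
            otu_table=inputs.get("otu_table", raw.pop("otu_table", None)),
            design=inputs.get("design", raw.pop("design", None)),
            tree=inputs.get("tree", raw.pop("tree", None)),
            **raw,
        )

    def validate(self) -> None:
        if self.depth < 1:
            raise PipelineError("config", "depth must be >= 1")
        for key in ("otu_table", "design", "tree", "output_dir"):
            if not getattr(self, key):
                raise PipelineError("config", f"missing required path {key!r}")


def _subset_ids(design: SampleDesign, table: OtuTable, spec: dict | None) -> list[str]:
    df = design.frame.loc[[s for s in table.sample_ids if s in design.frame.index]]
    if spec:
        for col, val in spec.items():
            if col not in df.columns:
                raise DesignError(f"undefined factor {col!r} in subset")
            vals = val if isinstance(val, (list, tuple)) else [val]
            df = df[df[col].astype(str).isin([str(v) for v in vals])]
    return df.index.tolist()


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute every configured stage; returns the JSON-ready summary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: dict = {"warnings": []}

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"{stage}: {msg}")

    def stage(name):
        def runner(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return runner

    # --- load + preprocess -------------------------------------------------
    run = stage("load")
    table = run(read_otu_table, config.otu_table)
    design = run(read_design, config.design)
    tree = run(read_tree, config.tree)
    log("load", f"table {table.n_taxa} taxa x {table.n_samples} samples")
    missing = [s for s in table.sample_ids if s not in design.frame.index]
    if missing:
        raise PipelineError("load", f"samples missing from design: {missing[:5]}")

    # validate every referenced factor against the design before any stage runs
    known = set(design.frame.columns)
    referenced: list[str] = []
    for spec in config.groupings:
        fac = spec.get("factor")
        referenced += fac if isinstance(fac, list) else [fac] if fac else []
        if spec.get("factor2"):
            referenced.append(spec["factor2"])
        referenced += list((spec.get("subset") or {}).keys())
    nm_cfg = config.null_model or {}
    referenced += list(nm_cfg.get("group_factors", []))
    for sub in ("nti_subset", "bnti_subset"):
        referenced += list((nm_cfg.get(sub) or {}).keys())
    if config.overlap:
        referenced.append(config.overlap.get("factor", "sample_type"))
    bad = sorted({f for f in referenced if f and f not in known})
    if bad:
        raise PipelineError("config", f"undefined factors {bad}; design has {sorted(known)}")

    run = stage("filter")
    if config.blacklist:
        table = run(filter_taxa_by_lineage, table, config.blacklist)
        log("filter", f"{table.n_taxa} taxa after lineage blacklist")

    run = stage("rarefy")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = run(rarefy, table, config.depth, config.rarefy_seed)
    for w in caught:
        summary["warnings"].append(str(w.message))
    log("rarefy", f"depth {config.depth}, {table.n_samples} samples retained")
    write_otu_table(table, out / "rarefied_table.tsv")
    summary["n_taxa"] = table.n_taxa
    summary["n_samples"] = table.n_samples

    # --- alpha diversity ---------------------------------------------------
    run = stage("alpha")
    alpha_df = run(alpha.alpha_table, table)
    alpha_df.to_csv(out / "alpha.tsv", sep="\t")
    log("alpha", f"wrote alpha.tsv for {len(alpha_df)} samples")

    # --- beta diversity + ordination --------------------------------------
    run = stage("beta")
    dm = run(beta.bray_curtis, table)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out / "bray_curtis.tsv", sep="\t"
    )
    ord_res = run(beta.pcoa, dm)
    ord_res.coordinates_frame().to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {
            "eigenvalue": ord_res.eigenvalues,
            "proportion": np.concatenate(
                [ord_res.proportion_explained,
                 np.full(len(ord_res.eigenvalues) - len(ord_res.proportion_explained), np.nan)]
            ),
        }
    ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
    log("beta", "wrote bray_curtis.tsv, pcoa_*.tsv")

    # --- PERMANOVA / SIMPER per grouping -----------------------------------
    run = stage("permanova")
    perm_rows = []
    summary["permanova"] = {}
    summary["simper_top"] = {}
    for spec in config.groupings:
        name = spec.get("name") or "+".join(np.atleast_1d(spec.get("factor")))
        ids = _subset_ids(design, table, spec.get("subset"))
        if len(ids) < 4:
            raise PipelineError("permanova", f"grouping {name!r} has too few samples")
        sub_dm = dm.filter(ids)
        n_perm = int(spec.get("permutations", 9999))
        seed = int(spec.get("seed", 1))
        if "factor2" in spec or (isinstance(spec.get("factor"), list) and len(spec["factor"]) == 2):
            fa, fb = (
                (spec["factor"], spec["factor2"])
                if "factor2" in spec
                else tuple(spec["factor"])
            )
            results = run(
                ctests.permanova_two_way,
                sub_dm,
                design.labels(fa, ids),
                design.labels(fb, ids),
                n_perm=n_perm,
                seed=seed,
                names=(fa, fb),
            )
        else:
            labels = design.labels(spec["factor"], ids)
            results = [
                run(ctests.permanova_one_way, sub_dm, labels, n_perm=n_perm, seed=seed,
                    term=str(spec["factor"]))
            ]
        for r in results:
            perm_rows.append(
                {
                    "grouping": name,
                    "term": r.term,
                    "pseudo_F": r.pseudo_f,
                    "df_between": r.df_between,
                    "df_within": r.df_within,
                    "p_value": r.p_value,
                    "n_permutations": r.n_permutations,
                    "exact": r.exact,
                }
            )
            summary["permanova"][f"{name}:{r.term}"] = r.p_value
        if spec.get("simper"):
            labels = design.labels(spec["factor"], ids)
            sub_table = table.select_samples(ids)
            sim = run(ctests.simper, sub_table, labels)
            sim.to_frame().to_csv(out / f"simper_{name}.tsv", sep="\t")
            summary["simper_top"][name] = sim.taxon_ids[:5]
            log("simper", f"wrote simper_{name}.tsv")
    if perm_rows:
        pd.DataFrame(perm_rows).to_csv(out / "permanova.tsv", sep="\t", index=False)
        log("permanova", f"{len(perm_rows)} terms tested")

    # --- phylogenetic null models ------------------------------------------
    nm = dict(config.null_model)
    run = stage("null_model")
    pdist_full = run(phylo.patristic_distances, tree)
    pdist = pdist_full.subset(table.taxon_ids)
    n_runs = int(nm.get("runs", 999))
    nm_seed = int(nm.get("seed", 1))
    weighted = bool(nm.get("weighted", True))
    nti_ids = _subset_ids(design, table, nm.get("nti_subset"))
    nti_res = run(
        phylo.ses_mntd,
        table.select_samples(nti_ids),
        pdist,
        n_runs=n_runs,
        seed=nm_seed,
        abundance_weighted=bool(nm.get("nti_weighted", False)),
    )
    nti_df = phylo.ses_mntd_frame(nti_res)
    nti_df.to_csv(out / "nti.tsv", sep="\t")
    valid_nti = nti_df["NTI"].dropna()
    summary["nti"] = {
        "n": int(len(valid_nti)),
        "mean": float(valid_nti.mean()) if len(valid_nti) else None,
        "frac_clustered": float((valid_nti > 2).mean()) if len(valid_nti) else None,
    }
    log("null_model", f"NTI for {len(nti_df)} samples")

    bnti_ids = _subset_ids(design, table, nm.get("bnti_subset", {"sample_type": "fish"}))
    group_factors = nm.get("group_factors", ["system", "day"])
    groups = design.groups(group_factors, bnti_ids)
    groups = {g: m for g, m in groups.items() if len(m) >= 2}
    if groups:
        sets = run(
            phylo.beta_nti,
            table,
            pdist,
            groups,
            n_runs=n_runs,
            seed=nm_seed,
            abundance_weighted=weighted,
            pool=nm.get("pool", "table"),
        )
        pd.concat([s.to_frame() for s in sets]).to_csv(
            out / "beta_nti_pairs.tsv", sep="\t", index=False
        )
        frac = phylo.process_fractions(sets)
        frac.to_csv(out / "process_fractions.tsv", sep="\t")
        summary["beta_nti_fractions"] = {
            g: {p: float(frac.loc[g, p]) for p in phylo.PROCESS_LABELS}
            for g in frac.index
        }
        log("null_model", f"beta-NTI for {len(sets)} groups")

    # --- screens ------------------------------------------------------------
    if config.overlap:
        run = stage("overlap")
        ov = run(
            screens.otu_overlap,
            table,
            design,
            config.overlap.get("factor", "sample_type"),
            min_prevalence=int(config.overlap.get("min_prevalence", 1)),
        )
        ov.per_level.to_csv(out / "overlap.tsv", sep="\t")
        summary["overlap_pct_unique"] = {
            l: float(ov.per_level.loc[l, "pct_unique"]) for l in ov.levels
        }
        log("overlap", f"factor {ov.factor}, union {ov.union_size()} taxa")
    if config.screen:
        run = stage("screen")
        sc = dict(config.screen)
        hits = run(
            screens.shared_abundant_otus,
            table,
            design,
            sc.get("type_a", "fish"),
            sc.get("type_b", "tank_water"),
            threshold=float(sc.get("threshold", 0.02)),
            statistic=sc.get("statistic", "mean"),
        )
        hits.to_csv(out / "shared_otus.tsv", sep="\t", index=False)
        summary["n_shared_abundant_otus"] = int(hits["taxon_id"].nunique())
        log("screen", f"{len(hits)} qualifying taxon-scope records")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
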