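# metacom

Statistical analysis of microbial metacommunity assembly, built around the
question posed by rearing-system microbiome studies: when bacterial
communities of individual host larvae differ from each other and from their
environment, how much of that difference is due to deterministic selection
and how much to stochastic processes such as drift?

The package implements the full analysis chain such studies use on a
processed (equal-depth) OTU table:

* **Alpha diversity** — Hill numbers `D_a = exp(H_a)` with
  `H_a = (1/(1−a))·ln Σ p_i^a` (richness `D0`, `D1 = exp(Shannon)`,
  `D2` = inverse Simpson), evenness `D1/D0`, and the Chao1 richness
  estimate `S_obs + F1²/(2F2)`.
* **Beta diversity** — Bray–Curtis dissimilarity
  `d_jk = Σ|x_ij − x_ik| / Σ(x_ij + x_ik)`, PCoA ordination (Gower
  double-centering, negative eigenvalues reported), and group similarity
  summaries with Welch t-tests.
* **Permutation tests** — one- and two-way PERMANOVA (pseudo-F on the
  distance-based sums of squares, exact enumeration of label arrangements
  when feasible) and SIMPER decomposition of between-group dissimilarity
  into per-taxon contributions.
* **Phylogenetic null models** — the core inference. MNTD (mean nearest
  taxon distance) and its standardised effect size against a
  taxa-label-shuffling null: `NTI = −(MNTD_obs − mean_null)/sd_null`,
  with NTI > 2 indicating phylogenetic clustering beyond chance, i.e.
  selection. The between-community analogue βMNTD yields β-NTI per sample
  pair, classified as **homogeneous selection** (β-NTI < −2),
  **heterogeneous selection** (β-NTI > 2) or **stochastic** assembly
  (|β-NTI| ≤ 2), with process fractions per group (system × day).
* **Synthetic metacommunities** — a generator with known ground truth
  (Yule tree, clade-structured habitat-preference traits, Gaussian
  environmental filtering, multinomial sampling, serial-resampling drift)
  that emulates the 3-system × 3-tank × multi-day × multi-sample-type
  design of a larval rearing experiment at 12 100 reads per sample.

## Worked example

```python
import metacom as mc

# simulate a metacommunity assembled under homogeneous selection
sc = mc.SyntheticScenario(regime="homogeneous_selection", days=(8,), seed=7)
data = mc.simulate_metacommunity(sc)

pdist = mc.patristic_distances(data.tree).subset(data.table.taxon_ids)
fish = [s for s in data.table.sample_ids
        if data.design.frame.loc[s, "sample_type"] == "fish"
        and data.design.frame.loc[s, "system"] == "FTS"]

res = mc.beta_nti(data.table, pdist, {"FTS|8": fish},
                  n_runs=199, seed=5, abundance_weighted=False)[0]
print(res.n_pairs, res.fractions())
```

prints

```
36 {'homogeneous_selection': 1.0, 'heterogeneous_selection': 0.0, 'stochastic': 0.0}
```

i.e. all 36 pairwise comparisons among the 9 fish of one system fall below
the β-NTI = −2 threshold: the classifier attributes assembly to homogeneous
selection, which is exactly how this dataset was generated. Under the
`"neutral"` regime the same analysis labels ≥ 90 % of pairs stochastic, and
under `"heterogeneous_selection"` the between-environment pairs exceed
β-NTI = 2.

The numbered scripts under `analysis/` run the whole study-shaped analysis
(simulation → alpha → ordination/similarities → PERMANOVA/SIMPER →
NTI/β-NTI process fractions) and write their tables to `results/`; bulky
intermediates (simulated datasets, distance matrices) go to `scratch/`.
Run them in order:

```sh
python analysis/01_simulate.py
python analysis/02_alpha_diversity.py
python analysis/03_beta_ordination.py
python analysis/04_community_tests.py
python analysis/05_assembly_processes.py
```

A CLI mirrors the library: `metacom simulate | rarefy | alpha | beta |
pcoa | permanova | simper | nti | bnti | overlap | screen | run` (see
`metacom --help`); `metacom run --config config.yaml` executes the full
pipeline from one config file.

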