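# crestflow

Trajectory analysis for branching single-cell differentiation, built around
the biology of the neural crest → Schwann-cell-precursor lineage: a
multipotent progenitor population moves through a transcriptionally
uncommitted **"hub"** state near a fate bifurcation before committing to
terminal programs (e.g. glial versus sympathoadrenal). `crestflow` provides
the complete desk-scale toolkit for dissecting such a process:

- **QC & preprocessing** for deep plate-based (SmartSeq2-style) count
  matrices: cell filters on transcript totals, detected genes and ERCC
  spike-in fraction; library-size normalization with log10 transform;
  overdispersed-gene ranking from a mean-variance trend; kNN smoothing over
  the cell graph as a light imputation step.
- **Principal-tree pseudotime** (SimplePPT): an acyclic principal graph is
  fitted to a low-dimensional embedding by alternating soft assignment
  (`R_ij ∝ exp(-‖x_i − c_j‖²/σ)`), minimum-spanning-tree topology, and an
  elastic least-squares node update. Pseudotime is geodesic distance from a
  root, projected to cells through R (or the best node); milestones (tips and
  forks) define subtrees and branch paths; probabilistic cell-to-node
  mappings quantify assignment uncertainty.
- **Association testing**: per-segment cubic-spline regression
  `exp_i ~ t_i` against the intercept-only model by F-test, BH-corrected,
  with an amplitude filter (`A_cut`) on the fitted trend.
- **Bifurcation analysis**: the interaction model
  `g ~ s(pseudotime) + s(pseudotime):Branch + Branch`, upregulation tests
  along progenitor→terminal paths, and activation timing via the binned
  relative expression rate `r(b) = (f(b+1) − f(b−1)) / (max f − min f)`,
  classifying branch-specific genes as *early* (activating before the fork)
  or *late*.
- **Module-correlation dynamics**: local (windowed) gene–gene Pearson
  correlations tracking how two competing fate modules first co-activate and
  then mutually repress around the fork.
- **Regulon dynamics**: TF-expression weighting of AUC-style regulon
  activities (weight = log10 expression clamped to [0, 1]), spline trend
  fitting, and cosine-kNN Leiden clustering of z-scored trends into
  **metaregulons** (each metaregulon's trend is the mean of its members').
- **Annotation & hub detection**: marker-based cell-type scoring with a
  multi-type discard rule, and the hub call: every Leiden community with
  ≥ 80 % type-unassigned cells is flagged, and hub markers come from a
  Wilcoxon rank-sum test of hub versus rest.
- **Reference mapping**: correlation-kNN projection of external (e.g.
  tumour) profiles onto the reference trajectory with weighted-average
  coordinates, labels and pseudotime.
- **A fully ground-truthed synthetic generator** that produces branching
  embeddings, negative-binomial counts with ERCC spike-ins and planted gene
  modules, and smooth regulon-activity trends — the substrate on which every
  inference above is validated.

## Worked example

```python
import crestflow as cf
from scipy.stats import spearmanr

# branching synthetic dataset: NC trunk forking into glial / sympathoadrenal,
# 600 clean cells plus 30 injected QC-violating cells
emb, truth, counts = cf.default_dataset(n_cells=600, n_low_quality_cells=30, seed=0)

kept, report = cf.filter_cells(counts)
print(f"QC kept {len(kept)} / {counts.n_cells} cells")

clean = truth.cells.loc[~truth.cells.low_quality, "cell_id"].tolist()
norm = cf.normalize_log(counts.subset_cells(clean))
t_true = truth.cells.set_index("cell_id").loc[clean, "pseudotime"].to_numpy()

tree = cf.fit_principal_tree(emb, n_nodes=30, seed=0)
root = cf.select_root(tree, -t_true)          # score high at the trajectory origin
pt = cf.compute_pseudotime(tree, root)
print(f"pseudotime vs truth: Spearman rho = "
      f"{spearmanr(pt.cell_pseudotime, t_true).statistic:.3f}")

ms, _ = cf.identify_milestones(tree, pt)
tips = [m.node for m in ms if m.kind == "tip" and m.node != root]
far = sorted(tips, key=lambda n: -pt.node_pseudotime[n])[:2]
path = cf.extract_path(tree, pt, root, far)
print(f"{len(ms)} milestones; fork at pseudotime {path.fork_pseudotime:.2f}; "
      f"{len(path.cell_indices)} cells on the two-branch path")

fork = cf.analyze_fork(norm.to_frame(), path)
assigned = fork[fork.branch.apply(lambda b: isinstance(b, str))]
print(f"fork analysis: {int(fork.candidate.sum())} candidates, "
      f"{len(assigned)} branch-assigned "
      f"({(assigned.timing == 'early').sum()} early, "
      f"{(assigned.timing == 'late').sum()} late)")
```

Output:

```
QC kept 600 / 630 cells
pseudotime vs truth: Spearman rho = 0.993
4 milestones; fork at pseudotime 0.89; 600 cells on the two-branch path
fork analysis: 103 candidates, 100 branch-assigned (43 early, 57 late)
```

The 30 injected low-quality cells are exactly the ones removed by QC; the
fitted 30-node tree recovers the planted Y topology (3 tips + 1 fork = 4
milestones) and orders cells in near-perfect agreement with true pseudotime.
The fork report recovers the planted 40 early fate-bias genes (activating
before the fork, then repressed on the opposing branch) and the late
commitment and terminal-marker genes, with activation timing estimated by the
binned rate formula.

## Command line

Every stage is also exposed as a subcommand —
`crestflow simulate | qc | preprocess | tree fit | tree pseudotime |
test-association | fit-trends | fork | modules-correlate | regulons |
annotate | hub | map | run` — reading and writing Matrix Market / TSV / JSON
files. `crestflow run --seed 1 --out OUT` drives the full pipeline on the
synthetic preset and writes a manifest with per-file sha256 checksums; a
rerun with the same seed is bit-identical.

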