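"""Synthetic branching single-cell datasets with full ground truth.

The generator emulates the structure the trajectory analysis assumes: a rooted
branching topology embedded in low-dimensional space (by default a neural-crest
trunk forking into glial and sympathoadrenal arms), deep plate-based counts
with negative-binomial noise, lognormal library-size factors and ERCC spike-in
fractions, fate-bias gene modules that co-activate before the fork and are
repressed on the opposing branch after it, late commitment modules, terminal
type markers, a marker-free intermediate ("hub") band around the fork, and
smooth regulon-activity trends grouped into planted clusters.

Every generated object carries its ground truth (pseudotime, segment, module
membership, activation times, cluster labels, hub membership) so that each
downstream inference step can be scored against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .qc import ExpressionMatrix

__all__ = [
    "Segment",
    "TopologySpec",
    "ModuleSpec",
    "SyntheticTruth",
    "y_topology",
    "default_modules",
    "default_templates",
    "simulate_trajectory",
    "simulate_expression",
    "simulate_regulon_activity",
    "default_dataset",
]

_ROLES = ("early", "late", "neutral", "noise", "hub-marker", "type-marker")


@dataclass(frozen=True)
class Segment:
    """One branch segment: a straight piece of the trajectory backbone."""

    id: str
    parent: str | None
    length: float
    direction: tuple[float, ...]


@dataclass
class TopologySpec:
    """A rooted tree of segments plus per-segment cell allocation fractions."""

    segments: list[Segment]
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("segment ids must be unique")
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root segment, found {len(roots)}")
        known = set(ids)
        for s in self.segments:
            if s.parent is not None and s.parent not in known:
                raise ValueError(f"segment {s.id} has unknown parent {s.parent}")
            if s.length <= 0:
                raise ValueError(f"segment {s.id} has non-positive length")
        dims = {len(s.direction) for s in self.segments}
        if len(dims) != 1:
            raise ValueError(f"inconsistent direction dimensions: {sorted(dims)}")
        if set(self.fractions) != known:
            raise ValueError("fractions must cover exactly the segment ids")
        if not math.isclose(sum(self.fractions.values()), 1.0, abs_tol=1e-9):
            raise ValueError("allocation fractions must sum to 1")
        # check acyclicity by walking to the root from every segment
        parent = {s.id: s.parent for s in self.segments}
        for sid in known:
            seen, cur = set(), sid
            while cur is not None:
                if cur in seen:
                    raise ValueError("segments do not form a tree (cycle detected)")
                seen.add(cur)
                cur = parent[cur]

    @property
    def root(self) -> Segment:
        return next(s for s in self.segments if s.parent is None)

    @property
    def n_dims(self) -> int:
        return len(self.segments[0].direction)

    def segment(self, sid: str) -> Segment:
        return next(s for s in self.segments if s.id == sid)

    def t_start(self, sid: str) -> float:
        """Pseudotime at which a segment begins (sum of ancestor lengths)."""
        s = self.segment(sid)
        return 0.0 if s.parent is None else self.t_start(s.parent) + self.segment(s.parent).length

    def t_end(self, sid: str) -> float:
        return self.t_start(sid) + self.segment(sid).length

    @property
    def t_max(self) -> float:
        return max(self.t_end(s.id) for s in self.segments)

    def start_position(self, sid: str) -> np.ndarray:
        s = self.segment(sid)
        if s.parent is None:
            return np.zeros(self.n_dims)
        p = self.segment(s.parent)
        u = np.asarray(p.direction, float)
        u = u / np.linalg.norm(u)
        return self.start_position(s.parent) + p.length * u

    def children(self, sid: str) -> list[str]:
        return [s.id for s in self.segments if s.parent == sid]

    def ancestors(self, sid: str) -> list[str]:
        out, cur = [], self.segment(sid).parent
        while cur is not None:
            out.append(cur)
            cur = self.segment(cur).parent
        return out

    def fork_pseudotimes(self) -> dict[str, float]:
        """Pseudotime of the end of every segment with >= 2 children."""
        return {
            s.id: self.t_end(s.id)
            for s in self.segments
            if len(self.children(s.id)) >= 2
        }


@dataclass(frozen=True)
class ModuleSpec:
    """A group of genes sharing one mean-expression program over the tree.

    Roles
    -----
    early
        Activates (logistic in pseudotime) before the fork on the path to the
        target branch; on the opposing branch the mean decays back to baseline
        past ``repression`` (reverse logistic), modelling co-activation followed
        by mutual repression.
    late
        Activates after the fork, only on the target branch.
    neutral
        Activates everywhere (tree-associated, not branch-specific).
    noise
        Flat baseline everywhere.
    hub-marker
        Gaussian bump of activity centred at ``activation`` (width
        ``steepness``), shared by all branches.
    type-marker
        Terminal cell-type marker: logistic activation on the target branch;
        with ``decreasing=True`` a marker that switches *off* at ``activation``
        on every branch (e.g. a neural-crest identity marker).
    """

    module_id: str
    role: str
    branch: str | None
    baseline: float
    amplitude: float
    activation: float
    steepness: float
    n_genes: int
    repression: float | None = None
    decreasing: bool = False

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown module role {self.role!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.role == "early" and self.repression is None:
            raise ValueError("early modules require a repression pseudotime")


@dataclass
class SyntheticTruth:
    """Ground truth accumulated across the three generators."""

    cells: pd.DataFrame  # cell_id, pseudotime, segment (+ lib_factor, low_quality, qc_mode)
    topology: TopologySpec
    fork_pseudotime: float | None
    genes: pd.DataFrame | None = None  # gene_id, module_id, role, branch
    modules: list[ModuleSpec] | None = None
    regulon_clusters: pd.Series | None = None
    hub_band: tuple[float, float] | None = None
    hub_mask: np.ndarray | None = None

    @property
    def pseudotime(self) -> np.ndarray:
        return self.cells["pseudotime"].to_numpy()

    @property
    def segment(self) -> np.ndarray:
        return self.cells["segment"].to_numpy()


def y_topology(
    trunk_len: float = 1.0,
    branch_len: float = 1.0,
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
) -> TopologySpec:
    """Default preset: NC trunk forking into glial and sympathoadrenal arms."""
    s = 1.0 / math.sqrt(2.0)
    return TopologySpec(
        segments=[
            Segment("NC", None, trunk_len, (1.0, 0.0)),
            Segment("glial", "NC", branch_len, (s, s)),
            Segment("sympathoadrenal", "NC", branch_len, (s, -s)),
        ],
        fractions={
            "NC": fractions[0],
            "glial": fractions[1],
            "sympathoadrenal": fractions[2],
        },
    )


def _allocate(n_cells: int, topology: TopologySpec) -> dict[str, int]:
    """Largest-remainder allocation so segment counts sum exactly to n_cells."""
    sids = [s.id for s in topology.segments]
    raw = np.array([topology.fractions[sid] * n_cells for sid in sids])
    base = np.floor(raw).astype(int)
    rem = n_cells - base.sum()
    order = np.argsort(-(raw - base), kind="mergesort")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(sids, base))


def simulate_trajectory(
    topology: TopologySpec,
    n_cells: int,
    embedding_noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Place cells uniformly along the backbone and add isotropic noise.

    Returns the noisy embedding (cells x dims) and a truth object recording
    each cell's exact pseudotime and segment.
    """
    if embedding_noise_sd < 0:
        raise ValueError("embedding_noise_sd must be >= 0")
    if n_cells < len(topology.segments):
        raise ValueError("need at least one cell per segment")
    rng = np.random.default_rng(seed)
    counts = _allocate(n_cells, topology)
    rows, backbone = [], []
    for seg in topology.segments:
        k = counts[seg.id]
        u = np.sort(rng.uniform(0.0, 1.0, size=k))
        t0 = topology.t_start(seg.id)
        start = topology.start_position(seg.id)
        d = np.asarray(seg.direction, float)
        d = d / np.linalg.norm(d)
        for ui in u:
            rows.append((seg.id, t0 + ui * seg.length))
            backbone.append(start + ui * seg.length * d)
    backbone = np.asarray(backbone)
    embedding = backbone + rng.normal(0.0, embedding_noise_sd, size=backbone.shape)
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n_cells)],
            "pseudotime": [t for _, t in rows],
            "segment": [s for s, _ in rows],
        }
    )
    forks = topology.fork_pseudotimes()
    fork_t = min(forks.values()) if forks else None
    return embedding, SyntheticTruth(cells=cells, topology=topology, fork_pseudotime=fork_t)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def module_mean(
    module: ModuleSpec, t: np.ndarray, segment: np.ndarray, topology: TopologySpec
) -> np.ndarray:
    """Closed-form mean expression of a module's genes for each cell."""
    t = np.asarray(t, float)
    segment = np.asarray(segment)
    base = np.full(t.shape, module.baseline, float)
    act = _logistic((t - module.activation) / module.steepness)
    if module.role == "noise":
        return base
    if module.role == "neutral":
        return base + module.amplitude * act
    if module.role == "hub-marker":
        bump = np.exp(-((t - module.activation) ** 2) / (2.0 * module.steepness**2))
        return base + module.amplitude * bump
    if module.role == "type-marker" and module.decreasing:
        return base + module.amplitude * (1.0 - act)
    # branch-targeted roles: early, late, type-marker (increasing)
    if module.branch is None:
        raise ValueError(f"module {module.module_id} ({module.role}) needs a target branch")
    on_path = np.isin(segment, topology.ancestors(module.branch) + [module.branch])
    out = base.copy()
    out[on_path] += module.amplitude * act[on_path]
    if module.role == "early":
        # opposing subtree: co-activation then decay past the repression time
        off = ~on_path
        rep = 1.0 - _logistic((t - module.repression) / module.steepness)
        out[off] += module.amplitude * act[off] * rep[off]
    return out


def _validate_modules(modules: Sequence[ModuleSpec], topology: TopologySpec) -> None:
    if not modules:
        raise ValueError("modules must be non-empty")
    t_max = topology.t_max
    forks = topology.fork_pseudotimes()
    fork_t = min(forks.values()) if forks else None
    for m in modules:
        if not 0.0 <= m.activation <= t_max:
            raise ValueError(
                f"module {m.module_id}: activation {m.activation} outside [0, {t_max}]"
            )
        if m.branch is not None and m.branch not in {s.id for s in topology.segments}:
            raise ValueError(f"module {m.module_id}: unknown branch {m.branch}")
        if fork_t is not None:
            if m.role == "early" and m.activation > fork_t:
                raise ValueError(f"early module {m.module_id} activates after the fork")
            if m.role == "late" and m.activation < fork_t:
                raise ValueError(f"late module {m.module_id} activates before the fork")


def default_modules(
    topology: TopologySpec | None = None,
    n_background: int = 1000,
    n_per_module: int = 20,
    seed: int = 1234,
) -> list[ModuleSpec]:
    """Default gene-program preset for the Y topology.

    Two early fate-bias modules (activation before the fork, repression on the
    opposing branch after it), two late commitment modules, terminal type
    markers per branch, a decreasing NC identity marker set, a hub-marker bump
    at the fork, and a flat background block sized for realistic per-cell gene
    detection. Count-scale means give roughly 1.5e5 transcripts per cell.
    """
    topology = topology or y_topology()
    fork = min(topology.fork_pseudotimes().values())
    b1, b2 = sorted(topology.children(topology.root.id))[:2]
    mods = [
        ModuleSpec("early_" + b1, "early", b1, 20.0, 100.0, fork - 0.4, 0.08, n_per_module, repression=fork + 0.15),
        ModuleSpec("early_" + b2, "early", b2, 20.0, 100.0, fork - 0.4, 0.08, n_per_module, repression=fork + 0.15),
        ModuleSpec("late_" + b1, "late", b1, 20.0, 100.0, fork + 0.6, 0.08, n_per_module),
        ModuleSpec("late_" + b2, "late", b2, 20.0, 100.0, fork + 0.6, 0.08, n_per_module),
        ModuleSpec("marker_NC", "type-marker", None, 20.0, 100.0, fork - 0.15, 0.05, 10, decreasing=True),
        ModuleSpec("marker_" + b1, "type-marker", b1, 20.0, 100.0, fork + 0.55, 0.05, 10),
        ModuleSpec("marker_" + b2, "type-marker", b2, 20.0, 100.0, fork + 0.55, 0.05, 10),
        ModuleSpec("hub_marker", "hub-marker", None, 20.0, 100.0, fork, 0.12, 10),
    ]
    if n_background > 0:
        mods.append(ModuleSpec("background", "noise", None, 140.0, 0.0, 0.0, 1.0, n_background))
    return mods


def hub_band_from_modules(
    modules: Sequence[ModuleSpec], activation_fraction: float = 0.25
) -> tuple[float, float]:
    """Pseudotime band in which no cell-type marker module is active.

    A marker module counts as "off" while its logistic program sits below
    ``activation_fraction`` of its amplitude; the band runs from the point
    where every decreasing (progenitor-identity) marker has switched off to
    the point where the first increasing (terminal) marker switches on.
    """
    z = math.log((1.0 - activation_fraction) / activation_fraction)
    lo = max(
        (m.activation + z * m.steepness
         for m in modules if m.role == "type-marker" and m.decreasing),
        default=None,
    )
    hi = min(
        (m.activation - z * m.steepness
         for m in modules if m.role == "type-marker" and not m.decreasing),
        default=None,
    )
    if lo is None or hi is None or lo >= hi:
        raise ValueError("module preset does not define a marker-free band")
    return (lo, hi)


def simulate_expression(
    truth: SyntheticTruth,
    modules: Sequence[ModuleSpec],
    nb_dispersion: float = 5.0,
    lib_size_lognormal_params: tuple[float, float] = (0.0, 0.2),
    ercc_fraction_range: tuple[float, float] = (0.02, 0.08),
    n_low_quality_cells: int = 0,
    n_ercc_genes: int = 20,
    seed: int = 0,
) -> ExpressionMatrix:
    """Draw a count matrix for the cells in ``truth``.

    Per-gene means follow the module programs evaluated at each cell's true
    pseudotime/segment, scaled by a lognormal per-cell library factor; counts
    are negative binomial with the stated dispersion (variance
    ``m + m^2/dispersion``). ERCC spike-in rows are added so each cell's ERCC
    read fraction falls in ``ercc_fraction_range``. ``n_low_quality_cells``
    extra cells are appended that violate the default QC thresholds (cycling
    through low transcript totals, few detected genes, high ERCC fraction);
    they are flagged in ``truth.cells``.

    Mutates ``truth`` in place (gene table, module list, hub band/mask,
    library factors) and returns the counts matrix with ERCC rows flagged.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    lo, hi = ercc_fraction_range
    if not (0.0 <= lo <= hi < 1.0):
        raise ValueError("ercc_fraction_range must satisfy 0 <= lo <= hi < 1")
    _validate_modules(modules, truth.topology)
    rng = np.random.default_rng(seed)

    base = truth.cells[["cell_id", "pseudotime", "segment"]].copy()
    n_clean = len(base)
    # low-quality cells replay random clean positions
    modes = ["low_transcripts", "few_genes", "high_ercc"]
    lq_rows = []
    for i in range(n_low_quality_cells):
        src = int(rng.integers(n_clean))
        lq_rows.append(
            {
                "cell_id": f"lowq{i:04d}",
                "pseudotime": base.loc[src, "pseudotime"],
                "segment": base.loc[src, "segment"],
                "qc_mode": modes[i % 3],
            }
        )
    cells = pd.concat([base, pd.DataFrame(lq_rows)], ignore_index=True)
    cells["low_quality"] = cells["cell_id"].str.startswith("lowq")
    cells["qc_mode"] = cells.get("qc_mode", pd.Series([None] * len(cells))).fillna("")
    n_total = len(cells)
    t = cells["pseudotime"].to_numpy()
    seg = cells["segment"].to_numpy()

    gene_rows, mean_blocks = [], []
    rng_gene = np.random.default_rng(seed + 1)
    for m in modules:
        mu = module_mean(m, t, seg, truth.topology)
        if m.role == "noise" and m.n_genes > 1:
            # heterogeneous flat baselines so background genes differ in depth
            scale = rng_gene.uniform(0.3, 1.7, size=m.n_genes)
        else:
            scale = np.ones(m.n_genes)
        for j in range(m.n_genes):
            gene_rows.append((f"{m.module_id}_g{j:03d}", m.module_id, m.role, m.branch))
            mean_blocks.append(mu * scale[j])
    M = np.asarray(mean_blocks)  # genes x cells

    lib = rng.lognormal(*lib_size_lognormal_params, size=n_total)
    lq = cells["low_quality"].to_numpy()
    mode = cells["qc_mode"].to_numpy()
    lib[lq & (mode == "low_transcripts")] *= 0.15
    M = M * lib[None, :]
    # few-genes cells: keep a random subset of genes, rescale to preserve depth
    few = np.flatnonzero(lq & (mode == "few_genes"))
    if few.size:
        n_keep = min(400, M.shape[0])
        for c in few:
            keep = rng.choice(M.shape[0], size=n_keep, replace=False)
            col = np.zeros(M.shape[0])
            col[keep] = M[keep, c] * (M[:, c].sum() / max(M[keep, c].sum(), 1e-12))
            M[:, c] = col

    p = nb_dispersion / (nb_dispersion + np.maximum(M, 1e-12))
    counts = rng.negative_binomial(nb_dispersion, p)
    counts[M <= 0] = 0

    # ERCC rows: per-cell target fraction drawn away from the range edges
    margin = 0.1 * (hi - lo)
    frac = rng.uniform(lo + margin, hi - margin if hi - margin > lo + margin else hi, size=n_total)
    frac[lq & (mode == "high_ercc")] = min(0.25, 2.0 * 0.15)
    endo_tot = counts.sum(axis=0)
    ercc_target = frac / (1.0 - frac) * endo_tot
    w = 2.0 ** (-np.arange(n_ercc_genes) / 4.0)
    w = w / w.sum()
    ercc_counts = rng.poisson(w[:, None] * ercc_target[None, :])

    values = np.vstack([counts, ercc_counts]).astype(np.int64)
    gene_ids = [g for g, *_ in gene_rows] + [f"ERCC-{k:05d}" for k in range(n_ercc_genes)]
    ercc_mask = np.array([False] * len(gene_rows) + [True] * n_ercc_genes)

    truth.cells = cells
    truth.cells["lib_factor"] = lib
    truth.modules = list(modules)
    truth.genes = pd.DataFrame(gene_rows, columns=["gene_id", "module_id", "role", "branch"])
    try:
        truth.hub_band = hub_band_from_modules(modules)
        truth.hub_mask = (t > truth.hub_band[0]) & (t < truth.hub_band[1])
    except ValueError:
        truth.hub_band = None
        truth.hub_mask = None
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cells["cell_id"].tolist(),
        ercc_mask=ercc_mask,
        layer="counts",
    )


def module_activation_onset(
    module: ModuleSpec,
    topology: TopologySpec,
    norm_factor: float,
    frac: float = 0.1,
    log_base: float = 10.0,
) -> float:
    """Ground-truth activation onset of a module on the analysis scale.

    Evaluates the noiseless mean curve along the root-to-target path, maps it
    through the library normalization (``log(1 + norm_factor * mu)``), and
    returns the first pseudotime at which it exceeds ``frac`` of its dynamic
    range — the scale-aware onset a rate-based activation call estimates
    (as opposed to the logistic midpoint, which is reached only at half
    amplitude).
    """
    branch = module.branch
    if branch is None:
        segs = [topology.root.id]
        while topology.children(segs[-1]):
            segs.append(sorted(topology.children(segs[-1]))[0])
        branch = segs[-1]
    path = topology.ancestors(branch)[::-1] + [branch]
    ts, labels = [], []
    for sid in path:
        g = np.linspace(topology.t_start(sid), topology.t_end(sid), 500)
        ts.append(g)
        labels.append(np.full(g.shape, sid, dtype=object))
    t = np.concatenate(ts)
    seg = np.concatenate(labels)
    mu = module_mean(module, t, seg, topology)
    y = np.log1p(norm_factor * mu) / np.log(log_base)
    rng_ = y.max() - y.min()
    if rng_ <= 0:
        raise ValueError(f"module {module.module_id} has a flat mean curve")
    hits = np.flatnonzero(y >= y.min() + frac * rng_)
    return float(t[hits[0]])


def default_templates() -> list[Callable[[np.ndarray], np.ndarray]]:
    """Five well-separated smooth activity trends on normalized pseudotime."""
    return [
        lambda s: _logistic((s - 0.75) / 0.06),           # late rising switch
        lambda s: 1.0 - _logistic((s - 0.25) / 0.06),     # early falling switch
        lambda s: np.exp(-((s - 0.25) ** 2) / 0.008),     # early peak
        lambda s: np.exp(-((s - 0.75) ** 2) / 0.008),     # late peak
        lambda s: np.exp(-((s - 0.5) ** 2) / 0.008),      # mid peak
    ]


def simulate_regulon_activity(
    truth: SyntheticTruth,
    n_regulons: int = 30,
    n_clusters: int = 5,
    trend_templates: Sequence[Callable] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Generate AUC-like regulon scores following planted trend clusters.

    Each regulon's per-cell score is its cluster template evaluated at the
    cell's normalized true pseudotime plus Gaussian noise, clipped to [0, 1].
    Regulons are assigned to clusters round-robin. Matching TF expression is
    returned on a log10 scale, proportional to the template (factor 2, so the
    standard AUC weight saturates once the template exceeds 0.5).

    Returns a :class:`~crestflow.regulons.RegulonActivity`; cluster truth is
    stored in ``truth.regulon_clusters``.
    """
    from .regulons import RegulonActivity

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    templates = list(trend_templates) if trend_templates is not None else default_templates()
    if n_clusters > len(templates):
        raise ValueError(f"need {n_clusters} templates, got {len(templates)}")
    if n_clusters > n_regulons:
        raise ValueError("n_clusters must be <= n_regulons")
    rng = np.random.default_rng(seed)
    # restrict to clean cells if low-quality cells were appended
    cells = truth.cells
    clean = ~cells.get("low_quality", pd.Series(False, index=cells.index)).to_numpy()
    cell_ids = cells.loc[clean, "cell_id"].tolist()
    t = cells.loc[clean, "pseudotime"].to_numpy()
    s = t / truth.topology.t_max

    labels, scores, tf_rows, tf_names = [], [], [], []
    for r in range(n_regulons):
        c = r % n_clusters
        labels.append(c)
        trend = templates[c](s)
        scores.append(np.clip(trend + rng.normal(0.0, noise_sd, size=s.shape), 0.0, 1.0))
        tf = f"Tf{r:03d}"
        tf_names.append(tf)
        tf_rows.append(np.clip(2.0 * trend + rng.normal(0.0, noise_sd, size=s.shape), 0.0, None))
    regulon_ids = [f"regulon{r:03d}" for r in range(n_regulons)]
    truth.regulon_clusters = pd.Series(labels, index=regulon_ids, name="cluster")
    return RegulonActivity(
        scores=pd.DataFrame(scores, index=regulon_ids, columns=cell_ids),
        tf_map=dict(zip(regulon_ids, tf_names)),
        tf_expression=pd.DataFrame(tf_rows, index=tf_names, columns=cell_ids),
        weighted=False,
    )


def default_dataset(
    n_cells: int = 600,
    embedding_noise_sd: float = 0.05,
    n_low_quality_cells: int = 0,
    n_background: int = 1000,
    seed: int = 0,
):
    """Convenience preset: Y trajectory + default modules + counts.

    Returns ``(embedding, truth, counts_matrix)``. The embedding covers clean
    cells only; expression columns cover clean plus any low-quality cells.
    """
    topo = y_topology()
    embedding, truth = simulate_trajectory(topo, n_cells, embedding_noise_sd, seed=seed)
    modules = default_modules(topo, n_background=n_background)
    expr = simulate_expression(
        truth, modules, n_low_quality_cells=n_low_quality_cells, seed=seed + 1
    )
    return embedding, truth, expr
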