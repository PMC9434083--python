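"""Principal-tree fitting (SimplePPT) and pseudotime machinery.

A principal tree is an acyclic principal graph fitted to a low-dimensional
embedding by alternating three steps until the nodes stop moving:

1. soft assignment: responsibilities ``R_ij ∝ exp(-||x_i - c_j||^2 / sigma)``,
   row-normalized over nodes;
2. topology: minimum spanning tree over the current node-node distances;
3. elastic update: node positions solve the linear system minimizing
   ``sum_ij R_ij ||x_i - c_j||^2 + lambda * sum_(j,k) in E ||c_j - c_k||^2``.

Pseudotime is geodesic distance from a chosen root along tree edges, projected
to cells either through the soft assignment matrix R (expected node pseudotime)
or through the best-assigned node. Milestones are the tips and forks of the
tree; paths between milestones subset cells for branch-level analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

logger = logging.getLogger("crestflow")

__all__ = [
    "PrincipalTree",
    "PseudotimeField",
    "Milestone",
    "fit_principal_tree",
    "compute_pseudotime",
    "probabilistic_mappings",
    "identify_milestones",
    "extract_path",
    "ForkPath",
    "select_root",
]


@dataclass
class PrincipalTree:
    """Fitted principal tree: node geometry, topology and soft assignments."""

    node_positions: np.ndarray  # nodes x dims
    edges: list[tuple[int, int]]
    R: np.ndarray  # cells x nodes, rows sum to 1
    sigma: float
    lambda_: float
    metric: str = "euclidean"
    root: int | None = None
    converged: bool = True
    n_iter: int = 0
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    @property
    def n_cells(self) -> int:
        return self.R.shape[0]

    def graph(self) -> nx.Graph:
        """Tree as a networkx graph with euclidean edge lengths."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for j, k in self.edges:
            w = float(np.linalg.norm(self.node_positions[j] - self.node_positions[k]))
            g.add_edge(j, k, weight=w)
        return g

    def best_node(self) -> np.ndarray:
        """Max-responsibility node per cell (ties broken toward lower ids)."""
        return np.argmax(self.R, axis=1)

    def validate(self) -> None:
        rows = self.R.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("rows of R must sum to 1")
        g = self.graph()
        if self.n_nodes > 1 and not nx.is_tree(g):
            raise ValueError("edges do not form a single connected tree")


@dataclass
class PseudotimeField:
    """Per-cell and per-node pseudotime plus segment decomposition."""

    cell_pseudotime: np.ndarray
    cell_segment: np.ndarray  # int segment ids
    node_pseudotime: np.ndarray
    node_segment: np.ndarray
    root: int
    mode: str = "soft"


@dataclass(frozen=True)
class Milestone:
    node: int
    kind: str  # "tip" or "fork"
    label: str


def fit_principal_tree(
    embedding: np.ndarray,
    n_nodes: int = 30,
    sigma: float | None = None,
    lambda_: float = 1.0,
    metric: str = "euclidean",
    max_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
) -> PrincipalTree:
    """Fit a SimplePPT principal tree to an embedding.

    Parameters
    ----------
    sigma
        Kernel bandwidth in squared embedding-distance units. If omitted it is
        set to 0.1 times the median pairwise squared distance — a desk-scale
        default; atlas-scale presets (e.g. sigma=0.0005, lambda=200 on a
        diffusion space) are passed explicitly.
    lambda_
        Elastic penalty pulling adjacent nodes together.
    tol
        Convergence threshold on the maximum node displacement per iteration.

    Notes
    -----
    Nodes are initialized by seeded k-means++ sampling of the embedding. The
    recorded objective is the soft-assignment free energy
    ``-sigma * sum_i log sum_j exp(-d_ij^2/sigma) + lambda * elastic``, which is
    non-increasing across iterations.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ValueError("embedding must be 2-D (cells x dims)")
    n_cells = X.shape[0]
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if n_nodes > n_cells:
        raise ValueError(f"n_nodes={n_nodes} exceeds the number of cells {n_cells}")
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}; only 'euclidean' is implemented")
    if sigma is None:
        rng = np.random.default_rng(seed)
        sub = X[rng.choice(n_cells, size=min(n_cells, 1000), replace=False)]
        d2 = cdist(sub, sub, "sqeuclidean")
        sigma = 0.1 * float(np.median(d2[np.triu_indices_from(d2, k=1)]))
        sigma = max(sigma, 1e-12)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")

    C, _ = kmeans_plusplus(X, n_clusters=n_nodes, random_state=seed)
    edges: list[tuple[int, int]] = []
    R = np.ones((n_cells, n_nodes)) / n_nodes
    converged = False
    trace: list[float] = []
    for it in range(max_iter):
        d2 = cdist(X, C, "sqeuclidean")
        shift = d2.min(axis=1, keepdims=True)
        W = np.exp(-(d2 - shift) / sigma)
        rowsum = W.sum(axis=1)
        # shifted kernel guarantees a max entry of 1, but guard degenerate rows
        bad = ~np.isfinite(rowsum) | (rowsum <= 0)
        if np.any(bad):
            warnings.warn(f"{int(bad.sum())} cells had degenerate kernels; using nearest node")
            W[bad] = 0.0
            W[bad, np.argmin(d2[bad], axis=1)] = 1.0
            rowsum = W.sum(axis=1)
        R = W / rowsum[:, None]

        if n_nodes > 1:
            Dn = cdist(C, C)
            mst = minimum_spanning_tree(Dn).tocoo()
            edges = sorted(
                (min(int(a), int(b)), max(int(a), int(b)))
                for a, b in zip(mst.row, mst.col)
            )
        L = np.zeros((n_nodes, n_nodes))
        for j, k in edges:
            L[j, j] += 1.0
            L[k, k] += 1.0
            L[j, k] -= 1.0
            L[k, j] -= 1.0
        r = R.sum(axis=0)
        A = np.diag(r) + lambda_ * L
        C_new = np.linalg.solve(A, R.T @ X)

        elastic = sum(
            float(np.sum((C_new[j] - C_new[k]) ** 2)) for j, k in edges
        )
        d2_new = cdist(X, C_new, "sqeuclidean")
        sh = d2_new.min(axis=1, keepdims=True)
        free = -sigma * float(
            np.sum(np.log(np.exp(-(d2_new - sh) / sigma).sum(axis=1)) - sh.ravel() / sigma)
        )
        trace.append(free + lambda_ * elastic)

        disp = float(np.max(np.linalg.norm(C_new - C, axis=1)))
        C = C_new
        if disp < tol:
            converged = True
            break
    # final responsibilities for the converged positions
    d2 = cdist(X, C, "sqeuclidean")
    shift = d2.min(axis=1, keepdims=True)
    W = np.exp(-(d2 - shift) / sigma)
    R = W / W.sum(axis=1)[:, None]
    if n_nodes > 1:
        Dn = cdist(C, C)
        mst = minimum_spanning_tree(Dn).tocoo()
        edges = sorted(
            (min(int(a), int(b)), max(int(a), int(b))) for a, b in zip(mst.row, mst.col)
        )
    if not converged:
        logger.warning("principal tree did not converge in %d iterations", max_iter)
    tree = PrincipalTree(
        node_positions=C,
        edges=edges,
        R=R,
        sigma=float(sigma),
        lambda_=float(lambda_),
        metric=metric,
        converged=converged,
        n_iter=it + 1,
        objective_trace=trace,
    )
    tree.validate()
    return tree


def _node_segments(g: nx.Graph, root: int) -> np.ndarray:
    """Deterministic segment decomposition of a rooted tree.

    A new segment starts below the root and below every fork; a node belongs to
    the segment of the edge above it (the root joins its first child's
    segment). Segments are numbered in DFS order with ascending-id tie-breaks.
    """
    n = g.number_of_nodes()
    if n == 1:
        return np.zeros(1, dtype=int)
    seg_id = -1
    seg = np.full(n, -1, dtype=int)
    visit = [(root, None, -1)]
    while visit:
        node, parent, cur = visit.pop()
        if cur == -1:
            seg_id += 1
            cur = seg_id
        seg[node] = cur
        children = sorted(c for c in g.neighbors(node) if c != parent)
        branching = len(children) > 1
        for c in reversed(children):
            visit.append((c, node, -1 if branching else cur))
    return seg


def compute_pseudotime(
    tree: PrincipalTree, root: int, mode: str = "soft"
) -> PseudotimeField:
    """Pseudotime as geodesic distance from the root, projected to cells.

    ``mode='soft'`` gives each cell the R-weighted mean of node pseudotimes;
    ``mode='hard'`` the pseudotime of its max-responsibility node (ties break
    toward the lower node id). Cell segments always come from the best node.
    """
    if mode not in ("soft", "hard"):
        raise ValueError("mode must be 'soft' or 'hard'")
    if root is None:
        raise ValueError("root is unset; choose a root node (see select_root)")
    if not 0 <= root < tree.n_nodes:
        raise ValueError(f"root {root} is not a tree node")
    g = tree.graph()
    dist = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    node_t = np.array([dist[j] for j in range(tree.n_nodes)])
    best = tree.best_node()
    if mode == "soft":
        cell_t = tree.R @ node_t
    else:
        cell_t = node_t[best]
    node_seg = _node_segments(g, root)
    tree.root = root
    return PseudotimeField(
        cell_pseudotime=cell_t,
        cell_segment=node_seg[best],
        node_pseudotime=node_t,
        node_segment=node_seg,
        root=root,
        mode=mode,
    )


def probabilistic_mappings(
    tree: PrincipalTree, n_mappings: int = 100, seed: int = 0
) -> np.ndarray:
    """Sample hard node assignments from R.

    Returns an ``(n_mappings, n_cells)`` integer array; in each mapping every
    cell draws one node with probabilities given by its row of R.
    """
    if n_mappings < 1:
        raise ValueError("n_mappings must be >= 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(tree.R, axis=1)
    cum[:, -1] = 1.0
    out = np.empty((n_mappings, tree.n_cells), dtype=int)
    for m in range(n_mappings):
        u = rng.random(tree.n_cells)
        out[m] = (u[:, None] <= cum).argmax(axis=1)
    return out


def identify_milestones(
    tree: PrincipalTree, pseudotime: PseudotimeField
) -> tuple[list[Milestone], np.ndarray]:
    """Tips and forks of the tree, plus per-cell milestone assignment.

    Each cell is assigned to the milestone on its own root-to-tip path (the
    milestones above its best node plus the next one downstream) minimizing
    the pseudotime distance ``|t_cell - t_milestone|``; ties break toward the
    earlier milestone.
    """
    g = tree.graph()
    if tree.n_nodes == 1:
        ms = [Milestone(0, "tip", "M0")]
        return ms, np.zeros(tree.n_cells, dtype=int)
    milestones = []
    for j in range(tree.n_nodes):
        deg = g.degree(j)
        if deg == 1:
            milestones.append(Milestone(j, "tip", f"M{j}"))
        elif deg >= 3:
            milestones.append(Milestone(j, "fork", f"M{j}"))
    mnodes = {m.node for m in milestones}
    root = pseudotime.root
    node_t = pseudotime.node_pseudotime
    # parents from root orientation
    parent = {root: None}
    for u, v in nx.bfs_edges(g, root):
        parent[v] = u

    def candidates(node: int) -> list[int]:
        cands = []
        cur = node
        while cur is not None:
            if cur in mnodes:
                cands.append(cur)
            cur = parent[cur]
        # walk downstream along the chain to the next milestone
        cur, prev = node, parent[node]
        while cur not in mnodes or cur == node:
            if cur in mnodes:
                break
            nxts = [w for w in g.neighbors(cur) if w != prev]
            if not nxts:
                break
            prev, cur = cur, min(nxts)
            if cur in mnodes:
                cands.append(cur)
                break
        return cands

    best = tree.best_node()
    cache: dict[int, list[int]] = {}
    assign = np.empty(tree.n_cells, dtype=int)
    for i, node in enumerate(best):
        if node not in cache:
            cache[node] = candidates(int(node))
        cands = cache[node]
        t = pseudotime.cell_pseudotime[i]
        # minimize |t - t_m|; ties -> earlier pseudotime, then lower id
        key = sorted(cands, key=lambda m: (abs(t - node_t[m]), node_t[m], m))
        assign[i] = key[0]
    return milestones, assign


@dataclass
class ForkPath:
    """Cells on the path(s) from a source milestone to one or two targets."""

    cell_indices: np.ndarray
    branch_labels: np.ndarray  # 'pre-fork' | 'branch-1' | 'branch-2' | 'path'
    pseudotime: np.ndarray
    fork_pseudotime: float | None
    fork_node: int | None
    source: int
    targets: tuple[int, ...]
    node_labels: dict[int, str]


def extract_path(
    tree: PrincipalTree,
    pseudotime: PseudotimeField,
    from_milestone: int,
    to_milestones,
) -> ForkPath:
    """Subset cells whose best node lies on the milestone path(s).

    With two targets their root paths must diverge at a unique fork; cells get
    labels pre-fork / branch-1 / branch-2. With a single target all path cells
    are labelled 'path'. Pseudotime values are passed through unchanged.
    """
    targets = [to_milestones] if np.isscalar(to_milestones) else list(to_milestones)
    if len(targets) not in (1, 2):
        raise ValueError("to_milestones must contain one or two milestone ids")
    g = tree.graph()
    paths = []
    for tgt in targets:
        try:
            paths.append(nx.shortest_path(g, from_milestone, tgt))
        except nx.NetworkXNoPath as e:  # disconnected should not happen on a tree
            raise ValueError(f"no path from {from_milestone} to {tgt}") from e
    node_labels: dict[int, str] = {}
    if len(targets) == 1:
        for n in paths[0]:
            node_labels[n] = "path"
        fork_node, fork_t = None, None
    else:
        p1, p2 = paths
        shared = 0
        while shared < min(len(p1), len(p2)) and p1[shared] == p2[shared]:
            shared += 1
        if shared == 0:
            raise ValueError("paths share no prefix; targets not downstream of source")
        if shared == len(p1) or shared == len(p2):
            raise ValueError(
                "one target lies on the path to the other; no fork between them"
            )
        fork_node = p1[shared - 1]
        for n in p1[:shared]:
            node_labels[n] = "pre-fork"
        for n in p1[shared:]:
            node_labels[n] = "branch-1"
        for n in p2[shared:]:
            node_labels[n] = "branch-2"
        fork_t = float(pseudotime.node_pseudotime[fork_node])
    best = tree.best_node()
    on_path = np.array([node_labels.get(int(n)) is not None for n in best])
    idx = np.flatnonzero(on_path)
    labels = np.array([node_labels[int(best[i])] for i in idx])
    return ForkPath(
        cell_indices=idx,
        branch_labels=labels,
        pseudotime=pseudotime.cell_pseudotime[idx],
        fork_pseudotime=fork_t,
        fork_node=fork_node,
        source=int(from_milestone),
        targets=tuple(int(t) for t in targets),
        node_labels=node_labels,
    )


def select_root(tree: PrincipalTree, cell_scores: np.ndarray) -> int:
    """Pick the tip whose R-weighted mean of a per-cell score is maximal.

    The score encodes external rooting knowledge (developmental stage, a
    stemness index, ...); higher means closer to the origin.
    """
    scores = np.asarray(cell_scores, float)
    if scores.shape != (tree.n_cells,):
        raise ValueError("cell_scores must have one value per cell")
    g = tree.graph()
    if tree.n_nodes == 1:
        return 0
    tips = [j for j in range(tree.n_nodes) if g.degree(j) == 1]
    best_tip, best_val = tips[0], -np.inf
    for j in tips:
        w = tree.R[:, j]
        tot = w.sum()
        val = float((w * scores).sum() / tot) if tot > 0 else -np.inf
        if val > best_val:
            best_tip, best_val = j, val
    return best_tip
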