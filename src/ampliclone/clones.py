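"""Clonal hierarchy inference and per-cell clone assignment.

From a cells x mutations genotype matrix (MUT / WT / MISSING), the maximum-
likelihood mutation tree is found by exhaustive enumeration of all rooted
labeled trees (one node per mutation plus a WT root), scoring each tree by a
per-entry error model with a false-positive rate ``fd`` (spurious MUT) and an
allelic-dropout rate ``ad`` (missed MUT), marginalizing each cell uniformly
over its possible attachment nodes.  This replaces MCMC tree search, which is
only needed for many mutations; carrier samples here have few genotyped
mutations, so the exhaustive regime (<= 6 mutations, (m+1)^(m-1) trees via
Pruefer sequences) is exact.

Cells are then assigned to the clone whose mutation set matches their
detected mutations; a cell whose detected set only matches a clone after
assuming dropout of an *ancestral* mutation is rescued into that clone with
an ``ado_rescued`` tag (dropout of a detected descendant is impossible,
dropout of an ancestor is the observed failure mode).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import MUT, UNDETERMINED, WT
from .errors import ConfigurationError, InsufficientDataError, SizeError

MISSING = "MISSING"

MAX_EXHAUSTIVE_MUTATIONS = 6


@dataclass(frozen=True)
class TreeScoreParams:
    """Per-entry error rates of the genotype matrix."""

    false_positive_rate: float = 0.01
    ado_rate: float = 0.02

    def __post_init__(self) -> None:
        for v in (self.false_positive_rate, self.ado_rate):
            if not 0 < v < 1:
                raise ConfigurationError("error rates must lie in (0, 1)")


@dataclass(frozen=True)
class CloneTree:
    """A rooted mutation tree.

    ``mutations[i]`` labels node i+1; ``parent[i]`` is the parent node of
    node i+1 (0 is the WT root).  Each node defines a clone whose mutation
    set is the path from the root.
    """

    mutations: tuple
    parent: tuple  # parent[i] = parent node index of node i+1; root is node 0

    @property
    def n_nodes(self) -> int:
        return len(self.mutations) + 1

    def clone_sets(self) -> list[frozenset]:
        """Mutation set of each node, root first, in node order."""
        sets: list[frozenset] = [frozenset()]
        # parents always have smaller depth but not necessarily smaller index;
        # resolve iteratively
        resolved: dict[int, frozenset] = {0: frozenset()}
        pending = set(range(1, self.n_nodes))
        while pending:
            progressed = False
            for node in sorted(pending):
                p = self.parent[node - 1]
                if p in resolved:
                    resolved[node] = resolved[p] | {self.mutations[node - 1]}
                    pending.discard(node)
                    progressed = True
            if not progressed:
                raise ConfigurationError("parent vector contains a cycle")
        return [resolved[i] for i in range(self.n_nodes)]

    def children(self, node: int) -> list[int]:
        return [i + 1 for i, p in enumerate(self.parent) if p == node]

    @property
    def n_branch_points(self) -> int:
        counts = [0] * self.n_nodes
        for p in self.parent:
            counts[p] += 1
        return sum(1 for c in counts if c > 1)

    def clone_id(self, node: int) -> str:
        if node == 0:
            return "WT"
        muts = self.clone_sets()[node]
        return "+".join(sorted(muts))

    def to_indented(self, counts: dict[int, int] | None = None) -> str:
        lines: list[str] = []

        def walk(node: int, depth: int) -> None:
            label = self.clone_id(node)
            if counts is not None:
                label += f"  [{counts.get(node, 0)} cells]"
            lines.append("  " * depth + label)
            for ch in self.children(node):
                walk(ch, depth + 1)

        walk(0, 0)
        return "\n".join(lines)

    def to_newick(self, counts: dict[int, int] | None = None) -> str:
        def label(node: int) -> str:
            name = self.clone_id(node).replace("+", "_")
            if counts is not None:
                name += f"_{counts.get(node, 0)}"
            return name

        def walk(node: int) -> str:
            kids = self.children(node)
            if not kids:
                return label(node)
            return "(" + ",".join(walk(k) for k in kids) + ")" + label(node)

        return walk(0) + ";"


def enumerate_trees(mutations) -> list[CloneTree]:
    """All rooted labeled mutation trees, via Pruefer sequences.

    Trees on m+1 labeled nodes (node 0 = WT root, node i+1 = mutations[i])
    number (m+1)^(m-1); each Pruefer sequence of length m-1 over the m+1
    labels yields one labeled tree, oriented away from the root.
    """
    mutations = tuple(mutations)
    m = len(mutations)
    if m == 0:
        raise InsufficientDataError("no mutations to build a tree from")
    if m > MAX_EXHAUSTIVE_MUTATIONS:
        raise SizeError(
            f"{m} mutations exceed the exhaustive regime "
            f"(<= {MAX_EXHAUSTIVE_MUTATIONS}); use an MCMC tree tool")
    if m == 1:
        return [CloneTree(mutations, (0,))]
    n = m + 1
    trees = []
    for seq in itertools.product(range(n), repeat=m - 1):
        # Pruefer decoding
        degree = [1] * n
        for s in seq:
            degree[s] += 1
        edges = []
        leaves = [i for i in range(n) if degree[i] == 1]
        heapq.heapify(leaves)
        for s in seq:
            leaf = heapq.heappop(leaves)
            edges.append((leaf, s))
            degree[s] -= 1
            if degree[s] == 1:
                heapq.heappush(leaves, s)
        u = heapq.heappop(leaves)
        v = heapq.heappop(leaves)
        edges.append((u, v))
        # orient away from root 0
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        parent = [0] * m
        stack = [0]
        seen = {0}
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    parent[nb - 1] = node
                    stack.append(nb)
        trees.append(CloneTree(mutations, tuple(parent)))
    return trees


def encode_genotype_matrix(calls: pd.DataFrame,
                           mutations: list[str] | None = None
                           ) -> tuple[np.ndarray, list[str], list[str]]:
    """Pivot consensus calls into a cells x mutations matrix of {1, 0, -1}.

    1 = MUT, 0 = WT, -1 = MISSING (undetermined/undetected/absent).
    """
    wide = calls.pivot(index="cell_id", columns="mutation_id",
                       values="consensus")
    if mutations is not None:
        wide = wide.reindex(columns=mutations)
    mat = np.full(wide.shape, -1, dtype=int)
    mat[(wide == MUT).to_numpy()] = 1
    mat[(wide == WT).to_numpy()] = 0
    return mat, list(wide.index), list(wide.columns)


def tree_log_likelihood(matrix: np.ndarray, tree: CloneTree,
                        params: TreeScoreParams) -> float:
    """Log-likelihood of the genotype matrix under one tree.

    Per cell, the likelihood is the mean over attachment nodes of the
    product over mutations of the per-entry error model:
    P(obs MUT | true MUT) = 1 - ad, P(obs WT | true MUT) = ad,
    P(obs MUT | true WT) = fd, P(obs WT | true WT) = 1 - fd;
    MISSING entries contribute 1.
    """
    fd, ad = params.false_positive_rate, params.ado_rate
    m = len(tree.mutations)
    truth = np.zeros((tree.n_nodes, m))
    for node, cset in enumerate(tree.clone_sets()):
        for j, mut in enumerate(tree.mutations):
            truth[node, j] = 1.0 if mut in cset else 0.0
    obs = matrix  # (n_cells, m) in {1, 0, -1}
    # per (cell, node) log prob = sum_j log P(obs_ij | truth_kj)
    logp = np.zeros((obs.shape[0], tree.n_nodes))
    for k in range(tree.n_nodes):
        t = truth[k]
        p = np.where(
            obs == 1, np.where(t == 1, 1 - ad, fd),
            np.where(obs == 0, np.where(t == 1, ad, 1 - fd), 1.0))
        logp[:, k] = np.log(p).sum(axis=1)
    # marginalize attachment uniformly over nodes
    per_cell = np.logaddexp.reduce(logp, axis=1) - np.log(tree.n_nodes)
    return float(per_cell.sum())


def infer_clone_tree(matrix: np.ndarray, mutations,
                     params: TreeScoreParams | None = None
                     ) -> tuple[CloneTree, float]:
    """Maximum-likelihood mutation tree by exhaustive enumeration.

    Ties are broken toward fewer branch points (linear over branching), then
    by lexicographic parent vector.
    """
    params = params or TreeScoreParams()
    matrix = np.asarray(matrix)
    if matrix.size == 0 or (matrix == -1).all():
        raise InsufficientDataError("genotype matrix carries no information")
    best: tuple | None = None
    for tree in enumerate_trees(mutations):
        score = tree_log_likelihood(matrix, tree, params)
        key = (-score, tree.n_branch_points, tree.parent)
        if best is None or key < best[0]:
            best = (key, tree, score)
    assert best is not None
    return best[1], best[2]


@dataclass(frozen=True)
class CloneAssignment:
    cell_id: str
    clone_id: str | None
    node: int | None
    n_inferred_ancestral_ados: int
    confidence: str  # exact | ado_rescued | unassignable
    diagnostic: str = ""


def _path_order(tree: CloneTree, node: int) -> list[str]:
    """Mutations on the root->node path, in acquisition order."""
    path = []
    while node != 0:
        path.append(tree.mutations[node - 1])
        node = tree.parent[node - 1]
    return path[::-1]


def assign_cell(cell_id: str, calls: dict[str, str], tree: CloneTree,
                max_ancestral_ado: int = 1) -> CloneAssignment:
    """Assign one cell to a clone given its per-mutation consensus calls.

    ``calls`` maps mutation_id -> consensus in {MUT, WT, UNDETERMINED,
    MISSING}.  A clone is consistent when it contains every detected
    mutation and each of its extra mutations is either undetermined
    (missing data) or WT-called but ancestral to a detected mutation
    (counted as an inferred ancestral dropout, at most
    ``max_ancestral_ado``).  A unique consistent clone is assigned; several
    consistent clones (undetermined data at a tree-discriminating locus)
    or none (detected set inconsistent with the tree) are unassignable.
    """
    detected = {m for m, c in calls.items() if c == MUT}
    candidates = []
    for node, cset in enumerate(tree.clone_sets()):
        if not detected <= cset:
            continue
        path = _path_order(tree, node)
        deepest_detected = max(
            (i for i, m in enumerate(path) if m in detected), default=-1)
        n_ado = 0
        ok = True
        for m in cset - detected:
            call = calls.get(m, MISSING)
            if call in (UNDETERMINED, MISSING) or call is None:
                continue
            if call == WT and path.index(m) < deepest_detected:
                n_ado += 1  # ancestral mutation undetected: inferred dropout
            else:
                ok = False
                break
        if ok and n_ado <= max_ancestral_ado:
            candidates.append((node, cset, n_ado))
    if not candidates:
        return CloneAssignment(cell_id, None, None, 0, "unassignable",
                               "detected mutations inconsistent with the tree")
    if len(candidates) > 1:
        return CloneAssignment(
            cell_id, None, None, 0, "unassignable",
            "undetermined call at a tree-discriminating locus; "
            f"{len(candidates)} consistent clones")
    node, cset, n_ado = candidates[0]
    confidence = "ado_rescued" if n_ado > 0 else "exact"
    return CloneAssignment(cell_id, tree.clone_id(node), node, n_ado,
                           confidence)


def assign_cells(calls: pd.DataFrame, tree: CloneTree,
                 max_ancestral_ado: int = 1) -> pd.DataFrame:
    """Assign every cell in a consensus-call table to a clone.

    Returns one row per cell: clone_id, node, n_inferred_ancestral_ados,
    confidence, diagnostic.
    """
    records = []
    for cell, grp in calls.groupby("cell_id", sort=True):
        cell_calls = dict(zip(grp["mutation_id"], grp["consensus"]))
        a = assign_cell(str(cell), cell_calls, tree, max_ancestral_ado)
        records.append({
            "cell_id": a.cell_id, "clone_id": a.clone_id, "node": a.node,
            "n_inferred_ancestral_ados": a.n_inferred_ancestral_ados,
            "confidence": a.confidence, "diagnostic": a.diagnostic,
        })
    return pd.DataFrame.from_records(records)
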