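"""Motif-anchored core trimming, alignment, NJ trees, bootstrap, congruence.

Tree inference is distance-based: Poisson-corrected distances
(d = -ln(1 - p), the uniform-rates choice) over mutually ungapped columns,
canonical neighbor joining with deterministic tie-breaking, and
column-resampling bootstrap. The family phylogenies here serve clade-grouping
and co-evolution questions, for which NJ + bootstrap is sufficient and fully
oracle-testable; externally computed trees (Newick) can be substituted
anywhere a Tree is accepted.

The co-evolution check between two gene families (e.g. ORF1 against
TrpRS-A) is a permutation test on the Robinson-Foulds distance of the two
trees restricted to their shared leaves: the null shuffles leaf labels of
the second tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .aars import scan_class_i_motifs
from .tree import Node, Tree, _canonical_bipartitions

AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


def _blosum_matrix() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(AA_ORDER), len(AA_ORDER)))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            m[i, j] = mat[a][b]
    return m


_BLOSUM = _blosum_matrix()
_GAP_PENALTY = -4.0


@dataclass
class MSA:
    ids: list
    rows: dict                      # id -> gapped sequence
    high_anchor_cols: list = field(default_factory=list)   # 0-based columns
    abd_end_col: Optional[int] = None                      # 0-based

    @property
    def ncol(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace("-", "")

    def column(self, c: int) -> str:
        return "".join(self.rows[i][c] for i in self.ids)


# ------------------------------------------------------------------ alignment

def _kmer_set(seq: str, k: int = 3) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _profile(rows: list[str]) -> np.ndarray:
    """(ncol, 21) residue-frequency profile; gaps carry zero weight."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, len(AA_ORDER)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != "-":
                prof[c, _AA_INDEX[ch]] += 1
    sums = prof.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1
    return prof / sums


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Profile-profile Needleman-Wunsch (linear gap, deterministic traceback)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    score = pa @ _BLOSUM @ pb.T    # (la, lb) expected column score
    dp = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)   # 0 diag, 1 up (A col), 2 left
    dp[1:, 0] = _GAP_PENALTY * np.arange(1, la + 1)
    dp[0, 1:] = _GAP_PENALTY * np.arange(1, lb + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        diag = dp[i - 1, :-1] + score[i - 1]
        up = dp[i - 1, 1:] + _GAP_PENALTY
        row = dp[i]
        prev_best = np.maximum(diag, up)
        choice = np.where(diag >= up, 0, 1)
        # left moves require a sequential pass
        for j in range(1, lb + 1):
            left = row[j - 1] + _GAP_PENALTY
            best = prev_best[j - 1]
            if best >= left:
                dp[i, j] = best
                ptr[i, j] = choice[j - 1]
            else:
                dp[i, j] = left
                ptr[i, j] = 2
    out_a = [""] * len(rows_a)
    out_b = [""] * len(rows_b)
    i, j = la, lb
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            for r in range(len(rows_a)):
                out_a[r] = rows_a[r][i - 1] + out_a[r]
            for r in range(len(rows_b)):
                out_b[r] = rows_b[r][j - 1] + out_b[r]
            i, j = i - 1, j - 1
        elif move == 1:
            for r in range(len(rows_a)):
                out_a[r] = rows_a[r][i - 1] + out_a[r]
            for r in range(len(rows_b)):
                out_b[r] = "-" + out_b[r]
            i -= 1
        else:
            for r in range(len(rows_a)):
                out_a[r] = "-" + out_a[r]
            for r in range(len(rows_b)):
                out_b[r] = rows_b[r][j - 1] + out_b[r]
            j -= 1
    return out_a, out_b


def align_progressive(seqs: Sequence[tuple[str, str]]) -> MSA:
    """Progressive MSA: k-mer guide clustering, profile-profile merges.

    Input order does not matter: sequences are keyed and tie-broken by
    lexicographic id, so permuting the input yields the same alignment.
    """
    items = sorted(seqs, key=lambda t: t[0])
    if len({i for i, _ in items}) != len(items):
        raise ValueError("duplicate sequence ids")
    if len(items) == 1:
        (sid, s), = items
        return MSA([sid], {sid: s})

    kmers = {sid: _kmer_set(s) for sid, s in items}
    ids = [sid for sid, _ in items]
    dist = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = len(kmers[a] & kmers[b])
            union = len(kmers[a] | kmers[b]) or 1
            dist[(a, b)] = 1.0 - inter / union

    # UPGMA-style guide clustering with lexicographic tie-breaks
    clusters: dict[tuple, list[str]] = {(sid,): [sid] for sid in ids}
    cdist = {(min(a, b), max(a, b)): d for (a, b), d in dist.items()}

    def cd(ka: tuple, kb: tuple) -> float:
        vals = [cdist[(min(x, y), max(x, y))]
                for x in ka for y in kb]
        return sum(vals) / len(vals)

    aligned: dict[tuple, list[str]] = {(sid,): [s] for sid, s in items}
    members: dict[tuple, list[str]] = {(sid,): [sid] for sid in ids}
    keys = sorted(clusters)
    while len(keys) > 1:
        best = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                d = cd(ka, kb)
                cand = (d, ka, kb)
                if best is None or cand < best:
                    best = cand
        _, ka, kb = best
        rows_a, rows_b = _align_profiles(aligned[ka], aligned[kb])
        merged_key = tuple(sorted(ka + kb))
        aligned[merged_key] = rows_a + rows_b
        members[merged_key] = members[ka] + members[kb]
        for k in (ka, kb):
            del aligned[k], members[k]
            keys.remove(k)
        keys.append(merged_key)
        keys.sort()
    final_key = keys[0]
    rows = dict(zip(members[final_key], aligned[final_key]))
    msa = MSA(sorted(rows), rows)
    annotate_high_anchors(msa)
    return msa


def annotate_high_anchors(msa: MSA) -> None:
    """Locate the HIGH anchor columns (modal first-HIGH start across rows)."""
    starts: dict[int, list[str]] = {}
    res2col: dict[str, list[int]] = {}
    for rid in msa.ids:
        row = msa.rows[rid]
        cols = [c for c, ch in enumerate(row) if ch != "-"]
        res2col[rid] = cols
        hits = [h for h in scan_class_i_motifs(msa.ungapped(rid))
                if h.motif_name == "HIGH"]
        if hits:
            col = cols[hits[0].start - 1]
            starts.setdefault(col, []).append(rid)
    if not starts:
        msa.high_anchor_cols = []
        return
    modal_col = max(starts, key=lambda c: (len(starts[c]), -c))
    rid = min(starts[modal_col])
    hit = [h for h in scan_class_i_motifs(msa.ungapped(rid))
           if h.motif_name == "HIGH"][0]
    msa.high_anchor_cols = [res2col[rid][p - 1]
                            for p in range(hit.start, hit.end + 1)]


@dataclass
class TrimConfig:
    upstream_residues: int = 13
    abd_end: object = "infer_from_reference"   # 1-based column index or the flag
    max_gap_fraction: float = 0.5

    def __post_init__(self):
        if self.upstream_residues < 0:
            raise ValueError("upstream_residues must be >= 0")


def trim_to_core(msa: MSA, cfg: Optional[TrimConfig] = None,
                 reference_row: Optional[str] = None,
                 reference_abd_end: Optional[int] = None) -> MSA:
    """Trim an alignment to the catalytic-core window.

    The window runs from ``upstream_residues`` columns before the HIGH
    anchor (clamped at the first column) to the end of the anticodon-binding
    domain; inside the window, columns that are mostly gaps (> 50% by
    default) are dropped as non-conserved insertions, except the anchor
    columns themselves.
    """
    cfg = cfg or TrimConfig()
    if not msa.high_anchor_cols:
        annotate_high_anchors(msa)
    if not msa.high_anchor_cols:
        raise ValueError("no HIGH anchor in any row: run the motif scan / "
                         "check the sequences before trimming")
    anchor_start = msa.high_anchor_cols[0]
    start = max(anchor_start - cfg.upstream_residues, 0)
    if isinstance(cfg.abd_end, int):
        end = cfg.abd_end - 1   # 1-based -> 0-based
    elif reference_row is not None and reference_abd_end is not None:
        cols = [c for c, ch in enumerate(msa.rows[reference_row]) if ch != "-"]
        end = cols[min(reference_abd_end, len(cols)) - 1]
    else:
        raise ValueError("abd_end: give a column index or a reference row "
                         "with its ABD end residue")
    end = min(end, msa.ncol - 1)
    nrow = len(msa.ids)
    keep = []
    anchors = set(msa.high_anchor_cols)
    for c in range(start, end + 1):
        gapfrac = sum(1 for i in msa.ids if msa.rows[i][c] == "-") / nrow
        if c in anchors or gapfrac <= cfg.max_gap_fraction:
            keep.append(c)
    rows = {i: "".join(msa.rows[i][c] for c in keep) for i in msa.ids}
    new = MSA(list(msa.ids), rows)
    remap = {c: k for k, c in enumerate(keep)}
    new.high_anchor_cols = [remap[c] for c in msa.high_anchor_cols if c in remap]
    return new


# ------------------------------------------------------------------ distances

def distance_matrix(msa: MSA, min_shared: int = 20,
                    cap: float = 0.95) -> tuple[np.ndarray, list]:
    """Poisson-corrected distances d = -ln(1 - p) over mutually ungapped
    columns (the uniform-rates model); p is capped at 0.95 with a warning."""
    ids = list(msa.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 rows")
    arr = np.array([list(msa.rows[i]) for i in ids])
    gap = arr == "-"
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            ns = int(shared.sum())
            if ns < min_shared:
                raise ValueError(
                    f"pair ({ids[i]}, {ids[j]}) shares only {ns} ungapped "
                    f"columns (< {min_shared})")
            p = float((arr[i][shared] != arr[j][shared]).mean())
            if p > cap:
                warnings.warn(
                    f"pair ({ids[i]}, {ids[j]}): p-distance {p:.3f} capped at {cap}")
                p = cap
            D[i, j] = D[j, i] = -np.log(1.0 - p)
    return D, ids


# ------------------------------------------------------------------ NJ

def nj_tree(D: np.ndarray, ids: Sequence[str]) -> Tree:
    """Canonical neighbor joining; Q-matrix ties broken by smallest (i, j)."""
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = np.asarray(D, dtype=float).copy()
    nodes: list[Node] = [Node(label) for label in ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))            # row-major: smallest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        ni, nj_ = nodes[ai], nodes[aj]
        ni.length = max(li, 0.0)
        nj_.length = max(lj, 0.0)
        parent.add(ni)
        parent.add(nj_)
        # distances to the new node
        newdist = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = newdist
        D[active, k] = newdist
        D[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [k]

    a, b, c = active
    root = Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    return Tree(root)


# ------------------------------------------------------------------ bootstrap

@dataclass
class BootstrapResult:
    tree: Tree
    resolved: bool
    n_replicates: int
    n_used: int
    seed: int


def bootstrap_support(msa: MSA, n_replicates: int = 100,
                      seed: int = 0) -> BootstrapResult:
    """Column-resampling bootstrap supports on the NJ tree of an alignment.

    Supports are the percentage of replicates whose NJ tree contains each
    internal bipartition of the full-data tree. With zero divergence the
    data carry no signal and an unresolved star tree is reported.
    """
    if len(msa.ids) < 4:
        raise ValueError("need at least 4 rows for bootstrap supports")
    D, ids = distance_matrix(msa)
    if np.allclose(D, 0.0):
        root = Node()
        for label in ids:
            root.add(Node(label, 0.0))
        return BootstrapResult(Tree(root), False, n_replicates, 0, seed)
    tree = nj_tree(D, ids)
    universe = set(ids)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    ncol = msa.ncol
    arr = {i: msa.rows[i] for i in ids}
    n_used = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = {i: "".join(arr[i][c] for c in cols) for i in ids}
        try:
            Dr, _ = distance_matrix(MSA(list(ids), rep_rows))
        except ValueError:
            continue
        rep_tree = nj_tree(Dr, ids)
        n_used += 1
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    # attach supports to matching internal edges of the full tree
    below: dict[int, set] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.label}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
            if node.parent is not None:
                canon = _canonical_bipartitions([below[id(node)]], universe)
                if canon:
                    bp = next(iter(canon))
                    node.support = 100.0 * counts.get(bp, 0) / max(n_used, 1)
    return BootstrapResult(tree, True, n_replicates, n_used, seed)


# ------------------------------------------------------------------ clades

@dataclass
class CladeAssignment:
    label: Optional[str]
    rule: str                 # monophyletic / nearest / tie
    tied: list = field(default_factory=list)


def assign_clade(tree: Tree, labeled_leaves: dict, query_leaf: str) -> CladeAssignment:
    """Clade label for a query leaf among labelled reference leaves.

    Rule 1: the smallest bipartition side containing the query whose labelled
    members carry exactly one label. Rule 2 (fallback): nearest labelled
    leaf by path length; exact ties are reported, never silently resolved.
    """
    leaves = set(tree.leaf_labels())
    if query_leaf not in leaves:
        raise ValueError(f"query leaf {query_leaf!r} not in tree")
    if len(set(labeled_leaves.values())) < 1 or len(labeled_leaves) < 2:
        raise ValueError("need at least 2 labelled leaves")

    sides = tree._raw_sides()
    candidates = []
    for side in sides:
        for s in (side, leaves - side):
            if query_leaf not in s:
                continue
            labels = {labeled_leaves[x] for x in s
                      if x in labeled_leaves and x != query_leaf}
            if len(labels) == 1:
                candidates.append((len(s), next(iter(labels))))
    if candidates:
        candidates.sort()
        size0 = candidates[0][0]
        labels0 = sorted({lab for sz, lab in candidates if sz == size0})
        if len(labels0) == 1:
            return CladeAssignment(labels0[0], "monophyletic")
        return CladeAssignment(None, "tie", tied=labels0)

    dists: dict[str, float] = {}
    for leaf, lab in sorted(labeled_leaves.items()):
        if leaf == query_leaf:
            continue
        d = tree.path_length(query_leaf, leaf)
        if lab not in dists or d < dists[lab]:
            dists[lab] = d
    best = min(dists.values())
    near = sorted(lab for lab, d in dists.items() if abs(d - best) < 1e-12)
    if len(near) > 1:
        return CladeAssignment(None, "tie", tied=near)
    return CladeAssignment(near[0], "nearest")


# ------------------------------------------------------------------ congruence

@dataclass
class CongruenceResult:
    rf_distance: int
    normalized_rf: float
    permutation_p: float
    n_permutations: int
    n_shared_leaves: int
    seed: int


def congruence_test(tree_a: Tree, tree_b: Tree, n_perm: int = 999,
                    seed: int = 0) -> CongruenceResult:
    """Permutation test of topological congruence between two gene trees.

    RF distance is computed on the shared-leaf restriction; the null
    distribution permutes the leaf labels of the second tree. The p-value is
    (1 + #{permuted RF <= observed}) / (n_perm + 1); its minimum, reached
    when the trees are identical, is 1 / (n_perm + 1).
    """
    la, lb = set(tree_a.leaf_labels()), set(tree_b.leaf_labels())
    shared = sorted(la & lb)
    if len(shared) < 4:
        raise ValueError(f"trees share only {len(shared)} leaves (< 4)")
    index = {lab: i for i, lab in enumerate(shared)}
    m = len(shared)

    def to_index_sides(tree: Tree, universe: set) -> list[set]:
        sides = []
        for side in tree._raw_sides():
            s = {index[x] for x in side if x in index}
            sides.append(s)
        return sides

    def canon(sides: list[set]) -> frozenset:
        out = set()
        for s in sides:
            if 0 in s:
                s = set(range(m)) - s
            if 2 <= len(s) <= m - 2:
                out.add(frozenset(s))
        return frozenset(out)

    ba = canon(to_index_sides(tree_a, la))
    b_sides = to_index_sides(tree_b, lb)
    bb = canon(b_sides)
    observed = len(ba ^ bb)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        permuted = canon([{int(perm[x]) for x in s} for s in b_sides])
        if len(ba ^ permuted) <= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    denom = 2 * (m - 3) if m > 3 else 1
    return CongruenceResult(
        rf_distance=observed, normalized_rf=observed / denom,
        permutation_p=p, n_permutations=n_perm,
        n_shared_leaves=m, seed=seed)
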