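"""Distance-based window phylogenetics and topology weighting.

Neighbor-joining trees are built from pairwise-deletion absolute distances
over non-overlapping windows.  Window trees are summarized two ways:
monophyly counting (the fraction of outgroup-rooted trees in which a
predefined group forms a clade) and topology weighting -- for each window
tree, the fraction of one-tip-per-group tip combinations whose induced
outgroup-rooted subtree matches each of the possible rooted group
topologies (15 for four groups).  The 15 four-group topologies partition
into five classes by the position of the parental lineage: basal (the
species tree), sister to one of the three populations (candidate
admixture), or nested without a specific partner.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, HaplotypeAlignment


class TreeError(ValueError):
    pass


@dataclass
class Clade:
    """Minimal rooted tree node (binary after NJ; the root may be trifurcating)."""

    name: str | None = None
    length: float = 0.0
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node):
            if node.is_leaf():
                s = node.name
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths:
                s += f":{node.length:.6g}"
            return s

        return "(" + ",".join(fmt(c) for c in self.children) + ");" if not self.is_leaf() else fmt(self) + ";"


def parse_newick(text: str) -> Clade:
    """Parse a newick string into a :class:`Clade` (via dendropy)."""
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick")

    def convert(nd):
        c = Clade(
            name=nd.taxon.label.replace(" ", "_") if nd.taxon else None,
            length=nd.edge.length or 0.0,
        )
        c.children = [convert(ch) for ch in nd.child_nodes()]
        return c

    return convert(tree.seed_node)


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def distance_matrix(
    aln: HaplotypeAlignment, mode: str = "count", strict: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Pairwise-deletion absolute distances between haplotypes.

    ``count`` mode returns differing-site counts; ``per-site`` divides by
    the number of pairwise-complete sites.  Pairs with zero comparable
    sites are nan (an error in strict mode).
    """
    if aln.n_haps < 3:
        raise TreeError("need >= 3 sequences")
    H = aln.haps
    n = aln.n_haps
    d = np.zeros((n, n))
    for i in range(n):
        ok_i = H[i] != MISSING
        for j in range(i + 1, n):
            ok = ok_i & (H[j] != MISSING)
            n_comp = int(ok.sum())
            if n_comp == 0:
                if strict:
                    raise TreeError(f"no comparable sites between {aln.names[i]} and {aln.names[j]}")
                d[i, j] = d[j, i] = np.nan
                continue
            diff = int(np.sum(H[i][ok] != H[j][ok]))
            d[i, j] = d[j, i] = diff / n_comp if mode == "per-site" else diff
    return d, list(aln.names)


def nj_tree(d: np.ndarray, labels: list[str]) -> Clade:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking.

    Nodes are agglomerated by minimizing the Q criterion, ties broken by
    first (label-sorted) index pair.  Negative branch lengths are clamped
    to zero with the negative amount transferred to the sibling branch.
    The returned tree is rooted arbitrarily at the final trifurcation.
    """
    d = np.array(d, dtype=float)
    if np.any(np.isnan(d)):
        raise TreeError("distance matrix has undefined entries")
    n = len(labels)
    if n < 3:
        raise TreeError("need >= 3 taxa")
    order = np.argsort(np.array(labels, dtype=object), kind="stable")
    d = d[np.ix_(order, order)]
    nodes = [Clade(name=labels[i]) for i in order]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)  # argmin is row-major: first pair wins ties
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent = Clade(children=[ni, nj_])
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_d
        d[active, k] = new_d
        d[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = max(ln, 0.0)
    return Clade(children=[nodes[a], nodes[b], nodes[c]])


def root_at_outgroup(tree: Clade, outgroup: str) -> Clade:
    """Reorient an (arbitrarily rooted) tree so the outgroup tip hangs off the root."""
    # build undirected adjacency over fresh nodes
    adj: dict[int, list[int]] = {}
    names: dict[int, str | None] = {}
    counter = itertools.count()

    def walk(node, parent_id):
        nid = next(counter)
        names[nid] = node.name
        adj.setdefault(nid, [])
        if parent_id is not None:
            adj[nid].append(parent_id)
            adj[parent_id].append(nid)
        for c in node.children:
            walk(c, nid)
        return nid

    walk(tree, None)
    try:
        og = next(k for k, v in names.items() if v == outgroup)
    except StopIteration:
        raise TreeError(f"outgroup {outgroup!r} not in tree") from None

    def build(nid, parent):
        kids = [build(c, nid) for c in adj[nid] if c != parent]
        node = Clade(name=names[nid])
        # suppress unifurcations created by reorientation
        flat = []
        for k in kids:
            if k.name is None and len(k.children) == 1:
                flat.append(k.children[0])
            else:
                flat.append(k)
        node.children = flat
        return node

    attach = adj[og][0]  # outgroup's neighbour becomes the ingroup root
    ingroup = build(attach, og)
    return Clade(children=[Clade(name=outgroup), ingroup])


# ---------------------------------------------------------------------------
# Sliding windows


def sliding_trees(
    aln: HaplotypeAlignment,
    window_bp: int = 100_000,
    min_complete_sites: int = 100,
    mode: str = "count",
):
    """One NJ tree per non-overlapping window with enough complete sites.

    Windows with fewer than ``min_complete_sites`` sites at which every
    haplotype is called are skipped and counted.  Returns
    ``(list of (scaffold, start, end, Clade), n_skipped)``.
    """
    from .popstats import tile_windows

    out = []
    n_skipped = 0
    complete = np.all(aln.haps != MISSING, axis=0)
    for scaf, start, end in tile_windows(aln.scaffolds, aln.positions, window_bp):
        sel = (aln.scaffolds == scaf) & (aln.positions - 1 >= start) & (aln.positions - 1 < end)
        if int(complete[sel].sum()) < min_complete_sites:
            n_skipped += 1
            continue
        sub = aln.take_sites(np.flatnonzero(sel))
        d, labels = distance_matrix(sub, mode=mode)
        out.append((scaf, start, end, nj_tree(d, labels)))
    return out, n_skipped


def monophyly_frequencies(
    trees: list[Clade], groups: dict[str, set], outgroup: str
) -> pd.DataFrame:
    """Fraction of outgroup-rooted trees in which each group is a clade."""
    counts = {g: 0 for g in groups}
    n_used = 0
    for tree in trees:
        tips = set(tree.leaf_names())
        if outgroup not in tips or any(not set(g) <= tips for g in groups.values()):
            continue
        n_used += 1
        rooted = root_at_outgroup(tree, outgroup)
        clades = set()

        def collect(node):
            s = frozenset(node.leaf_names())
            clades.add(s)
            for c in node.children:
                collect(c)

        collect(rooted)
        for name, members in groups.items():
            if frozenset(members) in clades:
                counts[name] += 1
    return pd.DataFrame(
        {
            "group": list(groups),
            "frequency": [counts[g] / n_used if n_used else np.nan for g in groups],
            "n_trees": n_used,
        }
    )


# ---------------------------------------------------------------------------
# Topology enumeration, weighting, classification


def _canon(t) -> str:
    """Canonical string of a nested-tuple rooted topology."""
    if isinstance(t, str):
        return t
    return "(" + ",".join(sorted(_canon(c) for c in t)) + ")"


def enumerate_topologies(groups: list[str]) -> list[str]:
    """All rooted binary leaf-labeled topologies over the group labels.

    There are (2k - 3)!! of them for k labels: 3 for three groups, 15 for
    four, 105 for five.  Returned as canonical sorted-parenthesis strings
    in stable order.
    """
    groups = sorted(groups)
    if len(groups) < 2:
        raise TreeError("need >= 2 groups")
    trees = [groups[0]]
    # grow by attaching each next label onto every edge (including the root edge)
    for label in groups[1:]:
        new = []
        for t in trees:
            for spot in _attachment_points(t):
                new.append(_attach(t, spot, label))
        trees = new
    return sorted({_canon(t) for t in trees})


def _attachment_points(t, prefix=()):
    yield prefix  # the edge above t (root edge when prefix is empty)
    if not isinstance(t, str):
        for i, c in enumerate(t):
            yield from _attachment_points(c, prefix + (i,))


def _attach(t, spot, label):
    if not spot:
        return (t, label)
    i = spot[0]
    return tuple(_attach(c, spot[1:], label) if j == i else c for j, c in enumerate(t))


def _leafsets(root: Clade) -> dict[int, frozenset]:
    """id(node) -> set of tip names below it, computed once per tree."""
    out: dict[int, frozenset] = {}

    def walk(node):
        s = frozenset([node.name]) if node.is_leaf() else frozenset().union(
            *(walk(c) for c in node.children)
        )
        out[id(node)] = s
        return s

    walk(root)
    return out


def induced_topology(
    rooted: Clade, chosen: dict[str, str], leafsets: dict[int, frozenset] | None = None
) -> str:
    """Rooted topology induced by one chosen tip per group.

    ``rooted`` must already be outgroup-rooted; ``chosen`` maps tip name ->
    group label.  Returns the canonical topology string over group labels.
    """
    targets = frozenset(chosen)
    ls = leafsets if leafsets is not None else _leafsets(rooted)

    def restrict(node, s):
        while True:
            parts_raw = [(c, s & ls[id(c)]) for c in node.children]
            parts_raw = [(c, t) for c, t in parts_raw if t]
            if len(parts_raw) == 1:
                child, t = parts_raw[0]
                if child.is_leaf():
                    return chosen[child.name]
                node, s = child, t
                continue
            parts = []
            for child, t in parts_raw:
                if len(t) == 1:
                    parts.append(chosen[next(iter(t))])
                else:
                    parts.append(restrict(child, t))
            return "(" + ",".join(sorted(parts)) + ")"

    return restrict(rooted, targets)


def topology_weights(
    tree: Clade,
    tip_to_group: dict[str, str],
    outgroup: str,
    method: str = "exhaustive",
    n_samples: int = 10_000,
    seed: int = 0,
    exhaustive_threshold: int = 100_000,
) -> dict[str, float]:
    """Weight of each rooted group topology for one window tree.

    The weight of topology T is the fraction of one-tip-per-group
    combinations whose induced subtree (rooted by the outgroup) equals T.
    Exhaustive when the combination count is at most
    ``exhaustive_threshold`` (or method="exhaustive"), else Monte Carlo
    with ``n_samples`` draws.
    """
    groups: dict[str, list[str]] = {g: [] for g in set(tip_to_group.values())}
    tips = set(tree.leaf_names())
    for tip, g in tip_to_group.items():
        if tip in tips:
            groups[g].append(tip)
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise TreeError("every group needs >= 1 tip present in the tree")
    labels = sorted(groups)
    rooted = root_at_outgroup(tree, outgroup)
    n_comb = math.prod(len(groups[g]) for g in labels)
    weights: dict[str, float] = {t: 0.0 for t in enumerate_topologies(labels)}
    ls = _leafsets(rooted)
    if method == "exhaustive" or (method == "auto" and n_comb <= exhaustive_threshold):
        for combo in itertools.product(*(groups[g] for g in labels)):
            chosen = {tip: g for tip, g in zip(combo, labels)}
            weights[induced_topology(rooted, chosen, ls)] += 1.0
        total = float(n_comb)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            chosen = {
                groups[g][rng.integers(len(groups[g]))]: g for g in labels
            }
            weights[induced_topology(rooted, chosen, ls)] += 1.0
        total = float(n_samples)
    return {t: w / total for t, w in weights.items()}


def snp_windows_for_weighting(
    aln: HaplotypeAlignment, window_snps: int = 100, min_genotyped: int = 50
):
    """SNP-count windows for topology weighting.

    Consecutive blocks of ``window_snps`` SNPs; windows where any
    haplotype is genotyped at fewer than ``min_genotyped`` SNPs are
    dropped (windows, not samples).  Returns a list of column-index arrays.
    """
    out = []
    for scaf in pd.unique(aln.scaffolds):
        cols = np.flatnonzero(aln.scaffolds == scaf)
        for k in range(0, len(cols) - window_snps + 1, window_snps):
            idx = cols[k : k + window_snps]
            genotyped = (aln.haps[:, idx] != MISSING).sum(axis=1)
            if genotyped.min() >= min_genotyped:
                out.append(idx)
    return out


def classify_topology_groups(
    weights: dict[str, float],
    parent: str = "PARENT",
    populations: tuple = ("ASI", "EUR", "ME"),
) -> dict[str, float]:
    """Aggregate 4-group topology weights into the five canonical classes.

    A topology is a species tree when the parental lineage is basal (the
    root splits it from all populations); it supports admixture of one
    population when the parental lineage is that population's direct
    sister; every other placement is "other".  Class weights sum to the
    input total.
    """
    classes = {
        "species-tree": 0.0,
        **{f"{p}+parent": 0.0 for p in populations},
        "other": 0.0,
    }
    for topo, w in weights.items():
        classes[_topology_class(topo, parent, populations)] += w
    return classes


def _topology_class(topo: str, parent: str, populations: tuple) -> str:
    tree = _parse_topology(topo)
    if not isinstance(tree, list):
        raise TreeError(f"degenerate topology {topo!r}")
    # basal parent: the root-level split isolates the parental label
    if any(sub == parent for sub in tree):
        return "species-tree"

    sister = _cherry_partner(tree, parent)
    if sister in populations:
        return f"{sister}+parent"
    return "other"


def _parse_topology(s: str):
    """Parse a canonical topology string into nested lists/labels."""
    pos = 0

    def parse():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            parts = [parse()]
            while s[pos] == ",":
                pos += 1
                parts.append(parse())
            assert s[pos] == ")"
            pos += 1
            return parts
        start = pos
        while pos < len(s) and s[pos] not in ",()":
            pos += 1
        return s[start:pos]

    return parse()


def _cherry_partner(tree, parent):
    """Label cherried with `parent`, or None."""
    if isinstance(tree, str):
        return None
    if parent in tree:
        others = [x for x in tree if x != parent]
        if len(others) == 1 and isinstance(others[0], str):
            return others[0]
        return None
    for sub in tree:
        r = _cherry_partner(sub, parent)
        if r is not None:
            return r
    return None
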