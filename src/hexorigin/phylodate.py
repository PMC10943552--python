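"""Alignment-based phylogeny and divergence dating.

The pieces are deliberately simple and auditable:

* center-star multiple alignment ("once a gap, always a gap") built from
  pairwise global alignments against the sequence closest to all others;
* complete-deletion gap trimming and concatenation with partition records;
* p-distance, JC69 (nucleotide) and Poisson (protein) distance matrices;
* neighbor joining (Saitou & Nei 1987) with negative branch lengths clamped
  to zero and the deficit transferred to the sister branch, so patristic
  distances between the joined leaves are preserved;
* nonparametric bootstrap by alignment-column resampling;
* divergence dating by mean path length: node ages relative to the root are
  proportional to the mean root-to-tip path through each node, scaled
  through a user-supplied calibration interval on one node, so every other
  node receives an age interval rather than a false point estimate.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .align_core import (
    NUCLEOTIDE_SCORING,
    PROTEIN_SCORING,
    Scoring,
    global_align,
)


@dataclass
class Msa:
    names: tuple[str, ...]
    rows: tuple[str, ...]
    partitions: tuple[tuple[str, int, int], ...] = ()  # (name, start, end)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]


def _is_protein(seq: str) -> bool:
    return any(ch not in "ACGTN-" for ch in seq.upper())


def align_star(
    sequences: dict[str, str],
    scoring: Scoring | None = None,
    method: str = "edit",
) -> Msa:
    """Center-star multiple alignment.

    The center is the sequence with the highest summed pairwise alignment
    score against all others; every other sequence is aligned to it globally
    and the pairwise alignments are merged under "once a gap, always a gap".
    """
    names = list(sequences)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    if scoring is None:
        scoring = (PROTEIN_SCORING
                   if _is_protein(next(iter(sequences.values())))
                   else NUCLEOTIDE_SCORING)

    pair_aln = {}
    totals = dict.fromkeys(names, 0.0)
    for a, b in itertools.combinations(names, 2):
        aln = global_align(sequences[a], sequences[b], scoring, method=method)
        pair_aln[(a, b)] = aln
        totals[a] += aln.score
        totals[b] += aln.score
    center = max(names, key=lambda n: (totals[n], -names.index(n)))

    master = sequences[center]          # center row, gaps accumulate
    merged: dict[str, str] = {}
    for other in names:
        if other == center:
            continue
        key = (center, other) if (center, other) in pair_aln else (other, center)
        aln = pair_aln[key]
        if key[0] == center:
            c_aln, o_aln = aln.query_aligned, aln.target_aligned
        else:
            c_aln, o_aln = aln.target_aligned, aln.query_aligned
        master, merged, o_merged = _merge_into_master(
            master, merged, c_aln, o_aln)
        merged[other] = o_merged
    rows = tuple(master if n == center else merged[n] for n in names)
    return Msa(tuple(names), rows)


def _merge_into_master(master, merged, c_aln, o_aln):
    """Merge one pairwise alignment (center row ``c_aln``) into the running
    master alignment, inserting gap columns where the gap patterns differ."""
    out_master, out_other = [], []
    out_rows = {n: [] for n in merged}
    i = j = 0
    while i < len(master) or j < len(c_aln):
        m_ch = master[i] if i < len(master) else None
        c_ch = c_aln[j] if j < len(c_aln) else None
        if m_ch == c_ch or (m_ch is not None and c_ch is not None
                            and m_ch != "-" and c_ch != "-"):
            out_master.append(m_ch)
            out_other.append(o_aln[j])
            for n in merged:
                out_rows[n].append(merged[n][i])
            i += 1
            j += 1
        elif m_ch == "-":                 # gap already in master only
            out_master.append("-")
            out_other.append("-")
            for n in merged:
                out_rows[n].append(merged[n][i])
            i += 1
        else:                             # new gap introduced by this pair
            out_master.append("-")
            out_other.append(o_aln[j])
            for n in merged:
                out_rows[n].append("-")
            j += 1
    return (
        "".join(out_master),
        {n: "".join(v) for n, v in out_rows.items()},
        "".join(out_other),
    )


def codon_msa(cds_seqs: dict[str, str], method: str = "affine") -> Msa:
    """Codon-aware nucleotide alignment: the translated proteins are aligned
    with :func:`align_star` and the gap pattern is expanded 3-fold onto the
    coding sequences.

    Protein-level alignment is much more reliable than direct nucleotide
    alignment once sequences diverge beyond ~20%: unit-cost nucleotide
    alignment starts matching random positions through spurious gaps, which
    systematically compresses large distances (and therefore old node ages).
    """
    from .codons import translate

    prots = {}
    for name, cds in cds_seqs.items():
        if len(cds) % 3:
            raise ValueError(f"{name}: CDS length not a multiple of 3")
        p = translate(cds)
        prots[name] = p[:-1] if p.endswith("*") else p
    pmsa = align_star(prots, PROTEIN_SCORING, method=method)
    rows = []
    for name, row in zip(pmsa.names, pmsa.rows):
        cds = cds_seqs[name]
        out, i = [], 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[3 * i : 3 * i + 3])
                i += 1
        rows.append("".join(out))
    return Msa(pmsa.names, tuple(rows))


def trim_gaps(msa: Msa) -> Msa:
    """Complete deletion: drop every column containing a gap."""
    arr = np.array([list(r) for r in msa.rows])
    keep = ~(arr == "-").any(axis=0)
    rows = tuple("".join(row) for row in arr[:, keep])
    return Msa(msa.names, rows)


def concatenate(msas: dict[str, Msa]) -> Msa:
    """Concatenate alignments sharing the same taxa; records partitions."""
    if not msas:
        raise ValueError("nothing to concatenate")
    names = None
    parts = []
    rows = None
    offset = 0
    for pname, msa in msas.items():
        if names is None:
            names = msa.names
            rows = [""] * len(names)
        elif set(msa.names) != set(names):
            raise ValueError(f"partition {pname!r} has different taxa")
        for k, n in enumerate(names):
            rows[k] += msa.row(n)
        parts.append((pname, offset, offset + msa.length))
        offset += msa.length
    return Msa(names, tuple(rows), tuple(parts))


def distance_matrix(msa: Msa, model: str = "auto") -> np.ndarray:
    """Pairwise distances from an (ungapped-column) alignment.

    Models: ``p`` (raw proportion of differing columns), ``jc69``
    (nucleotide, d = -3/4 ln(1 - 4p/3)), ``poisson`` (protein,
    d = -ln(1 - p)); ``auto`` picks jc69 or poisson by alphabet. Sites where
    either row has a gap are skipped pairwise. Distances beyond the model's
    domain are clamped to a finite ceiling with a warning.
    """
    if model == "auto":
        model = "poisson" if _is_protein(msa.rows[0]) else "jc69"
    if model not in ("p", "jc69", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    n = len(msa.names)
    arr = np.array([list(r) for r in msa.rows])
    dist = np.zeros((n, n))
    clamped = False
    for i, j in itertools.combinations(range(n), 2):
        ok = (arr[i] != "-") & (arr[j] != "-")
        m = int(ok.sum())
        if m == 0:
            raise ValueError(
                f"no comparable sites between {msa.names[i]} and {msa.names[j]}")
        p = float(((arr[i] != arr[j]) & ok).sum()) / m
        if model == "p":
            d = p
        elif model == "jc69":
            if p >= 0.75:
                d, clamped = _JC_CEILING, True
            else:
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
        else:
            if p >= 1.0 - 1.0 / m:
                d, clamped = -math.log(1.0 / m), True
            else:
                d = -math.log(1.0 - p)
        dist[i, j] = dist[j, i] = d
    if clamped:
        warnings.warn(
            "some distances exceeded the correction's domain and were "
            "clamped; the sequences are saturated for this model",
            stacklevel=2,
        )
    return dist


def nj_tree(dist: np.ndarray, names: list[str]) -> dendropy.Tree:
    """Neighbor joining (Saitou & Nei 1987).

    Returns an unrooted dendropy tree. Negative branch lengths produced by
    the standard formulas are clamped to zero with the deficit moved to the
    sister branch so the joined pair's mutual distance is preserved.
    """
    n = len(names)
    if dist.shape != (n, n):
        raise ValueError("distance matrix / names size mismatch")
    if n < 3:
        raise ValueError("need at least three taxa")
    if not np.allclose(dist, dist.T) or (np.diag(dist) != 0).any():
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in names:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
    D = dist.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            li, lj = 0.0, D[i, j]
        if lj < 0:
            lj, li = 0.0, D[i, j]
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node to every remaining taxon
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    li = max(D[i, j], 0.0)
    if nodes[i].is_leaf() and not nodes[j].is_leaf():
        i, j = j, i
    # attach the last cherry: node i becomes the seed (root of the unrooted
    # tree), node j hangs off it with the full remaining distance
    nodes[i].add_child(nodes[j])
    nodes[j].edge.length = li
    tree.seed_node = nodes[i]
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    bips = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(all_taxa) - 1:
            bips.add(min(side, all_taxa - side, key=sorted))
    return bips


def bootstrap_support(
    msa: Msa,
    model: str = "auto",
    n_replicates: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """NJ tree plus bootstrap support (percent) for its bipartitions.

    Replicates resample alignment columns with replacement; support is the
    fraction of replicate NJ trees containing each original bipartition.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    tree = nj_tree(distance_matrix(msa, model), list(msa.names))
    target = _bipartitions(tree)
    counts = dict.fromkeys(target, 0)
    arr = np.array([list(r) for r in msa.rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, msa.length, size=msa.length)
        rep = Msa(msa.names,
                  tuple("".join(row) for row in arr[:, cols]))
        rep_bips = _bipartitions(
            nj_tree(distance_matrix(rep, model), list(rep.names)))
        for bip in target & rep_bips:
            counts[bip] += 1
    support = {b: 100.0 * c / n_replicates for b, c in counts.items()}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        key = min(side, all_taxa - side, key=sorted)
        if key in support:
            node.label = f"{support[key]:.0f}"
    return tree, support


@dataclass
class DatedNode:
    taxa: frozenset
    relative_age: float
    age_lo: float
    age_hi: float
    is_calibration: bool = False


def date_tree(
    tree: dendropy.Tree,
    outgroup: str,
    calibration_taxa: tuple[str, str],
    calibration_interval: tuple[float, float],
) -> list[DatedNode]:
    """Date internal nodes by mean path length.

    The tree is rooted by splitting the ``outgroup`` terminal edge at a
    clock-consistent point (the outgroup side gets half the mean patristic
    distance from the outgroup to every other leaf, clamped to the edge).
    Each internal node's relative age is then the mean branch-length path
    from the node to its descendant leaves. The most recent common ancestor
    of ``calibration_taxa`` is pinned to ``calibration_interval`` (lo, hi),
    and every other node's age interval is scaled proportionally:
    age = relative_age * interval / relative_age(cal).

    Splitting the edge (rather than rooting at the outgroup's attachment
    node) matters: an unrooted tree carries the entire outgroup divergence
    on its terminal branch, and a root placed at the attachment node would
    average one long root-to-outgroup path with many short ingroup paths,
    deflating the calibration depth and inflating every scaled age.
    """
    lo, hi = calibration_interval
    if not (0 < lo <= hi):
        raise ValueError("calibration interval must satisfy 0 < lo <= hi")
    tree = tree.clone(depth=1)
    pdm = tree.phylogenetic_distance_matrix()
    og = tree.find_node_with_taxon_label(outgroup)
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    others = [t for t in tree.taxon_namespace if t.label != outgroup]
    mean_patristic = float(np.mean(
        [pdm.patristic_distance(og.taxon, t) for t in others]))
    edge_len = og.edge.length or 0.0
    root_to_og = min(max(mean_patristic / 2.0, 0.0), edge_len)
    # Insert the root node on the outgroup edge by hand (library edge
    # rerooting is not length-preserving across versions), then reroot
    # there; suppressing the resulting degree-two old root merges edge
    # lengths, so every patristic distance is preserved.
    parent = og.parent_node
    parent.remove_child(og)
    split = dendropy.Node()
    parent.add_child(split)
    split.edge.length = edge_len - root_to_og
    split.add_child(og)
    og.edge.length = root_to_og
    tree.reroot_at_node(split, update_bipartitions=False)
    tree.suppress_unifurcations()
    tree.is_rooted = True

    def mpl(node) -> float:
        leaves = list(node.leaf_iter())
        total = 0.0
        for leaf in leaves:
            cur, d = leaf, 0.0
            while cur is not node:
                d += cur.edge.length or 0.0
                cur = cur.parent_node
            total += d
        return total / len(leaves)

    cal = tree.mrca(taxon_labels=list(calibration_taxa))
    if cal is None or cal.is_leaf():
        raise ValueError("calibration taxa do not define an internal node")
    cal_rel = mpl(cal)
    if cal_rel <= 0:
        raise ValueError("calibration node has zero relative age; the tree "
                         "has no signal at the calibration point")
    dated = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        rel = mpl(node)
        dated.append(DatedNode(
            taxa=frozenset(l.taxon.label for l in node.leaf_iter()),
            relative_age=rel,
            age_lo=rel * lo / cal_rel,
            age_hi=rel * hi / cal_rel,
            is_calibration=node is cal,
        ))
    return dated


_JC_CEILING = 5.0
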