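"""Independent brute-force oracles used by the property tests.

Everything here is deliberately naive (full enumeration, no dynamic
programming shared with the implementations under test) so agreement is
meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from hexorigin.align_core import Scoring
from hexorigin.codons import GENETIC_CODE


def brute_force_global_score(a: str, b: str, scoring: Scoring) -> float:
    """Best affine-gap global alignment score by recursive enumeration of
    every alignment (no memoization on score). Feasible for inputs ≤ ~8."""
    best = [-float("inf")]

    def rec(i: int, j: int, score: float, state: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + scoring.pair_score(a[i], b[j]), "m")
        # gap cost convention: the first gap position scores open_gap,
        # each following position extend_gap
        if i < len(a):  # gap in b (consume a)
            cost = scoring.extend_gap if state == "ga" else scoring.open_gap
            rec(i + 1, j, score + cost, "ga")
        if j < len(b):  # gap in a (consume b)
            cost = scoring.extend_gap if state == "gb" else scoring.open_gap
            rec(i, j + 1, score + cost, "gb")

    rec(0, 0, 0.0, "m")
    return best[0]


def brute_force_chain_score(anchors, max_gap: int, gap_penalty: float,
                            flip_b: bool = False) -> float:
    """Best collinear-chain score by enumerating every subset of anchors."""
    sign = -1 if flip_b else 1
    best = max(a.score for a in anchors)  # single-anchor chains always legal
    n = len(anchors)
    for r in range(2, n + 1):
        for combo in itertools.combinations(range(n), r):
            chain = sorted((anchors[k] for k in combo),
                           key=lambda x: (x.rank_a, sign * x.rank_b))
            score = chain[0].score
            ok = True
            for prev, cur in zip(chain, chain[1:]):
                da = cur.rank_a - prev.rank_a
                db = sign * (cur.rank_b - prev.rank_b)
                if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                    ok = False
                    break
                score += cur.score - gap_penalty * (da - 1 + db - 1)
            if ok:
                best = max(best, score)
    return best


def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """NG86 pathway-averaged (synonymous, nonsynonymous) difference counts
    for one codon pair, by direct enumeration of substitution orders.
    Paths passing through a stop codon are excluded; if every path does,
    all orders are averaged unfiltered."""
    diff = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff:
        return 0.0, 0.0

    def walk(order, filter_stops):
        cur, steps = codon_a, []
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1:]
            if filter_stops and GENETIC_CODE[nxt] == "*":
                return None
            steps.append((cur, nxt))
            cur = nxt
        return steps

    paths = [s for order in itertools.permutations(diff)
             if (s := walk(order, True)) is not None]
    if not paths:
        paths = [walk(order, False)
                 for order in itertools.permutations(diff)]
    syn = sum(1 for steps in paths for s, d in steps
              if GENETIC_CODE[s] == GENETIC_CODE[d])
    total = sum(len(steps) for steps in paths)
    return syn / len(paths), (total - syn) / len(paths)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary tree with positive branch lengths plus its exact
    additive (patristic) distance matrix.

    Returns (names, matrix, splits) where ``splits`` is the set of
    non-trivial bipartitions (each as a frozenset of the smaller side,
    min by sorted order).
    """
    import dendropy

    names = [f"T{k}" for k in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=_RngShim(rng))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    lut = {t.label: t for t in taxa}
    mat = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        d = pdm.patristic_distance(lut[names[i]], lut[names[j]])
        mat[i, j] = mat[j, i] = d
    all_taxa = frozenset(names)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < n_taxa - 1:
            splits.add(min(side, all_taxa - side, key=sorted))
    return names, mat, splits


class _RngShim:
    """random.Random-like facade over a numpy Generator (what dendropy's
    simulators expect)."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def random(self):
        return float(self._rng.random())

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def gauss(self, mu, sigma):
        return float(self._rng.normal(mu, sigma))

    def expovariate(self, lam):
        return float(self._rng.exponential(1.0 / lam))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(len(seq)))]

    def shuffle(self, x):
        self._rng.shuffle(x)
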