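"""Partitioning six homologous chromosomes into three heterozygous pairs.

An autoallohexaploid (A1 A1 A2 A2 B B) carries, in every homologous group,
six chromosomes forming three pairs; chromosomes within a pair are slightly
more similar to each other (here ~97.7% coding identity) than chromosomes
from different pairs (~97.2-97.3%). The partition is found by exhaustive
search over all 15 perfect matchings of the six chromosomes, maximising the
summed within-pair identity — a tiny search space, so no greedy heuristic is
needed (greedy pairing is provably wrong on adversarial matrices).

The B subgenome is then the pair most divergent from the other two; the two
A pairs are labelled A1/A2 in chromosome-name order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align_core import global_align
from .orthology import OrthologGroup, compute_group_identities
from .records import GeneRecord

def _perfect_matchings(items: tuple[int, ...]):
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for k, partner in enumerate(rest):
        remaining = rest[:k] + rest[k + 1 :]
        for sub in _perfect_matchings(remaining):
            yield ((first, partner),) + sub


#: the 15 perfect matchings of 6 items, each a tuple of 3 index pairs
ALL_PAIRINGS: tuple[tuple[tuple[int, int], ...], ...] = tuple(
    _perfect_matchings(tuple(range(6)))
)


@dataclass
class GroupPartition:
    chromosomes: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    labels: dict[str, str]          # chromosome -> A1 / A2 / B
    score: float                    # summed within-pair mean identity
    runner_up_score: float
    ambiguous: bool
    intra_pair_identity: float
    inter_pair_identity: float
    identity: np.ndarray = field(repr=False, default=None)


def identity_matrix(
    groups: list[OrthologGroup],
    records: dict[str, GeneRecord],
    chromosomes: list[str],
    method: str = "edit",
) -> np.ndarray:
    """Mean pairwise CDS identity between chromosomes over ortholog groups.

    Entry (i, j) is the mean, over all single-copy groups, of the global
    alignment identity between the group's gene on chromosome i and its gene
    on chromosome j. The diagonal is NaN.
    """
    n = len(chromosomes)
    index = {c: i for i, c in enumerate(chromosomes)}
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for group in groups:
        if not group.pair_identities:
            compute_group_identities(group, records, method=method)
        for (ga, gb), ident in group.pair_identities.items():
            ia = index.get(records[ga].chromosome)
            ib = index.get(records[gb].chromosome)
            if ia is None or ib is None or ia == ib:
                continue
            total[ia, ib] += ident
            total[ib, ia] += ident
            count[ia, ib] += 1
            count[ib, ia] += 1
    with np.errstate(invalid="ignore"):
        matrix = total / count
    np.fill_diagonal(matrix, np.nan)
    return matrix


def partition_subgenomes(
    matrix: np.ndarray,
    chromosomes: list[str],
    ambiguity_tolerance: float = 0.01,
) -> GroupPartition:
    """Best partition of six chromosomes into three pairs.

    Scores every one of the 15 perfect matchings by its summed within-pair
    identity and keeps the maximum; the partition is flagged ``ambiguous``
    when the runner-up is within ``ambiguity_tolerance`` (percentage points)
    of the winner. When all matchings tie (e.g. an autopolyploid with
    equidistant chromosomes) the lexicographically first pairing is returned
    with a warning.
    """
    if matrix.shape != (6, 6) or len(chromosomes) != 6:
        raise ValueError("subgenome partitioning expects six chromosomes")
    if np.isnan(matrix[~np.eye(6, dtype=bool)]).any():
        raise ValueError("identity matrix has missing off-diagonal entries")

    scored = sorted(
        ((sum(matrix[i, j] for i, j in pairing), pairing)
         for pairing in ALL_PAIRINGS),
        key=lambda t: (-t[0], t[1]),
    )
    best_score, best = scored[0]
    runner_up = scored[1][0]
    ambiguous = best_score - runner_up <= ambiguity_tolerance
    if best_score - scored[-1][0] <= ambiguity_tolerance:
        warnings.warn(
            "all pairings are equally good; chromosomes appear equidistant "
            "and the returned partition is arbitrary",
            stacklevel=2,
        )
        best = min(ALL_PAIRINGS)
        ambiguous = True

    pairs = tuple(
        tuple(sorted((chromosomes[i], chromosomes[j]))) for i, j in best
    )
    labels = label_subgenomes(matrix, chromosomes, best)
    intra = float(np.mean([matrix[i, j] for i, j in best]))
    mask = np.zeros((6, 6), dtype=bool)
    for i, j in best:
        mask[i, j] = mask[j, i] = True
    off = ~np.eye(6, dtype=bool) & ~mask
    inter = float(np.mean(matrix[off]))
    return GroupPartition(
        chromosomes=tuple(chromosomes),
        pairs=pairs,
        labels=labels,
        score=float(best_score),
        runner_up_score=float(runner_up),
        ambiguous=ambiguous,
        intra_pair_identity=intra,
        inter_pair_identity=inter,
        identity=matrix,
    )


def label_subgenomes(
    matrix: np.ndarray,
    chromosomes: list[str],
    pairing: tuple[tuple[int, int], ...],
    tolerance: float = 0.005,
) -> dict[str, str]:
    """Assign A1/A2/B labels to the three pairs of a partition.

    The B pair is the one whose mean identity to the other two pairs is
    lowest (the diverged diploid donor); the remaining pairs are A1 and A2
    in order of their first chromosome name. If the three between-pair
    identities are indistinguishable (within ``tolerance``), the topology is
    a star and labels fall back to name order with a warning.
    """
    between = {}
    for a, b in itertools.combinations(range(3), 2):
        vals = [matrix[i, j] for i in pairing[a] for j in pairing[b]]
        between[(a, b)] = between[(b, a)] = float(np.mean(vals))
    mean_to_others = [
        np.mean([between[(k, o)] for o in range(3) if o != k])
        for k in range(3)
    ]
    spread = max(between.values()) - min(between.values())
    if spread <= tolerance:
        warnings.warn(
            "between-pair identities are indistinguishable (star topology); "
            "subgenome labels assigned by name order",
            stacklevel=2,
        )
        order = sorted(range(3),
                       key=lambda k: min(chromosomes[i] for i in pairing[k]))
        names = dict(zip(order, ("A1", "A2", "B")))
    else:
        b_pair = int(np.argmin(mean_to_others))
        a_pairs = sorted(
            (k for k in range(3) if k != b_pair),
            key=lambda k: min(chromosomes[i] for i in pairing[k]),
        )
        names = {b_pair: "B", a_pairs[0]: "A1", a_pairs[1]: "A2"}
    return {
        chromosomes[i]: names[k]
        for k in range(3)
        for i in pairing[k]
    }


def summarize_group(
    groups: list[OrthologGroup],
    records: dict[str, GeneRecord],
    chromosomes: list[str],
    method: str = "edit",
    ambiguity_tolerance: float = 0.01,
) -> GroupPartition:
    """Identity matrix + partition + labels for one homologous group."""
    single = [g for g in groups if g.single_copy]
    if not single:
        raise ValueError("no single-copy ortholog groups to partition on")
    matrix = identity_matrix(single, records, chromosomes, method=method)
    return partition_subgenomes(matrix, chromosomes, ambiguity_tolerance)
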