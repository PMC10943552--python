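"""Karyotype correspondence, rearrangement counting, and inversions.

From synteny blocks between two genomes, this module derives the
chromosome-level correspondence map (which chromosome matches which, with
anchor fractions), classifies chromosomes as one-to-one or translocated,
counts the break and fusion operations needed to produce both karyotypes
from an explicit ancestor hypothesis, and detects inversions as runs of
reverse-orientation blocks.

Breaks and fusions are counted on gene-rank adjacencies of shared segments
(a segment is the syntenic content one chromosome of genome A shares with
one chromosome of genome B): along each branch ancestor -> descendant, every
ancestor adjacency missing in the descendant is one break and every
descendant adjacency missing in the ancestor is one fusion. No de novo
ancestral karyotype is reconstructed — counts are reported per supplied
hypothesis and are lower bounds for any unobserved true ancestor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .ksynteny import SyntenyBlock

#: a segment is identified by the chromosome pair that shares it
SegmentId = tuple[str, str]


@dataclass
class KaryotypeMap:
    """Chromosome correspondence between genome A and genome B.

    ``partners_a[chrom]`` lists (partner chromosome in B, anchor fraction)
    in positional order along ``chrom`` (and symmetrically for
    ``partners_b``). Partners carrying less than ``minor_threshold`` of a
    chromosome's anchors are dropped.
    """

    partners_a: dict[str, list[tuple[str, float]]]
    partners_b: dict[str, list[tuple[str, float]]]
    minor_threshold: float = 0.05
    classification_a: dict[str, str] = field(default_factory=dict)
    classification_b: dict[str, str] = field(default_factory=dict)

    def karyotype_a(self) -> dict[str, tuple[SegmentId, ...]]:
        """Genome A chromosomes as ordered tuples of shared segments."""
        return {c: tuple((c, p) for p, _ in parts)
                for c, parts in self.partners_a.items()}

    def karyotype_b(self) -> dict[str, tuple[SegmentId, ...]]:
        return {c: tuple((p, c) for p, _ in parts)
                for c, parts in self.partners_b.items()}


@dataclass
class RearrangementCount:
    ancestor: str
    breaks: int
    fusions: int
    events: list[dict]
    inversions: dict[tuple[str, str], int] = field(default_factory=dict)


def chromosome_correspondence(
    blocks: list[SyntenyBlock],
    minor_threshold: float = 0.05,
) -> KaryotypeMap:
    """Karyotype map from synteny blocks between two genomes.

    A partner's anchor fraction is its share of the chromosome's anchors in
    blocks; partners below ``minor_threshold`` are dropped. Partner order
    follows the mean anchor rank along the chromosome, so multi-partner
    chromosomes list their segments in positional order.
    """
    if not blocks:
        warnings.warn("no synteny blocks; correspondence map is empty",
                      stacklevel=2)
        return KaryotypeMap({}, {}, minor_threshold)

    counts: dict[tuple[str, str], int] = {}
    rank_sum_a: dict[tuple[str, str], float] = {}
    rank_sum_b: dict[tuple[str, str], float] = {}
    for block in blocks:
        key = (block.chrom_a, block.chrom_b)
        counts[key] = counts.get(key, 0) + block.n_anchors
        rank_sum_a[key] = rank_sum_a.get(key, 0.0) + sum(
            a.rank_a for a in block.anchors)
        rank_sum_b[key] = rank_sum_b.get(key, 0.0) + sum(
            a.rank_b for a in block.anchors)

    total_a: dict[str, int] = {}
    total_b: dict[str, int] = {}
    for (ca, cb), n in counts.items():
        total_a[ca] = total_a.get(ca, 0) + n
        total_b[cb] = total_b.get(cb, 0) + n

    partners_a: dict[str, list[tuple[str, float]]] = {}
    partners_b: dict[str, list[tuple[str, float]]] = {}
    for (ca, cb), n in counts.items():
        fa = n / total_a[ca]
        if fa >= minor_threshold:
            partners_a.setdefault(ca, []).append(
                (cb, fa, rank_sum_a[(ca, cb)] / n))
        fb = n / total_b[cb]
        if fb >= minor_threshold:
            partners_b.setdefault(cb, []).append(
                (ca, fb, rank_sum_b[(ca, cb)] / n))
    for parts in (partners_a, partners_b):
        for c in parts:
            parts[c] = [(p, f) for p, f, _ in
                        sorted(parts[c], key=lambda t: t[2])]
    return KaryotypeMap(
        {c: partners_a[c] for c in sorted(partners_a)},
        {c: partners_b[c] for c in sorted(partners_b)},
        minor_threshold,
    )


def karyotype_map_from_partner_lists(
    partners_a: dict[str, list[str]],
    fractions_a: dict[str, list[float]] | None = None,
) -> KaryotypeMap:
    """Encode a published correspondence (partner lists per chromosome of
    genome A) as a KaryotypeMap; anchor fractions default to equal shares.
    The reciprocal view is derived, ordered by genome A chromosome name."""
    pa = {}
    pb: dict[str, list[tuple[str, float]]] = {}
    for ca in sorted(partners_a):
        plist = partners_a[ca]
        fracs = (fractions_a[ca] if fractions_a is not None
                 else [1.0 / len(plist)] * len(plist))
        if len(fracs) != len(plist):
            raise ValueError(f"fractions for {ca} do not match partners")
        pa[ca] = list(zip(plist, fracs))
        for cb in plist:
            pb.setdefault(cb, []).append((ca, 0.0))
    for cb in pb:
        n = len(pb[cb])
        pb[cb] = [(ca, 1.0 / n) for ca, _ in pb[cb]]
    return KaryotypeMap(pa, {c: pb[c] for c in sorted(pb)})


def classify_chromosome_pairs(kmap: KaryotypeMap) -> KaryotypeMap:
    """Label every chromosome one_to_one or translocated (in place).

    A chromosome is one_to_one iff it has exactly one retained partner and
    that partner's only retained partner is it; the rule is symmetric, so
    transposing the genomes preserves the labels.
    """
    for view, other, out in (
        (kmap.partners_a, kmap.partners_b, kmap.classification_a),
        (kmap.partners_b, kmap.partners_a, kmap.classification_b),
    ):
        for chrom, parts in view.items():
            if len(parts) == 1:
                partner = parts[0][0]
                back = other.get(partner, [])
                if len(back) == 1 and back[0][0] == chrom:
                    out[chrom] = "one_to_one"
                    continue
            out[chrom] = "translocated"
    return kmap


#: the published H. tuberosus (subgenome A1 representatives) vs H. annuus
#: chromosome correspondence: 9 one-to-one chromosomes and 8 translocated
#: ones forming one 2-cycle ({06,15}) and two 3-cycles ({04,13,07} and
#: {12,16,17})
PRINTED_HTUB_HANN_MAP: dict[str, list[str]] = {
    **{f"chr{i:02d}": [f"chr{i:02d}"]
       for i in (1, 2, 3, 5, 8, 9, 10, 11, 14)},
    "chr04": ["chr04", "chr13"],
    "chr06": ["chr06", "chr15"],
    "chr07": ["chr07", "chr13"],
    "chr12": ["chr12", "chr16"],
    "chr13": ["chr07", "chr04"],
    "chr15": ["chr15", "chr06"],
    "chr16": ["chr16", "chr17"],
    "chr17": ["chr17", "chr12"],
}


def _adjacencies(karyotype: dict[str, tuple[SegmentId, ...]]) -> set[frozenset]:
    adj = set()
    for segs in karyotype.values():
        for x, y in zip(segs, segs[1:]):
            adj.add(frozenset((x, y)))
    return adj


def count_breaks_fusions(
    kmap: KaryotypeMap,
    ancestor: str | dict[str, tuple[SegmentId, ...]] = "genome_b",
) -> RearrangementCount:
    """Breaks and fusions needed to derive both karyotypes from an ancestor.

    ``ancestor`` is ``"genome_a"``, ``"genome_b"`` or an explicit karyotype
    (chromosome -> ordered segment tuple over the same segment set). Along
    each branch, breaks are ancestor segment adjacencies absent in the
    descendant and fusions are descendant adjacencies absent in the
    ancestor; totals are summed over both branches. The returned event list
    replays to both karyotypes (see :func:`replay_events`).
    """
    ka = kmap.karyotype_a()
    kb = kmap.karyotype_b()
    segs_a = {s for v in ka.values() for s in v}
    segs_b = {s for v in kb.values() for s in v}
    if segs_a != segs_b:
        raise ValueError(
            "inconsistent segment partition: the two views retain different "
            "segments (check the minor-signal threshold)")
    for name, kt in (("genome_a", ka), ("genome_b", kb)):
        flat = [s for v in kt.values() for s in v]
        if len(flat) != len(set(flat)):
            raise ValueError(f"{name} lists a segment more than once")

    if ancestor == "genome_a":
        anc, anc_name = ka, "genome_a"
    elif ancestor == "genome_b":
        anc, anc_name = kb, "genome_b"
    elif isinstance(ancestor, dict):
        anc, anc_name = ancestor, "explicit"
        flat = [s for v in anc.values() for s in v]
        if sorted(flat) != sorted(segs_a):
            raise ValueError(
                "explicit ancestor must cover exactly the shared segments")
    else:
        raise ValueError(f"unknown ancestor hypothesis {ancestor!r}")

    anc_adj = _adjacencies(anc)
    breaks = fusions = 0
    events: list[dict] = []
    for branch, desc in (("genome_a", ka), ("genome_b", kb)):
        desc_adj = _adjacencies(desc)
        for adj in sorted(anc_adj - desc_adj, key=sorted):
            breaks += 1
            events.append(dict(branch=branch, event="break",
                               adjacency=tuple(sorted(adj))))
        for adj in sorted(desc_adj - anc_adj, key=sorted):
            fusions += 1
            events.append(dict(branch=branch, event="fusion",
                               adjacency=tuple(sorted(adj))))
    return RearrangementCount(anc_name, breaks, fusions, events)


def replay_events(
    ancestor: dict[str, tuple[SegmentId, ...]],
    events: list[dict],
    branch: str,
) -> list[tuple[SegmentId, ...]]:
    """Apply one branch's break/fusion events to the ancestor karyotype.

    Returns the resulting chromosomes as segment tuples, canonicalized so
    each tuple (and the list) is orientation- and name-independent; compare
    against :func:`canonical_karyotype` of the target genome.
    """
    pieces = [list(v) for v in ancestor.values()]
    for ev in events:
        if ev["branch"] != branch:
            continue
        x, y = ev["adjacency"]
        if ev["event"] == "break":
            for k, piece in enumerate(pieces):
                for i in range(len(piece) - 1):
                    if {piece[i], piece[i + 1]} == {x, y}:
                        pieces[k : k + 1] = [piece[: i + 1], piece[i + 1:]]
                        break
                else:
                    continue
                break
            else:
                raise ValueError(f"break adjacency {x},{y} not found")
        else:
            left = next((k for k, p in enumerate(pieces)
                         if x in (p[0], p[-1])), None)
            right = next((k for k, p in enumerate(pieces)
                          if k != left and y in (p[0], p[-1])), None)
            if left is None or right is None:
                raise ValueError(f"fusion adjacency {x},{y} not applicable")
            a = pieces[left] if pieces[left][-1] == x else pieces[left][::-1]
            b = pieces[right] if pieces[right][0] == y else pieces[right][::-1]
            pieces = [p for k, p in enumerate(pieces)
                      if k not in (left, right)] + [a + b]
    return canonical_karyotype(pieces)


def canonical_karyotype(chromosomes) -> list[tuple[SegmentId, ...]]:
    """Orientation- and name-independent form: each chromosome as the
    lexicographically smaller of its two reading directions, sorted."""
    if isinstance(chromosomes, dict):
        chromosomes = chromosomes.values()
    return sorted(min(tuple(c), tuple(reversed(tuple(c)))) for c in chromosomes)


def detect_inversions(
    blocks: list[SyntenyBlock],
) -> tuple[int, list[tuple[int, int]]]:
    """Inversions between one chromosome pair.

    Blocks are ordered along genome A; every maximal run of "-"-orientation
    blocks counts as one inversion. Returns the count and each run's rank
    span on genome A.
    """
    if not blocks:
        raise ValueError("need at least one block for the chromosome pair")
    pair = {(b.chrom_a, b.chrom_b) for b in blocks}
    if len(pair) != 1:
        raise ValueError("blocks must all belong to one chromosome pair")
    ordered = sorted(blocks, key=lambda b: b.rank_span_a())
    spans = []
    run: list[SyntenyBlock] = []
    for block in ordered + [None]:
        if block is not None and block.orientation == "-":
            run.append(block)
        elif run:
            lo = min(b.rank_span_a()[0] for b in run)
            hi = max(b.rank_span_a()[1] for b in run)
            spans.append((lo, hi))
            run = []
    return len(spans), spans
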