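"""Synteny block detection and synonymous-rate (Ks) analysis.

* Anchors (homologous gene pairs with ordinal positions on their
  chromosomes) are chained per chromosome pair and orientation with a
  collinear sparse dynamic program; chains must be strictly monotone in both
  genomes and longer than ``min_anchors`` (the "more than 10 genes" rule).
* Ka/Ks per gene pair is estimated with the Nei-Gojobori (1986) method:
  per-position synonymous site fractions averaged over the two sequences,
  multi-difference codons averaged over all substitution orders with equal
  weights, Jukes-Cantor correction. NG86 is closed-form and checkable
  against a brute-force pathway oracle, unlike ML codon models.
* Ks peaks are located by Gaussian KDE on log10(Ks + 1e-4) (so a 0.03 peak
  and a 0.55 peak are both resolvable) with Silverman bandwidth, and mapped
  to polyploidization / divergence events by Ks windows. The ~0.03 window is
  ambiguous between the recent triplication and species divergence; it is
  disambiguated by the comparison type (within-genome paralogs vs
  between-genome orthologs), not by the Ks value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .codons import (
    BASE_INDEX,
    CODONS,
    GENETIC_CODE,
    PATHWAY_ND,
    PATHWAY_SD,
    SYN_SITES,
    jc_correct,
)


@dataclass(frozen=True)
class Anchor:
    id_a: str
    id_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float = 1.0

    def __post_init__(self):
        if self.rank_a < 0 or self.rank_b < 0:
            raise ValueError("anchor ranks must be non-negative")


@dataclass(frozen=True)
class SyntenyBlock:
    anchors: tuple[Anchor, ...]
    chrom_a: str
    chrom_b: str
    orientation: str  # "+" or "-"
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def rank_span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    def rank_span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)


@dataclass(frozen=True)
class KsEstimate:
    id_a: str
    id_b: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    valid: bool
    n_codons: int = 0


@dataclass
class KsPeak:
    mode: float
    height: float
    label: str = "unassigned"


# --------------------------------------------------------------------------
# NG86
# --------------------------------------------------------------------------

_STOP_IDX = np.array(
    [i for i, c in enumerate(CODONS) if GENETIC_CODE[c] == "*"])


def _codon_indices(cds: str) -> np.ndarray:
    """Codon table indices; -1 for codons containing non-ACGT symbols."""
    arr = np.frombuffer(cds.encode(), dtype=np.uint8)
    base = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        base[arr == ord(b)] = i
    tri = base.reshape(-1, 3)
    idx = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
    idx[(tri < 0).any(axis=1)] = -1
    return idx


def ng86_ka_ks(cds_a: str, cds_b: str, id_a: str = "a",
               id_b: str = "b") -> KsEstimate:
    """Nei-Gojobori (1986) Ka/Ks for an in-frame, gap-free codon alignment.

    Codon columns containing a gap/ambiguity symbol or a stop codon in
    either sequence are excluded from all counts. The estimate is flagged
    invalid when ps or pn reaches the Jukes-Cantor domain edge (3/4).
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be codon-aligned to equal length")
    if len(cds_a) % 3:
        raise ValueError("alignment length is not a multiple of 3")
    ia = _codon_indices(cds_a)
    ib = _codon_indices(cds_b)
    keep = (ia >= 0) & (ib >= 0)
    keep &= ~np.isin(ia, _STOP_IDX) & ~np.isin(ib, _STOP_IDX)
    ia, ib = ia[keep], ib[keep]
    n_codons = int(ia.size)
    if n_codons == 0:
        raise ValueError("no comparable codons")
    s_sites = float(0.5 * (SYN_SITES[ia].sum() + SYN_SITES[ib].sum()))
    n_sites = 3.0 * n_codons - s_sites
    sd = float(PATHWAY_SD[ia, ib].sum())
    nd = float(PATHWAY_ND[ia, ib].sum())
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    valid = ps < 0.75 and pn < 0.75
    ks = jc_correct(ps) if ps < 0.75 else math.nan
    ka = jc_correct(pn) if pn < 0.75 else math.nan
    return KsEstimate(id_a, id_b, s_sites, n_sites, sd, nd, ps, pn,
                      ks, ka, valid, n_codons)


def codon_align(cds_a: str, cds_b: str, method: str = "affine"):
    """Codon-align two coding sequences by globally aligning their proteins
    and expanding the gap pattern back onto the nucleotides (3 nt per
    residue). Returns the two gapped CDS strings."""
    from .align_core import PROTEIN_SCORING, global_align
    from .codons import translate

    if len(cds_a) % 3 or len(cds_b) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    pa, pb = translate(cds_a), translate(cds_b)
    pa = pa[:-1] if pa.endswith("*") else pa
    pb = pb[:-1] if pb.endswith("*") else pb
    aln = global_align(pa, pb, PROTEIN_SCORING, method=method)

    def expand(gapped: str, cds: str) -> str:
        out, i = [], 0
        for ch in gapped:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[3 * i : 3 * i + 3])
                i += 1
        return "".join(out)

    return expand(aln.query_aligned, cds_a), expand(aln.target_aligned, cds_b)


def ng86_from_cds(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b",
                  method: str = "edit") -> KsEstimate:
    """Codon-align two (possibly unequal-length) CDS and run NG86; gap
    columns are excluded by the estimator."""
    aa, ab = codon_align(cds_a, cds_b, method=method)
    return ng86_ka_ks(aa, ab, id_a, id_b)


# --------------------------------------------------------------------------
# anchor chaining
# --------------------------------------------------------------------------

def _best_chain(anchors: list[Anchor], max_gap: int, gap_penalty: float,
                flip_b: bool = False) -> tuple[float, list[int]]:
    """Maximum-scoring strictly collinear chain (rank_a increasing, rank_b
    increasing, or decreasing with ``flip_b``) over ``anchors``; quadratic
    sparse DP. Returns (score, index list)."""
    sign = -1 if flip_b else 1
    order = sorted(range(len(anchors)),
                   key=lambda k: (anchors[k].rank_a, sign * anchors[k].rank_b))
    best = [anchors[order[k]].score for k in range(len(order))]
    back = [-1] * len(order)
    for k in range(len(order)):
        ak = anchors[order[k]]
        for j in range(k):
            aj = anchors[order[j]]
            da = ak.rank_a - aj.rank_a
            db = sign * (ak.rank_b - aj.rank_b)
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            cand = best[j] + ak.score - gap_penalty * (da - 1 + db - 1)
            if cand > best[k]:
                best[k] = cand
                back[k] = j
    k = int(np.argmax(best))
    chain = []
    while k >= 0:
        chain.append(order[k])
        k = back[k]
    chain.reverse()
    return float(max(best)), chain


def chain_anchors(
    anchors: list[Anchor],
    max_gap: int = 25,
    min_anchors: int = 10,
    gap_penalty: float = 0.05,
) -> list[SyntenyBlock]:
    """Chain anchors into synteny blocks.

    Per chromosome pair and orientation, maximum-scoring collinear chains
    are extracted greedily (best chain first, its anchors removed, repeat);
    each anchor joins at most one block. A chain is kept only when its
    anchor count is strictly greater than ``min_anchors`` ("blocks with more
    than 10 genes"). Orientation "-" chains have ranks increasing in genome
    A and decreasing in genome B.
    """
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    seen = set()
    for a in anchors:
        key = (a.id_a, a.id_b)
        if key in seen:
            raise ValueError(f"duplicate anchor for gene pair {key}")
        seen.add(key)
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (ca, cb), pool in sorted(by_pair.items()):
        pool = list(pool)
        while len(pool) > min_anchors:
            fwd_score, fwd = _best_chain(pool, max_gap, gap_penalty)
            rev_score, rev = _best_chain(pool, max_gap, gap_penalty,
                                         flip_b=True)
            if fwd_score >= rev_score:
                orientation, chain, score = "+", fwd, fwd_score
            else:
                orientation, chain, score = "-", rev, rev_score
            if len(chain) <= min_anchors:
                break
            chosen = [pool[k] for k in chain]
            blocks.append(SyntenyBlock(
                anchors=tuple(chosen), chrom_a=ca, chrom_b=cb,
                orientation=orientation, score=score))
            used = set(chain)
            pool = [a for k, a in enumerate(pool) if k not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, -b.score))
    return blocks


def anchors_from_records(pairs, records) -> list[Anchor]:
    """Anchors from (gene_id_a, gene_id_b[, score]) pairs using the ranks
    and chromosomes recorded on the gene records."""
    anchors = []
    for pair in pairs:
        ga, gb = pair[0], pair[1]
        score = float(pair[2]) if len(pair) > 2 else 1.0
        ra, rb = records[ga], records[gb]
        anchors.append(Anchor(ga, gb, ra.chromosome, rb.chromosome,
                              ra.rank, rb.rank, score))
    return anchors


def block_ks(block: SyntenyBlock, records,
             method: str = "edit") -> list[KsEstimate]:
    """NG86 estimates for every anchor pair of a block."""
    return [
        ng86_from_cds(records[a.id_a].cds, records[a.id_b].cds,
                      a.id_a, a.id_b, method=method)
        for a in block.anchors
    ]


# --------------------------------------------------------------------------
# Ks peaks
# --------------------------------------------------------------------------

_LOG_EPS = 1e-4


def ks_distribution_peaks(
    ks_values,
    bw_method="silverman",
    min_values: int = 20,
    grid_points: int = 512,
) -> list[KsPeak]:
    """Modes of the Ks distribution.

    A Gaussian KDE is fit to log10(Ks + 1e-4); local maxima of the density
    are mapped back to Ks units and returned sorted by density height
    (highest first). Requires at least ``min_values`` finite values.
    """
    vals = np.asarray([v for v in ks_values if np.isfinite(v) and v >= 0.0],
                      dtype=float)
    if vals.size < min_values:
        raise ValueError(
            f"need at least {min_values} valid Ks values, got {vals.size}")
    x = np.log10(vals + _LOG_EPS)
    if np.ptp(x) < 1e-12:
        return [KsPeak(mode=float(vals[0]), height=math.inf)]
    kde = gaussian_kde(x, bw_method=bw_method)
    lo, hi = x.min() - 0.25, x.max() + 0.25
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.flatnonzero(interior) + 1
    peaks = [
        KsPeak(mode=float(10.0 ** grid[i] - _LOG_EPS), height=float(dens[i]))
        for i in idx
    ]
    peaks.sort(key=lambda p: -p.height)
    return peaks


#: default Ks windows for the study system's polyploidization history
DEFAULT_KS_WINDOWS: dict[str, tuple[float, float]] = {
    "WGT1": (1.0, 1.8),     # old whole-genome triplication, peak ~1.4
    "WGD2": (0.3, 0.8),     # whole-genome duplication, peak ~0.55
    "recent": (0.005, 0.1),  # recent WGT (~0.03) / species divergence (~0.035)
}


def classify_wgd_peaks(
    peaks: list[KsPeak],
    comparison: str = "intra",
    windows: dict[str, tuple[float, float]] | None = None,
) -> list[KsPeak]:
    """Label peaks by Ks window.

    The "recent" window (~0.03) cannot be attributed by Ks value alone: for
    within-genome paralog pairs (``comparison="intra"``) it is the recent
    whole-genome triplication (WGT3); for between-genome ortholog pairs
    (``comparison="inter"``) it is species divergence. Peaks outside every
    window stay "unassigned".
    """
    if comparison not in ("intra", "inter"):
        raise ValueError("comparison must be 'intra' or 'inter'")
    if windows is None:
        windows = DEFAULT_KS_WINDOWS
    spans = sorted(windows.items(), key=lambda kv: kv[1])
    for (na, (a0, a1)), (nb, (b0, b1)) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError(f"windows {na!r} and {nb!r} overlap")
    out = []
    for peak in peaks:
        label = "unassigned"
        for name, (lo, hi) in windows.items():
            if lo <= peak.mode <= hi:
                label = name
                break
        if label == "recent":
            label = "WGT3" if comparison == "intra" else "divergence"
        out.append(KsPeak(peak.mode, peak.height, label))
    return out
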