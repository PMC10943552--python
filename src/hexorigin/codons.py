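"""Genetic-code tables shared by the sequence simulator and the Ka/Ks estimator.

Codons are indexed 0..63 with base order A, C, G, T (codon index =
16*b1 + 4*b2 + b3). Site-counting conventions follow Nei & Gojobori (1986):
for every position of a sense codon, each of the three possible single-nucleotide
changes is classified as synonymous or nonsynonymous; changes that would create
a stop codon count as nonsynonymous, so synonymous + nonsynonymous site
fractions always sum to exactly 1 per position (3 per codon).
"""

from __future__ import annotations

import itertools

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

def _standard_code():
    from Bio.Data.CodonTable import standard_dna_table

    code = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        code[stop] = "*"
    return code


#: standard genetic code, '*' for stops
GENETIC_CODE = _standard_code()

CODONS = [BASES[i // 16] + BASES[(i // 4) % 4] + BASES[i % 4] for i in range(64)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")

#: amino acid per codon index ('*' for stops)
AA_BY_INDEX = np.array([GENETIC_CODE[c] for c in CODONS])


def codon_index(codon: str) -> int:
    return CODON_INDEX[codon]


def translate(cds: str, to_stop: bool = False) -> str:
    """Translate an in-frame nucleotide sequence.

    With ``to_stop`` the protein is truncated at the first stop codon,
    mirroring what a ribosome (and an emitted protein FASTA record for a
    lesioned gene copy) would produce.
    """
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        aa = GENETIC_CODE.get(cds[i : i + 3], "X")
        if aa == "*" and to_stop:
            break
        aas.append(aa)
    return "".join(aas)


def encode_codons(cds: str) -> np.ndarray:
    """Encode an in-frame sequence as an int array of codon indices."""
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    arr = np.frombuffer(cds.encode(), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        idx[arr == ord(b)] = i
    if (idx < 0).any():
        raise ValueError("non-ACGT symbol in coding sequence")
    return idx[0::3] * 16 + idx[1::3] * 4 + idx[2::3]


def _neighbors(codon: str, pos: int):
    for b in BASES:
        if b != codon[pos]:
            yield codon[:pos] + b + codon[pos + 1 :]


def _syn_fraction_tables():
    """Per-codon, per-position fraction of one-step changes that are synonymous.

    Stops get NaN; changes producing a stop are nonsynonymous.
    """
    syn = np.full((64, 3), np.nan)
    for i, codon in enumerate(CODONS):
        aa = GENETIC_CODE[codon]
        if aa == "*":
            continue
        for pos in range(3):
            n_syn = sum(
                1
                for nb in _neighbors(codon, pos)
                if GENETIC_CODE[nb] == aa  # stop neighbours are nonsynonymous
            )
            syn[i, pos] = n_syn / 3.0
    return syn


#: (64, 3) fraction of synonymous one-step changes per codon position
SYN_FRACTION = _syn_fraction_tables()

#: (64,) synonymous sites per codon (sum over the three positions)
SYN_SITES = SYN_FRACTION.sum(axis=1)


def _pathway_tables():
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    For each ordered codon pair, differences are classified by averaging over
    all substitution orders with equal weight, skipping paths that pass
    through a stop codon (if every path does, all orders are averaged anyway
    so the pair still contributes its full difference count).
    """
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, a in enumerate(CODONS):
        if GENETIC_CODE[a] == "*":
            sd[i, :] = nd[i, :] = np.nan
            continue
        for j, b in enumerate(CODONS):
            if GENETIC_CODE[b] == "*":
                sd[i, j] = nd[i, j] = np.nan
                continue
            diff_pos = [p for p in range(3) if a[p] != b[p]]
            if not diff_pos:
                continue
            paths = []
            for order in itertools.permutations(diff_pos):
                cur = a
                steps = []
                ok = True
                for p in order:
                    nxt = cur[:p] + b[p] + cur[p + 1 :]
                    if GENETIC_CODE[nxt] == "*":
                        ok = False
                        break
                    steps.append((cur, nxt))
                    cur = nxt
                if ok:
                    paths.append(steps)
            if not paths:
                # all intermediates are stops; fall back to unfiltered paths
                for order in itertools.permutations(diff_pos):
                    cur = a
                    steps = []
                    for p in order:
                        nxt = cur[:p] + b[p] + cur[p + 1 :]
                        steps.append((cur, nxt))
                        cur = nxt
                    paths.append(steps)
            s_tot = n_tot = 0.0
            for steps in paths:
                for src, dst in steps:
                    if GENETIC_CODE[src] == GENETIC_CODE[dst]:
                        s_tot += 1
                    else:
                        n_tot += 1
            sd[i, j] = s_tot / len(paths)
            nd[i, j] = n_tot / len(paths)
    return sd, nd


#: (64, 64) pathway-averaged synonymous / nonsynonymous difference counts
PATHWAY_SD, PATHWAY_ND = _pathway_tables()


def jc_forward(branch_length: float) -> float:
    """Expected observed proportion of differing sites after ``branch_length``
    substitutions per site under the Jukes-Cantor model."""
    return 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance for an observed difference proportion ``p``."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise ValueError("p-distance out of JC69 domain (p >= 0.75)")
    return -0.75 * float(np.log(arg))
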