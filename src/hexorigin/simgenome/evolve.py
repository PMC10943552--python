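"""Sequence evolution for the synthetic hexaploid generator.

Two generators are provided:

* :func:`evolve_sequence` — Jukes-Cantor evolution for a branch of a given
  expected length (substitutions/site). The end state is sampled directly
  from the JC transition probabilities, which is exact and composes across
  consecutive branches. An optional codon mode applies an elevated rate to
  third codon positions.
* :func:`mutate_pair_at_ks` — produces a partner sequence at a target
  synonymous divergence (Ks) and nonsynonymous divergence (Ka). Differences
  are planted per position with probability p*(K) x (fraction of one-step
  changes at that position that are synonymous/nonsynonymous), where p* is
  the JC forward transform, so the expected Nei-Gojobori ps equals p* and
  the downstream NG86 estimator is unbiased by construction.

Coding-sequence wrappers keep the start and stop codons fixed and avoid
creating internal stop codons, so translations stay full length unless a
lesion is planted deliberately.
"""

from __future__ import annotations

import numpy as np

from ..codons import (
    BASES,
    BASE_INDEX,
    CODONS,
    GENETIC_CODE,
    SYN_FRACTION,
    jc_forward,
)

_BASE_ARR = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    if (out < 0).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return out


def _decode(idx: np.ndarray) -> str:
    return _BASE_ARR[idx].tobytes().decode()


def evolve_sequence(
    seq: str,
    branch_length: float,
    rng: np.random.Generator,
    codon_mode: bool = False,
    third_pos_multiplier: float = 4.0,
) -> str:
    """Evolve ``seq`` along a branch of ``branch_length`` expected
    substitutions per site under Jukes-Cantor.

    In codon mode, third positions receive ``third_pos_multiplier`` times the
    rate of first/second positions while the sequence-wide expected number of
    substitutions per site stays ``branch_length``.
    """
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    idx = _encode(seq)
    if branch_length == 0:
        return seq
    n = idx.size
    if codon_mode:
        if n % 3:
            raise ValueError("codon mode requires length divisible by 3")
        r12 = 3.0 * branch_length / (2.0 + third_pos_multiplier)
        p = np.empty(n)
        p[0::3] = jc_forward(r12)
        p[1::3] = jc_forward(r12)
        p[2::3] = jc_forward(third_pos_multiplier * r12)
    else:
        p = np.full(n, jc_forward(branch_length))
    hit = rng.random(n) < p
    shift = rng.integers(1, 4, size=int(hit.sum()))
    idx[hit] = (idx[hit] + shift) % 4
    return _decode(idx)


def _fix_internal_stops(idx: np.ndarray, original: np.ndarray,
                        rng: np.random.Generator) -> None:
    """Redraw mutated positions inside codons that became stop codons.

    The replacement stays different from the original base so the realised
    substitution count is preserved; if no stop-free alternative exists the
    mutation is reverted (vanishingly rare).
    """
    n_codons = idx.size // 3
    for ci in range(n_codons):
        s = 3 * ci
        codon = _decode(idx[s : s + 3])
        if GENETIC_CODE[codon] != "*":
            continue
        mutated = [p for p in range(3) if idx[s + p] != original[s + p]]
        fixed = False
        for p in mutated:
            for alt in rng.permutation(4):
                if alt == original[s + p] or alt == idx[s + p]:
                    continue
                trial = idx[s : s + 3].copy()
                trial[p] = alt
                if GENETIC_CODE[_decode(trial)] != "*":
                    idx[s + p] = alt
                    fixed = True
                    break
            if fixed:
                break
        if not fixed and mutated:
            idx[s + mutated[0]] = original[s + mutated[0]]


def evolve_cds(
    cds: str,
    branch_length: float,
    rng: np.random.Generator,
    codon_mode: bool = False,
    third_pos_multiplier: float = 4.0,
) -> str:
    """Evolve a coding sequence, keeping the first and last codon fixed and
    avoiding the creation of internal stop codons."""
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    if len(cds) <= 6 or branch_length == 0:
        return cds
    head, core, tail = cds[:3], cds[3:-3], cds[-3:]
    original = _encode(core)
    evolved = _encode(
        evolve_sequence(core, branch_length, rng, codon_mode, third_pos_multiplier)
    )
    _fix_internal_stops(evolved, original, rng)
    return head + _decode(evolved) + tail


def _alternative_tables():
    """Per codon and position: synonymous and nonsynonymous (non-stop)
    replacement bases."""
    syn_alts: list[list[list[int]]] = []
    nonsyn_alts: list[list[list[int]]] = []
    for codon in CODONS:
        aa = GENETIC_CODE[codon]
        s_row, n_row = [], []
        for pos in range(3):
            s_opts, n_opts = [], []
            if aa != "*":
                for bi, b in enumerate(BASES):
                    if b == codon[pos]:
                        continue
                    nb = codon[:pos] + b + codon[pos + 1 :]
                    nb_aa = GENETIC_CODE[nb]
                    if nb_aa == aa:
                        s_opts.append(bi)
                    elif nb_aa != "*":
                        n_opts.append(bi)
            s_row.append(s_opts)
            n_row.append(n_opts)
        syn_alts.append(s_row)
        nonsyn_alts.append(n_row)
    return syn_alts, nonsyn_alts


_SYN_ALTS, _NONSYN_ALTS = _alternative_tables()

#: per codon/position fraction of one-step changes that are nonsynonymous
#: and stop-free (used as planting weights for nonsynonymous differences)
_NONSTOP_NONSYN_FRACTION = np.zeros((64, 3))
for _i in range(64):
    for _p in range(3):
        _NONSTOP_NONSYN_FRACTION[_i, _p] = len(_NONSYN_ALTS[_i][_p]) / 3.0


def mutate_pair_at_ks(
    cds: str,
    ks: float,
    ka: float,
    rng: np.random.Generator,
    nonsyn_protected_codons: np.ndarray | None = None,
) -> str:
    """Return a copy of ``cds`` at target synonymous divergence ``ks`` and
    nonsynonymous divergence ``ka`` (substitutions per synonymous /
    nonsynonymous site).

    ``nonsyn_protected_codons`` is an optional boolean mask (one entry per
    codon) marking codons under strong purifying selection: no nonsynonymous
    change is planted there (used for conserved domain motifs).

    The first and last codons are never touched.
    """
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    if ks < 0 or ka < 0:
        raise ValueError("divergence targets must be non-negative")
    ps = jc_forward(ks)
    pn = jc_forward(ka)
    idx = _encode(cds)
    n_codons = idx.size // 3
    codon_idx = idx[0::3] * 16 + idx[1::3] * 4 + idx[2::3]
    protected = (
        np.zeros(n_codons, dtype=bool)
        if nonsyn_protected_codons is None
        else np.asarray(nonsyn_protected_codons, dtype=bool)
    )
    u = rng.random((n_codons, 3))
    for ci in range(1, n_codons - 1):
        c = int(codon_idx[ci])
        if GENETIC_CODE[CODONS[c]] == "*":
            continue
        for pos in range(3):
            p_syn = ps * SYN_FRACTION[c, pos]
            p_non = 0.0 if protected[ci] else pn * _NONSTOP_NONSYN_FRACTION[c, pos]
            x = u[ci, pos]
            if x < p_syn:
                opts = _SYN_ALTS[c][pos]
                idx[3 * ci + pos] = opts[rng.integers(len(opts))]
            elif x < p_syn + p_non:
                opts = _NONSYN_ALTS[c][pos]
                idx[3 * ci + pos] = opts[rng.integers(len(opts))]
    return _decode(idx)


_NONSTOP_CODONS = [c for c in CODONS if GENETIC_CODE[c] != "*"]


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random coding sequence: ATG + (n-2) random sense codons + TAA."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    body = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + "TAA"


def random_nucleotides(n: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, size=n).astype(np.int8))
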