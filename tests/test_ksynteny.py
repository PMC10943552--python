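import itertools

import numpy as np
import pytest

from hexorigin.codons import GENETIC_CODE
from hexorigin.ksynteny import (
    Anchor,
    chain_anchors,
    classify_wgd_peaks,
    codon_align,
    ks_distribution_peaks,
    ng86_from_cds,
    ng86_ka_ks,
    _best_chain,
)
from hexorigin.simgenome.evolve import mutate_pair_at_ks, random_cds
from oracles import brute_force_chain_score, pathway_counts

SENSE_CODONS = [c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"]


# --------------------------------------------------------------------------
# NG86 Ka/Ks
# --------------------------------------------------------------------------

def test_identical_sequences_have_zero_ks():
    cds = "ATGGCTGCAAAGTTT" * 4
    est = ng86_ka_ks(cds, cds)
    assert est.sd == 0.0 and est.nd == 0.0
    assert est.ks == 0.0 and est.ka == 0.0
    assert est.valid


def test_hand_counted_synonymous_example():
    # six TTT (Phe) codons vs one synonymous TTT->TTC change: each Phe codon
    # has 1/3 synonymous site, so S = 6/3 = 2, Sd = 1, ps = 0.5,
    # Ks = -3/4 ln(1 - 4*0.5/3)
    a = "TTT" * 6
    b = "TTC" + "TTT" * 5
    est = ng86_ka_ks(a, b)
    assert est.s_sites == pytest.approx(2.0)
    assert est.sd == pytest.approx(1.0)
    assert est.nd == pytest.approx(0.0)
    assert est.ps == pytest.approx(0.5)
    assert est.ks == pytest.approx(-0.75 * np.log(1 - 2 / 3))
    assert est.ka == 0.0


def test_sites_partition_three_per_codon():
    rng = np.random.default_rng(0)
    a = random_cds(50, rng)
    b = mutate_pair_at_ks(a, 0.1, 0.02, rng)
    est = ng86_ka_ks(a, b)
    assert est.s_sites + est.n_sites == pytest.approx(3.0 * est.n_codons)


def test_estimate_is_symmetric():
    rng = np.random.default_rng(1)
    a = random_cds(60, rng)
    b = mutate_pair_at_ks(a, 0.3, 0.06, rng)
    fwd, rev = ng86_ka_ks(a, b), ng86_ka_ks(b, a)
    assert fwd.sd == pytest.approx(rev.sd)
    assert fwd.nd == pytest.approx(rev.nd)
    assert fwd.ks == pytest.approx(rev.ks)
    assert fwd.ka == pytest.approx(rev.ka)


def test_pathway_counts_match_enumeration_on_all_two_difference_pairs():
    """For every ordered pair of sense codons differing at exactly two
    positions, the tabulated pathway-averaged Sd/Nd must equal direct
    enumeration of substitution orders (stop-blocked paths excluded)."""
    checked = 0
    for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
        ndiff = sum(x != y for x, y in zip(ca, cb))
        if ndiff != 2:
            continue
        est = ng86_ka_ks(ca, cb)
        syn, nonsyn = pathway_counts(ca, cb)
        assert est.sd == pytest.approx(syn), (ca, cb)
        assert est.nd == pytest.approx(nonsyn), (ca, cb)
        checked += 1
    assert checked > 1000


def test_single_and_triple_difference_codons_also_match_enumeration():
    rng = np.random.default_rng(2)
    for _ in range(200):
        ca, cb = (SENSE_CODONS[i]
                  for i in rng.integers(0, len(SENSE_CODONS), 2))
        est = ng86_ka_ks(ca, cb)
        syn, nonsyn = pathway_counts(ca, cb)
        assert est.sd == pytest.approx(syn)
        assert est.nd == pytest.approx(nonsyn)


def test_misaligned_input_is_rejected():
    with pytest.raises(ValueError):
        ng86_ka_ks("ATGAAA", "ATG")
    with pytest.raises(ValueError):
        ng86_ka_ks("ATGA", "ATGA")


def test_saturated_pairs_are_flagged_invalid():
    est = ng86_ka_ks("AAA" * 20, "CCC" * 20)
    assert not est.valid
    assert np.isnan(est.ka)


@pytest.mark.parametrize("target,tol", [(0.03, 0.005), (0.1, 0.012),
                                        (0.55, 0.05)])
def test_mean_ks_tracks_the_simulated_synonymous_divergence(target, tol):
    rng = np.random.default_rng(int(target * 1000))
    values = []
    for _ in range(150):
        a = random_cds(300, rng)
        b = mutate_pair_at_ks(a, target, target * 0.2, rng)
        est = ng86_ka_ks(a, b)
        if est.valid:
            values.append(est.ks)
    assert np.mean(values) == pytest.approx(target, abs=tol)


# --------------------------------------------------------------------------
# codon-aware alignment
# --------------------------------------------------------------------------

def test_codon_align_inserts_whole_codon_gaps():
    rng = np.random.default_rng(3)
    a = random_cds(40, rng)
    b = a[:30] + a[33:]
    ga, gb = codon_align(a, b)
    # the terminal stop codon is stripped before aligning
    assert len(ga) == len(gb) == len(a) - 3
    assert gb.count("-") == 3
    assert gb.index("-") % 3 == 0
    est = ng86_from_cds(a, b)
    assert est.n_codons == 38  # the gapped codon column is excluded
    assert est.ks == 0.0


def test_codon_align_rejects_partial_codons():
    with pytest.raises(ValueError):
        codon_align("ATGAA", "ATGAAA")


# --------------------------------------------------------------------------
# anchor chaining
# --------------------------------------------------------------------------

def _collinear(n, chrom_a="a1", chrom_b="b1", reverse=False, start_b=0,
               step=1):
    return [
        Anchor(f"{chrom_a}.g{k}", f"{chrom_b}.g{k}", chrom_a, chrom_b, k,
               start_b + (n - 1 - k if reverse else k) * step)
        for k in range(n)
    ]


def test_blocks_require_strictly_more_than_min_anchors():
    assert chain_anchors(_collinear(10), min_anchors=10) == []
    blocks = chain_anchors(_collinear(11), min_anchors=10)
    assert len(blocks) == 1
    assert len(blocks[0].anchors) == 11


def test_collinear_run_with_small_gaps_forms_one_forward_block():
    anchors = _collinear(15, step=3)  # rank gaps of 3 < default max_gap
    blocks = chain_anchors(anchors, min_anchors=10)
    assert len(blocks) == 1
    block = blocks[0]
    assert block.orientation == "+"
    assert len(block.anchors) == 15
    assert [a.id_a for a in block.anchors] == [f"a1.g{k}" for k in range(15)]


def test_reversed_segment_is_chained_with_minus_orientation():
    blocks = chain_anchors(_collinear(15, reverse=True), min_anchors=10)
    assert len(blocks) == 1
    assert blocks[0].orientation == "-"


def test_gaps_beyond_max_gap_split_the_chain():
    near = _collinear(12)
    far = [Anchor(f"gx{k}", f"gy{k}", "a1", "b1", 200 + k, 200 + k)
           for k in range(12)]
    blocks = chain_anchors(near + far, max_gap=25, min_anchors=10)
    assert len(blocks) == 2
    assert all(len(b.anchors) == 12 for b in blocks)


def test_duplicate_anchor_pairs_are_rejected():
    a = Anchor("g1", "g2", "a1", "b1", 0, 0)
    with pytest.raises(ValueError):
        chain_anchors([a, a])


def test_anchors_on_different_chromosome_pairs_never_mix():
    one = _collinear(12, chrom_a="a1", chrom_b="b1")
    two = _collinear(12, chrom_a="a2", chrom_b="b2")
    blocks = chain_anchors(one + two, min_anchors=10)
    assert {(b.chrom_a, b.chrom_b) for b in blocks} == \
        {("a1", "b1"), ("a2", "b2")}


@pytest.mark.parametrize("seed", range(6))
def test_chain_dp_matches_subset_enumeration(seed):
    """The chaining DP must equal brute-force enumeration over all anchor
    subsets, in both orientations."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    ranks_a = rng.choice(60, size=n, replace=False)
    ranks_b = rng.choice(60, size=n, replace=False)
    anchors = [
        Anchor(f"p{k}", f"q{k}", "a1", "b1", int(ranks_a[k]),
               int(ranks_b[k]), float(rng.uniform(0.5, 2.0)))
        for k in range(n)
    ]
    for flip in (False, True):
        dp_score, chain = _best_chain(anchors, max_gap=10, gap_penalty=0.05,
                                      flip_b=flip)
        brute = brute_force_chain_score(anchors, max_gap=10,
                                        gap_penalty=0.05, flip_b=flip)
        assert dp_score == pytest.approx(brute)
        assert len(chain) == len(set(chain))


# --------------------------------------------------------------------------
# Ks distribution peaks
# --------------------------------------------------------------------------

def test_constant_values_give_a_single_exact_peak():
    peaks = ks_distribution_peaks([0.55] * 30)
    assert len(peaks) == 1
    assert peaks[0].mode == pytest.approx(0.55)


def test_too_few_values_are_rejected():
    with pytest.raises(ValueError):
        ks_distribution_peaks([0.5] * 5)


def test_bimodal_mixture_yields_both_modes():
    rng = np.random.default_rng(4)
    old = np.exp(rng.normal(np.log(0.55), 0.15, 400))
    recent = np.exp(rng.normal(np.log(0.03), 0.15, 400))
    peaks = ks_distribution_peaks(np.concatenate([old, recent]))
    assert len(peaks) >= 2
    modes = sorted(p.mode for p in peaks[:2])
    assert modes[0] == pytest.approx(0.03, abs=0.01)
    assert modes[1] == pytest.approx(0.55, abs=0.08)


def test_peak_labels_follow_the_polyploidy_windows():
    from hexorigin.ksynteny import KsPeak
    raw = [KsPeak(1.4, 1.0), KsPeak(0.55, 2.0), KsPeak(5.0, 0.5),
           KsPeak(0.03, 3.0)]
    intra = classify_wgd_peaks(raw, comparison="intra")
    assert [p.label for p in intra] == ["WGT1", "WGD2", "unassigned", "WGT3"]
    inter = classify_wgd_peaks(raw, comparison="inter")
    assert inter[3].label == "divergence"


def test_peak_classification_validates_inputs():
    from hexorigin.ksynteny import KsPeak
    with pytest.raises(ValueError):
        classify_wgd_peaks([], comparison="both")
    with pytest.raises(ValueError):
        classify_wgd_peaks([KsPeak(0.5, 1.0)],
                           windows={"x": (0.0, 1.0), "y": (0.5, 2.0)})


# --------------------------------------------------------------------------
# integration: orthologous synteny between the hexaploid and its relative
# --------------------------------------------------------------------------

def test_ortholog_anchors_chain_and_date_the_species_split(default_dataset):
    """Anchors between one focal chromosome and its close-relative ortholog
    chromosome must chain into a single forward block whose Ks matches the
    species divergence scale (~0.05), not the polyploidy scale."""
    from hexorigin.ksynteny import anchors_from_records, block_ks

    ds = default_dataset
    lineage_of = dict(zip(ds.chromosomes["chromosome"],
                          ds.chromosomes["lineage"]))
    records = {r.gene_id: r for r in ds.all_records()}
    pairs = []
    truth = ds.truth_orthologs
    for og_id, rows in truth[truth["group"] == 0].groupby("og_id"):
        by_lineage = {lineage_of[r.chromosome]: r.gene_id
                      for r in rows.itertuples()}
        pairs.append((by_lineage["A1a"], by_lineage["Hann"]))
    anchors = anchors_from_records(pairs[:30], records)
    blocks = chain_anchors(anchors, min_anchors=10)
    assert len(blocks) == 1
    assert blocks[0].orientation == "+"
    estimates = block_ks(blocks[0], records)
    mean_ks = np.mean([e.ks for e in estimates if e.valid])
    assert 0.02 <= mean_ks <= 0.1
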