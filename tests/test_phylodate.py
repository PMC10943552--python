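import itertools

import dendropy
import numpy as np
import pytest

from hexorigin.phylodate import (
    Msa,
    align_star,
    bootstrap_support,
    codon_msa,
    concatenate,
    date_tree,
    distance_matrix,
    nj_tree,
    trim_gaps,
    _bipartitions,
)
from hexorigin.simgenome import evolve_sequence, random_cds
from oracles import random_additive_tree


def _newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


# --------------------------------------------------------------------------
# multiple alignment
# --------------------------------------------------------------------------

def test_star_alignment_of_identical_sequences_has_no_gaps():
    msa = align_star({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
    assert all("-" not in row for row in msa.rows)
    assert msa.length == 8


def test_star_alignment_places_gap_for_deleted_segment():
    msa = align_star({"a": "ACGTACGTAC", "b": "ACGTAC", "c": "ACGTACGTAC"})
    assert msa.length == 10
    assert msa.row("b").count("-") == 4
    assert msa.row("a") == "ACGTACGTAC"


def test_star_alignment_requires_two_sequences():
    with pytest.raises(ValueError):
        align_star({"a": "ACGT"})


def test_codon_alignment_expands_protein_gaps_threefold():
    rng = np.random.default_rng(0)
    cds = random_cds(40, rng)
    # delete one internal codon from the second copy
    deleted = cds[:30] + cds[33:]
    msa = codon_msa({"full": cds, "short": deleted, "full2": cds})
    assert msa.length % 3 == 0
    row = msa.row("short")
    assert row.count("-") == 3
    gap_at = row.index("-")
    assert gap_at % 3 == 0
    assert row[gap_at:gap_at + 3] == "---"


def test_codon_alignment_rejects_partial_codons():
    with pytest.raises(ValueError):
        codon_msa({"a": "ACGTA", "b": "ACGTAA"})


def test_trim_gaps_performs_complete_deletion():
    msa = Msa(("a", "b"), ("AC-GT", "ACCG-"))
    trimmed = trim_gaps(msa)
    assert trimmed.rows == ("ACG", "ACG")


def test_concatenate_tracks_partitions_and_rejects_taxon_mismatch():
    m1 = Msa(("a", "b"), ("ACGT", "ACGA"))
    m2 = Msa(("b", "a"), ("GG", "GC"))
    cat = concatenate({"p1": m1, "p2": m2})
    assert cat.row("a") == "ACGTGC"
    assert cat.row("b") == "ACGAGG"
    assert cat.partitions == (("p1", 0, 4), ("p2", 4, 6))
    with pytest.raises(ValueError):
        concatenate({"p1": m1, "p2": Msa(("a", "c"), ("AC", "AC"))})
    with pytest.raises(ValueError):
        concatenate({})


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

def test_p_distance_counts_differing_columns():
    a = "A" * 80
    b = "C" * 3 + "A" * 77
    msa = Msa(("a", "b"), (a, b))
    d = distance_matrix(msa, model="p")
    assert d[0, 1] == pytest.approx(3 / 80)


def test_jc69_correction_matches_closed_form():
    # p = 0.0375 -> d = -3/4 ln(1 - 4p/3)
    a = "ACGT" * 20
    b = "CCGT" + "ACGT" * 17 + "AAGT" + "ACGG"
    msa = Msa(("a", "b"), (a, b))
    p = distance_matrix(msa, model="p")[0, 1]
    d = distance_matrix(msa, model="jc69")[0, 1]
    assert d == pytest.approx(-0.75 * np.log(1 - 4 * p / 3))
    assert d > p


def test_saturated_distances_are_clamped_with_warning():
    msa = Msa(("a", "b"), ("A" * 40, "C" * 40))  # p = 1.0 >= 0.75
    with pytest.warns(UserWarning, match="saturated"):
        d = distance_matrix(msa, model="jc69")
    assert np.isfinite(d[0, 1])


def test_gapped_sites_are_excluded_pairwise():
    msa = Msa(("a", "b"), ("AC-T", "ACGT"))
    d = distance_matrix(msa, model="p")
    assert d[0, 1] == 0.0


def test_protein_alignment_selects_poisson_model():
    msa = Msa(("a", "b"), ("MKTLV" * 4, "MKTLV" * 3 + "MKTLW"))
    d = distance_matrix(msa, model="auto")[0, 1]
    assert d == pytest.approx(-np.log(1 - 0.05))


def test_unknown_model_is_rejected():
    with pytest.raises(ValueError):
        distance_matrix(Msa(("a", "b"), ("AC", "AC")), model="k2p")


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def test_nj_recovers_hand_four_taxon_tree_exactly():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances below
    names = ["A", "B", "C", "D"]
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], dtype=float)
    tree = nj_tree(d, names)
    assert _bipartitions(tree) == {frozenset({"A", "B"})}
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, j in itertools.combinations(range(4), 2):
        assert pdm.patristic_distance(
            taxa[names[i]], taxa[names[j]]) == pytest.approx(d[i, j])


def test_nj_three_taxon_closed_form():
    names = ["A", "B", "C"]
    d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    tree = nj_tree(d, names)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, j in itertools.combinations(range(3), 2):
        assert pdm.patristic_distance(
            taxa[names[i]], taxa[names[j]]) == pytest.approx(d[i, j])


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
def test_nj_is_exact_on_random_additive_matrices(n_taxa):
    """On an additive matrix NJ provably recovers the generating tree;
    topology and all patristic distances must match exactly."""
    for seed in range(4):
        rng = np.random.default_rng(1000 * n_taxa + seed)
        names, mat, splits = random_additive_tree(n_taxa, rng)
        tree = nj_tree(mat, names)
        assert _bipartitions(tree) == splits
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, j in itertools.combinations(range(n_taxa), 2):
            assert pdm.patristic_distance(
                taxa[names[i]], taxa[names[j]]) == pytest.approx(mat[i, j])


def test_nj_topology_agrees_with_independent_implementation():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(7)
    names, mat, splits = random_additive_tree(6, rng)
    ref = skbio_nj(DistanceMatrix(mat, ids=names))
    all_taxa = frozenset(names)
    ref_splits = set()
    for node in ref.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(names) - 1:
            ref_splits.add(min(side, all_taxa - side, key=sorted))
    assert _bipartitions(nj_tree(mat, names)) == ref_splits


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["A", "B"])
    bad = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], dtype=float)
    with pytest.raises(ValueError):
        nj_tree(bad, ["A", "B", "C"])


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def _structured_msa(rng, n_cols=600, noise=0.0):
    anc = random_cds(n_cols // 3, rng)
    near = evolve_sequence(anc, 0.02, rng)
    far_anc = evolve_sequence(anc, 0.4, rng)
    far = evolve_sequence(far_anc, 0.02, rng)
    rows = {"A": anc, "B": near, "C": far_anc, "D": far}
    if noise:
        rows = {k: evolve_sequence(v, noise, rng) for k, v in rows.items()}
    return Msa(tuple(rows), tuple(rows.values()))


def test_bootstrap_gives_full_support_to_a_deep_clean_split():
    msa = _structured_msa(np.random.default_rng(2))
    tree, support = bootstrap_support(msa, n_replicates=100,
                                      rng=np.random.default_rng(3))
    assert support[frozenset({"A", "B"})] == pytest.approx(100.0)
    labelled = [n.label for n in tree.preorder_node_iter()
                if not n.is_leaf() and n.label]
    assert "100" in labelled


def test_bootstrap_is_deterministic_given_the_generator():
    msa = _structured_msa(np.random.default_rng(4))
    _, s1 = bootstrap_support(msa, n_replicates=50,
                              rng=np.random.default_rng(9))
    _, s2 = bootstrap_support(msa, n_replicates=50,
                              rng=np.random.default_rng(9))
    assert s1 == s2


# --------------------------------------------------------------------------
# dating
# --------------------------------------------------------------------------

def test_point_calibration_on_ultrametric_tree_gives_exact_ages():
    tree = _newick("((A:1,B:1):1,C:2);")
    dated = date_tree(tree, outgroup="C",
                      calibration_taxa=("A", "B"),
                      calibration_interval=(20.0, 20.0))
    by_taxa = {d.taxa: d for d in dated}
    cal = by_taxa[frozenset({"A", "B"})]
    assert cal.is_calibration
    assert cal.age_lo == cal.age_hi == pytest.approx(20.0)
    root = by_taxa[frozenset({"A", "B", "C"})]
    assert root.age_lo == pytest.approx(40.0)


def test_dated_ages_are_invariant_under_rate_scaling():
    base = "((A:1,B:1):0.5,(C:1.2,D:1.3):0.4,E:3);"
    t1 = _newick(base)
    t2 = _newick(base)
    for edge in t2.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= 7.3
    kw = dict(outgroup="E", calibration_taxa=("A", "B"),
              calibration_interval=(10.0, 14.0))
    d1 = {d.taxa: d for d in date_tree(t1, **kw)}
    d2 = {d.taxa: d for d in date_tree(t2, **kw)}
    assert set(d1) == set(d2)
    for taxa in d1:
        assert d1[taxa].age_lo == pytest.approx(d2[taxa].age_lo)
        assert d1[taxa].age_hi == pytest.approx(d2[taxa].age_hi)


def test_age_intervals_scale_with_the_calibration_interval():
    tree1 = _newick("((A:1,B:1):1,C:2);")
    tree2 = _newick("((A:1,B:1):1,C:2);")
    kw = dict(outgroup="C", calibration_taxa=("A", "B"))
    d1 = {d.taxa: d for d in date_tree(tree1, calibration_interval=(10, 20),
                                       **kw)}
    d2 = {d.taxa: d for d in date_tree(tree2, calibration_interval=(20, 40),
                                       **kw)}
    for taxa in d1:
        assert 2 * d1[taxa].age_lo == pytest.approx(d2[taxa].age_lo)
        assert 2 * d1[taxa].age_hi == pytest.approx(d2[taxa].age_hi)


def test_dating_input_validation():
    tree = _newick("((A:1,B:1):1,C:2);")
    with pytest.raises(ValueError):
        date_tree(tree, "C", ("A", "B"), (0.0, 1.0))
    with pytest.raises(ValueError):
        date_tree(tree, "Z", ("A", "B"), (1.0, 2.0))


# --------------------------------------------------------------------------
# simulated six-chromosome recovery
# --------------------------------------------------------------------------

def test_concatenated_msa_recovers_heterozygous_pairs(default_dataset):
    """NJ on a concatenated codon alignment of simulated single-copy
    orthologs must place each heterozygous chromosome pair as a cherry."""
    ds = default_dataset
    meta = ds.chromosomes
    group0 = meta[meta["group"] == 0]
    lineage_of = dict(zip(group0["chromosome"], group0["lineage"]))
    records = {r.gene_id: r for r in ds.all_records()}

    truth = ds.truth_orthologs
    msas = {}
    for og_id, rows in truth[truth["group"] == 0].groupby("og_id"):
        seqs = {lineage_of[r.chromosome]: records[r.gene_id].cds
                for r in rows.itertuples()}
        if len(seqs) != 8:
            continue
        msas[og_id] = trim_gaps(codon_msa(seqs))
        if len(msas) == 12:
            break
    cat = concatenate(msas)
    tree = nj_tree(distance_matrix(cat, model="jc69"), list(cat.names))
    bips = _bipartitions(tree)
    all_taxa = frozenset(cat.names)

    def canonical(side):
        side = frozenset(side)
        return min(side, all_taxa - side, key=sorted)

    for pair in ({"A1a", "A1b"}, {"A2a", "A2b"}, {"Ba", "Bb"}):
        assert canonical(pair) in bips
    assert canonical({"A1a", "A1b", "A2a", "A2b"}) in bips
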