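import dendropy
import numpy as np
import pytest

from hexorigin.codons import translate
from hexorigin.inulin_family import (
    GH32_C_CONSENSUS,
    GH32_N_CONSENSUS,
    DomainProfile,
    call_pseudogene,
    check_gh32_domains,
    classify_copy_origin,
    find_family_members,
    protein_to_locus_align,
)
from hexorigin.pipeline import family_analysis
from hexorigin.simgenome import random_cds

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(n, rng):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


def _mutate(protein, fraction, rng):
    out = list(protein)
    k = int(round(fraction * len(out)))
    for pos in rng.choice(len(out), size=k, replace=False):
        out[pos] = AA[(AA.index(out[pos]) + 1 + int(rng.integers(18))) % 20]
    return "".join(out)


def _locus(rng, n_codons=100, flank=40):
    """A clean gene locus: (protein, cds, genomic window, cds offset)."""
    cds = random_cds(n_codons, rng)
    protein = translate(cds)
    protein = protein[:-1] if protein.endswith("*") else protein
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    return protein, cds, left + cds + right, flank


# --------------------------------------------------------------------------
# domain detection
# --------------------------------------------------------------------------

def test_calibration_is_deterministic():
    p1 = DomainProfile("n", GH32_N_CONSENSUS)
    p2 = DomainProfile("n", GH32_N_CONSENSUS)
    assert p1.calibrate() == p2.calibrate()


def test_protein_with_both_domains_flags_both():
    rng = np.random.default_rng(0)
    prot = (_random_protein(60, rng) + GH32_N_CONSENSUS
            + _random_protein(120, rng) + GH32_C_CONSENSUS
            + _random_protein(40, rng))
    flags = check_gh32_domains(prot)
    assert flags == {"n_terminal": True, "c_terminal": True}


def test_protein_with_only_the_n_domain_flags_one():
    rng = np.random.default_rng(1)
    prot = (_random_protein(60, rng) + GH32_N_CONSENSUS
            + _random_protein(160, rng))
    flags = check_gh32_domains(prot)
    assert flags["n_terminal"] and not flags["c_terminal"]


def test_random_proteins_rarely_flag_domains():
    rng = np.random.default_rng(2)
    hits = sum(
        any(check_gh32_domains(_random_protein(300, rng)).values())
        for _ in range(50)
    )
    assert hits <= 3  # two 1%-FPR tests per protein


def test_short_protein_warns_and_fails_the_check():
    with pytest.warns(UserWarning, match="shorter"):
        flags = check_gh32_domains("MKT")
    assert flags == {"n_terminal": False, "c_terminal": False}


# --------------------------------------------------------------------------
# homology search
# --------------------------------------------------------------------------

def test_exact_copy_is_retained_at_full_identity():
    rng = np.random.default_rng(3)
    seed = _random_protein(300, rng)
    hits = find_family_members({"g1": seed}, {"seed": seed},
                               check_domains=False)
    assert len(hits) == 1
    assert hits[0].retained
    assert hits[0].identity == pytest.approx(100.0)
    assert hits[0].query_coverage == pytest.approx(100.0)


def test_diverged_homolog_fails_the_ninety_percent_filter():
    rng = np.random.default_rng(4)
    seed = _random_protein(300, rng)
    homolog = _mutate(seed, 0.15, rng)   # ~85% identity
    hits = find_family_members({"g1": homolog}, {"seed": seed},
                               check_domains=False)
    assert not hits[0].retained
    assert hits[0].identity < 90.0


def test_raising_thresholds_never_adds_members():
    rng = np.random.default_rng(5)
    seed = _random_protein(250, rng)
    proteome = {
        f"g{k}": _mutate(seed, f, rng)
        for k, f in enumerate((0.0, 0.02, 0.05, 0.08, 0.12, 0.2))
    }
    kept = {}
    for thr in (80.0, 90.0, 95.0, 99.0):
        hits = find_family_members(proteome, {"seed": seed},
                                   min_identity=thr, check_domains=False)
        kept[thr] = {h.gene_id for h in hits if h.retained}
    assert kept[99.0] <= kept[95.0] <= kept[90.0] <= kept[80.0]


def test_empty_inputs_are_rejected():
    with pytest.raises(ValueError):
        find_family_members({}, {"s": "MKT"})
    with pytest.raises(ValueError):
        find_family_members({"g": "MKT"}, {})


# --------------------------------------------------------------------------
# protein-to-locus alignment
# --------------------------------------------------------------------------

def test_clean_locus_aligns_with_no_events():
    rng = np.random.default_rng(6)
    protein, cds, window, flank = _locus(rng)
    aln = protein_to_locus_align(protein, window)
    assert aln.aligned_protein_span == (0, len(protein))
    assert aln.events == []
    assert aln.genome_span == (flank, flank + 3 * len(protein))


def test_planted_single_nucleotide_insertions_are_detected_and_located():
    """Every planted 1-nt insertion must be detected as a single frameshift
    and called a pseudogene; its coordinate must fall within 3 nt of the
    insertion in at least 95% of fixtures (the exact position within the
    disrupted codon can be ambiguous when the inserted base repeats its
    neighbours)."""
    located = total = 0
    for seed in range(60):
        rng = np.random.default_rng(100 + seed)
        protein, cds, window, flank = _locus(rng, n_codons=120)
        pos = int(rng.integers(60, 300))  # nucleotide offset inside the CDS
        broken = window[:flank + pos] + "A" + window[flank + pos:]
        aln = protein_to_locus_align(protein, broken)
        fs = aln.frameshifts()
        assert len(fs) == 1
        assert fs[0].length == 1
        call = call_pseudogene("g", aln, broken)
        assert call.verdict == "pseudogene"
        assert call.frameshifts == [fs[0].genome_pos]
        total += 1
        located += abs(fs[0].genome_pos - (flank + pos)) <= 3
    assert located / total >= 0.95


def test_spliced_intron_is_skipped_without_frameshift():
    rng = np.random.default_rng(7)
    protein, cds, window, flank = _locus(rng, n_codons=120)
    intron = "GT" + "".join("ACGT"[i] for i in rng.integers(0, 4, 26)) + "AG"
    cut = flank + 150  # codon boundary (150 % 3 == 0)
    spliced = window[:cut] + intron + window[cut:]
    aln = protein_to_locus_align(protein, spliced)
    assert aln.frameshifts() == []
    introns = aln.introns()
    assert len(introns) == 1
    assert introns[0].length == len(intron)
    assert introns[0].genome_pos == cut
    call = call_pseudogene("g", aln, spliced)
    assert call.verdict == "true_gene"


def test_window_shorter_than_the_protein_is_rejected():
    with pytest.raises(ValueError):
        protein_to_locus_align("M" * 50, "ACGT" * 10)


# --------------------------------------------------------------------------
# pseudogene calling
# --------------------------------------------------------------------------

def test_internal_stop_lesion_is_called_with_its_position():
    rng = np.random.default_rng(8)
    protein, cds, window, flank = _locus(rng, n_codons=200)
    stop_codon = 150
    cut = flank + 3 * stop_codon
    lesioned = window[:cut] + "TAA" + window[cut + 3:]
    aln = protein_to_locus_align(protein, lesioned)
    call = call_pseudogene("g", aln, lesioned)
    assert call.verdict == "pseudogene"
    assert call.internal_stops == [stop_codon]
    assert call.frameshifts == []


def test_clean_alignment_is_called_true_gene():
    rng = np.random.default_rng(9)
    protein, cds, window, flank = _locus(rng)
    aln = protein_to_locus_align(protein, window)
    call = call_pseudogene("g", aln, window)
    assert call.verdict == "true_gene"
    assert call.internal_stops == [] and call.truncated_terminus is None


# --------------------------------------------------------------------------
# the planted nine-copy family fixture
# --------------------------------------------------------------------------

def test_family_scan_recovers_nine_copies_with_one_frameshift_pseudogene(
        family_dataset):
    copies, origins = family_analysis(family_dataset)
    assert len(copies) == 9
    pseudo = [c for c in copies if c.status == "pseudogene"]
    assert len(pseudo) == 1
    assert len(pseudo[0].call.frameshifts) >= 1

    truth = family_dataset.truth_family
    focal = truth[truth["chromosome"].str.startswith("Htub")]
    assert {c.gene_id for c in copies} == set(focal["copy_id"])
    truth_pseudo = focal.loc[focal["is_pseudogene"], "copy_id"].iloc[0]
    assert pseudo[0].gene_id == truth_pseudo

    # duplication origins of the true-gene copies match the planted history
    truth_origin = dict(zip(focal["copy_id"], focal["origin"]))
    assert len(origins) == 8
    for label in origins:
        assert label.origin == truth_origin[label.gene_id], label.gene_id


# --------------------------------------------------------------------------
# copy-origin classification on hand trees
# --------------------------------------------------------------------------

def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def test_multi_chromosome_clades_label_wgt3_and_tandem():
    tree = _tree("(((F1:0.01,F2:0.01):0.3,O1:0.3):0.05,"
                 "((F3:0.01,F4:0.01):0.3,O2:0.3):0.05);")
    locations = {"F1": ("c1", 5), "F2": ("c2", 40),
                 "F3": ("c3", 5), "F4": ("c3", 8)}
    labels = {l.gene_id: l for l in classify_copy_origin(
        tree, locations, {"F1", "F2", "F3", "F4"}, {"O1", "O2"})}
    assert labels["F1"].origin == "WGT3"
    assert labels["F2"].origin == "WGT3"
    assert labels["F1"].clade == labels["F2"].clade
    # clade 2 sits on one chromosome: founder is WGD2-level, second copy
    # within 10 ranks is tandem
    assert labels["F3"].origin == "WGD2_clade"
    assert labels["F4"].origin == "tandem"
    assert labels["F4"].rank_distance == 3
    assert labels["F3"].clade != labels["F1"].clade


def test_distant_same_chromosome_copies_are_not_tandem():
    tree = _tree("((F1:0.01,F2:0.01):0.3,O1:0.3);")
    locations = {"F1": ("c1", 5), "F2": ("c1", 50)}
    labels = {l.gene_id: l.origin for l in classify_copy_origin(
        tree, locations, {"F1", "F2"}, {"O1"})}
    assert "tandem" not in labels.values()


def test_missing_outgroup_warns_and_leaves_origins_unresolved():
    tree = _tree("((F1:0.01,F2:0.01):0.1,F3:0.2);")
    locations = {"F1": ("c1", 5), "F2": ("c1", 8), "F3": ("c2", 5)}
    with pytest.warns(UserWarning, match="outgroup"):
        labels = {l.gene_id: l.origin for l in classify_copy_origin(
            tree, locations, {"F1", "F2", "F3"}, set())}
    assert labels["F1"] == "unresolved"
    assert labels["F2"] == "tandem"      # location-based, still available
    assert labels["F3"] == "unresolved"
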