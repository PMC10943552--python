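"""End-to-end analysis pipeline over a hexaploid dataset.

Given a dataset (typically from :mod:`hexorigin.simgenome`, but anything
exposing the same gene records works), the pipeline runs, per homologous
group: ortholog detection, identity-based subgenome partitioning, a
chromosome tree with divergence dating against the outgroups, Ks
distributions (within-genome paralogs and between-genome orthologs),
karyotype correspondence against the close outgroup, and — when family seed
proteins are available — gene family identification with pseudogene calls
and duplication-origin labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .inulin_family import classify_copy_origin, find_family_copies
from .karyotype import (
    KaryotypeMap,
    RearrangementCount,
    chromosome_correspondence,
    classify_chromosome_pairs,
    count_breaks_fusions,
)
from .ksynteny import (
    Anchor,
    KsPeak,
    chain_anchors,
    classify_wgd_peaks,
    ks_distribution_peaks,
    ng86_from_cds,
)
from .orthology import (
    best_hits,
    build_single_copy_groups,
    filter_groups_by_identity,
    select_conserved_ogs,
)
from .phylodate import (
    DatedNode,
    codon_msa,
    concatenate,
    date_tree,
    distance_matrix,
    nj_tree,
    trim_gaps,
)
from .subgenome import GroupPartition, summarize_group


@dataclass
class GroupResult:
    group: int
    chromosomes: list[str]
    partition: GroupPartition
    n_single_copy: int
    n_filtered: int
    dated_nodes: list[DatedNode] = field(default_factory=list)


@dataclass
class PipelineResult:
    groups: list[GroupResult]
    intra_pair_identity: float
    inter_pair_identity: float
    ks_peaks_intra: list[KsPeak] = field(default_factory=list)
    ks_peaks_inter: list[KsPeak] = field(default_factory=list)
    karyotype: KaryotypeMap | None = None
    rearrangements: RearrangementCount | None = None
    family_copies: list = field(default_factory=list)
    family_origins: list = field(default_factory=list)


def partition_group(dataset, group: int, min_identity: float = 92.0,
                    max_identity: float = 100.0) -> GroupResult:
    """Ortholog groups + identity filter + subgenome partition for one
    homologous group of the focal hexaploid."""
    chroms = dataset.chromosomes_of("Htub", group)
    if len(chroms) != 6:
        raise ValueError(f"group {group} does not have six chromosomes")
    gene_sets = {c: dataset.genes[c] for c in chroms}
    groups = build_single_copy_groups(gene_sets)
    single = [g for g in groups if g.single_copy]
    records = {r.gene_id: r for recs in gene_sets.values() for r in recs}
    filtered = filter_groups_by_identity(single, records,
                                         min_identity, max_identity)
    partition = summarize_group(filtered, records, chroms)
    return GroupResult(group, chroms, partition, len(single), len(filtered))


def date_group(dataset, group: int, calibration=(16.0, 27.0),
               max_ogs: int = 40) -> list[DatedNode]:
    """Date the six chromosomes of one group against the two outgroups.

    Conserved ortholog groups (6 focal copies + 1 per outgroup) are
    concatenated into a nucleotide supermatrix; the NJ/JC69 tree is dated by
    mean path length with the distant-outgroup split pinned to
    ``calibration`` (million years).
    """
    chroms = dataset.chromosomes_of("Htub", group)
    focal_sets = {c: dataset.genes[c] for c in chroms}
    outgroup_sets = {
        t: [r for c in dataset.chromosomes_of(t, group)
            for r in dataset.genes[c]]
        for t in ("Hann", "Mmic")
    }
    records = {r.gene_id: r for r in dataset.all_records()}
    selected = select_conserved_ogs(focal_sets, outgroup_sets,
                                    focal_copy_number=6)
    if not selected:
        warnings.warn(f"group {group}: no conserved ortholog groups; "
                      "dating skipped", stacklevel=2)
        return []
    msas = {}
    for og, _rep in selected[:max_ogs]:
        seqs = {key: records[ids[0]].cds for key, ids in og.members.items()}
        msas[og.og_id] = trim_gaps(codon_msa(seqs))
    supermatrix = concatenate(msas)
    tree = nj_tree(distance_matrix(supermatrix, "jc69"),
                   list(supermatrix.names))
    return date_tree(tree, "Mmic", ("Hann", "Mmic"), calibration)


def _self_anchors(dataset, chrom: str) -> list[Anchor]:
    """Within-chromosome anchors (non-self best hits), for paralog synteny."""
    recs = dataset.genes[chrom]
    hits = best_hits(recs, recs)
    anchors = []
    rec_by_id = {r.gene_id: r for r in recs}
    seen = set()
    for q, hit in hits.items():
        key = tuple(sorted((q, hit.target)))
        if key in seen:
            continue
        seen.add(key)
        a, b = rec_by_id[key[0]], rec_by_id[key[1]]
        anchors.append(Anchor(a.gene_id, b.gene_id, chrom, chrom,
                              a.rank, b.rank))
    return anchors


def ks_analysis(dataset, max_pairs: int = 400) -> tuple[list[KsPeak],
                                                        list[KsPeak]]:
    """Ks peaks for within-genome paralog pairs and between-genome ortholog
    pairs.

    Paralog pairs come from chaining within-chromosome self-anchors (the
    signature of whole-genome duplication); ortholog pairs from
    focal-vs-outgroup reciprocal best hits on matching groups.
    """
    intra_ks: list[float] = []
    for chrom in dataset.chromosomes_of("Htub"):
        records = {r.gene_id: r for r in dataset.genes[chrom]}
        for block in chain_anchors(_self_anchors(dataset, chrom)):
            for a in block.anchors:
                est = ng86_from_cds(records[a.id_a].cds, records[a.id_b].cds)
                if est.valid:
                    intra_ks.append(est.ks)
        if len(intra_ks) >= max_pairs:
            break

    inter_ks: list[float] = []
    records = {r.gene_id: r for r in dataset.all_records()}
    for group in sorted(set(dataset.chromosomes["group"])):
        htub = dataset.chromosomes_of("Htub", group)
        hann = dataset.chromosomes_of("Hann", group)
        if not htub or not hann:
            continue
        set_a = dataset.genes[htub[0]]
        set_b = [r for c in hann for r in dataset.genes[c]]
        fwd = best_hits(set_a, set_b)
        rev = best_hits(set_b, set_a)
        for q, hit in fwd.items():
            back = rev.get(hit.target)
            if back is None or back.target != q:
                continue
            est = ng86_from_cds(records[q].cds, records[hit.target].cds)
            if est.valid:
                inter_ks.append(est.ks)
            if len(inter_ks) >= max_pairs:
                break

    peaks_intra = (classify_wgd_peaks(ks_distribution_peaks(intra_ks),
                                      "intra")
                   if len(intra_ks) >= 20 else [])
    peaks_inter = (classify_wgd_peaks(ks_distribution_peaks(inter_ks),
                                      "inter")
                   if len(inter_ks) >= 20 else [])
    return peaks_intra, peaks_inter


def karyotype_analysis(dataset, representative: str = "H1"):
    """Correspondence between one focal representative per group and the
    close outgroup's chromosomes, plus break/fusion counts under the
    outgroup-as-ancestor hypothesis."""
    anchors = []
    for group in sorted(set(dataset.chromosomes["group"])):
        htub = dataset.chromosomes_of("Htub", group)
        reps = [c for c in htub if c.endswith(representative)]
        if not reps:
            continue
        set_a = dataset.genes[reps[0]]
        set_b = [r for c in dataset.chromosomes_of("Hann")
                 for r in dataset.genes[c]]
        fwd = best_hits(set_a, set_b)
        rev = best_hits(set_b, set_a)
        rec = {r.gene_id: r for r in set_b}
        for q, hit in fwd.items():
            back = rev.get(hit.target)
            if back is None or back.target != q:
                continue
            qa = next(r for r in set_a if r.gene_id == q)
            tb = rec[hit.target]
            anchors.append(Anchor(q, hit.target, qa.chromosome,
                                  tb.chromosome, qa.rank, tb.rank))
    blocks = chain_anchors(anchors)
    if not blocks:
        return None, None
    kmap = classify_chromosome_pairs(chromosome_correspondence(blocks))
    try:
        counts = count_breaks_fusions(kmap, "genome_b")
    except ValueError:
        counts = None
    return kmap, counts


def family_analysis(dataset, family: str = "FEHII", flank: int = 150):
    """Find all family copies (incl. pseudogenes) and label their
    duplication origins from a nucleotide gene tree."""
    seeds = {f"{family}_seed": dataset.family_seeds[family]}
    proteome = {}
    windows = {}
    for r in dataset.all_records():
        if not r.chromosome.startswith("Htub"):
            continue
        if r.protein:
            proteome[r.gene_id] = r.protein
        genome = dataset.genome_sequence(r.chromosome)
        windows[r.gene_id] = genome[max(0, r.start - 1 - flank)
                                    : r.end + flank]
    copies = find_family_copies(proteome, seeds, windows)

    records = {r.gene_id: r for r in dataset.all_records()}
    true_ids = [c.gene_id for c in copies if c.status == "true_gene"]
    og_ids = [r.gene_id for r in dataset.all_records()
              if r.attributes.get("family") == family
              and not r.chromosome.startswith("Htub")]
    origins = []
    if len(true_ids) + len(og_ids) >= 3:
        seqs = {g: records[g].cds for g in true_ids + og_ids}
        msa = trim_gaps(codon_msa(seqs))
        tree = nj_tree(distance_matrix(msa, "jc69"), list(msa.names))
        locs = {g: (records[g].chromosome, records[g].rank) for g in seqs}
        origins = classify_copy_origin(tree, locs, set(true_ids), set(og_ids))
    return copies, origins


def run_pipeline(dataset, date_groups: bool = True,
                 run_ks: bool = True, run_karyotype: bool = True,
                 run_family: bool = True) -> PipelineResult:
    """Full analysis: per-group partitions (always), then dating, Ks,
    karyotype, and family analyses (each optional)."""
    group_ids = sorted(set(
        dataset.chromosomes[dataset.chromosomes["taxon"] == "Htub"]["group"]))
    groups = []
    intra, inter = [], []
    for g in group_ids:
        result = partition_group(dataset, g)
        if date_groups:
            result.dated_nodes = date_group(dataset, g)
        groups.append(result)
        intra.append(result.partition.intra_pair_identity)
        inter.append(result.partition.inter_pair_identity)

    out = PipelineResult(
        groups=groups,
        intra_pair_identity=float(np.mean(intra)),
        inter_pair_identity=float(np.mean(inter)),
    )
    if run_ks:
        out.ks_peaks_intra, out.ks_peaks_inter = ks_analysis(dataset)
    if run_karyotype:
        out.karyotype, out.rearrangements = karyotype_analysis(dataset)
    if run_family and getattr(dataset, "family_seeds", None):
        for family in dataset.family_seeds:
            copies, origins = family_analysis(dataset, family)
            out.family_copies.extend(copies)
            out.family_origins.extend(origins)
    return out
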