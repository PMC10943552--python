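"""Planting a GH32-like gene family with a known duplication history.

The family mimics the inulin metabolism enzymes (1-SST / 1-FFT / 1-FEH):
an ancestral gene duplicates at the old whole-genome duplication (clade
divergence ~ Ks 0.55), each clade keeps an outgroup ortholog, the focal
hexaploid carries one copy per subgenome-representative chromosome from the
recent whole-genome triplication (~ Ks 0.03), and tandem duplicates may sit
at adjacent gene ranks. The enzymes are under strong purifying selection
(default Ka/Ks 0.05) and two domain motif segments — an N-terminal
sucrose-box-like segment and a C-terminal segment, standing in for the two
glycosyl hydrolase family 32 domains — are held invariant at the protein
level. Lesions (frameshift, internal stop, terminal truncation) are planted
at recorded coordinates to create pseudogenes.
"""

from __future__ import annotations

import numpy as np

from ..codons import GENETIC_CODE, translate
from ..records import GeneRecord
from .config import FamilySpec
from .evolve import mutate_pair_at_ks, random_cds

from ..inulin_family import GH32_C_CONSENSUS, GH32_N_CONSENSUS

#: the planted family carries the packaged GH32-like domain consensus
#: segments, held invariant at the protein level, so domain detection on the
#: synthetic data behaves like on real family members
N_TERMINAL_MOTIF = GH32_N_CONSENSUS
C_TERMINAL_MOTIF = GH32_C_CONSENSUS
N_MOTIF_CODON = 10


def c_motif_codon(length_codons: int) -> int:
    return length_codons - 10 - len(C_TERMINAL_MOTIF)


_CODONS_FOR = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()


def _encode_protein_segment(segment: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice for each residue of ``segment``."""
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in segment
    )


def family_ancestor_cds(spec: FamilySpec, rng: np.random.Generator) -> str:
    """The ancestral (pre-duplication) family coding sequence with both
    motif segments embedded."""
    cds = random_cds(spec.length_codons, rng)
    n0 = 3 * N_MOTIF_CODON
    n_seg = _encode_protein_segment(N_TERMINAL_MOTIF, rng)
    c0 = 3 * c_motif_codon(spec.length_codons)
    c_seg = _encode_protein_segment(C_TERMINAL_MOTIF, rng)
    cds = cds[:n0] + n_seg + cds[n0 + len(n_seg):]
    cds = cds[:c0] + c_seg + cds[c0 + len(c_seg):]
    return cds


def motif_protection_mask(spec: FamilySpec) -> np.ndarray:
    mask = np.zeros(spec.length_codons, dtype=bool)
    mask[N_MOTIF_CODON : N_MOTIF_CODON + len(N_TERMINAL_MOTIF)] = True
    c0 = c_motif_codon(spec.length_codons)
    mask[c0 : c0 + len(C_TERMINAL_MOTIF)] = True
    return mask


def _descend(cds: str, ks: float, spec: FamilySpec, mask,
             rng: np.random.Generator) -> str:
    return mutate_pair_at_ks(cds, ks, ks * spec.ka_ks_ratio, rng,
                             nonsyn_protected_codons=mask)


def _apply_lesion(record: GeneRecord, kind: str, codon: int,
                  rng: np.random.Generator) -> None:
    cds = record.cds
    if kind == "frameshift":
        ins = "ACGT"[rng.integers(4)]
        lesioned = cds[: 3 * codon] + ins + cds[3 * codon:]
        record.cds = lesioned
        record.attributes["genomic_body"] = lesioned
        frame = lesioned[: len(lesioned) // 3 * 3]
        record.protein = translate(frame, to_stop=True)
    elif kind == "internal_stop":
        lesioned = cds[: 3 * codon] + "TAA" + cds[3 * codon + 3:]
        record.cds = lesioned
        record.attributes["genomic_body"] = lesioned
        record.protein = translate(lesioned, to_stop=True)
    elif kind == "truncation":
        lesioned = cds[: 3 * codon]
        record.cds = lesioned
        record.attributes["genomic_body"] = lesioned
        record.protein = translate(lesioned, to_stop=True)
    else:  # pragma: no cover - validated upstream
        raise ValueError(kind)
    record.attributes["lesion"] = kind
    record.attributes["lesion_codon"] = codon


def plant_gene_family(dataset, spec: FamilySpec,
                      rng: np.random.Generator | None = None):
    """Insert the family described by ``spec`` into ``dataset`` (in place).

    Copy indices (for lesion targeting and truth rows) run over placements
    in order, homologs in order, with each chromosome's primary copy first
    and its tandem duplicates after it.
    """
    import pandas as pd

    spec.validate(dataset.config.n_groups)
    if rng is None:
        rng = np.random.default_rng(dataset.config.seed + 7919)
    if not spec.placements:
        return dataset

    mask = motif_protection_mask(spec)
    ancestor = family_ancestor_cds(spec, rng)
    clades = sorted({p.clade for p in spec.placements})
    clade_anc = {c: _descend(ancestor, spec.clade_ks / 2.0, spec, mask, rng)
                 for c in clades}
    focal_node = {
        c: _descend(clade_anc[c],
                    max(spec.speciation_ks - spec.wgt3_ks, 0.0) / 2.0,
                    spec, mask, rng)
        for c in clades
    }

    lesion_by_index = {l.copy_index: l for l in spec.lesions}
    family_rows = []
    copy_counter = 0
    chrom_df = dataset.chromosomes

    from .simulate import LINEAGES

    for placement in spec.placements:
        for h in placement.homolog_indices:
            # indices address the six chromosomes in subgenome order
            # (A1a, A1b, A2a, A2b, Ba, Bb), so (0, 2, 4) selects one
            # representative per heterozygous pair
            sel = chrom_df[
                (chrom_df["taxon"] == "Htub")
                & (chrom_df["group"] == placement.group)
                & (chrom_df["lineage"] == LINEAGES[h])
            ]
            if sel.empty:
                raise ValueError(
                    f"no chromosome for group {placement.group} "
                    f"lineage {LINEAGES[h]}")
            chrom = sel["chromosome"].iloc[0]
            primary_cds = _descend(focal_node[placement.clade],
                                   spec.wgt3_ks / 2.0, spec, mask, rng)
            copies = [("WGT3", primary_cds)]
            for _ in range(placement.copies_per_chromosome - 1):
                copies.append(
                    ("tandem",
                     _descend(primary_cds, spec.tandem_ks, spec, mask, rng)))
            after = min(placement.insert_after_rank,
                        len(dataset.genes[chrom]) - 1)
            for offset, (origin, cds) in enumerate(copies):
                rec = GeneRecord(
                    gene_id=f"{chrom}.{spec.name}{copy_counter}",
                    chromosome=chrom, rank=0, cds=cds,
                    protein=translate(cds, to_stop=True),
                )
                rec.attributes.update(
                    family=spec.name, clade=placement.clade, origin=origin)
                lesion = lesion_by_index.get(copy_counter)
                if lesion is not None:
                    _apply_lesion(rec, lesion.kind, lesion.codon, rng)
                dataset.insert_gene(chrom, after + offset, rec, rng)
                family_rows.append(dict(
                    copy_id=rec.gene_id, family=spec.name, chromosome=chrom,
                    rank=-1, clade=placement.clade, origin=origin,
                    lesion=lesion.kind if lesion else None,
                    lesion_codon=lesion.codon if lesion else None,
                    is_pseudogene=lesion is not None,
                ))
                copy_counter += 1

    if spec.outgroup_copies:
        for clade in clades:
            group = next(p.group for p in spec.placements if p.clade == clade)
            chrom = f"Hann.g{group + 1:02d}"
            cds = _descend(clade_anc[clade], spec.speciation_ks / 2.0,
                           spec, mask, rng)
            rec = GeneRecord(
                gene_id=f"{chrom}.{spec.name}o{clade}",
                chromosome=chrom, rank=0, cds=cds,
                protein=translate(cds, to_stop=True),
            )
            rec.attributes.update(
                family=spec.name, clade=clade, origin="outgroup")
            dataset.insert_gene(chrom, 30, rec, rng)
            family_rows.append(dict(
                copy_id=rec.gene_id, family=spec.name, chromosome=chrom,
                rank=-1, clade=clade, origin="outgroup", lesion=None,
                lesion_codon=None, is_pseudogene=False,
            ))

    dataset.rebuild()
    rank_of = {r.gene_id: r.rank for r in dataset.all_records()}
    for row in family_rows:
        row["rank"] = rank_of[row["copy_id"]]
    new_rows = pd.DataFrame(family_rows)
    if dataset.truth_family.empty:
        dataset.truth_family = new_rows
    else:
        dataset.truth_family = pd.concat(
            [dataset.truth_family, new_rows], ignore_index=True)
    dataset.family_seeds[spec.name] = translate(ancestor, to_stop=True)
    return dataset
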