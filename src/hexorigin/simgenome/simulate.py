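"""Synthetic autoallohexaploid genome generator.

For each homologous group an ancestral gene set is evolved down the species
tree

    (((A1a,A1b),(A2a,A2b)),(Ba,Bb))  +  outgroups Hann, Mmic

producing six focal-species chromosomes (three heterozygous pairs from
subgenomes A1, A2 and B) plus one chromosome per outgroup. A block of
whole-genome-duplication paralogs at a chosen synonymous divergence is
planted on each focal and Hann chromosome, and inter-chromosomal
translocations and a GH32-like gene family can be planted on top. Ground
truth for every planted feature is recorded in tidy tables so each
downstream inference stage can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..codons import translate
from ..records import GeneRecord
from .config import FamilySpec, SimConfig
from .evolve import evolve_cds, mutate_pair_at_ks, random_cds, random_nucleotides

#: the six focal-species lineages, their subgenome and heterozygous pair
LINEAGES = ("A1a", "A1b", "A2a", "A2b", "Ba", "Bb")
SUBGENOME_OF = {lin: lin[:-1] for lin in LINEAGES}
PAIR_OF = {lin: lin[:-1] for lin in LINEAGES}

FOCAL_TAXON = "Htub"
OUTGROUPS = ("Hann", "Mmic")


@dataclass
class SimulatedDataset:
    """A generated dataset plus complete ground truth."""

    config: SimConfig
    genes: dict[str, list[GeneRecord]]
    tail_spacers: dict[str, str]
    chromosomes: pd.DataFrame
    truth_orthologs: pd.DataFrame
    truth_paralogs: pd.DataFrame
    truth_rearrangements: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["event", "lineage", "chromosome", "position", "detail"]
        )
    )
    truth_family: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["copy_id", "family", "chromosome", "rank", "clade",
                     "origin", "lesion", "lesion_codon", "is_pseudogene"]
        )
    )
    family_seeds: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    # -- bookkeeping ---------------------------------------------------

    def rebuild(self) -> None:
        """Recompute ranks and 1-based genomic coordinates of every gene."""
        for chrom, records in self.genes.items():
            pos = 0
            for rank, rec in enumerate(records):
                spacer = rec.attributes.get("upstream_spacer", "")
                body = rec.attributes.get("genomic_body", rec.cds)
                rec.rank = rank
                rec.start = pos + len(spacer) + 1
                rec.end = rec.start + len(body) - 1
                pos = rec.end

    def genome_sequence(self, chrom: str) -> str:
        parts = []
        for rec in self.genes[chrom]:
            parts.append(rec.attributes.get("upstream_spacer", ""))
            parts.append(rec.attributes.get("genomic_body", rec.cds))
        parts.append(self.tail_spacers.get(chrom, ""))
        return "".join(parts)

    def chromosomes_of(self, taxon: str | None = None,
                       group: int | None = None) -> list[str]:
        df = self.chromosomes
        if taxon is not None:
            df = df[df["taxon"] == taxon]
        if group is not None:
            df = df[df["group"] == group]
        return list(df["chromosome"])

    def all_records(self):
        for records in self.genes.values():
            yield from records

    def proteome(self) -> dict[str, str]:
        return {r.gene_id: r.protein for r in self.all_records() if r.protein}

    def record_by_id(self, gene_id: str) -> GeneRecord:
        for rec in self.all_records():
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(gene_id)

    def insert_gene(self, chrom: str, after_rank: int, record: GeneRecord,
                    rng: np.random.Generator) -> None:
        """Insert ``record`` after gene rank ``after_rank`` (use -1 for the
        chromosome start); a fresh intergenic spacer is generated."""
        record.attributes.setdefault(
            "upstream_spacer",
            random_nucleotides(self.config.intergenic_length, rng),
        )
        record.chromosome = chrom
        self.genes[chrom].insert(after_rank + 1, record)

    def write(self, outdir) -> None:
        from .writers import write_dataset

        write_dataset(self, outdir)


def _evolve_gene_set(genes: list[str], branch_my: float, rate: float,
                     rng: np.random.Generator) -> list[str]:
    bl = branch_my * rate
    return [evolve_cds(g, bl, rng) for g in genes]


def _make_records(chrom: str, cds_list: list[str], prefix: str = "g",
                  spacer_len: int = 200, rng: np.random.Generator = None,
                  id_indices=None) -> list[GeneRecord]:
    records = []
    indices = id_indices if id_indices is not None else range(len(cds_list))
    for j, cds in zip(indices, cds_list):
        rec = GeneRecord(
            gene_id=f"{chrom}.{prefix}{j:04d}",
            chromosome=chrom,
            rank=0,
            cds=cds,
            protein=translate(cds, to_stop=True),
        )
        rec.attributes["upstream_spacer"] = random_nucleotides(spacer_len, rng)
        records.append(rec)
    return records


def simulate_hexaploid(config: SimConfig) -> SimulatedDataset:
    """Generate a synthetic hexaploid dataset under ``config``.

    Identical config + seed produces byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.lineage_rate
    genes: dict[str, list[GeneRecord]] = {}
    tails: dict[str, str] = {}
    chrom_rows = []
    og_rows = []
    paralog_rows = []

    for g in range(config.n_groups):
        root = [random_cds(config.cds_length_codons, rng)
                for _ in range(config.genes_per_chromosome)]
        # evolve internal nodes top-down
        mmic = _evolve_gene_set(root, config.t_outgroup, rate, rng)
        n_hann = _evolve_gene_set(
            root, config.t_outgroup - config.t_htub_hann, rate, rng)
        hann = _evolve_gene_set(n_hann, config.t_htub_hann, rate, rng)
        n_ab = _evolve_gene_set(
            n_hann, config.t_htub_hann - config.t_ab_split, rate, rng)
        n_b = _evolve_gene_set(
            n_ab, config.t_ab_split - config.t_pair_split, rate, rng)
        n_a = _evolve_gene_set(
            n_ab, config.t_ab_split - config.t_subgenome_split, rate, rng)
        n_a1 = _evolve_gene_set(
            n_a, config.t_subgenome_split - config.t_pair_split, rate, rng)
        n_a2 = _evolve_gene_set(
            n_a, config.t_subgenome_split - config.t_pair_split, rate, rng)
        tip_sets = {
            "A1a": _evolve_gene_set(n_a1, config.t_pair_split, rate, rng),
            "A1b": _evolve_gene_set(n_a1, config.t_pair_split, rate, rng),
            "A2a": _evolve_gene_set(n_a2, config.t_pair_split, rate, rng),
            "A2b": _evolve_gene_set(n_a2, config.t_pair_split, rate, rng),
            "Ba": _evolve_gene_set(n_b, config.t_pair_split, rate, rng),
            "Bb": _evolve_gene_set(n_b, config.t_pair_split, rate, rng),
        }

        # assign homolog labels H1..H6 in a random order so nothing
        # downstream can rely on label conventions
        perm = rng.permutation(6)
        label_of = {LINEAGES[i]: f"H{perm[i] + 1}" for i in range(6)}

        group_chroms = {}
        for lin in LINEAGES:
            chrom = f"{FOCAL_TAXON}.g{g + 1:02d}.{label_of[lin]}"
            group_chroms[lin] = chrom
            genes[chrom] = _make_records(
                chrom, tip_sets[lin], spacer_len=config.intergenic_length,
                rng=rng)
            tails[chrom] = random_nucleotides(config.intergenic_length, rng)
            chrom_rows.append(dict(
                chromosome=chrom, taxon=FOCAL_TAXON, group=g,
                lineage=lin, subgenome=SUBGENOME_OF[lin],
                pair=f"g{g + 1:02d}.{PAIR_OF[lin]}",
                homolog=label_of[lin],
            ))
        for taxon, cds_list in (("Hann", hann), ("Mmic", mmic)):
            chrom = f"{taxon}.g{g + 1:02d}"
            genes[chrom] = _make_records(
                chrom, cds_list, spacer_len=config.intergenic_length, rng=rng)
            tails[chrom] = random_nucleotides(config.intergenic_length, rng)
            chrom_rows.append(dict(
                chromosome=chrom, taxon=taxon, group=g, lineage=taxon,
                subgenome=None, pair=None, homolog=None,
            ))

        for j in range(config.genes_per_chromosome):
            og = f"g{g + 1:02d}.og{j:04d}"
            for lin in LINEAGES:
                chrom = group_chroms[lin]
                og_rows.append(dict(og_id=og, group=g, chromosome=chrom,
                                    gene_id=genes[chrom][j].gene_id))
            for taxon in OUTGROUPS:
                chrom = f"{taxon}.g{g + 1:02d}"
                og_rows.append(dict(og_id=og, group=g, chromosome=chrom,
                                    gene_id=genes[chrom][j].gene_id))

        # planted WGD-like duplicated block (focal + Hann chromosomes):
        # the last `wgd_block_genes` genes are duplicated as a collinear
        # block appended at the chromosome end, at the target paralog Ks
        nblock = min(config.wgd_block_genes, config.genes_per_chromosome)
        if nblock > 0 and config.wgd_paralog_ks > 0:
            dup_chroms = [group_chroms[lin] for lin in LINEAGES]
            dup_chroms.append(f"Hann.g{g + 1:02d}")
            for chrom in dup_chroms:
                sources = genes[chrom][-nblock:]
                dup_cds = [
                    mutate_pair_at_ks(
                        src.cds, config.wgd_paralog_ks,
                        config.wgd_paralog_ks * config.wgd_paralog_ka_ks, rng)
                    for src in sources
                ]
                dups = _make_records(
                    chrom, dup_cds, prefix="d",
                    spacer_len=config.intergenic_length, rng=rng,
                    id_indices=[int(s.gene_id.rsplit("g", 1)[-1])
                                for s in sources])
                for src, dup in zip(sources, dups):
                    paralog_rows.append(dict(
                        gene_id=dup.gene_id, source_gene_id=src.gene_id,
                        chromosome=chrom, planted_ks=config.wgd_paralog_ks,
                        planted_ka=config.wgd_paralog_ks
                        * config.wgd_paralog_ka_ks,
                    ))
                genes[chrom].extend(dups)

    dataset = SimulatedDataset(
        config=config,
        genes=genes,
        tail_spacers=tails,
        chromosomes=pd.DataFrame(chrom_rows),
        truth_orthologs=pd.DataFrame(og_rows),
        truth_paralogs=pd.DataFrame(
            paralog_rows,
            columns=["gene_id", "source_gene_id", "chromosome",
                     "planted_ks", "planted_ka"],
        ),
        provenance=dict(
            config={k: (v if not dataclasses.is_dataclass(v)
                        else dataclasses.asdict(v))
                    for k, v in dataclasses.asdict(config).items()},
            seed=config.seed,
            note="split-time defaults are calibrated to printed summary "
                 "statistics, not asserted as biological point estimates",
        ),
    )
    if config.translocation_map:
        dataset = apply_karyotype_map(dataset, config.translocation_map)
    if config.family_spec is not None:
        from .family import plant_gene_family

        dataset = plant_gene_family(dataset, config.family_spec, rng=rng)
    dataset.rebuild()
    return dataset


def apply_karyotype_map(dataset: SimulatedDataset, translocation_map,
                        record_events: bool = True) -> SimulatedDataset:
    """Cut and re-join gene blocks between chromosomes.

    ``translocation_map`` is a sequence of
    ``(source_chromosome, ((start_rank, end_rank, dest_chromosome), ...))``
    entries; ranks are 0-based and half-open, and the segments of each source
    must partition its current gene list. The set of destination chromosomes
    must equal the set of sources (content is permuted among them). Each
    source split into k segments records k-1 breaks; each destination
    assembled from m segments records m-1 fusions.
    """
    if not translocation_map:
        return dataset

    sources = [src for src, _ in translocation_map]
    if len(set(sources)) != len(sources):
        raise ValueError("duplicate source chromosome in map")
    dests = {seg[2] for _, segs in translocation_map for seg in segs}
    if dests != set(sources):
        raise ValueError(
            "destination chromosomes must be exactly the source set")
    for src, segs in translocation_map:
        if src not in dataset.genes:
            raise ValueError(f"unknown chromosome {src!r}")
        n = len(dataset.genes[src])
        segs_sorted = sorted(segs, key=lambda s: s[0])
        cursor = 0
        for start, end, _dest in segs_sorted:
            if start != cursor or end <= start:
                raise ValueError(
                    f"segments of {src} do not partition its genes")
            cursor = end
        if cursor != n:
            raise ValueError(f"segments of {src} do not partition its genes")

    # keyed in source order so downstream output order is deterministic
    pieces: dict[str, list[tuple[str, list[GeneRecord]]]] = {
        s: [] for s in sources}
    events = []
    for src, segs in translocation_map:
        records = dataset.genes[src]
        for k, (start, end, dest) in enumerate(segs):
            pieces[dest].append((src, records[start:end]))
            if k > 0 and record_events:
                events.append(dict(event="break", lineage=_taxon_of(src),
                                   chromosome=src, position=start,
                                   detail=f"fission before rank {start}"))

    new_genes = dict(dataset.genes)
    for dest, segments in pieces.items():
        merged: list[GeneRecord] = []
        for k, (src, recs) in enumerate(segments):
            for rec in recs:
                rec.chromosome = dest
            merged.extend(recs)
            if k > 0 and record_events:
                events.append(dict(
                    event="fusion", lineage=_taxon_of(dest), chromosome=dest,
                    position=len(merged) - len(recs),
                    detail=f"joined segment from {src}"))
        new_genes[dest] = merged

    dataset.genes = new_genes
    if record_events and events:
        new_rows = pd.DataFrame(events)
        if dataset.truth_rearrangements.empty:
            dataset.truth_rearrangements = new_rows
        else:
            dataset.truth_rearrangements = pd.concat(
                [dataset.truth_rearrangements, new_rows], ignore_index=True)
    dataset.rebuild()
    return dataset


def invert_segment(dataset: SimulatedDataset, chrom: str, start_rank: int,
                   end_rank: int, record_event: bool = True) -> SimulatedDataset:
    """Invert the gene block [start_rank, end_rank) on ``chrom`` in place:
    gene order is reversed and every gene's strand is flipped."""
    records = dataset.genes.get(chrom)
    if records is None:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not (0 <= start_rank < end_rank <= len(records)):
        raise ValueError("inversion ranks outside the chromosome")
    block = records[start_rank:end_rank][::-1]
    for rec in block:
        rec.strand = "-" if rec.strand == "+" else "+"
    dataset.genes[chrom] = records[:start_rank] + block + records[end_rank:]
    if record_event:
        row = pd.DataFrame([dict(
            event="inversion", lineage=_taxon_of(chrom), chromosome=chrom,
            position=start_rank,
            detail=f"ranks [{start_rank}, {end_rank}) reversed")])
        if dataset.truth_rearrangements.empty:
            dataset.truth_rearrangements = row
        else:
            dataset.truth_rearrangements = pd.concat(
                [dataset.truth_rearrangements, row], ignore_index=True)
    dataset.rebuild()
    return dataset


def _taxon_of(chrom: str) -> str:
    return chrom.split(".", 1)[0]
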