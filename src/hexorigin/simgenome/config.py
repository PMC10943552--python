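"""Configuration for the synthetic hexaploid generator.

The defaults are calibrated so that the statistics measured downstream land
on the values the study system exhibits: ~2.3% nucleotide divergence within
a heterozygous chromosome pair (97.7% gene identity), slightly larger
divergence between subgenomes (~97.2-97.3% identity), ~5% divergence to the
sunflower-like outgroup at 2.5 million years (mya), and a planted
whole-genome-duplication paralog peak at Ks ~ 0.55.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Lesion:
    """A single disabling lesion planted in one gene-family copy.

    ``kind`` is one of ``frameshift`` (1-nt insertion), ``internal_stop``
    (point mutation to TAA), or ``truncation`` (loss of the 3' terminal part
    of the locus). ``codon`` is the 0-based codon coordinate of the lesion;
    for ``truncation`` it is the first missing codon.
    """

    copy_index: int
    kind: str = "frameshift"
    codon: int = 150

    def __post_init__(self):
        if self.kind not in ("frameshift", "internal_stop", "truncation"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")


@dataclass(frozen=True)
class SubfamilyPlacement:
    """Placement of one WGD-derived clade of family copies.

    One primary copy is placed on each listed homologous chromosome.
    ``homolog_indices`` are 0-based indices into the group's six chromosomes
    in subgenome order (A1a, A1b, A2a, A2b, Ba, Bb), so ``(0, 2, 4)`` puts a
    copy on one representative of each heterozygous pair. With
    ``copies_per_chromosome`` > 1 the extra copies are tandem duplicates at
    adjacent gene ranks.
    """

    clade: int
    group: int
    homolog_indices: tuple[int, ...]
    copies_per_chromosome: int = 1
    tandem: bool = False
    insert_after_rank: int = 30

    def __post_init__(self):
        if self.copies_per_chromosome > 1 and not self.tandem:
            raise ValueError("multiple copies per chromosome must be tandem")


@dataclass(frozen=True)
class FamilySpec:
    """A planted GH32-like gene family with known duplication history."""

    name: str = "FEHII"
    length_codons: int = 300
    clade_ks: float = 0.55       # divergence between WGD-derived clades
    speciation_ks: float = 0.05  # focal species vs outgroup ortholog
    wgt3_ks: float = 0.03        # among copies on homologous chromosomes
    tandem_ks: float = 0.005     # tandem duplicate vs its template
    ka_ks_ratio: float = 0.05    # strong purifying selection on the enzymes
    placements: tuple[SubfamilyPlacement, ...] = ()
    lesions: tuple[Lesion, ...] = ()
    outgroup_copies: bool = True  # one outgroup ortholog per clade

    def validate(self, n_groups: int) -> None:
        for p in self.placements:
            if not (0 <= p.group < n_groups):
                raise ValueError(f"placement group {p.group} outside dataset")
            for h in p.homolog_indices:
                if not (0 <= h < 6):
                    raise ValueError(f"homolog index {h} out of range")
        n_copies = self.total_copies()
        seen = set()
        for les in self.lesions:
            if not (0 <= les.copy_index < n_copies):
                raise ValueError("lesion references a missing copy")
            if les.copy_index in seen:
                raise ValueError("at most one lesion per copy")
            if les.kind != "truncation" and not (
                0 < les.codon < self.length_codons - 1
            ):
                raise ValueError("lesion coordinate outside the CDS")
            seen.add(les.copy_index)

    def total_copies(self) -> int:
        return sum(
            len(p.homolog_indices) * p.copies_per_chromosome
            for p in self.placements
        )


def default_fehii_spec() -> FamilySpec:
    """The 1-FEHII-like configuration: two tandem copies on each of the three
    subgenome representatives of one homologous group plus one copy on each
    of the three representatives of a second group — nine copies from two
    WGD-derived clades, one carrying a 1-nt frameshift insertion."""
    return FamilySpec(
        name="FEHII",
        placements=(
            SubfamilyPlacement(
                clade=0, group=0, homolog_indices=(0, 2, 4),
                copies_per_chromosome=2, tandem=True,
            ),
            SubfamilyPlacement(clade=1, group=1, homolog_indices=(0, 2, 4)),
        ),
        lesions=(Lesion(copy_index=3, kind="frameshift", codon=150),),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic autoallohexaploid dataset.

    Times are in millions of years (mya); ``pairwise_divergence_rate`` is the
    expected substitutions/site accumulating per my BETWEEN two lineages
    (i.e. twice the per-lineage rate), so two taxa separated at time t are
    ``rate * t`` substitutions/site apart. If ``intra_pair_divergence`` is
    given it overrides ``t_pair_split`` via t = divergence / rate.
    """

    n_groups: int = 3
    genes_per_chromosome: int = 60
    cds_length_codons: int = 300
    t_outgroup: float = 21.5      # Mmic-like outgroup split
    t_htub_hann: float = 2.5      # focal species vs Hann-like outgroup
    t_ab_split: float = 1.5       # A-genome vs B-genome donors
    t_subgenome_split: float = 1.35  # A1 vs A2 (autotetraploid doubling)
    t_pair_split: float = 1.15    # within heterozygous pairs (hybridization)
    pairwise_divergence_rate: float = 0.02
    intra_pair_divergence: float | None = 0.023
    wgd_paralog_ks: float = 0.55
    wgd_block_genes: int = 15     # genes in the planted duplicated block
    wgd_paralog_ka_ks: float = 0.2
    intergenic_length: int = 200
    translocation_map: tuple = ()
    family_spec: FamilySpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.intra_pair_divergence is not None:
            object.__setattr__(
                self,
                "t_pair_split",
                self.intra_pair_divergence / self.pairwise_divergence_rate,
            )
        times = (self.t_outgroup, self.t_htub_hann, self.t_ab_split,
                 self.t_subgenome_split, self.t_pair_split)
        if not all(t > 0 for t in times):
            raise ValueError("all split times must be positive")
        if not (self.t_outgroup > self.t_htub_hann > self.t_ab_split
                > self.t_subgenome_split >= self.t_pair_split):
            raise ValueError(
                "split times must satisfy t_outgroup > t_htub_hann > "
                "t_ab_split > t_subgenome_split >= t_pair_split"
            )
        if self.pairwise_divergence_rate <= 0:
            raise ValueError("divergence rate must be positive")
        if self.wgd_paralog_ks < 0 or self.wgd_paralog_ka_ks < 0:
            raise ValueError("paralog divergences must be non-negative")
        if self.n_groups < 1 or self.n_groups > 17:
            raise ValueError("n_groups must be in 1..17")
        if self.genes_per_chromosome < 1 or self.cds_length_codons < 10:
            raise ValueError("degenerate gene content")
        if self.family_spec is not None:
            self.family_spec.validate(self.n_groups)

    @property
    def lineage_rate(self) -> float:
        """Expected substitutions/site per my along one lineage."""
        return self.pairwise_divergence_rate / 2.0
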