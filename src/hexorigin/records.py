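"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class GeneRecord:
    """One gene model on a chromosome.

    ``rank`` is the 0-based ordinal position along the chromosome; ``start``
    and ``end`` are 1-based inclusive genomic coordinates (GFF3 convention).
    For true genes the CDS length is divisible by 3 and ``protein`` is its
    translation (stop codon stripped); for lesioned copies the protein is
    whatever the broken reading frame yields up to the first stop.
    """

    gene_id: str
    chromosome: str
    rank: int
    start: int = 0
    end: int = 0
    strand: str = "+"
    cds: str = ""
    protein: str = ""
    attributes: dict = field(default_factory=dict)

    def copy(self, **changes) -> "GeneRecord":
        new = replace(self, **changes)
        new.attributes = dict(self.attributes)
        new.attributes.update(changes.get("attributes", {}))
        return new
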