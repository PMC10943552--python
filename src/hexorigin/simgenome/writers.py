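"""On-disk emission of a simulated dataset.

Layout under the output directory:

* ``genome.fasta``   — one record per chromosome
* ``cds.fasta`` / ``proteins.fasta`` — one record per gene
* ``genes.gff3``     — gene/mRNA/CDS features, 1-based inclusive
* ``truth/*.tsv``    — ground-truth tables
* ``provenance.json``— configuration + seed
"""

from __future__ import annotations

import json
from pathlib import Path


def _fasta(path: Path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_dataset(dataset, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    dataset.rebuild()
    chroms = list(dataset.genes)
    _fasta(out / "genome.fasta",
           ((c, dataset.genome_sequence(c)) for c in chroms))
    _fasta(out / "cds.fasta",
           ((r.gene_id, r.cds) for r in dataset.all_records()))
    _fasta(out / "proteins.fasta",
           ((r.gene_id, r.protein) for r in dataset.all_records() if r.protein))

    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in chroms:
            fh.write(f"##sequence-region {chrom} 1 "
                     f"{len(dataset.genome_sequence(chrom))}\n")
            for rec in dataset.genes[chrom]:
                attrs = f"ID={rec.gene_id}"
                if rec.attributes.get("family"):
                    attrs += f";family={rec.attributes['family']}"
                if rec.attributes.get("lesion"):
                    attrs += f";lesion={rec.attributes['lesion']}"
                base = (f"{chrom}\thexorigin-sim\t{{}}\t{rec.start}\t{rec.end}"
                        f"\t.\t{rec.strand}\t{{}}\t{{}}\n")
                fh.write(base.format("gene", ".", attrs))
                fh.write(base.format("mRNA", ".",
                                     f"ID={rec.gene_id}.t1;Parent={rec.gene_id}"))
                fh.write(base.format("CDS", "0",
                                     f"ID={rec.gene_id}.cds;Parent={rec.gene_id}.t1"))

    truth = {
        "chromosomes.tsv": dataset.chromosomes,
        "orthologs.tsv": dataset.truth_orthologs,
        "paralogs.tsv": dataset.truth_paralogs,
        "rearrangements.tsv": dataset.truth_rearrangements,
        "family.tsv": dataset.truth_family,
    }
    for name, df in truth.items():
        df.to_csv(out / "truth" / name, sep="\t", index=False)

    with open(out / "provenance.json", "w") as fh:
        json.dump(dataset.provenance, fh, indent=1, default=str)
        fh.write("\n")
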