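# Methods

This note records the models and algorithms implemented in `hexorigin`, the
calibration of the synthetic generator, and every place where the package
deliberately substitutes a simpler, checkable method for a heavyweight tool.

## Synthetic hexaploid generator (`hexorigin.simgenome`)

Gene sequences evolve down the fixed species tree
`(((A1a,A1b),(A2a,A2b)),(Ba,Bb))` plus two outgroups (a close relative and a
distant one), under Jukes–Cantor substitution with an elevated
third-codon-position rate (default 4:1). The third-position multiplier lets
synonymous divergence be targeted independently of protein divergence, so
NG86 Ks expectations are analytically checkable. Evolution is indel-free
except for planted lesions; this keeps identity and Ks oracles exact.

Default branch times are a calibration, not biology: they are chosen so the
downstream statistics land on the published values for Jerusalem artichoke —
~5% coding divergence from the close relative at 2.5 mya, ~2.3% divergence
within heterozygous chromosome pairs, intra-subgenome identity 97.7%,
inter-subgenome 97.2–97.3%.

Each dataset carries complete truth tables (ortholog sets, planted
rearrangements, gene-family copies with lesions), and identical
configuration plus seed reproduces byte-identical output.

Planted features:

* `apply_karyotype_map` cuts and re-joins chromosome segments
  (translocations), recording each break and fusion;
* `invert_segment` reverses a gene block and flips strands;
* `plant_gene_family` inserts a GH32-like family with configurable clades
  (deep WGD2-scale split), WGT3-scale cross-chromosome copies, tandem
  duplicates, outgroup orthologs per clade, and lesions (frameshift,
  internal stop, truncation).

## Pairwise alignment (`hexorigin.align_core`)

Global and local alignment with affine gaps (nucleotide defaults
match/mismatch 2/−3, gap open/extend −5/−2; protein BLOSUM62, −11/−1).
Identity is computed over aligned columns excluding terminal gap columns.
The dynamic programs are verified against exhaustive enumeration of all
alignments for short inputs.

## Ortholog detection (`hexorigin.orthology`)

Reciprocal best hits: candidates share ≥2 protein 4-mers with the query,
are ranked by global protein edit distance (computed with `edlib`; at the
2–35% divergence this pipeline sees, edit distance and optimal alignment
distance coincide for ranking purposes), and the champion must clear a
local-alignment score floor. Ortholog groups are connected components of
the RBH graph; a group is single-copy when it has exactly one member per
chromosome. This stands in for BLAST/OrthoFinder at desk scale.

## Subgenome partitioning (`hexorigin.subgenome`)

The 6×6 matrix of mean per-gene CDS identities is searched exhaustively
over all 15 perfect matchings of six chromosomes; the matching maximizing
the summed within-pair identity wins. Greedy pairing is provably wrong on
adversarial matrices (taking the single best cell first can force a
sub-optimal completion), and with 15 candidates exhaustive search is free.
The B subgenome is the pair least similar to the other two; ties trigger an
explicit star-topology warning. The objective is unweighted by gene counts,
matching per-chromosome averaging of the published tables.

## Phylogeny and dating (`hexorigin.phylodate`)

* **MSA:** center-star multiple alignment under "once a gap, always a gap";
  codon alignments are built by aligning translated proteins and expanding
  the gap pattern threefold onto the CDS. Protein-level alignment is far
  more reliable than direct nucleotide alignment beyond ~20% divergence,
  where unit-cost nucleotide alignment starts matching random positions
  through spurious gaps and compresses large distances (and therefore old
  node ages).
* **Distances:** p-distance with JC69 (nucleotide) or Poisson (protein)
  correction; saturated distances are clamped to a finite ceiling with a
  warning. Gapped sites are excluded pairwise.
* **Trees:** Saitou–Nei neighbor joining, exact on additive matrices
  (property-tested against randomly generated trees and cross-checked
  against scikit-bio); negative branch lengths are clamped with the deficit
  moved to the sister branch. Bootstrap support resamples alignment
  columns. NJ on a concatenated supermatrix stands in for ML inference
  (IQ-TREE/ASTRAL): at the divergences simulated here distances are far
  from saturation, where NJ and ML topologies agree.
* **Dating:** mean-path-length (MPL) relative ages with a calibration
  interval pinned at the distant-outgroup split, a relative-rate stand-in
  for MCMCTree. The tree is rooted by splitting the outgroup's terminal
  edge at a clock-consistent point — half the mean patristic distance from
  the outgroup to every other leaf, clamped to the edge. Rooting at the
  outgroup's attachment node instead would average one long root-to-outgroup
  path with many short ingroup paths, deflating the calibration depth and
  inflating every scaled age roughly threefold. Ages are invariant under a
  global rescaling of branch lengths (property-tested).

## Ka/Ks and synteny (`hexorigin.ksynteny`)

* **NG86:** Nei–Gojobori (1986) with pathway averaging, implemented from
  first principles and verified against brute-force enumeration of
  substitution orders for every two-difference codon pair. Synonymous site
  counts treat mutations to stop codons as nonsynonymous; substitution
  paths through stop codons are excluded (falling back to unfiltered
  averaging when every path is blocked). Codon columns containing gaps or
  stops are excluded; estimates with ps or pn at the Jukes–Cantor domain
  edge (3/4) are flagged invalid. NG86 is used instead of the γ-MYN or ML
  estimators of KaKs_Calculator: it is exactly checkable, and at the Ks
  scales that matter here (0.03–0.55) the methods agree closely.
* **Chaining:** anchors (ortholog/paralog gene pairs with chromosome ranks)
  are chained by a quadratic DP maximizing summed anchor scores minus gap
  penalties, per chromosome pair and orientation, greedily extracting the
  best chain and repeating. Blocks require strictly more than
  `min_anchors` (default 10) anchors. The DP equals brute-force subset
  enumeration (property-tested).
* **Ks peaks:** Gaussian KDE in log10(Ks) space; local maxima are reported
  as modes. Peaks are labelled by Ks window (WGT1 ≈ 1.4, WGD2 ≈ 0.55,
  recent ≈ 0.03); the recent window is WGT3 for within-genome paralogs but
  species divergence for between-genome orthologs — the comparison type,
  not the Ks value, disambiguates.

## Karyotype (`hexorigin.karyotype`)

Chromosome correspondence aggregates anchor counts per chromosome pair;
partners under a minor-signal threshold (5%) are dropped, and partner order
follows mean anchor rank. A chromosome pair is one-to-one iff the
correspondence is mutually exclusive in both directions (a symmetric rule,
invariant under genome transposition). Breaks and fusions are counted on
segment adjacencies against an explicit ancestor hypothesis (no ancestral
reconstruction is attempted; counts are lower bounds for any unobserved
ancestor), and the emitted event list replays exactly to both observed
karyotypes (round-trip tested). Inversions are maximal runs of
reverse-orientation blocks along a chromosome.

The published *H. tuberosus* vs *H. annuus* map ships as data
(`PRINTED_HTUB_HANN_MAP`): 9 one-to-one chromosomes plus 8 translocated
ones forming one 2-cycle and two 3-cycles, requiring 8 breaks and 8 fusions
under the close-relative-as-ancestor hypothesis.

## Gene family and pseudogenes (`hexorigin.inulin_family`)

1. **Homology:** every protein is scored against the seed enzymes by local
   alignment; hits with identity and coverage strictly above 90% are
   true-gene candidates.
2. **Domains:** the two GH32 domain segments are detected with
   position-specific scoring over packaged consensus segments, thresholded
   at a seeded 1% false-positive quantile on random proteins. This is a
   deliberate, documented simplification of profile-HMM search (HMMER):
   the PSSM is self-contained, deterministic, and calibratable in-process.
3. **Pseudogenes:** candidates matching a seed well but with low coverage
   are re-examined by a protein-to-locus dynamic program whose states are
   codon match/mismatch (BLOSUM62; stop codons scored as heavy mismatches
   so paths can run through pseudogene stops), codon deletion, +1/+2
   frameshift, and GT..AG-bounded intron skip. Loci whose best path shows
   internal stops, frameshifts, or terminal truncation are called
   pseudogenes; the call is a pure function of the alignment.
4. **Origins:** true copies plus outgroup orthologs are put in a
   nucleotide NJ tree (nucleotide rather than protein: the family's recent
   copies are nearly identical in protein space and only synonymous sites
   resolve them). Focal genes are assigned to WGD2-scale clades by nearest
   outgroup gene in patristic distance — each clade retains its own
   outgroup ortholog, and the deep between-clade divergence dwarfs
   within-clade branches, which makes the assignment robust even when a
   near-zero internal branch breaks strict monophyly. Within a clade,
   same-chromosome copies within 10 gene ranks are tandem; clades spanning
   two or more chromosomes mark their cluster founders WGT3; a
   single-chromosome clade's founder is WGD2-level when at least two clades
   exist.

## Statistical conventions in the tests

Stochastic assertions state the quantity, the tolerance, and the sample
size explicitly, and run on fixed seeds. Where a per-gene comparison is
noise-limited (e.g. within-pair vs between-subgenome p-distance, whose
expected gap is ~6 substitutions over ~900 nt), the tested statistic
averages the available comparisons per gene rather than widening the
tolerance.
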