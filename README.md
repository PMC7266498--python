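# codonguide

Protein-centric CRISPR gRNA design: pick guides by where their cut lands
**relative to an amino acid**, not just anywhere in a gene.

Most gRNA design tools are gene-centric — they enumerate every guide in a
genomic locus and leave it to the user to work out, manually and across
intron-exon boundaries, which guides cut near the residue they actually want
to engineer. That matters because homology-directed repair (HDR) is only
efficient within roughly 30 nt of the nuclease cut site, so site-directed
mutagenesis of a catalytic residue or a PTM site needs guides chosen by
cut-to-codon distance. `codonguide` automates exactly that curation step.

## What it computes

Given a gene's genomic locus with the exons encoded in UPPERCASE (introns and
UTRs lowercase), and the protein's coding sequence (CDS) as a consistency
check, the package:

1. derives the CDS from the uppercase bases, verifies it against the supplied
   one, translates it, and builds a **codon matrix** mapping each residue
   *i* to its codon and the genomic coordinates of the codon's three bases
   (codons split across introns keep their genomic endpoints);
2. scans **both strands** for all protospacer+PAM sites (`NGG` and `YG` with
   the blunt SpCas9 cut 3 nt 5' of the PAM; `TTTN` with the Cas12a proximal
   cut after protospacer base 18) and annotates each 20-nt guide with G/C%,
   leading-G, poly-T (TTTT) and an exact-match off-target count against an
   optional genome FASTA (both strands, minus the on-target site);
3. answers either a **position-specific** query — all guides whose cut lies
   within a chosen distance of residue *p*, split into 5'/3' lists and sorted
   toward the codon — or a **type-specific** query — for every residue of one
   amino-acid type, the closest 5' and 3' guide after removing guides with
   more than 75% G/C.

The signed distance follows four strand/direction conventions (positive =
guide upstream of the codon; measured between the strand-appropriate cut-side
base and codon-end base along genomic DNA), and a cut inside the codon counts
as distance 0.

## Worked example

```bash
python examples/position_query.py
```

builds a deterministic synthetic two-exon gene and targets residue 40 with a
30-nt window:

```
gene: 450 nt locus, 90 residues
target: residue 40 (Q), codon at genomic positions (177, 178, 179)

62 candidate guides in the locus; 16 cut within 30 nt of the codon:

protospacer            PAM   strand    G/C%  dist
CGAGTGGACGGGACATCTCA   AGG   forward   60.0   +27
GAGTGGACGGGACATCTCAA   GGG   forward   55.0   +26
...
AACCTCGGGATACCGCAACC   GGG   forward   60.0    +0
...
GGGGAGTGTAGTAATAATGG   GGG   forward   45.0   -20
```

Of the 62 guides a gene-centric scan would return, only the 16 with a cut
site within 30 nt of the codon survive; `+27` means the guide cuts 27 nt
upstream (5') of the codon, `+0` that it cuts inside the codon — the ideal
case for HDR — and negative values are downstream (3') cuts. The other
examples demonstrate the type-specific query (`examples/type_query.py`) and
off-target counting (`examples/offtarget_counting.py`).

The same pipeline is available as a CLI writing the CSV report:

```bash
codonguide --locus locus.fasta --cds cds.fasta --genome genome.fa \
    --mode position --position 143 --max-distance 30 --pam NGG \
    --output guides.csv
```

## Scope

Off-target counting is exact-match only (no mismatch-tolerant scoring) and no
efficacy score is assigned to guides — outputs are ordered purely by cut-site
proximity to the targeted residue(s). One locus maps to one CDS; the case
encoding is the sole source of gene structure. See `docs/methods.md` for the
model, conventions and limitations.
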