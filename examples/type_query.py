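"""Find the closest guide pair for every residue of one amino-acid type.

Typical use: a post-translational modification (say S-palmitoylation of
cysteines) has been profiled protein-wide but not localised, so every cysteine
needs its own pair of flanking guides.  Guides with more than 75% G/C are
removed before selection.
"""

from codonguide import (
    PAMS,
    ResidueQuery,
    build_codon_matrix,
    extract_guides,
    query_type,
)
from codonguide.synthetic import make_gene

gene = make_gene(seed=7, exon_lengths=[300], pad5=80, pad3=80)
matrix = build_codon_matrix(gene.locus, gene.cds)
guides = extract_guides(gene.locus, PAMS["NGG"])

target = "C"
rows = query_type(guides, matrix, ResidueQuery("type", amino_acid=target))
print(f"{matrix.protein.count(target)} cysteine(s) in a {len(matrix)}-residue "
      f"protein; {len(guides)} candidate guides\n")

for row in rows:
    print(f"residue {row.position:3d}  context {row.context}")
    for label, item in (("5'", row.five_prime), ("3'", row.three_prime)):
        if item is None:
            print(f"   {label} guide: none within the locus")
        else:
            hit, dist = item
            print(f"   {label} guide: {hit.protospacer} ({hit.strand}, "
                  f"cut {dist:+d} nt from the codon)")

print("\neach residue gets the nearest guide on each side; the context string"
      "\nshows the two neighbouring residues with '*' marking the target.")
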