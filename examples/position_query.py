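"""Design guides around one residue of a protein (position-specific query).

Builds a small synthetic two-exon gene, then asks for every NGG guide whose
cut site lies within 30 nt of residue 40 — the range over which
homology-directed repair is efficient enough for site-directed mutagenesis.
"""

from codonguide import (
    PAMS,
    ResidueQuery,
    build_codon_matrix,
    extract_guides,
    query_position,
)
from codonguide.synthetic import make_gene

gene = make_gene(seed=42, exon_lengths=[150, 120], intron_lengths=[60], pad5=60, pad3=60)
matrix = build_codon_matrix(gene.locus, gene.cds)
print(f"gene: {len(gene.raw_locus)} nt locus, {len(matrix)} residues")
print(f"target: residue 40 ({matrix[40].amino_acid}), codon at genomic "
      f"positions {matrix[40].base_positions}")

guides = extract_guides(gene.locus, PAMS["NGG"])
query = ResidueQuery("position", position=40, max_distance=30)
upstream, downstream = query_position(guides, matrix, query)

print(f"\n{len(guides)} candidate guides in the locus; "
      f"{len(upstream) + len(downstream)} cut within 30 nt of the codon:\n")
print(f"{'protospacer':22s} {'PAM':5s} {'strand':8s} {'G/C%':>5s} {'dist':>5s}")
for hit, dist in upstream + downstream:
    print(f"{hit.protospacer:22s} {hit.pam:5s} {hit.strand:8s} "
          f"{hit.gc_percent:5.1f} {dist:+5d}")

print("\npositive distances are 5' (upstream) cuts, negative 3' (downstream);"
      "\nsmaller magnitudes mean better HDR efficiency at the target codon.")
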