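"""Exact-match off-target counting against a toy genome.

Counts additional occurrences of a protospacer across all genome records and
their reverse complements.  The single on-target site does not count, so 0
means the guide is unique in the genome.
"""

from codonguide import Genome, count_offtargets, reverse_complement
from codonguide.synthetic import PlantSpec, make_gene

gene = make_gene(seed=3, exon_lengths=[120], plants=[PlantSpec(residue=20, distance=10)])
proto = gene.planted[0].protospacer
print(f"guide: {proto}")

unique = Genome.from_records([("chr1", gene.raw_locus.upper())])
print(f"genome = locus only           -> off-targets: {count_offtargets(proto, unique)}")

with_copy = Genome.from_records(
    [
        ("chr1", gene.raw_locus.upper()),
        ("chr2", "ACGT" * 20 + reverse_complement(proto) + "TTGA" * 20),
    ]
)
print(f"genome + reverse-strand copy  -> off-targets: {count_offtargets(proto, with_copy)}")

print("\na count of 0 means the only genomic match is the targeted site itself;"
      "\neach extra copy, on either strand, adds 1.")
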