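"""Shared fixtures and independent oracles for the test suite."""

import random

import pytest

# Independently keyed standard genetic code (kept separate from the
# implementation's translation path on purpose).
STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_distance(strand: str, cut5: int, left: int, right: int) -> int:
    """Independent transcription of the four printed distance rules.

    The cut lies between forward indices cut5 and cut5+1; left/right are the
    genomic coordinates of the codon's first/last base.
    """
    if cut5 + 1 <= left:  # guide upstream: positive
        if strand == "forward":
            return left - (cut5 + 1)  # right of cut -> left of codon
        return left - cut5  # left of cut -> left of codon
    if cut5 >= right:  # guide downstream: negative
        if strand == "forward":
            return -(cut5 - right)  # left of cut -> right of codon
        return -((cut5 + 1) - right)  # right of cut -> right of codon
    return 0


def random_structure(rng: random.Random, max_len: int = 2000):
    """A random exon/intron structure within a total-length budget."""
    n_exons = rng.randint(1, 4)
    exon_lengths = [3 * rng.randint(10, 40) for _ in range(n_exons)]
    intron_lengths = [rng.randint(5, 120) for _ in range(n_exons - 1)]
    pad = rng.randint(25, 60)
    while sum(exon_lengths) + sum(intron_lengths) + 2 * pad > max_len:
        exon_lengths = exon_lengths[:1]
        intron_lengths = []
    return exon_lengths, intron_lengths, pad


@pytest.fixture
def small_gene():
    """A reproducible two-exon gene with no plants."""
    from codonguide.synthetic import make_gene

    return make_gene(11, [90, 60], [25], pad5=40, pad3=40)
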