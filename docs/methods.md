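# Methods

## Model

A gene is represented by its genomic locus as a case-encoded string: exonic
bases UPPERCASE, introns/UTRs lowercase, 5'→3'. Optional upstream/downstream
flanks (~100 nt is a sensible choice) extend the searchable sequence so that
residues near the protein termini can still attract guides; flanks are forced
non-coding regardless of input case. Concatenating the uppercase bases yields
the coding sequence (CDS), which must equal the user-supplied CDS **exactly**
(string identity after uppercasing, not alignment): a mismatch aborts guide
generation, because a wrong intron-exon assignment would silently corrupt
every downstream coordinate. The CDS is translated with the standard genetic
code; a terminal stop codon, if present, is kept as residue `*` and is itself
targetable.

The core data structure is the codon matrix: for residue *i* (1-based), the
amino acid, the codon, and the 0-based genomic coordinates of the codon's
three bases. Codons split across introns keep their genomic coordinates, so
the codon "span" on the genome can be much wider than 3 nt.

All internal coordinates are 0-based; user-facing residue positions are
1-based.

## Guide discovery

Candidate guides are 20-nt protospacers adjacent to a PAM, found by an
overlapping IUPAC motif scan of the uppercased sequence — guides legitimately
span intron/exon boundaries and flanks, since the nuclease acts on genomic
DNA. The forward strand is scanned directly, the reverse strand via the
reverse complement with coordinates mapped back.

Cut geometry per PAM (configurable on `PamSpec`):

| PAM  | side of protospacer | cut position |
|------|---------------------|--------------|
| NGG  | 3' | blunt, 3 nt 5' of the PAM (SpCas9) |
| YG   | 3' | same as NGG (Cas9 convention adopted; the relaxed motif does not change the nuclease) |
| TTTN | 5' | proximal cut of the staggered pair, after protospacer base 18 (Cas12a) |

Each hit stores `cut5_index`, the forward-locus coordinate of the base
immediately 5' of the cut, for both strands — making distance arithmetic
uniform. Hits are ordered by `cut5_index`, forward strand first at ties, then
by protospacer, so output order is fully deterministic.

Annotations: G/C percentage; leading G (protospacer starts with G, favoured
by U6/T7 transcription); poly-T (a TTTT run, a Pol III terminator); high G/C
(> 75%).

## Signed cut-to-codon distance

With the cut between forward indices `c` and `c+1` and the codon's first/last
genomic bases `L`/`R`, the distance is the difference between the
strand-appropriate cut-side base and codon-side base:

* forward, upstream: `L − (c+1)` (positive)
* forward, downstream: `R − c` (negative)
* reverse, upstream: `L − c` (positive)
* reverse, downstream: `R − (c+1)` (negative)

The asymmetry between strands is deliberate: each strand measures from its
own 5' side of the cut. A cut inside the codon span (`L ≤ c < R`) scores 0,
and zero-distance guides are classified as upstream/5' for list assignment —
the sign rules do not define the zero case, and "inside the codon" is the
best possible outcome for HDR, so it sorts to the most proximal 5' slot.
Distances are genomic: an intron between the cut and the codon inflates the
distance, which is faithful to what HDR template design cares about.

## Queries

**Position-specific.** Guides with |distance| > the window are removed (no
window = every guide in the locus, the default). The remainder are split by
sign; the 5' list is sorted by decreasing distance and the 3' list by
increasing magnitude, so both lists read toward the codon. No G/C filter is
applied in this mode — high G/C is surfaced in Notes only.

**Type-specific.** Guides over 75% G/C are removed *first*; then, for every
residue of the queried type, the minimum-|distance| surviving guide on each
side is selected (ties: forward strand, then lexicographically smaller
protospacer). A side with no guide is reported explicitly empty. Each row
carries the residue position and its ±2-residue context with `*` marking the
target, padded with `-` at the protein termini.

## Off-target counting

Exact-match only: occurrences of the protospacer are counted in every genome
record and in each record's reverse complement (matches cannot span record
boundaries), then 1 is subtracted for the on-target site and the result is
floored at 0 — the floor guards against guides lying in flank sequence absent
from the genome file. A self-reverse-complementary protospacer is counted
once per strand occurrence; this double-counting is accepted and noted here.
No mismatch-tolerant scoring or PAM requirement is applied at off-target
sites, so the count is a uniqueness screen, not a cleavage-likelihood score.

## Output

CSV, RFC-4180. Position mode: `gRNA Sequence, PAM, Strand, G/C Content,
Distance from aa (bp), Notes, Off-target Count`. Type mode: `Amino Acid
Position, Adjacent amino acids, 5' gRNA Sequence, 3' gRNA Sequence` followed
by two repeated per-guide groups (`PAM, Strand, G/C Content, Distance of cut
site from Amino Acid (bp), Notes, Off-target Count`), the first group for the
5' guide and the second for the 3' guide. G/C is printed with one decimal,
distances as signed integers, and Notes as semicolon-joined phrases
(`polyT`; `leading G`; `G/C > 75%`). Without a genome file the off-target
cells are left blank and a warning is logged, keeping the tool fully usable
offline.

## Synthetic genes and testing

`codonguide.synthetic` generates test genes: uniform-ACGT background with
exon codons drawn from the 61 sense codons (so the CDS is stop-free), a
requested exon/intron structure, and optionally guides *planted* at exact
signed distances from chosen residues by inverting the distance rules to a
cut coordinate and writing protospacer+PAM into the sequence. Construction is
rejection-sampled (default cap 1000 attempts) until every planted protospacer
is unique across both strands, recoverable at its intended coordinate by the
brute-force oracle, and the CDS remains stop-free; infeasible geometry
(overlapping plants, plants outside the locus) fails fast. The companion
`oracle_find_guides` is an independent exhaustive window scan used to verify
the production scanner — test equivalence of the two is checked over hundreds
of random loci.

What the generator does **not** emulate: codon-usage bias, realistic
intron/exon length distributions, repeat content, or GC heterogeneity of real
genomes. Passing tests therefore demonstrate coordinate/selection
correctness, not performance or guide yield on any particular organism.

## Numerical and interface choices

* Problem sizes in tests and the reproduction script (loci ≤ 2 kb, a few
  hundred genes, toy genomes) were chosen to exercise every code path —
  multi-exon structures, split codons, both strands, all three PAMs — while
  keeping the whole suite near-instant; all logic is exact integer/string
  arithmetic, so size does not affect correctness.
* IUPAC ambiguity codes are rejected in the locus (an ambiguous exonic base
  breaks translation); `N` is accepted in the genome FASTA, where it simply
  never matches a guide.
* A CDS whose length is not a multiple of 3 is a hard error, never a
  truncation.
* The legacy genome filename `INSERT_ORGANISM_GENOME_HERE.txt` is honoured as
  a fallback when `--genome` is omitted and the file exists in the working
  directory.

## Limitations

* No guide efficacy scores (Doench etc.) and no mismatch-tolerant off-target
  scores; ordering is purely by cut-site proximity.
* One locus, one CDS: no transcript isoforms, no alignment-based exon
  inference.
* Single-residue queries only; amino-acid motif queries and multi-gene batch
  runs are out of scope.
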