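"""Synthetic gene construction and an independent brute-force guide oracle.

``make_gene`` builds a case-encoded locus with a requested exon/intron
structure and, optionally, guides planted at exact signed cut-site distances
from chosen residues — so discovery, distance and selection logic can be
tested against known ground truth without any genome download.
``oracle_find_guides`` is a deliberately naive exhaustive window scan written
independently of the production scanner, for equivalence testing.

Background composition is uniform over ACGT; construction is rejection-sampled
(bounded attempts) until every planted guide is uniquely recoverable and the
coding sequence is free of internal stop codons.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import FixtureError
from .guides import PAMS, GuideHit, PamSpec
from .locus import AnnotatedLocus, parse_locus

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant one guide at a signed distance from a residue.

    ``residue`` is 1-based; ``distance`` is the signed cut-to-codon distance
    the planted guide must have (positive = upstream/5', 0 = cut inside the
    codon); ``protospacer`` may fix the 20-nt sequence (random otherwise).
    """

    residue: int
    distance: int
    strand: str = "forward"
    pam: str = "NGG"
    protospacer: str | None = None


@dataclass(frozen=True)
class PlantedGuide:
    """A realised plant: the concrete guide and where it landed."""

    spec: PlantSpec
    protospacer: str
    pam: str
    strand: str
    cut5_index: int


@dataclass(frozen=True)
class SyntheticGene:
    """A generated locus with known structure and planted guides."""

    seed: int
    raw_locus: str  # case-encoded
    cds: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    planted: tuple[PlantedGuide, ...] = field(default=())

    @property
    def locus(self) -> AnnotatedLocus:
        return parse_locus(self.raw_locus)


def _exon_positions(exon_lengths, intron_lengths, pad5: int) -> list[int]:
    positions = []
    cursor = pad5
    for i, elen in enumerate(exon_lengths):
        positions.extend(range(cursor, cursor + elen))
        cursor += elen
        if i < len(intron_lengths):
            cursor += intron_lengths[i]
    return positions


def _invert_distance(distance: int, strand: str, left: int, right: int) -> int:
    """Cut5 coordinate giving the requested signed distance to a codon."""
    if distance > 0:
        return left - distance - 1 if strand == "forward" else left - distance
    if distance < 0:
        return right - distance if strand == "forward" else right - distance - 1
    return left  # cut between the codon's first and second genomic base


def _plant_geometry(spec: PlantSpec, pam: PamSpec, codon_bases, total: int):
    """Forward-coordinate spans for a plant: (cut5, local segment span, strand).

    The segment is the contiguous protospacer+PAM block on the protospacer
    strand; for reverse plants its forward-strand footprint is the mirrored
    span, to be filled with the reverse complement of the segment.
    """
    left, right = codon_bases[0], codon_bases[2]
    cut5 = _invert_distance(spec.distance, spec.strand, left, right)
    c_local = cut5 if spec.strand == "forward" else total - 2 - cut5
    pam_start = c_local - pam.cut_offset
    a, b = pam.protospacer_span(pam_start)
    seg_lo = min(a, pam_start)
    seg_hi = max(b, pam_start + len(pam.pattern))
    if spec.strand == "forward":
        fwd_span = (seg_lo, seg_hi)
    else:
        fwd_span = (total - seg_hi, total - seg_lo)
    if fwd_span[0] < 0 or fwd_span[1] > total:
        raise FixtureError(
            f"plant at distance {spec.distance} from residue {spec.residue} "
            "falls outside the locus; lengthen the padding"
        )
    pam_is_first = pam.side == "5prime"
    return cut5, fwd_span, pam_is_first


def _concrete_pam(pattern: str, rng: random.Random) -> str:
    return "".join(
        ch if ch in "ACGT" else rng.choice({"N": "ACGT", "Y": "CT"}[ch])
        for ch in pattern
    )


_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def make_gene(
    seed: int,
    exon_lengths,
    intron_lengths=(),
    plants=(),
    pad5: int = 30,
    pad3: int = 30,
    terminal_stop: bool = False,
    max_attempts: int = 1000,
) -> SyntheticGene:
    """Build a synthetic gene with the requested structure and plants.

    The returned locus is pad5 lowercase background + alternating
    exon(UPPER)/intron(lower) blocks + pad3 lowercase background.  Every plant
    is verified against the brute-force oracle: the planted protospacer must
    occur exactly once across both strands and be recovered at its intended
    cut coordinate; the CDS must translate without internal stops.  Failing
    attempts are re-rolled with fresh background up to ``max_attempts``.
    """
    exon_lengths = tuple(exon_lengths)
    intron_lengths = tuple(intron_lengths)
    plants = tuple(plants)
    if len(intron_lengths) != max(len(exon_lengths) - 1, 0):
        raise FixtureError("need exactly one intron length between adjacent exons")
    cds_len = sum(exon_lengths)
    if cds_len % 3 != 0:
        raise FixtureError(f"total exon length {cds_len} not divisible by 3")
    n_res = cds_len // 3
    total = pad5 + cds_len + sum(intron_lengths) + pad3
    exon_pos = _exon_positions(exon_lengths, intron_lengths, pad5)
    exon_set = set(exon_pos)

    # plant geometry is structural, so infeasibility is detected up front
    geometries = []
    for spec in plants:
        if not 1 <= spec.residue <= n_res:
            raise FixtureError(f"plant residue {spec.residue} outside protein")
        codon_bases = exon_pos[3 * spec.residue - 3 : 3 * spec.residue]
        geometries.append(
            _plant_geometry(spec, PAMS[spec.pam], codon_bases, total)
        )
    spans = sorted(g[1] for g in geometries)
    for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
        if a1 < b0:
            raise FixtureError("planted guides overlap; space the distances out")

    for attempt in range(max_attempts):
        rng = random.Random(seed * 1_000_003 + attempt)
        bases = [rng.choice("ACGT") for _ in range(total)]
        # sample exon codons from the sense set so the background CDS is
        # stop-free; plants overwriting exons are re-checked below
        for ci in range(n_res):
            codon = rng.choice(_SENSE_CODONS)
            for k in range(3):
                bases[exon_pos[3 * ci + k]] = codon[k]
        if terminal_stop:
            for offset, b in zip((-3, -2, -1), "TAA"):
                bases[exon_pos[offset]] = b

        planted: list[PlantedGuide] = []
        for spec, (cut5, (lo, hi), pam_is_first) in zip(plants, geometries):
            pam_seq = _concrete_pam(PAMS[spec.pam].pattern, rng)
            proto = spec.protospacer or "".join(
                rng.choice("ACGT") for _ in range(20)
            )
            segment = pam_seq + proto if pam_is_first else proto + pam_seq
            if spec.strand == "reverse":
                segment = _revcomp(segment)
            bases[lo:hi] = segment
            planted.append(
                PlantedGuide(spec, proto, pam_seq, spec.strand, cut5)
            )

        cds = "".join(bases[i] for i in exon_pos)
        codons = [cds[i : i + 3] for i in range(0, cds_len, 3)]
        internal = codons[:-1] if terminal_stop else codons
        if any(c in _STOP_CODONS for c in internal):
            continue
        if terminal_stop and codons[-1] not in _STOP_CODONS:
            continue

        raw = "".join(
            b if i in exon_set else b.lower() for i, b in enumerate(bases)
        )
        if _plants_recoverable(raw, planted):
            return SyntheticGene(
                seed=seed,
                raw_locus=raw,
                cds=cds,
                exon_lengths=exon_lengths,
                intron_lengths=intron_lengths,
                planted=tuple(planted),
            )
    raise FixtureError(
        f"could not realise the requested plants in {max_attempts} attempts"
    )


def _plants_recoverable(raw_locus: str, planted) -> bool:
    upper = raw_locus.upper()
    rc = _revcomp(upper)
    by_pam: dict[str, list[GuideHit]] = {}
    for pg in planted:
        if upper.count(pg.protospacer) + rc.count(pg.protospacer) != 1:
            return False  # protospacer must be unique across both strands
        hits = by_pam.setdefault(
            pg.spec.pam, oracle_find_guides(raw_locus, pg.spec.pam)
        )
        match = [
            h
            for h in hits
            if h.protospacer == pg.protospacer
            and h.strand == pg.strand
            and h.cut5_index == pg.cut5_index
        ]
        if len(match) != 1:
            return False
        # no unintended guide may collide with a planted cut coordinate
        collisions = [
            h
            for h in hits
            if h.cut5_index == pg.cut5_index
            and h.strand == pg.strand
            and h.protospacer != pg.protospacer
        ]
        if collisions:
            return False
    return True


def oracle_find_guides(locus: str, pam: PamSpec | str) -> list[GuideHit]:
    """Exhaustive brute-force guide scan, independent of the production code.

    Tests every window on both strands with a literal per-character motif
    check and hardcoded per-nuclease cut geometry.  O(L * |PAM|); intended for
    small test loci only.
    """
    name = pam if isinstance(pam, str) else pam.name
    pattern, side = {
        "NGG": ("NGG", "3prime"),
        "YG": ("YG", "3prime"),
        "TTTN": ("TTTN", "5prime"),
    }[name]
    allowed = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT", "Y": "CT"}
    seq = locus.upper()
    total = len(seq)
    hits: list[GuideHit] = []
    for strand, s in (("forward", seq), ("reverse", _revcomp(seq))):
        for p in range(total - len(pattern) + 1):
            if any(s[p + i] not in allowed[ch] for i, ch in enumerate(pattern)):
                continue
            if side == "3prime":
                a, b = p - 20, p
                c_local = p - 4  # blunt Cas9 cut 3 nt 5' of the PAM
            else:
                a, b = p + len(pattern), p + len(pattern) + 20
                c_local = a + 17  # Cas12a proximal cut after protospacer base 18
            if a < 0 or b > total:
                continue
            proto = s[a:b]
            gc = 100.0 * (proto.count("G") + proto.count("C")) / 20
            hits.append(
                GuideHit(
                    protospacer=proto,
                    pam=s[p : p + len(pattern)],
                    strand=strand,
                    cut5_index=c_local if strand == "forward" else total - 2 - c_local,
                    gc_percent=gc,
                    leading_g=proto.startswith("G"),
                    poly_t="TTTT" in proto,
                    high_gc=gc > 75.0,
                )
            )
    hits.sort(key=lambda h: (h.cut5_index, h.strand != "forward", h.protospacer))
    return hits


def make_genome_fasta(path, records) -> None:
    """Write (id, sequence) pairs as a FASTA file for io tests."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
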