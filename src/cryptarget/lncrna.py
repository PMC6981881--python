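"""Positional lncRNA classification, a coding-potential stand-in, and cis-target screening.

Coordinates follow the GFF3 convention: 1-based, closed intervals. A lncRNA
overlapping a protein-coding gene on the same strand is "sense", on the
opposite strand only "antisense", and with no overlap at all it is an
intergenic lncRNA (lincRNA). Overlap is judged on the gene's full span;
no exon-level logic is applied.

The coding score here is a deliberately simple open-reading-frame statistic
standing in for a full coding-potential classifier: it is calibrated so that
a transcript with no ORF scores at or below -1 (called noncoding) and a long
transcript that is nearly one continuous ORF scores at or above +1 (called
coding), with everything in between labelled ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .duplex import DuplexError, normalize_rna

__all__ = [
    "TranscriptModel",
    "LncClass",
    "classify_lncrna",
    "coding_label",
    "orf_score",
    "longest_orf",
    "orf_aa_length",
    "cis_candidates",
]

START_CODON = "AUG"
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

# anchors of the affine coding-score mapping (see orf_score): the floor sits
# strictly below the -1 noncoding cutoff so an ORF-free transcript is CALLED
# noncoding, and the span puts 90% ORF coverage of a >= 300-nt transcript at +1
CODING_SCORE_FLOOR = -1.5
CODING_COVERAGE_ANCHOR = 0.9
CODING_LENGTH_ANCHOR = 300
CODING_SCORE_SPAN = 2.5


@dataclass(frozen=True)
class TranscriptModel:
    """A genomic interval with strand and biotype (GFF3 1-based closed coords)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DuplexError(f"{self.id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise DuplexError(f"{self.id}: strand must be + or -, got {self.strand!r}")

    def overlaps(self, other: "TranscriptModel") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def distance_to(self, other: "TranscriptModel") -> int:
        """0 if the closed intervals overlap or are adjacent, else the number of
        bases strictly between the nearest interval ends."""
        if self.chrom != other.chrom:
            raise DuplexError(f"{self.id} and {other.id} are on different chromosomes")
        if self.overlaps(other):
            return 0
        if other.start > self.end:
            return other.start - self.end - 1
        return self.start - other.end - 1


@dataclass(frozen=True)
class LncClass:
    label: str  # lincRNA | sense | antisense
    evidence: str | None  # overlapping gene id, or None for lincRNA


def classify_lncrna(
    tx: TranscriptModel,
    genes: list[TranscriptModel],
    merge_antisense_into_sense: bool = False,
) -> LncClass:
    """Label a lncRNA by overlap with protein-coding genes.

    Same-strand overlap wins over opposite-strand overlap when both exist.
    ``merge_antisense_into_sense`` folds antisense overlaps into the sense
    bucket (for comparison with two-category summaries).
    """
    if tx.biotype != "lncRNA":
        raise DuplexError(f"{tx.id} has biotype {tx.biotype!r}, expected 'lncRNA'")
    same_chrom = [g for g in genes if g.chrom == tx.chrom and g.biotype == "coding"]
    if not same_chrom and not any(g.chrom == tx.chrom for g in genes):
        warnings.warn(
            f"lncRNA {tx.id}: no annotated genes on chromosome {tx.chrom!r}; "
            "classifying as lincRNA",
            stacklevel=2,
        )
    sense = [g for g in same_chrom if tx.overlaps(g) and g.strand == tx.strand]
    if sense:
        return LncClass("sense", sense[0].id)
    anti = [g for g in same_chrom if tx.overlaps(g)]
    if anti:
        label = "sense" if merge_antisense_into_sense else "antisense"
        return LncClass(label, anti[0].id)
    return LncClass("lincRNA", None)


def coding_label(score: float, lower: float = -1.0, upper: float = 1.0) -> str:
    """Three-band call: score < lower -> noncoding; score > upper -> coding; else ambiguous."""
    if lower >= upper:
        raise DuplexError(f"coding_label thresholds must satisfy lower < upper, got {lower}, {upper}")
    if score < lower:
        return "noncoding"
    if score > upper:
        return "coding"
    return "ambiguous"


def longest_orf(transcript_seq: str) -> int:
    """Length in nt (stop codon included) of the longest AUG..stop ORF in the
    three forward frames; 0 if none. Transcript orientation is assumed known,
    so reverse frames are not scanned."""
    seq = normalize_rna(transcript_seq)
    best = 0
    for frame in range(3):
        start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                best = max(best, pos + 3 - start)
                start = None
    return best


def orf_aa_length(orf_nt: int) -> int:
    """Amino acids encoded by an ORF of ``orf_nt`` nucleotides including its stop codon."""
    if orf_nt < 6 or orf_nt % 3:
        raise DuplexError(f"ORF length {orf_nt} nt is not a whole number of codons >= 2")
    return orf_nt // 3 - 1


def orf_score(transcript_seq: str) -> float:
    """Deterministic coding score increasing with longest-ORF coverage.

    score = floor + span * (coverage / coverage_anchor) * min(len / length_anchor, 1),
    so a transcript with no ORF scores -1.5 (below the -1 noncoding cutoff)
    and an ORF covering >= 90% of a transcript of >= 300 nt scores >= +1.
    Sequences shorter than one codon score the 0-ORF value.
    """
    seq = normalize_rna(transcript_seq)
    if len(seq) < 3:
        return CODING_SCORE_FLOOR
    coverage = longest_orf(seq) / len(seq)
    length_factor = min(len(seq) / CODING_LENGTH_ANCHOR, 1.0)
    return CODING_SCORE_FLOOR + CODING_SCORE_SPAN * (coverage / CODING_COVERAGE_ANCHOR) * length_factor


def cis_candidates(
    lnc: TranscriptModel,
    genes: list[TranscriptModel],
    window: int = 100_000,
) -> list[tuple[TranscriptModel, int]]:
    """Protein-coding genes strictly closer than ``window`` bp to the lncRNA locus.

    Distance is 0 for overlap, else the gap between nearest interval ends;
    inclusion is strict (< window), both strands eligible; sorted by
    (distance, gene id).
    """
    out = []
    for g in genes:
        if g.chrom != lnc.chrom or g.biotype != "coding":
            continue
        d = lnc.distance_to(g)
        if d < window:
            out.append((g, d))
    out.sort(key=lambda gd: (gd[1], gd[0].id))
    return out
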