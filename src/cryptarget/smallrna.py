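"""Small-RNA read filtering, composition summaries and a hairpin-fold stand-in.

The fold is a Nussinov maximum-base-pairing dynamic program (AU/GC and
optionally GU pairs, nested structures, hairpin loops of at least
``min_loop`` unpaired bases). It replaces an energy-based folding engine for
precursor validation only: the question asked of it is "does the mature
miRNA sit on one arm of a well-paired hairpin", not "what is the MFE
structure".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .duplex import DuplexError, MatureMiRNA, normalize_rna

__all__ = [
    "ReadSet",
    "HairpinFold",
    "PrecursorVerdict",
    "filter_reads",
    "length_histogram",
    "five_prime_bias",
    "nussinov_fold",
    "validate_precursor",
]


@dataclass(frozen=True)
class ReadSet:
    """Small-RNA reads as (id, RNA 5'->3') with the length bounds they satisfy."""

    reads: tuple[tuple[str, str], ...]
    length_range: tuple[int, int]
    n_input: int

    @property
    def n_kept(self) -> int:
        return len(self.reads)

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


def filter_reads(
    reads: list[tuple[str, str]], min_len: int = 18, max_len: int = 30
) -> ReadSet:
    """Keep reads with min_len <= length <= max_len (both inclusive)."""
    if min_len > max_len:
        raise DuplexError(f"min_len {min_len} > max_len {max_len}")
    kept = tuple(
        (rid, normalize_rna(seq)) for rid, seq in reads if min_len <= len(seq) <= max_len
    )
    return ReadSet(reads=kept, length_range=(min_len, max_len), n_input=len(reads))


def length_histogram(readset: ReadSet) -> tuple[dict[int, int], int | None, float]:
    """(length -> count, modal length, modal fraction). Empty sets give (., None, 0.0)."""
    counts = Counter(len(seq) for _, seq in readset.reads)
    if not counts:
        return {}, None, 0.0
    # deterministic mode: highest count, ties to the shortest length
    modal_len = min(counts, key=lambda ln: (-counts[ln], ln))
    return dict(sorted(counts.items())), modal_len, counts[modal_len] / readset.n_kept


def five_prime_bias(readset: ReadSet) -> dict[str, float]:
    """Frequency of each of A/C/G/U at read position 1; frequencies sum to 1."""
    if readset.n_kept == 0:
        raise DuplexError("cannot compute 5' base bias of an empty read set")
    counts = Counter(seq[0] for _, seq in readset.reads)
    return {b: counts.get(b, 0) / readset.n_kept for b in "ACGU"}


@dataclass(frozen=True)
class HairpinFold:
    """A nested (pseudoknot-free) pairing: 0-based pairs (i, j) with i < j."""

    seq: str
    pairs: tuple[tuple[int, int], ...]
    structure: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def nussinov_fold(seq: str, min_loop: int = 3, allow_gu: bool = True) -> HairpinFold:
    """Maximize base-pair count over nested structures; deterministic traceback.

    Ties are broken toward pairing the smallest i, then its smallest admissible
    partner j, so the structure is a pure function of the sequence.
    """
    s = normalize_rna(seq)
    n = len(s)
    ok_pairs = _CANONICAL | _GU if allow_gu else _CANONICAL

    def can_pair(i: int, j: int) -> bool:
        return (s[i], s[j]) in ok_pairs and j - i > min_loop

    # M[i][j] = max pairs in s[i..j]
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    inner = M[i + 1][k - 1] if k - i > 1 else 0
                    outer = M[k + 1][j] if k < j else 0
                    best = max(best, 1 + inner + outer)
            M[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i][j] == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):  # smallest partner first
            if can_pair(i, k):
                inner = M[i + 1][k - 1] if k - i > 1 else 0
                outer = M[k + 1][j] if k < j else 0
                if 1 + inner + outer == M[i][j]:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))

    pairs.sort()
    structure = ["."] * n
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    return HairpinFold(seq=s, pairs=tuple(pairs), structure="".join(structure))


def _hairpin_loops(fold: HairpinFold) -> list[tuple[int, int]]:
    """Closing pairs (i, j) with no pair strictly inside: the hairpin loops."""
    loops = []
    for i, j in fold.pairs:
        if not any(i < a and b < j for a, b in fold.pairs):
            loops.append((i, j))
    return loops


@dataclass(frozen=True)
class PrecursorVerdict:
    valid: bool
    reason: str
    paired_fraction: float
    helix_fraction: float
    mature_start: int  # -1 when the mature is absent
    fold: HairpinFold | None = None


def _longest_helix_run(partner: dict[int, int], start: int, end: int) -> int:
    """Longest run of consecutive positions in [start, end) whose fold partners
    form an antiparallel helix (partner decreasing by exactly 1)."""
    best = run = 0
    prev = None
    for i in range(start, end):
        p = partner.get(i)
        if p is None:
            run, prev = 0, None
            continue
        run = run + 1 if (prev is not None and p == prev - 1) else 1
        prev = p
        best = max(best, run)
    return best


def validate_precursor(
    precursor: str,
    mature: MatureMiRNA,
    min_paired_fraction: float = 0.6,
    min_loop: int = 3,
) -> PrecursorVerdict:
    """Accept a precursor iff the mature miRNA sits on one arm of the main hairpin.

    Requirements: the mature occurs as a substring; it does not intersect the
    interior of the fold's largest hairpin loop (one arm only); and at least
    ``min_paired_fraction`` of its positions lie in a single contiguous helix
    (consecutive positions paired to consecutive partners). The helix
    requirement, rather than a plain paired fraction, is what discriminates a
    genuine stem from the promiscuous pairing a maximum-base-pairing fold
    finds in shuffled sequence.
    """
    pre = normalize_rna(precursor)
    start = pre.find(mature.seq)
    if start < 0:
        return PrecursorVerdict(False, "mature sequence not found in precursor", 0.0, 0.0, -1)
    end = start + len(mature)

    fold = nussinov_fold(pre, min_loop=min_loop)
    loops = _hairpin_loops(fold)
    if not loops:
        return PrecursorVerdict(False, "fold has no hairpin loop", 0.0, 0.0, start, fold)
    li, lj = max(loops, key=lambda p: (p[1] - p[0], -p[0]))
    # loop interior is (li, lj) exclusive; the mature must stay on one side
    if not (end - 1 <= li or start >= lj):
        return PrecursorVerdict(False, "mature spans the hairpin loop", 0.0, 0.0, start, fold)

    partner = {}
    for i, j in fold.pairs:
        partner[i], partner[j] = j, i
    paired_frac = sum(1 for i in range(start, end) if i in partner) / len(mature)
    helix_frac = _longest_helix_run(partner, start, end) / len(mature)
    if helix_frac < min_paired_fraction:
        return PrecursorVerdict(
            False,
            f"longest mature helix covers {helix_frac:.2f} (< {min_paired_fraction})",
            paired_frac,
            helix_frac,
            start,
            fold,
        )
    return PrecursorVerdict(True, "ok", paired_frac, helix_frac, start, fold)
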