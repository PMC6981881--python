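"""Ungapped miRNA:target duplex alignment, weighted mismatch counting and site scanning.

The scoring scheme is the plant-style one: every aligned position of an
antiparallel, equal-length miRNA:site duplex is classified as Watson-Crick
(``|``), G:U wobble (``o``) or mismatch (``x``); wobbles count 0.5 mismatch and
a candidate site must clear four filters (total weight, a clean central window,
a 5'-weight cap, and a hybridization-energy ratio against the perfect
complement).

Positions are 1-based from the miRNA 5' end throughout, so "positions 10-11"
means the 10th and 11th miRNA bases. Target sites are reported in 0-based
half-open transcript coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "DuplexError",
    "MatureMiRNA",
    "Duplex",
    "MismatchWeights",
    "FilterCriteria",
    "Verdict",
    "TargetSite",
    "normalize_rna",
    "classify_pair",
    "align_duplex",
    "weighted_mismatch",
    "check_criteria",
    "scan_transcript",
]

RNA_ALPHABET = frozenset("ACGU")

_WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
_WOBBLE = frozenset({("G", "U"), ("U", "G")})

#: pairing-string vocabulary
WC_SYMBOL, WOBBLE_SYMBOL, MISMATCH_SYMBOL = "|", "o", "x"

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class DuplexError(ValueError):
    """Invalid sequence, window or duplex geometry."""


def normalize_rna(seq: str) -> str:
    """Uppercase, convert DNA T to U, and validate the RNA alphabet."""
    norm = seq.upper().replace("T", "U")
    bad = set(norm) - RNA_ALPHABET
    if bad:
        raise DuplexError(f"non-RNA character(s) {sorted(bad)} in sequence {seq!r}")
    return norm


def perfect_complement(seq: str) -> str:
    """Position-wise complement: the 3'->5' strand pairing every base Watson-Crick."""
    return "".join(_COMPLEMENT[b] for b in normalize_rna(seq))


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA written 5'->3'. T is accepted on input and normalized to U."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        norm = normalize_rna(self.seq)
        if not norm:
            raise DuplexError(f"miRNA {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", norm)
        if not 18 <= len(norm) <= 30:
            warnings.warn(
                f"miRNA {self.id!r} length {len(norm)} outside the typical 18-30 nt range",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.seq)


def classify_pair(mirna_base: str, target_base: str) -> str:
    """Classify one aligned base pair as ``|`` (Watson-Crick), ``o`` (G:U) or ``x``."""
    for b in (mirna_base, target_base):
        if b not in RNA_ALPHABET:
            raise DuplexError(f"non-RNA character {b!r} in pair ({mirna_base!r}, {target_base!r})")
    pair = (mirna_base, target_base)
    if pair in _WATSON_CRICK:
        return WC_SYMBOL
    if pair in _WOBBLE:
        return WOBBLE_SYMBOL
    return MISMATCH_SYMBOL


@dataclass(frozen=True)
class Duplex:
    """An ungapped antiparallel duplex.

    ``site_3to5`` is the target strand written 3'->5' so that index i faces
    miRNA position i + 1 (the miRNA being 5'->3'). Reversing ``site_3to5``
    recovers the site in transcript (5'->3') orientation.
    """

    mirna: MatureMiRNA
    site_3to5: str
    pairing: str

    def __post_init__(self) -> None:
        if not (len(self.site_3to5) == len(self.pairing) == len(self.mirna)):
            raise DuplexError(
                f"duplex lengths differ: miRNA {len(self.mirna)}, "
                f"site {len(self.site_3to5)}, pairing {len(self.pairing)}"
            )

    @property
    def site_5to3(self) -> str:
        return self.site_3to5[::-1]

    def __len__(self) -> int:
        return len(self.pairing)


def align_duplex(mirna: MatureMiRNA, site_3to5: str) -> Duplex:
    """Pair a miRNA with an equal-length site written 3'->5'.

    Gapped/bulged duplexes are unsupported by design and rejected loudly.
    """
    site = normalize_rna(site_3to5)
    if len(site) != len(mirna):
        raise DuplexError(
            f"ungapped alignment requires equal lengths: miRNA {len(mirna)} nt "
            f"vs site {len(site)} nt (gapped duplexes are unsupported)"
        )
    pairing = "".join(classify_pair(m, t) for m, t in zip(mirna.seq, site))
    return Duplex(mirna=mirna, site_3to5=site, pairing=pairing)


@dataclass(frozen=True)
class MismatchWeights:
    """Per-symbol mismatch weights; G:U wobble counts 0.5 by default."""

    watson_crick: float = 0.0
    gu_wobble: float = 0.5
    other: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.gu_wobble <= self.other:
            raise DuplexError(
                f"require 0 <= gu_wobble ({self.gu_wobble}) <= other ({self.other})"
            )

    def of(self, symbol: str) -> float:
        if symbol == WC_SYMBOL:
            return self.watson_crick
        if symbol == WOBBLE_SYMBOL:
            return self.gu_wobble
        if symbol == MISMATCH_SYMBOL:
            return self.other
        raise DuplexError(f"unknown pairing symbol {symbol!r}")


DEFAULT_WEIGHTS = MismatchWeights()


def weighted_mismatch(
    duplex: Duplex,
    window: tuple[int, int] | None = None,
    weights: MismatchWeights = DEFAULT_WEIGHTS,
) -> float:
    """Weighted mismatch count over a 1-based inclusive window (default: whole duplex)."""
    n = len(duplex)
    if window is None:
        window = (1, n)
    lo, hi = window
    if lo > hi:
        raise DuplexError(f"empty or inverted window {window}")
    if lo < 1 or hi > n:
        raise DuplexError(f"window {window} outside duplex positions [1, {n}]")
    return sum(weights.of(s) for s in duplex.pairing[lo - 1 : hi])


@dataclass(frozen=True)
class FilterCriteria:
    """The four-filter target-site acceptance rule.

    Defaults: <= 4.0 weighted mismatches overall, no mismatch in positions
    10-11, <= 2.5 weighted mismatches in positions 1-12, and a duplex/perfect
    hybridization-energy ratio >= 0.74. Each criterion can be toggled.

    ``wobble_fails_forbidden`` controls whether a G:U wobble inside the
    forbidden window counts as a mismatch there (strict default: any nonzero
    weight fails).
    """

    max_total_mismatch: float = 4.0
    forbidden_window: tuple[int, int] = (10, 11)
    five_prime_window: tuple[int, int] = (1, 12)
    max_five_prime_mismatch: float = 2.5
    min_energy_ratio: float = 0.74
    wobble_fails_forbidden: bool = True
    check_total: bool = True
    check_forbidden: bool = True
    check_five_prime: bool = True
    check_energy: bool = True

    def __post_init__(self) -> None:
        for name in ("max_total_mismatch", "max_five_prime_mismatch", "min_energy_ratio"):
            if getattr(self, name) < 0:
                raise DuplexError(f"{name} must be >= 0")
        for name in ("forbidden_window", "five_prime_window"):
            lo, hi = getattr(self, name)
            if lo < 1 or lo > hi:
                raise DuplexError(f"{name} {getattr(self, name)} is not a valid 1-based window")

    def without_energy(self) -> "FilterCriteria":
        return replace(self, check_energy=False)


DEFAULT_CRITERIA = FilterCriteria()


@dataclass(frozen=True)
class Verdict:
    """Per-criterion booleans plus the overall pass (AND of the enabled ones)."""

    total_ok: bool
    forbidden_ok: bool
    five_prime_ok: bool
    energy_ok: bool
    passes: bool


@dataclass(frozen=True)
class TargetSite:
    """A candidate miRNA binding site on a transcript.

    ``start`` is a 0-based half-open offset on the transcript read 5'->3';
    the site occupies ``[start, end)``.
    """

    transcript_id: str
    start: int
    duplex: Duplex
    total_mismatch: float
    five_prime_mismatch: float
    energy_ratio: float | None
    verdict: Verdict = field(compare=False)

    @property
    def end(self) -> int:
        return self.start + len(self.duplex)


def check_criteria(
    duplex: Duplex,
    energy_ratio: float | None = None,
    criteria: FilterCriteria = DEFAULT_CRITERIA,
    weights: MismatchWeights = DEFAULT_WEIGHTS,
) -> Verdict:
    """Evaluate the four filters on a duplex (pure predicate, no side effects).

    ``energy_ratio`` may be None only if the energy criterion is disabled.
    """
    n = len(duplex)
    total = weighted_mismatch(duplex, (1, n), weights)
    total_ok = total <= criteria.max_total_mismatch

    lo, hi = criteria.forbidden_window
    lo, hi = max(lo, 1), min(hi, n)
    if lo > hi:
        forbidden_ok = True
    elif criteria.wobble_fails_forbidden:
        forbidden_ok = weighted_mismatch(duplex, (lo, hi), weights) == 0
    else:
        forbidden_ok = MISMATCH_SYMBOL not in duplex.pairing[lo - 1 : hi]

    flo, fhi = criteria.five_prime_window
    fhi = min(fhi, n)
    five_prime = weighted_mismatch(duplex, (flo, fhi), weights)
    five_prime_ok = five_prime <= criteria.max_five_prime_mismatch

    if criteria.check_energy:
        if energy_ratio is None:
            raise DuplexError("energy criterion enabled but no energy_ratio supplied")
        energy_ok = energy_ratio >= criteria.min_energy_ratio
    else:
        energy_ok = True

    enabled = [
        (criteria.check_total, total_ok),
        (criteria.check_forbidden, forbidden_ok),
        (criteria.check_five_prime, five_prime_ok),
        (criteria.check_energy, energy_ok),
    ]
    passes = all(ok for on, ok in enabled if on)
    return Verdict(total_ok, forbidden_ok, five_prime_ok, energy_ok, passes)


def evaluate_site(
    mirna: MatureMiRNA,
    transcript_seq: str,
    start: int,
    criteria: FilterCriteria = DEFAULT_CRITERIA,
    weights: MismatchWeights = DEFAULT_WEIGHTS,
    energy_params=None,
    transcript_id: str = "",
    _perfect_dg: float | None = None,
) -> TargetSite:
    """Evaluate one offset of a (normalized) transcript as a candidate site.

    ``_perfect_dg`` lets a caller that evaluates many offsets of the same
    miRNA reuse the perfect-complement ΔG instead of recomputing it.
    """
    m = len(mirna)
    window = transcript_seq[start : start + m]
    duplex = align_duplex(mirna, window[::-1])
    ratio: float | None = None
    if criteria.check_energy:
        from .energy import default_parameters, duplex_delta_g, energy_ratio as _energy_ratio

        if energy_params is None:
            energy_params = default_parameters()
        if _perfect_dg is None:
            ratio = _energy_ratio(mirna, duplex, energy_params)
        else:
            dg = duplex_delta_g(duplex, energy_params).delta_g
            ratio = 0.0 if dg >= 0 else abs(dg) / abs(_perfect_dg)
    verdict = check_criteria(duplex, ratio, criteria, weights)
    return TargetSite(
        transcript_id=transcript_id,
        start=start,
        duplex=duplex,
        total_mismatch=weighted_mismatch(duplex, None, weights),
        five_prime_mismatch=weighted_mismatch(
            duplex, (criteria.five_prime_window[0], min(criteria.five_prime_window[1], m)), weights
        ),
        energy_ratio=ratio,
        verdict=verdict,
    )


def scan_transcript(
    mirna: MatureMiRNA,
    transcript_seq: str,
    criteria: FilterCriteria = DEFAULT_CRITERIA,
    weights: MismatchWeights = DEFAULT_WEIGHTS,
    energy_params=None,
    transcript_id: str = "",
    best_per_transcript: bool = False,
) -> list[TargetSite]:
    """Exhaustive sliding-window scan of a transcript for passing target sites.

    Every offset 0..len-m is evaluated; the transcript window (5'->3') is
    reversed to 3'->5' so that target position i faces miRNA position i.
    Returns passing sites sorted by (total_mismatch, start); overlapping sites
    are all reported unless ``best_per_transcript`` collapses to the single
    minimum-mismatch site (tie -> smallest start). Transcripts shorter than
    the miRNA return [].
    """
    if len(mirna) == 0:
        raise DuplexError("empty miRNA")
    seq = normalize_rna(transcript_seq)
    m = len(mirna)
    perfect_dg: float | None = None
    if criteria.check_energy:
        from .energy import default_parameters, duplex_delta_g

        if energy_params is None:
            energy_params = default_parameters()
        perfect = align_duplex(mirna, perfect_complement(mirna.seq))
        perfect_dg = duplex_delta_g(perfect, energy_params).delta_g
        if perfect_dg >= 0:
            raise DuplexError(
                f"degenerate miRNA {mirna.id!r}: perfect-complement ΔG is non-negative"
            )
    hits = []
    for start in range(len(seq) - m + 1):
        site = evaluate_site(
            mirna, seq, start, criteria, weights, energy_params, transcript_id,
            _perfect_dg=perfect_dg,
        )
        if site.verdict.passes:
            hits.append(site)
    hits.sort(key=lambda s: (s.total_mismatch, s.start))
    if best_per_transcript and hits:
        return [hits[0]]
    return hits
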