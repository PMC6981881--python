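"""Nearest-neighbor hybridization free energy for ungapped duplexes.

ΔG of a duplex is assembled additively: a duplex-initiation penalty, one
stacking increment for every adjacent pair of paired positions (Watson-Crick
or G:U), and a flat penalty for every maximal run of mismatched positions
(mismatches terminate helices; no sequence-dependent internal-loop terms).

The default stack table is the Chen et al. 2012 RNA nearest-neighbor set with
G:U parameters, reduced to ΔG at 37 °C and shipped as a plain-text TSV. The
energy criterion used downstream is scale-free (a ratio of absolute ΔG
against the miRNA's perfect complement), so the pass/fail boundary for
marginal duplexes is model-dependent — treat borderline ratios with care.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .duplex import (
    Duplex,
    DuplexError,
    MatureMiRNA,
    MISMATCH_SYMBOL,
    align_duplex,
    perfect_complement,
)

__all__ = [
    "EnergyParameterError",
    "NNParameterSet",
    "EnergyResult",
    "default_parameters",
    "duplex_delta_g",
    "energy_ratio",
]

DEFAULT_LOOP_DG = 1.5  # kcal/mol per maximal mismatch run: small internal-loop initiation scale


class EnergyParameterError(KeyError):
    """A doublet missing from the stack table, or an inconsistent parameter set."""


@dataclass(frozen=True)
class NNParameterSet:
    """Stacking ΔG table plus initiation and loop penalties (kcal/mol).

    ``stack_dg`` keys are doublets ``XY/WZ``: top strand (miRNA) 5'->3', bottom
    strand (site) 3'->5', aligned position-by-position. A missing doublet is a
    hard error, never silently 0.
    """

    stack_dg: dict[str, float]
    init_dg: float
    loop_dg: float = DEFAULT_LOOP_DG
    source_tag: str = "unspecified"

    def __post_init__(self) -> None:
        if self.init_dg <= 0:
            raise EnergyParameterError("init_dg must be > 0 (duplex initiation is penalized)")
        if self.loop_dg < 0:
            raise EnergyParameterError("loop_dg must be >= 0")
        for key, dg in self.stack_dg.items():
            top, bot = key.split("/")
            if all(p in _WC_PAIRS for p in ((top[0], bot[0]), (top[1], bot[1]))) and dg >= 0:
                raise EnergyParameterError(f"Watson-Crick stack {key} must be stabilizing (< 0)")

    def stack(self, top: str, bottom: str) -> float:
        key = f"{top}/{bottom}"
        try:
            return self.stack_dg[key]
        except KeyError:
            raise EnergyParameterError(f"stack doublet {key} absent from table {self.source_tag!r}") from None

    @classmethod
    def from_table(cls, path: str | Path, loop_dg: float = DEFAULT_LOOP_DG,
                   source_tag: str | None = None) -> "NNParameterSet":
        """Load a (doublet, delta_g) TSV; the row keyed ``init`` is the initiation penalty."""
        stacks: dict[str, float] = {}
        init = None
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            key, value = line.split("\t")
            if key == "doublet":
                continue
            if key == "init":
                init = float(value)
            else:
                stacks[key] = float(value)
        if init is None:
            raise EnergyParameterError(f"no init entry in parameter table {path}")
        return cls(stack_dg=stacks, init_dg=init, loop_dg=loop_dg,
                   source_tag=source_tag or str(path))


_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

_DEFAULT: NNParameterSet | None = None


def default_parameters() -> NNParameterSet:
    """The packaged Chen 2012 ΔG37 set (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
            resources.files("cryptarget.data") / "nn_rna_chen2012.tsv"
        ) as path:
            _DEFAULT = NNParameterSet.from_table(
                path, source_tag="Chen et al. 2012 RNA NN dG37 (via Bio.SeqUtils RNA_NN3)"
            )
    return _DEFAULT


@dataclass(frozen=True)
class EnergyResult:
    delta_g: float  # kcal/mol
    n_stacks: int
    n_loops: int
    ratio_basis: float | None = None  # ΔG of the perfect complement, when computed


def duplex_delta_g(duplex: Duplex, params: NNParameterSet | None = None) -> EnergyResult:
    """Additive ΔG: initiation + stacks over adjacent paired positions + flat loop penalties.

    A duplex with zero paired positions returns the initiation penalty alone.
    """
    if params is None:
        params = default_parameters()
    pairing = duplex.pairing
    dg = params.init_dg
    n_stacks = 0
    for i in range(len(pairing) - 1):
        if pairing[i] != MISMATCH_SYMBOL and pairing[i + 1] != MISMATCH_SYMBOL:
            dg += params.stack(duplex.mirna.seq[i : i + 2], duplex.site_3to5[i : i + 2])
            n_stacks += 1
    n_loops = 0
    in_run = False
    for s in pairing:
        if s == MISMATCH_SYMBOL and not in_run:
            n_loops += 1
        in_run = s == MISMATCH_SYMBOL
    dg += params.loop_dg * n_loops
    return EnergyResult(delta_g=dg, n_stacks=n_stacks, n_loops=n_loops)


def energy_ratio(
    mirna: MatureMiRNA, duplex: Duplex, params: NNParameterSet | None = None
) -> float:
    """|ΔG(duplex)| / |ΔG(perfect complement)|, with positive duplex ΔG clamped to 0.

    The ratio-of-absolute-values convention keeps "at least 74% of the perfect
    binding energy" pointing the intended way despite negative ΔG values.
    """
    if params is None:
        params = default_parameters()
    if duplex.mirna.seq != mirna.seq:
        raise DuplexError("duplex does not belong to the given miRNA")
    perfect = align_duplex(mirna, perfect_complement(mirna.seq))
    dg_perfect = duplex_delta_g(perfect, params).delta_g
    if dg_perfect == 0:
        raise DuplexError(f"degenerate miRNA {mirna.id!r}: perfect-complement ΔG is 0")
    if dg_perfect > 0:
        raise DuplexError(
            f"perfect-complement ΔG of {mirna.id!r} is positive ({dg_perfect:.2f} kcal/mol); "
            "the energy-ratio criterion is meaningless for this miRNA/parameter set"
        )
    dg = duplex_delta_g(duplex, params).delta_g
    if dg >= 0:
        return 0.0
    return abs(dg) / abs(dg_perfect)
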