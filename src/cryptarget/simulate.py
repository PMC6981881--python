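"""Seeded synthetic-data generators for every pipeline stage.

Each generator draws from its own substream of a single global seed
(numpy ``SeedSequence(seed, spawn_key=(STREAM,))`` with a fixed per-generator
stream id), so adding a generator never perturbs the output of another, and
the same (config, seed) always reproduces byte-identical output. Every
generator returns its ground truth alongside the data.

Defaults encode the stated experimental world: 4-hourly sampling over 72 h
(ZT2..ZT70), a 12:12 photoperiod, six near-perfectly co-expressed lincRNAs,
one anti-correlated miRNA, a small-RNA length distribution peaking at 21 nt
with 61% of the mass, and a 5'-U fraction of 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .duplex import (
    DuplexError,
    FilterCriteria,
    MatureMiRNA,
    MismatchWeights,
    align_duplex,
    check_criteria,
    perfect_complement,
)

__all__ = [
    "GeneratorConfig",
    "SiteSpec",
    "gen_transcripts_with_sites",
    "gen_hairpin",
    "gen_expression",
    "gen_ct_table",
    "gen_reads",
    "gen_annotation",
]

# fixed substream ids: appending new generators must not renumber these
_STREAMS = {
    "transcripts": 1,
    "hairpin": 2,
    "expression": 3,
    "ct": 4,
    "reads": 5,
    "annotation": 6,
}

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
# substitutions of the SITE base that create a wobble against the miRNA base
_WOBBLE_SITE = {"G": "U", "U": "G"}

#: the mature miRNA central to the studied circuit, used as the default guide
DEFAULT_MIRNA = MatureMiRNA("novel-m3234-5p", "UCCAGCCCGGCGUUGAUGGC")

#: default Table-1-like correlation targets for the planted lincRNAs
DEFAULT_RHO = (0.999986, 0.999975, 0.999995, 0.999993, 0.999996, 0.999996)


@dataclass(frozen=True)
class SiteSpec:
    """Mutation recipe for one planted site: counts of x and o substitutions.

    ``must_pass`` constrains sampling so the planted duplex satisfies the
    mismatch criteria (no x/o in the forbidden window; 5'-window weight within
    budget). With ``must_pass=False`` positions are unconstrained.
    """

    n_x: int = 0
    n_o: int = 0
    must_pass: bool = True


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    # transcripts
    n_transcripts: int = 10
    transcript_length: int = 500
    # expression design
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(2, 71, 4))
    photoperiod: tuple[int, int] = (12, 12)
    amplitude: float = 4.0
    baseline: float = 6.0
    phase: float = 6.0  # peak hour within the cycle
    noise_sd: float = 0.2
    rho_targets: tuple[float, ...] = DEFAULT_RHO
    n_decoys: int = 10
    # qPCR design
    planted_fold_changes: tuple[float, ...] = (3.68, 5.89, 6.10)
    ct_noise_sd: float = 0.0
    n_replicates: int = 1
    # genome annotation design
    n_genes: int = 8
    n_lncrnas: int = 9
    chrom_length: int = 2_400_000
    # read design: mass at 21 nt mirrors the observed 61% peak
    length_probs: tuple[tuple[int, float], ...] = (
        (18, 0.03), (19, 0.05), (20, 0.13), (21, 0.61), (22, 0.13),
        (23, 0.02), (24, 0.01), (25, 0.01), (26, 0.01),
    )
    five_prime_u: float = 0.7


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg_seed, spawn_key=(_STREAMS[stream],))
    )


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# ---------------------------------------------------------------------------
# transcripts with planted target sites
# ---------------------------------------------------------------------------

def _mutate_site(
    rng: np.random.Generator,
    mirna: MatureMiRNA,
    spec: SiteSpec,
    criteria: FilterCriteria,
    weights: MismatchWeights,
    max_tries: int = 200,
) -> str:
    """Build a site (3'->5') by mutating the perfect complement per the recipe.

    x = substitution abolishing pairing; o = substitution creating a G:U
    wobble (only possible where the miRNA base is G or U).
    """
    m = len(mirna)
    if spec.n_x + spec.n_o > m:
        raise DuplexError(f"site spec wants {spec.n_x + spec.n_o} mutations on a {m}-mer")
    wobble_ok = [i for i, b in enumerate(mirna.seq) if b in _WOBBLE_SITE]
    if spec.n_o > len(wobble_ok):
        raise DuplexError(
            f"spec requests {spec.n_o} wobbles but only {len(wobble_ok)} miRNA positions admit one"
        )
    flo, fhi = criteria.forbidden_window
    forbidden = set(range(flo - 1, fhi))
    for _ in range(max_tries):
        site = list(perfect_complement(mirna.seq))
        positions = list(range(m))
        if spec.must_pass:
            positions = [p for p in positions if p not in forbidden]
            wob = [p for p in wobble_ok if p not in forbidden]
        else:
            wob = list(wobble_ok)
        if spec.n_o > len(wob) or spec.n_x + spec.n_o > len(positions):
            raise DuplexError("site spec unsatisfiable under the positional constraints")
        o_pos = list(rng.choice(wob, size=spec.n_o, replace=False)) if spec.n_o else []
        rest = [p for p in positions if p not in o_pos]
        x_pos = list(rng.choice(rest, size=spec.n_x, replace=False)) if spec.n_x else []
        for p in o_pos:
            site[p] = _WOBBLE_SITE[mirna.seq[p]]
        for p in x_pos:
            # any base that neither Watson-Crick- nor wobble-pairs the miRNA base
            mb = mirna.seq[p]
            bad = [b for b in "ACGU" if b != _COMPLEMENT[mb] and _WOBBLE_SITE.get(mb) != b]
            site[p] = rng.choice(bad)
        candidate = "".join(site)
        if not spec.must_pass:
            return candidate
        duplex = align_duplex(mirna, candidate)
        verdict = check_criteria(duplex, criteria=criteria.without_energy(), weights=weights)
        if verdict.passes:
            return candidate
    raise DuplexError(f"could not satisfy site spec {spec} in {max_tries} tries")


def gen_transcripts_with_sites(
    cfg: GeneratorConfig,
    mirna: MatureMiRNA = DEFAULT_MIRNA,
    site_specs: list[SiteSpec] | None = None,
    criteria: FilterCriteria = FilterCriteria(),
    weights: MismatchWeights = MismatchWeights(),
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Random-background transcripts, each with one planted site; plus ground truth.

    One transcript per site spec (cycled over ``n_transcripts``). Ground-truth
    columns: transcript_id, offset, n_x, n_o, pairing, expect_pass — where
    ``expect_pass`` applies the configured criteria (energy included when
    enabled) directly to the planted duplex.
    """
    rng = _rng(cfg.seed, "transcripts")
    if site_specs is None:
        site_specs = [SiteSpec(0, 0), SiteSpec(2, 1), SiteSpec(4, 0), SiteSpec(5, 0, must_pass=False)]
    m = len(mirna)
    if cfg.transcript_length < m:
        raise DuplexError("transcripts must be at least as long as the miRNA")
    energy_params = None
    if criteria.check_energy:
        from .energy import default_parameters, energy_ratio

        energy_params = default_parameters()
    records, truth = [], []
    for i in range(cfg.n_transcripts):
        spec = site_specs[i % len(site_specs)]
        tid = f"TX_{i:04d}"
        seq = _random_rna(rng, cfg.transcript_length)
        offset = int(rng.integers(0, cfg.transcript_length - m + 1))
        site_3to5 = _mutate_site(rng, mirna, spec, criteria, weights)
        seq = seq[:offset] + site_3to5[::-1] + seq[offset + m :]
        duplex = align_duplex(mirna, site_3to5)
        ratio = energy_ratio(mirna, duplex, energy_params) if criteria.check_energy else None
        verdict = check_criteria(duplex, ratio, criteria, weights)
        records.append((tid, seq))
        truth.append(
            {
                "transcript_id": tid,
                "offset": offset,
                "n_x": spec.n_x,
                "n_o": spec.n_o,
                "pairing": duplex.pairing,
                "energy_ratio": ratio,
                "expect_pass": verdict.passes,
            }
        )
    return records, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# hairpin precursors
# ---------------------------------------------------------------------------

def gen_hairpin(
    cfg: GeneratorConfig,
    mature: MatureMiRNA = DEFAULT_MIRNA,
    loop_len: int = 8,
    arm: str = "5p",
    wobble_fraction: float = 0.1,
    scramble_arm: bool = False,
) -> tuple[str, str]:
    """A stem-loop precursor embedding the mature miRNA on one arm.

    precursor = mature + loop + reverse complement of mature (5p arm), with a
    fraction of stem pairs converted to G:U wobbles. The loop is adenosine-run
    based so it cannot pair internally. ``scramble_arm`` shuffles the far arm
    (a negative control that should fail validation).
    """
    if loop_len < 8:
        raise DuplexError("loop must be at least 8 nt")
    rng = _rng(cfg.seed, "hairpin")
    comp = [_COMPLEMENT[b] for b in mature.seq]
    for i, b in enumerate(mature.seq):
        if b in _WOBBLE_SITE and rng.random() < wobble_fraction:
            comp[i] = _WOBBLE_SITE[b]  # stem pair becomes G:U
    far_arm = "".join(comp)[::-1]  # reverse: the arm runs back 5'->3'
    if scramble_arm:
        arm_chars = np.array(list(far_arm))
        rng.shuffle(arm_chars)
        far_arm = "".join(arm_chars)
    loop = "A" * loop_len
    if arm == "5p":
        return mature.seq + loop + far_arm, "5p"
    if arm == "3p":
        return far_arm + loop + mature.seq, "3p"
    raise DuplexError(f"arm must be '5p' or '3p', got {arm!r}")


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

def gen_annotation(cfg: GeneratorConfig):
    """Coding genes on a grid plus lncRNAs with planted positional classes.

    lncRNAs cycle through sense (same-strand overlap), antisense
    (opposite-strand overlap) and lincRNA (intergenic) placements; intergenic
    ones alternate between inside and outside the 100-kb cis window of their
    nearest gene. Returns (genes, lncrnas, truth DataFrame with columns
    lncrna_id, label, cis_of).
    """
    from .lncrna import TranscriptModel

    rng = _rng(cfg.seed, "annotation")
    gene_len, spacing = 3_000, cfg.chrom_length // max(cfg.n_genes, 1)
    if spacing < gene_len + 260_000:
        raise DuplexError("chromosome too short for the requested gene count")
    genes = [
        TranscriptModel(
            id=f"GENE_{i:04d}",
            chrom="chr1",
            start=1 + i * spacing,
            end=i * spacing + gene_len,
            strand="+" if i % 2 == 0 else "-",
            biotype="coding",
        )
        for i in range(cfg.n_genes)
    ]
    lncs, truth = [], []
    labels = ["sense", "antisense", "lincRNA"]
    for j in range(cfg.n_lncrnas):
        label = labels[j % 3]
        anchor = genes[j % cfg.n_genes]
        length = int(rng.integers(400, 2_000))
        if label in ("sense", "antisense"):
            start = anchor.start + int(rng.integers(0, gene_len // 2))
            strand = anchor.strand if label == "sense" else ("-" if anchor.strand == "+" else "+")
            cis_of = anchor.id
        else:
            # alternate inside/outside the cis window, clear of neighboring genes
            inside = (j // 3) % 2 == 0
            gap = 50_000 if inside else 150_000
            start = anchor.end + gap + 1
            strand = "+"
            cis_of = anchor.id if inside else None
        lncs.append(
            TranscriptModel(
                id=f"LNC_{j:04d}", chrom="chr1", start=start, end=start + length - 1,
                strand=strand, biotype="lncRNA",
            )
        )
        truth.append({"lncrna_id": f"LNC_{j:04d}", "label": label, "cis_of": cis_of})
    return genes, lncs, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def gen_expression(
    cfg: GeneratorConfig,
    focal_id: str = "sjCRY-DASH",
    mirna_id: str = "novel-m3234-5p",
) -> tuple[pd.DataFrame, dict]:
    """Circadian expression matrix with planted co-expression structure.

    The focal gene is a 24-h cosine (peak at ``cfg.phase``) plus Gaussian
    noise. Each planted lincRNA is built in standardized space as
    ρ·x̂ + sqrt(1-ρ²)·ẑ with ẑ orthonormal to the focal vector, so its sample
    correlation equals the target ρ exactly; with ``noise_sd == 0`` the
    lincRNAs are exact affine copies (ρ = 1). The miRNA is an anti-correlated
    mirror of the focal profile; decoys are independent noise.
    """
    rng = _rng(cfg.seed, "expression")
    t = np.asarray(cfg.timepoints, dtype=float)
    n = t.size
    if n < 4:
        raise DuplexError("need at least 4 timepoints")
    focal = (
        cfg.baseline
        + cfg.amplitude * np.cos(2 * np.pi * (t - cfg.phase) / 24.0)
        + rng.normal(0.0, cfg.noise_sd, size=n)
    )
    focal = np.clip(focal, 0.05, None)
    xhat = _standardize(focal)

    rows = {focal_id: focal}
    truth_rho = {}
    for j, rho in enumerate(cfg.rho_targets):
        lid = f"TCONS_{j:08d}"
        if cfg.noise_sd == 0 or rho >= 1.0:
            y = 1.5 * focal + 2.0  # exact affine copy: r = 1
            planted = 1.0
        else:
            z = rng.normal(size=n)
            z -= z @ xhat / (xhat @ xhat) * xhat
            z -= z.mean()
            zhat = z / z.std()
            y = rho * xhat + np.sqrt(1 - rho**2) * zhat
            y = cfg.baseline + cfg.amplitude * 0.8 * y  # back to expression scale
            planted = float(rho)
        rows[lid] = np.clip(y, 0.05, None)
        truth_rho[lid] = planted

    mirna = cfg.baseline + cfg.amplitude * 0.6 * (-xhat) + rng.normal(
        0.0, cfg.noise_sd * 0.1, size=n
    )
    rows[mirna_id] = np.clip(mirna, 0.05, None)

    for d in range(cfg.n_decoys):
        rows[f"DECOY_{d:04d}"] = np.clip(
            cfg.baseline + rng.normal(0.0, cfg.amplitude * 0.5, size=n), 0.05, None
        )

    cols = [f"ZT{int(h) if h == int(h) else h}" for h in t]
    expr = pd.DataFrame(rows, index=cols).T
    expr.index.name = "feature_id"
    truth = {
        "focal": focal_id,
        "mirna": mirna_id,
        "rho": truth_rho,
        "phase": cfg.phase,
        "amplitude": cfg.amplitude,
        "decoys": [f"DECOY_{d:04d}" for d in range(cfg.n_decoys)],
    }
    return expr, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_ct_table(
    cfg: GeneratorConfig,
    target_gene: str = "sjCRY-DASH",
    reference_gene: str = "actin",
    calibrator_sample: str = "dark",
):
    """Ct table whose 2^-ΔΔCt recovers the planted fold changes (exactly at sd 0).

    Construction: reference Ct fixed at 20, calibrator target Ct at 25, and
    sample_k target Ct = 25 - log2(fold_k); Gaussian Ct noise optional.
    """
    from .expression import CtTable

    rng = _rng(cfg.seed, "ct")
    rows = []
    samples = [calibrator_sample] + [f"S{k}" for k in range(len(cfg.planted_fold_changes))]
    cts = {calibrator_sample: 25.0}
    for k, fold in enumerate(cfg.planted_fold_changes):
        if fold <= 0:
            raise DuplexError("planted fold changes must be positive")
        cts[f"S{k}"] = 25.0 - np.log2(fold)
    for rep in range(1, cfg.n_replicates + 1):
        for sample in samples:
            rows.append(
                {
                    "sample": sample,
                    "gene": reference_gene,
                    "replicate": rep,
                    "ct": 20.0 + rng.normal(0, cfg.ct_noise_sd),
                }
            )
            rows.append(
                {
                    "sample": sample,
                    "gene": target_gene,
                    "replicate": rep,
                    "ct": cts[sample] + rng.normal(0, cfg.ct_noise_sd),
                }
            )
    table = CtTable(
        data=pd.DataFrame(rows),
        reference_gene=reference_gene,
        calibrator_sample=calibrator_sample,
    )
    truth = {f"S{k}": float(f) for k, f in enumerate(cfg.planted_fold_changes)}
    truth[calibrator_sample] = 1.0
    return table, truth


# ---------------------------------------------------------------------------
# small-RNA read sets
# ---------------------------------------------------------------------------

def gen_reads(cfg: GeneratorConfig, n_reads: int = 10_000) -> list[tuple[str, str]]:
    """Reads with the configured length distribution and 5'-U probability."""
    rng = _rng(cfg.seed, "reads")
    lengths = np.array([ln for ln, _ in cfg.length_probs])
    probs = np.array([p for _, p in cfg.length_probs], dtype=float)
    probs = probs / probs.sum()
    out = []
    for i in range(n_reads):
        ln = int(rng.choice(lengths, p=probs))
        first = "U" if rng.random() < cfg.five_prime_u else str(rng.choice(np.array(list("ACG"))))
        out.append((f"read_{i:06d}", first + _random_rna(rng, ln - 1)))
    return out
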