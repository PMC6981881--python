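# Methods

This note documents the models and conventions the package implements, the
defaults and why they were chosen, and what the synthetic-data tests do and
do not establish.

## Duplex scoring

Only ungapped, equal-length miRNA:site duplexes are considered; gapped or
bulged alignments are rejected with an error rather than approximated. All
24 published reference duplexes for the miRNA novel-m3234-5p are 20/20
ungapped, so nothing in scope requires bulges. Positions are 1-based from
the miRNA 5′ end, matching the phrasing of the filter rules ("positions
10–11", "positions 1–12 of the 5′ end").

Weighted mismatches: Watson–Crick 0, G:U wobble 0.5, anything else 1.0; the
weights are configurable but the 0.5 wobble weight is applied in **every**
window, including the total-count filter. Whether a wobble at positions
10–11 violates the "no mismatches" rule is genuinely ambiguous (no reference
duplex has one there); the strict reading — any nonzero weight fails — is
the default, with `wobble_fails_forbidden=False` available.

`scan_transcript` evaluates every offset exhaustively (the original screen
used an external pattern matcher; an exhaustive scan is exact and fast at
these scales). All passing sites are reported; `best_per_transcript`
collapses to the minimum-mismatch site with ties to the smallest offset.

## Hybridization energy

The energy model is deliberately simple and fully specified, because the
published screen names no model:

ΔG = ΔG_init + Σ stack ΔG over adjacent paired positions + loop_dg × (number
of maximal mismatch runs).

Stacking parameters are the Chen et al. 2012 RNA nearest-neighbor set
(which includes G:U-containing stacks), reduced to ΔG at 37 °C and shipped
as a plain-text table (`data/nn_rna_chen2012.tsv`); a missing doublet is a
hard error, never a silent zero. `loop_dg` defaults to +1.5 kcal/mol, a
representative small-internal-loop initiation penalty; it was fixed before
any downstream number was computed and is configurable. Terminal A:U/G:U
penalties are omitted.

The acceptance filter is the scale-free ratio |ΔG(duplex)| /
|ΔG(perfect complement)| ≥ 0.74. A ratio of absolute values keeps "at
least 74% of the perfect binding energy" pointing the right way despite
negative ΔG; a non-binding (ΔG ≥ 0) duplex is clamped to ratio 0.

**Model dependence, recorded not hidden:** under this stand-in, mismatches
terminate helices entirely, which is far harsher than an internal-loop-aware
folding engine. Of the 24 published reference duplexes, only 4 reach the
0.74 ratio (minimum 0.46); the original screen evidently used a gentler
model. The per-row ratios are frozen as a regression record
(`tests/test_energy.py`), and all published-table acceptance checks use the
three mismatch criteria, which all 24 rows pass. Pass/fail near the 0.74
boundary should always be treated as model-dependent.

A related caveat: with a flat per-run loop penalty, repairing a mismatch in
the **middle** of a run of three or more can transiently raise ΔG (it splits
one run into two without gaining a stack), so "fixing a mismatch never
weakens binding" holds only for mismatches at run boundaries; the property
test is scoped accordingly.

## Small-RNA statistics and hairpin validation

Reads are filtered to 18–30 nt inclusive; the histogram, modal fraction and
5′-base bias are straightforward tallies, permutation-invariant by
construction.

The fold is a Nussinov maximum-base-pairing dynamic program (AU/GC/GU,
nested structures, hairpin loops ≥ 3 unpaired bases) with a deterministic
traceback (pair the smallest index first, to its smallest admissible
partner). It stands in for an energy-based folder for one question only:
does the mature miRNA sit on one arm of a well-paired hairpin?

Validation requires (a) the mature occurs as a substring, (b) it does not
intersect the interior of the largest hairpin loop, and (c) at least 60% of
the mature lies in a **single contiguous helix** (consecutive positions
paired to consecutive partners). Requirement (c) is stronger than a plain
paired fraction on purpose: maximum-base-pairing folds pair ~80% of a
mature sequence even against a shuffled far arm, so a raw paired fraction
discriminates nothing, whereas a 12+-bp uninterrupted helix essentially
never arises by chance in shuffled sequence.

## lncRNA classification and cis/trans screens

Coordinates are GFF3 1-based closed intervals; BED input is converted on
read. Overlap is judged on full gene spans (no exon logic, matching the
available annotation detail). Same-strand overlap ⇒ sense; opposite-strand
overlap only ⇒ antisense; no overlap ⇒ lincRNA. The source analysis reports
only lincRNA and "natural sense" counts; antisense overlaps get their own
label here, with a merge flag for two-category comparisons.

Distance between disjoint loci counts the bases strictly between the nearest
interval ends (adjacent = 0). Cis candidacy is strict: distance < 100,000,
both strands eligible, which makes the relation symmetric between the
lncRNA and the gene.

The coding score is an ORF statistic standing in for a full coding-potential
classifier: score = −1.5 + 2.5 · (coverage / 0.9) · min(len/300, 1), where
coverage is the longest AUG..stop ORF (three forward frames; transcript
orientation is known) as a fraction of transcript length. The anchors put an
ORF-free transcript strictly below the −1 "noncoding" cutoff and a ≥90%-ORF
transcript of ≥300 nt at or above +1; everything between is "ambiguous".
The score is **not** comparable to CPC/CNCI values numerically — only the
three-band labels are.

## Expression statistics

Pearson correlation refuses vectors shorter than 3 or with zero variance
(an undefined correlation is an error, not a silent 0). The trans screen
keeps pairs with |r| ≥ 0.9 by default; the stricter 0.99 cut used for the
headline co-expression table is `TABLE1_R_MIN`. Whether the original
correlations were computed on raw or transformed expression is
unrecoverable; the packaged reference table is used as printed values, and
synthetic fixtures are constructed to reproduce them.

2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt subtracts the
calibrator's ΔCt; fold changes are computed per biological replicate and
then averaged (mean ± sd), mirroring the six-replicate design. The
calibrator's fold change is exactly 1 by construction.

Circadian profiles are fold changes against the ZT2 sample. Peak detection
uses local maxima above a prominence of 0.2 (scipy `find_peaks`);
"24-h periodicity" requires ≥ 2 peaks with every consecutive spacing within
±4 h (one sampling interval) of 24 h. This is an explicit operationalization
of what the source judged by inspection.

Clustering is agglomerative with distance 1 − r and average linkage — a
declared convention of this package, not of the source, which does not state
its method. Constant rows are reported as errors (their correlation distance
is undefined). "Similar expression pattern" for ceRNA flagging means
same-cluster membership at the configured cut.

## Network assembly

Nodes are typed miRNA/mRNA/lincRNA; `represses` edges are directed
(miRNA → mRNA), `coexpressed` and `shares_mirna` are undirected and stored
under canonically sorted endpoints, so rebuilding a network from its own
edge list is idempotent. Self-edges and duplicate typed edges are rejected
or collapsed. Functional annotations are carried as free-text labels from a
user-supplied table; no ontology lookup is performed.

## Synthetic data: what it emulates, and what a green test does not show

The generators draw from per-generator substreams of one seed
(`SeedSequence(seed, spawn_key=(stream,))`), so outputs are bit-reproducible
and adding a generator never perturbs existing ones.

- **Transcripts** are i.i.d. uniform RNA with one planted site each, built
  by mutating the miRNA's perfect complement (x = non-pairing substitution,
  o = wobble-creating substitution, only where the miRNA base admits one),
  honoring the positional constraints when a passing site is requested.
  Real 3′-UTR composition bias, repeated sites and cross-hybridizing
  paralogs are not modeled.
- **Expression** is a 24-h cosine (amplitude 4, baseline 6, peak ZT6,
  Gaussian noise sd 0.2, sampled 4-hourly ZT2–ZT70) with planted lincRNAs
  constructed in standardized space as ρ·x̂ + √(1−ρ²)·ẑ, ẑ orthonormal to
  the focal vector — so the sample correlation equals the target ρ exactly.
  The planted ρ defaults are the printed reference correlations. The miRNA
  is an anti-correlated mirror; decoys are independent noise. Count noise,
  normalization artifacts and shared-clock confounding are not modeled, so
  a perfect trans-screen recovery here shows the screen's bookkeeping is
  right, not that 0.99 correlations are attainable from real RNA-seq.
- **Ct tables** plant fold changes (defaults: the 3.68 / 5.89 / 6.10 blue
  light series) exactly at zero noise, via fixed reference and calibrator
  Ct values.
- **Reads** draw lengths from a distribution with 61% mass at 21 nt and a
  5′-U probability of 0.7, mirroring the reported composition summaries.
- **Annotation** places genes on a grid with lncRNAs cycling through
  sense / antisense / lincRNA placements, intergenic ones alternately inside
  (50 kb) and outside (150 kb) the cis window.

The packaged reference fixtures are the 24 printed duplex rows (the source
text mentions 25 targeted genes, but only 24 rows appear in the printed
table) and the nine printed lincRNA correlations.

## Known limitations

- The energy ratio is model-dependent near its 0.74 boundary (above).
- No bulged duplexes, no conservation filter, no cleavage-vs-inhibition
  classification.
- Coding scores are labels-only stand-ins; lncRNA discovery itself
  (assembly, expression thresholds) is out of scope.
- Cluster counts and lincRNA/sense totals from the original libraries are
  not reproducible without the raw sequencing data and are not asserted
  anywhere; only structural properties on synthetic data are.
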