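# Methods

This note documents the models behind each pipeline stage, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not
establish.

## Sort-seq protein-content model

A sorted library is modelled as follows.  Each peptide i is displayed on
many cells; each cell's surface-stain fluorescence scatters around the
peptide's mean.  Cells are sorted into B contiguous fluorescence gates
(default four, labelled lowest/low/high/highest) and each gate is
sequenced.  The quantitation inverts this chain:

1. Within gate b the peptide's read fraction f_ib = r_ib / Σ_j r_jb
   estimates its share of the gate's C_b sorted cells, so the estimated
   cell count is c_ib = f_ib · C_b.
2. The content score is the cell-weighted mean of gate median
   fluorescences, S_i = Σ_b c_ib M_b / Σ_b c_ib.

Properties that follow directly: Σ_i c_ib = C_b exactly for every gate
with nonzero reads (cell conservation); min_b M_b ≤ S_i ≤ max_b M_b
(the score can saturate for peptides brighter than the top gate's median
or dimmer than the bottom one's); multiplying all M_b by k multiplies
every S_i by k; and rescaling all counts within one gate changes nothing
(sequencing depth per gate is arbitrary).  Gates with zero total reads
contribute zero cells rather than being imputed; a peptide with no
estimated cells anywhere is flagged undefined, never scored zero.

The score is a weighted mean over gate *medians*, so it is a coarse
summary: it recovers the rank order and approximate scale of per-peptide
mean fluorescence, not the full per-cell distribution.  A `log_domain`
option averages log₁₀ M_b instead and reports 10^mean, for data where
the natural averaging scale is logarithmic; linear is the default
because the target quantity is the average fluorescence of a cell.

**Trypsin resistance.**  T_i = 100 · S_treated / S_untreated, with a
division floor (default 1 % of the smallest gate median) below which T
is flagged undefined.  Values above 100 % are legitimate (a peptide
whose staining survives protease slightly better than the untreated
control measurement) and are passed through.

**QC.**  A peptide passes a sample when its summed reads reach
`per_sample_min` (default 20) and passes overall when it passes every
sample and its input-pool reads reach `min_input_reads` (default 50).
Thresholds are reporting choices, not measured constants, and must be
set explicitly to match any particular screen.

**Replicates.**  Replicate scores are averaged arithmetically
(geometric in log domain) over peptides defined in both, and concordance
is reported as squared Pearson correlation in the configured domain.

## Folding classification and statistics

**Surface call.**  HC/TR vs LC/TS is split by a line
T = m·log₁₀(S) + c in score space.  The cutoff is intentionally a free
parameter of the analysis (there is no natural constant); points exactly
on the line are assigned HC/TR, and a grid-search helper
(`fit_boundary`) calibrates (m, c) against any supplied reference
classification.

**HPLC call.**  Per condition (native and reduced), peaks with area
≥ `minor_frac` (default 0.05) of the condition total are counted; the
peptide is well folded (PEAKS_1_2) only if in *both* conditions the
largest peak reaches `dominant_frac` (default 0.5) of the total and at
most one other counted peak exists.  Native total area below the
detection floor means no secreted material (PEAKS_0).  Requiring both
conditions is a choice; counting native-only peaks is the plausible
alternative and would only relax the call.  The class is invariant to
uniform rescaling of areas.

**Permutation concordance test.**  The observed statistic is the
matched fraction: the proportion of peptides whose surface indicator
(HC/TR) agrees with their solution indicator (PEAKS_1_2).  The null is
generated by uniformly shuffling the solution labels; the Monte-Carlo
p-value uses the add-one form (1 + #{null ≥ observed})/(1 + n_perm), so
with the default n_perm = 10⁶ the smallest attainable p is 1e-6.  For
the matched-fraction statistic, a uniform shuffle makes the statistic a
deterministic function of the hypergeometric overlap between the two
positive sets, so the null is sampled directly from that distribution —
exactly equivalent to explicit shuffles and orders of magnitude faster;
other statistics (Matthews correlation is built in) fall back to
explicit shuffling.  An exhaustive mode enumerates all distinct label
arrangements (practical for n ≲ 10) and returns the exact tail
fraction.  A single-class label vector makes the statistic
permutation-invariant; the test warns and returns p = 1.

**Chi-square.**  Pearson chi-square on 2×2 tables with df = 1, two
tailed, continuity correction off by default (both modes exposed, since
either convention is common for tables of this size).

**Unweighted GSEA.**  Peptides are ranked within a sort bin by
pseudocounted log₂ enrichment vs the input pool.  The running sum gains
1/G at set members and loses 1/(N−G) elsewhere; ES is the signed
maximum-magnitude deviation, so |ES| ≤ 1 with equality when the set
occupies an extreme block.  Significance is two-sided on |ES| against
random same-size sets.  Extrema can only occur adjacent to set members,
which gives an O(G) evaluation that is vectorized across permutations.
The leading edge is the members at or before a positive extremum, or at
or after a negative one.

## Saturation mutagenesis

The variant library is every single substitution of the parent peptide
except to cysteine (which would disrupt the disulfide scaffold);
wild-type cysteines *are* substituted to non-Cys residues.  Reads map to
variants only on full-length exact identity — the variants differ by one
residue, so any tolerance would cross-map them — and unmapped reads are
tallied, never silently dropped.  Enrichment is a single input → final
round frequency ratio, pseudocounted (default 0.5 per tracked sequence
per round), log₂-transformed, and normalized by subtracting the wild
type's log-ratio, making the wild-type cell identically 0.  Frequencies
are computed over all tracked sequences including the wild type.  The
heat-map export fixes rows as substitutions grouped by chemical category
(nonpolar aliphatic, aromatic, polar uncharged, positive, negative,
special) and columns as positions; per-position averages are taken over
defined non-wild-type cells only.  The package ships the 40-residue
TB1G1 parent sequence (six cysteines; residue numbering starts after the
GS left by expression-tag cleavage) as the default wild type.

## Library curation

Motif scanning enumerates every cysteine-bounded window (first and last
residue C) with length in [30, 50] and total cysteine count in
{6, 8, 10}; windows strictly contained in another reported window of the
same parent are collapsed by default (the maximal window is the natural
"protein segment"), with a flag to keep all.  Requiring the window to
*start and end* on cysteines is a design choice; windows merely
containing the cysteines is the alternative reading, noted here because
nothing in the data format forces either.  Glycosite scanning reports
every N-X-S/T position, overlapping sequons included; the default is the
literal rule, with a canonical mode (X ≠ P) behind a flag.  Context
categories split the peptide/protein length fraction at 25 % and 50 %
with boundaries assigned upward.  Toxin exclusion is an id-blocklist
supplied by the caller; no regulatory list is embedded.

Taxonomy-weighted sampling flattens classes before weighting: the draw
is allocated across classes proportionally to class weights (systematic
rounding, so expected allocations are exactly proportional, with
overflow past a class's size redistributed), then filled uniformly
without replacement within each class.  This gives every candidate an
inclusion probability equal to its class weight divided by its class
size, which sequential weighted drawing without replacement does not.
Records with missing lineages form class UNKNOWN at default weight 1.

## Synthetic data generator

The generator emulates the screen's data-generating process:

- per-peptide true mean log₁₀ fluorescence from a two-component
  (folded/unfolded) Gaussian mixture — defaults: 40 % folded at mean
  3.5, unfolded at 2.3, component SD 0.4, spanning the roughly
  two-decade dynamic range of a surface stain;
- per-cell log-normal scatter (SD 0.2 log₁₀ units) plus an additive
  autofluorescence floor (1 % of the folded-component mean);
- four gates cut at the 25/50/75 % quantiles of the pooled untreated
  fluorescence.  The treated condition re-uses the untreated cuts — a
  cytometer gate is set once per experiment — which matters: recomputing
  quantiles per condition shifts the fluorescence scale between
  conditions and biases T as an estimator of survival;
- 400,000 sorted cells, multinomial reads (2 × 10⁶ per gate)
  proportional to each gate's peptide cell counts;
- trypsin survival factors uniform on [0.6, 1.1] for folded and
  [0.05, 0.35] for unfolded peptides;
- HPLC labels drawn from a 2×3 per-folding-state confusion matrix
  (identity-like rows plant concordance; uniform rows give the null);
- SSM selection: uniform input pool, each round multiplying a variant's
  relative abundance by 2^(effect/rounds) with multinomial re-observation
  at the configured depth, so the expected estimated score equals the
  planted effect;
- library fixtures: random cysteine-free backgrounds with one planted
  cysteine-bounded motif (and optionally a sequon) per protein, with a
  truth sidecar.

All generators are pure functions of configuration + seed.

What passing against this generator shows: the estimators invert the
assumed observation model correctly, at realistic depths, including
saturation and discreteness effects.  What it does not show: robustness
to features of real screens the generator omits — PCR amplification
bias, index hopping, gate spillover/compensation, cell doublets,
peptide-dependent display efficiency uncoupled from folding, or
sequencing error beyond unmapped-read loss.  Conclusions about real
data rest on the experiment's own controls (replicate concordance, QC
thresholds), not on these simulations.

## Problem sizes and numerical choices

The validation suite and `scripts/acceptance.py` use: 2000 peptides /
400k cells / 2 × 10⁶ reads per gate for sort-seq recovery (Spearman vs
truth computed among peptides with ≥ 200 reads); two full independent
replicates for R²; a 604-member subset with an 80 %-faithful HPLC
readout for the concordance test at 10⁶ permutations; 1000 null
datasets of 500 peptides (n_perm = 999) for type-I error and 200 runs
of 600 peptides (n_perm = 9999) for power; the 726-variant TB1G1 SSM
library at 10⁶ reads per round with planted effects ~ N(0, 0.8²); and
25 random proteins of 50–300 residues for motif-scan equivalence with
exhaustive enumeration.

Tie-breaks and degenerate inputs: points on the HC/TR line go to HC/TR;
enrichment rank ties break by peptide id; a gate with zero sorted cells
is legal only when it also has zero reads and is then dropped from the
weighted mean; equal-magnitude positive and negative GSEA extrema
resolve to the positive one; undefined scores propagate as NaN flags
and are excluded from downstream classification rather than coerced.

## Known limitations

- The content score saturates at the extreme gate medians, compressing
  differences among the brightest and dimmest peptides; T inherits a
  corresponding mild bias for peptides near saturation (visible in the
  synthetic recovery as a median |T/100 − survival| of ≈ 0.08).
- The matched-fraction concordance statistic ignores class imbalance;
  the Matthews-correlation option is provided for imbalanced panels.
- Exact-match variant counting discards reads with any error, trading
  yield for zero cross-mapping; error-corrected counting is out of
  scope.
- The permutation and GSEA p-values are Monte-Carlo estimates with the
  add-one floor; exact enumeration is only practical for tiny n.
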