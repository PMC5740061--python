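# cdpscreen

Quantitative analysis for mammalian surface-display screens of
**cystine-dense peptides** (CDPs) — 10–80 residue peptides stabilized by
intra-chain disulfides.  In such a screen, a library of CDPs is displayed
on the surface of mammalian cells, cells are flow-sorted into fluorescence
bins, and each bin is deep-sequenced.  `cdpscreen` implements the full
downstream analysis for this kind of experiment:

- **Library curation** — extract cysteine-bounded motifs (6, 8, or 10
  cysteines within 30–50 residues) from source proteins, annotate
  N-linked glycosylation sequons (N-X-S/T) and native-protein context,
  and assemble a library by taxonomy-weighted sampling so no
  over-represented class dominates.
- **Sort-seq quantitation** — convert per-bin read counts plus bin-level
  cytometry statistics into a per-peptide *protein content score*

  S_i = Σ_b c_ib·M_b / Σ_b c_ib,  with c_ib = (r_ib / Σ_j r_jb)·C_b,

  where r_ib are the peptide's reads in bin b, C_b the bin's sorted-cell
  count and M_b its median fluorescence: a unitless estimate of the
  average fluorescence of a cell expressing peptide i.  A protease-treated
  re-sort gives the *trypsin resistance score* T_i = 100·S_treated/S_untreated.
- **Folding statistics** — classify peptides as HC/TR (high content
  and/or trypsin resistant) vs LC/TS by a configurable line in
  (log₁₀ S, T) space; classify solution behaviour from reversed-phase
  HPLC peak patterns (1–2 / 3+ / 0 peaks); test surface-vs-solution
  concordance by label-shuffling permutation; two-tailed 2×2 chi-square;
  and unweighted (KS running-sum) GSEA of well-folded peptides over
  bin-enrichment rankings.
- **Saturation-mutagenesis enrichment** — build every non-Cys single
  substitution of a parent peptide, count reads by exact sequence
  identity, and compute wild-type-normalized log₂ enrichment scores
  E_v = log₂(f_v,sel/f_v,in) − log₂(f_wt,sel/f_wt,in), exported in the
  standard position × substitution heat-map layout.
- **Synthetic data** — seeded generators with the statistical structure
  the analysis assumes (log-normal per-cell fluorescence, quantile
  gates, multinomial sequencing, planted trypsin-survival factors, HPLC
  confusion, planted SSM effects), so every stage can be validated
  end-to-end against known ground truth.

## Worked example

Simulate a sort-seq experiment, score it, and test folding concordance:

```bash
cdp simulate sortseq --seed 5 --out sim/
cdp quantify --reads sim/reads.tsv --bins sim/bins.tsv --out quant.tsv
cdp classify --quant quant.tsv --boundary -50,150 --out classes.tsv
cdp stats chi2 --table 20,10,10,20
```

The last command prints

```
chi2=6.66667 p=0.00982327
```

the Pearson chi-square statistic (df = 1, no continuity correction) and
two-tailed p-value for the 2×2 table.  `quant.tsv` holds one row per
peptide with its content score per condition (`S_untreated`,
`S_trypsin`), resistance percentage `T`, and read-abundance QC flag;
`quant.tsv.json` records the replicate R² values.  The same operations
are available as plain functions:

```python
>>> from cdpscreen import chi_square_2x2, find_glycosites
>>> chi_square_2x2([[20, 10], [10, 20]])
(6.666666666666667, 0.009823274507519235)
>>> find_glycosites("AANGSAA")   # N-X-S/T sequon at position 2
[2]
```

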