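# chromdyn

Analysis pipeline for ATAC-seq time courses of cell differentiation, built
around the design of an 8-timepoint (days 7–35), 2-replicate study of
natural-killer (NK) cell differentiation from cord-blood CD34+ progenitors.
It answers three questions a regulatory-genomics analyst asks of such data:

1. **Which regulatory elements change, and when?** Median-of-ratios
   normalization, per-peak negative-binomial Wald tests between all pairs of
   timepoint categories (thresholds P < 0.01, |log2 FC| > 5, FDR < 0.01),
   plus an *intrinsic* score that favours peaks varying between timepoints
   but not between replicates (z > 1); hierarchical clustering (1 − Pearson,
   average linkage, silhouette-selected k) organizes the differential peaks
   into temporal programs and the samples into differentiation stages.
2. **Which transcription factors drive the changes?** PWM scanning of peak
   sequences (log2-odds, both strands, threshold 0.8 × max score),
   hypergeometric motif enrichment per peak set against the peak universe,
   and aggregate TF footprints (flank-minus-core insertion depth) per
   timepoint.
3. **How is the TF network wired over time?** Promoters are the 2 kb
   upstream of each TSS; an edge TF A → TF B means A's motif occurs in B's
   promoter; edges are typed by the Pearson correlation of the two
   expression time courses (positive > 0.4, negative < −0.4, otherwise
   none); one directed network is built per timepoint from the TFs
   specifically expressed then (FC > 1.5 over every other timepoint).

A seeded synthetic-data generator (`chromdyn.simulate`) produces a complete
desk-scale study — genome, peaks, counts, motifs, expression, insertion
tracks, phenotype trajectory — with planted ground truth (peak programs,
onset days, expression lag, regulatory edges), so every stage is testable
without any download. A change-point module recovers the chronology of
chromatin opening → gene expression → phenotype.

## Worked example

Run the whole pipeline on simulated data (about half a minute):

```sh
chromdyn --seed 7 --out run all
```

The manifest (`run/manifest.json`) summarizes each stage; with seed 7:

```
"diffpeaks": {"n_comparisons": 28, "n_selected": 601},
"cluster":   {"k_peaks": 3, "k_samples": 3, "n_conserved": 1109},
"dynamics":  {"onset_accessibility": 14.0, "onset_expression": 19.0,
              "onset_phenotype": 26.0},
"network":   {"n_candidates": 20, "n_edges_total": 24}
```

Reading these numbers: of 2,400 peaks, 601 are called differential across
the 28 pairwise timepoint comparisons plus the intrinsic filter; silhouette
selection finds **3 peak programs** (opening, closing, transient) and **3
sample stages**; the mean accessibility of the opening program starts to
rise at **day 14**, the matched gene-expression signature turns on shortly
after (grid day 19; sub-grid refinement places it ≈ 1.5 days after the
chromatin change), and the NK-cell fraction rises only after **day 21**
(estimated onset day 26); 20 candidate TFs survive the
enrichment-and-expression filter and form per-day regulatory networks with
24 promoter-supported edges.

The same stages are available as a library; for example, the differential
step alone:

```python
from chromdyn.simulate import SimulationConfig, generate_dataset
from chromdyn import diffacc

ds = generate_dataset(SimulationConfig(seed=7))
factors = diffacc.estimate_size_factors(ds.counts)
pairwise = diffacc.all_pairwise(ds.counts, factors)
norm = diffacc.normalize(ds.counts, factors)
intrinsic = diffacc.intrinsic_scores(norm, ds.counts.sample_meta)
selection = diffacc.select_differential_peaks(pairwise, intrinsic)
print(len(selection.selected))   # 601
```

Real data enter through the same formats the generator exports: BED peaks
(+ optional summit column), TSV count/expression matrices, FASTA genome,
JASPAR PFM motifs, bedGraph insertion tracks, and a TF → gene mapping TSV.

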