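# lysorna

Quantitative analysis of lysosomal RNA degradation from bulk RNA-seq:
spike-in-normalized organellar (LysoIP) enrichment scoring and 5EU
pulse-chase RNA half-life estimation, driven by a ground-truthed
synthetic-data generator.

## Who this is for

Lysosomes degrade RNA delivered by autophagy and by direct RNA import.
Two sequencing designs quantify this: (1) immunoprecipitation of intact
lysosomes (LysoIP) with external RNase treatment, sequenced alongside
whole-cell RNA with ERCC/SIRV spike-ins, which yields per-gene *lysosomal
enrichment*; and (2) metabolic labeling with 5-ethynyl-uridine (5EU)
followed by a chase, which yields per-gene *half-lives* and, compared
across autophagy-competent and autophagy-deficient (ATG7-KO) cells with
and without the mTORC1 inhibitor Torin1, a per-gene *autophagy-dependent
stability* statistic. `lysorna` implements the quantitative core of both
designs as a tested, reusable Python library with a CLI, for researchers
who have count-level data (or want calibrated synthetic data) rather than
raw reads.

## The statistics at the core

**Enrichment.** For sample *s*, expression values are placed on an absolute
scale by dividing by the slope β_s of the OLS regression of spike-in reads
on known spike concentrations (after filtering spikes with ≥ 10 reads in
≥ 75% of samples), then multiplying by the sample's lysosome
capture-efficiency factor f_s. Per gene,

    E = mean(normalized LysoIP replicates) / mean(normalized whole-cell replicates)

and the knockout dependence ratio is D = E_KO / E_control (D < 1: lysosomal
entry depends on the knocked-out factor).

**Half-life.** Time courses are normalized to an nLuc spike RNA, then to
the 0 h point so every series starts at 1. Each replicate is fit by bounded
nonlinear least squares to

    y = log2(C·e^(−k·x)) + z

with y the log2 normalized signal at chase time x (hours), C, k ∈ [0, ∞)
(starting values 2^max(y) and 1), and z a fixed per-gene background term,
z = max(max(mock-IP values), 5·10⁻⁶) / (spike-normalized reads at t = 0).
An alternative `background_mode="linear_plateau"` places the background
inside the logarithm, y = log2(C·e^(−k·x) + z). For Torin1-treated series C
is fixed to the untreated C of the same replicate. Fits are kept when the
Wald p-values for k (and C, when free) are < 0.05; half-life is
t½ = ln(2)/k capped at 50 h, synthesis rate S = C·k, and replicate
half-lives are averaged. The autophagy-dependent Torin1-induced stability
value is

    A = (t½_WT,Torin1 / t½_WT) / (t½_KO,Torin1 / t½_KO)

with A < 1 meaning autophagy destabilizes the RNA upon mTORC1 inhibition.

## Worked example

```python
from lysorna import *

cfg = SimulationConfig(n_genes=500, seed=42)
truth = simulate_transcriptome(cfg)
design = default_design(genotypes=["WT"], n_replicates=2)
counts, spikes = simulate_fraction_counts(truth, design, cfg)
norm, _, slopes = normalize_counts(counts, spikes, design, min_reads=1)
e = lysosomal_enrichment(norm, design, "WT")
print(class_summary(e, annotation_from_truth(truth)).sort_values("median"))
```

prints the per-class enrichment summary (n, median, quartiles):

```
         group   n    median        q1        q3
      mito_RNA  75  0.204180  0.116393  0.342928
         snRNA  30  0.741854  0.447188  1.018545
     bulk_mRNA 200  1.069237  0.661621  2.037132
secretory_mRNA  50  1.980556  0.880300  2.940151
 membrane_mRNA  50  2.889165  2.056535  4.827553
          tRNA  50  5.144244  2.706251  7.907836
      TOP_mRNA  25  6.790424  4.202492 12.709346
     vault_RNA   5 11.440002 10.066632 25.476985
       SRP_RNA   5 21.347941 20.430405 48.588694
         Y_RNA  10 22.577943  7.983780 38.102893
```

i.e. mitochondrial and nuclear snRNA transcripts are depleted from
lysosomes while SRP RNA, Y RNAs, vault RNA, tRNAs and 5' TOP mRNAs are
strongly enriched — the rank order of the configured class effects, with
Spearman(E_est, E_true) = 0.96 against the generator's ground truth.
Continuing with the pulse-chase arm (Torin1 doubles decay rates in WT but
not ATG7-KO cells by default):

```python
tc, mock = simulate_pulse_chase(truth, cfg)
fits = filter_fits(fit_timecourse(tc, mock, background_mode="linear_plateau"))
stab = stability_table(average_replicates(fits))
print(stab.dropna().head(3).round(3))
```

```
gene_id  halflife_wt  halflife_wt_torin  halflife_ko  halflife_ko_torin  stability
 g00000       13.784              6.999       14.008             15.747      0.452
 g00001        1.308              0.660        1.344              1.312      0.517
 g00002        2.168              1.070        2.173              2.197      0.488
```

Half-lives in hours; the stability values cluster at 0.5 (median 0.499),
recovering the simulated two-fold WT-specific Torin1 destabilization.

The same flow is available from the shell:

```sh
lysorna run --outdir run1 --seed 42
lysorna simulate --outdir sim --seed 1
lysorna normalize --counts sim/counts.tsv --spikes sim/spikein_reads.tsv \
    --design sim/design.tsv --out norm.tsv
lysorna decay --timecourse sim/timecourse.tsv --mock sim/mock.tsv --out fits/
```

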