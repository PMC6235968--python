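# prmquantkit

A toolkit for targeted proteomics by parallel reaction monitoring (PRM):
it designs spike-in quantification assays, simulates PRM acquisitions
with known ground truth, quantifies peptides by stable-isotope
single-point calibration, rolls peptides up to protein-level stage
profiles, computes qPCR relative expression, and correlates protein and
mRNA profiles measured on disjoint biological replicates.

## Modules

| Module | What it does |
| --- | --- |
| `assay_design` | In-silico tryptic digestion, candidate filtering (7–25 residues, no missed cleavages, no M/C/H), proteome uniqueness screening, light/heavy precursor and fragment m/z arithmetic, panel CSV IO. Ships a 21-peptide / 11-protein reference panel (`load_reference_panel`). |
| `simdata` | Seeded generators: Gaussian co-eluting light/heavy transition groups with hidden true fmol, spike dilution series (0/1/5/10/100/200 fmol), qPCR plates with standard curves and three constant reference genes, paired mean±SE stage profiles with a controlled latent correlation. |
| `prm_quant` | XIC extraction (2 m/z precursor window, 0.5 Da product tolerance, ±5 min RT window), trapezoidal AUC with apex ± 3σ boundaries, transition-group scoring (RT, <5 ppm mass error, co-elution, intensity dot product), decoy-based q-values with 0.01/0.05 gates, single-point calibration, dilution-series linearity. |
| `protein_stats` | Mixed model (stage fixed; peptide and sample as crossed random effects) or one-way ANOVA for single-peptide proteins; Tukey HSD compact letter display. |
| `qpcr_quant` | Standard-curve efficiency (E = 10^(−1/slope)), efficiency-corrected relative quantities against per-gene minimum Ct, normalization to the mean of three reference genes, stage ANOVA + letters. |
| `correlation` | Monte-Carlo correlation of two mean±SE profiles (1500 Normal resamples per pair), Fisher-z percentile confidence interval, significance when the 95% CI excludes 0; max-normalization for joint plotting. |
| `pipeline` / `cli` | Config-driven end-to-end run with seeded determinism and a checksummed manifest. |

## CLI

```sh
# end-to-end demo (simulate -> quantify -> roll up -> qPCR -> correlate)
prmquantkit all --out pipeline_out

# individual stages
prmquantkit design --fasta proteome.fasta --targets targets.txt --out panel.csv
prmquantkit simulate --mode run --seed 3 --out sim/
prmquantkit quantify --runs sim/ --out quant.csv [--q-strict]
prmquantkit dilution --series series/ --out fits.csv
prmquantkit proteinstats --quant quant.csv --out profiles.csv
prmquantkit qpcr --cts cts.csv --refs ACT,EF1,GAPDH --out expr.csv
prmquantkit correlate --protein profiles.csv --rna expr.csv --n 1500 --seed 42 --out corr.csv
```

Omitting `--panel` uses the bundled reference panel.

## Notes

- Masses are monoisotopic; heavy labels are ¹³C₆¹⁵N₂-K (+8.014199 Da)
  and ¹³C₆¹⁵N₄-R (+10.008269 Da), applied to the C-terminal residue, so
  y ions shift and b ions do not.
- q-values use a transparent target/decoy estimator (shuffled transition
  order + RT offset decoys), not a semi-supervised learner; the two
  decision gates (q < 0.01 keep, q > 0.05 remove, flagged in between)
  are fixed.
- A zero heavy AUC produces an explicit quantification-failure record,
  never a silent drop.
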