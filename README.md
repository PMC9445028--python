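# qtronset

Genotyping of a hexanucleotide quasi-tandem repeat (QTR) from short-read
sequencing, and ascertainment-corrected association of repeat length with
residual age at motor onset in Huntington's disease (HD).

## The problem

*TCERG1* exon 4 carries a repeat tract of 38 tandem hexamers
(chr5:145,838,546–145,838,773 on hg19): a central perfect short tandem
repeat (STR) of (CAGGCC)₆ embedded in a larger imperfect "quasi" tandem
repeat, translated as an imperfect glutamine/alanine (QA)₃₈ tract.
Repeat length at this locus modifies the age at which HD motor symptoms
begin.  Two obstacles stand between short reads and that conclusion:

1. **A 75 bp read cannot span the 228 bp tract**, so repeat length must
   be inferred from reads whose alignments carry repeat-unit insertions
   or deletions anchored in unique sequence.
2. **The cohort was recruited for extreme residual onsets**, so a naive
   regression of residual onset on repeat length overestimates the
   effect.

`qtronset` implements both of the methods needed: a repeat-aware caller
built on a match-matrix alignment with the mismatch-error score

    M = m + Σᵢ Δᵢ · exp(5 − lᵢ)

(m mismatching bases; Δᵢ the height of gap i; lᵢ the shorter of the two
match pieces adjoining it), and a **regression with selection**: a
maximum-likelihood linear model whose per-individual likelihood

    L(σ, β₀, β₁ | Rᵢ, xᵢ) = p_N(εᵢ)·S(Rᵢ) / ∫ p_N(R − β₀ − β₁xᵢ)·S(R) dR

weights the normal error density p_N by the recruitment probability

    S(R) = 1 / (1 + exp((R_thr − |R|)/Δ))

and renormalises per individual.  The selection parameters (σ, R_thr, Δ)
are estimated beforehand by minimising the Kolmogorov–Smirnov distance
between expected and observed cumulative distributions of |R|.
Residuals R are observed onset minus the CAG-length expectation of the
Langbehn model (positive = later than expected).

The caller follows the enumerate-then-realign strategy: align each read
to the reference window, collect the indel signatures seen in single
reads, enumerate candidate haplotypes from their combinations, realign
every read to every candidate and keep the smallest-M assignment,
resolve ties with mates, project everything into an asterisk-padded
multiple alignment (indels become substitutions), split the reads into
two groups that agree at every discordant column, and emit one allele
per group.

A synthetic-data module generates the full study conditions: reads over
the eight-allele inventory at its published frequencies, and cohorts of
n = 610 with residual SD σ = 7.02 y, selection (R_thr = 17.6 y,
Δ = 3.30 y), effect −1.0 y per added hexamer on the repeat-length sum,
and a tag marker co-occurring with the three-repeat allele at 99%
fidelity.

## Worked example

Simulate a heterozygous A1/A2 individual (reference allele plus the
three-repeat allele), call its genotype, then run the association
engines on a simulated selected cohort:

```sh
$ qtronset simulate-reads --alleles A1,A2 --seed 1 --out-prefix sr
wrote 208 reads to sr.sam / _1.fastq / _2.fastq
$ qtronset call --sam sr.sam --out gt.tsv
S0: QTR 35/38, STR 3/6 (het)
```

The caller reports 38 and 35 QTR units (pure runs of 6 and 3 units):
exactly the simulated pair.

```sh
$ qtronset simulate-cohort -n 200 --seed 2 --out coh.tsv
$ qtronset assoc --cohort coh.tsv --engine ols
{ "method": "ols", ... "beta1": -3.332, "p": 6.8e-05, ... }
$ qtronset assoc --cohort coh.tsv --engine selection --selection-fit 7.02,17.6,3.30
{ "method": "selection", ... "beta1": -1.100, "sigma": 7.059,
  "p": 4.4e-05, "ci95_beta1": [-1.70, -0.55], ... }
```

The cohort was simulated with a true effect of −1.0 y/hexamer under
extreme-residual selection.  Ordinary least squares on the selected
sample reports −3.3 y/hexamer — the ascertainment inflation — while the
regression with selection recovers −1.10 with a 95% CI covering the
truth, at comparable significance.  `qtronset fit-selection --cohort
coh.tsv` estimates the selection parameters themselves from the cohort's
residuals (here σ = 7.77, R_thr = 16.3, Δ = 3.58, KS p = 0.98 at
n = 200).

The same analyses are available as library functions
(`qtronset.call_genotype`, `qtronset.fit_selection_model`,
`qtronset.fit_regression_with_selection`, …); `qtronset pipeline` chains
simulate → call → assoc end to end.

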