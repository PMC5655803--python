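# subfrac

Tools for quantifying **biased subgenome fractionation** and regulatory
remodeling in allopolyploid genomes.

After an interspecific hybridization plus genome doubling, an
allotetraploid carries two complete parental chromosome sets
("subgenomes", here L and S) that erode at different rates: one subgenome
accumulates more deletions, more mutations, and loses more genes and
regulatory elements than the other. `subfrac` implements the comparative
pipeline for measuring that erosion against a diploid outgroup (T):

* **Deletion calling** from pairwise whole-genome alignment blocks —
  regions of one subgenome reciprocally aligned to the outgroup but not to
  the sister, flanked (500 bp) by reciprocally aligned sequence, with an
  inter-flank gap ≤ 4 kb on the deleted genome and a retained span ≥ 3×
  that gap.
* **Randomization enrichment** — observed deleted bp per feature class vs
  the mean of within-chromosome shuffles, z-score p-values,
  Benjamini–Hochberg adjustment, Mann–Whitney L-vs-S contrasts.
* **NAHR evidence** — are retained regions enriched for long repeats, and
  are their 1-kb flanks more similar to each other than random pairs
  (the signature of non-allelic homologous recombination)?
* **Unitary-pseudogene dating** — NG86 Ka/Ks per branch against a Fitch
  parsimony ancestor at the subgenome split; the loss-of-constraint time
  follows from the two-epoch mixture

  ω_obs = (ω_f·(T−t) + t)/T  ⟹  t = T·(ω_obs − ω_f)/(1 − ω_f),

  clamped to [0, T], with confidence intervals from a codon-column
  bootstrap.
* **Gene-loss accounting** — four pseudogene feature classes (premature
  stop, ≥50% truncation, ≥75% promoter loss, frameshift), tenfold
  homeolog expression filters, nonsense-variant (PTV) annotation from VCF,
  and protein-complex retention under an independent-loss expectation.
* **Regulatory landscape** — peak conservation through alignment,
  subgenome-specific peaks, hypergeometric annotation enrichment,
  repeats-per-Mb, mean+2SD active-transcription thresholds, and a 5-kb
  enhancer-proximity expression test.
* **A synthetic triplet-genome generator** (`subfrac.simulate`) that emits
  FASTA/GFF3/BED/VCF/TSV plus alignment blocks with a full ground-truth
  ledger, so every stage is testable for parameter recovery without any
  downloads.

The audience is comparative genomicists working on polyploid systems who
need the statistics above as tested, seedable library calls rather than
one-off scripts.

## Worked example

Dating a pseudogene whose branch shows ω_obs = 0.6 when its functional
homeolog evolves at ω_f = 0.2 over a T = 34 My branch:

```python
>>> from subfrac import date_pseudogene
>>> date_pseudogene(omega_obs=0.6, omega_f=0.2, T=34.0).t_loss
17.0
```

i.e. the copy lost constraint an estimated 17 My ago — half the branch
spent neutral, consistent with ω_obs lying midway between 0.2 and 1.

The seeded end-to-end run simulates a 10-Mb five-chromosome system with a
2:1 S:L deletion bias and analyses it (about 6 s):

```bash
subfrac run-all --out run/ --seed 7 --n-rand 200 --n-boot 100
```

```json
{
  "deletions": {"n_LdS": 300, "n_SdL": 150, "precision": 1.0,
                "recall": 1.0, "share_LdS_pct": 66.67},
  "nahr": {"repeat_length_ratio": 2.898, "repeat_length_p": 2.07e-09,
           "mean_flank_identity": 0.5824, "mean_random_identity": 0.518,
           "flank_similarity_p": 0.000169},
  "pseudogenes": {"n_dated": 86, "n_on_L": 27, "n_on_S": 59},
  "regulatory": {"h3k4me3_conserved_fraction_T_to_L": 0.408,
                 "p300_conserved_fraction_T_to_L": 0.095,
                 "n_specific_p300": {"L": 30, "S": 30}}
}
```

(abridged; see `run/report.json`). Reading the numbers: all 450 implanted
deletions are recovered with no false calls (`precision`/`recall`), the
recovered S:L split matches the configured 2:1 bias
(`share_LdS_pct ≈ 66.7`), retained regions carry ~2.9× longer repeats and
mutually similar flanks (the NAHR signature), twice as many pseudogenes
date to the S subgenome as to L, promoter peaks are ~41% conserved versus
~10% for enhancer peaks, and all 60 implanted subgenome-specific enhancer
peaks are found. Each stage also writes its own artifact
(`deletions.bed`, `enrichment.tsv`, `gene_rates.tsv`,
`pseudogene_dates.tsv`); the report only collects their numbers, and a
rerun with the same seed is byte-identical.

Single stages run on a simulation directory: `subfrac simulate`,
`delcall`, `enrich`, `nahr`, `molevol`, `geneloss`, `regland`,
`report` — see `subfrac <cmd> --help`.

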