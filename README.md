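# litterkin

Microsatellite parentage analysis for mother–litter data in a two-species
setting: diagnostic-locus species and F1-hybrid identification, per-locus
population-genetic summaries, exhaustive minimum-sire reconstruction with
likelihood-ranked father genotypes, Monte-Carlo multiple-paternity
detection power, Bayesian estimation of the population frequency of
multiple mating, and fecundity/skew summaries — plus a forward simulator
that generates complete synthetic studies for testing every stage.

## Data model

Inputs are rectangular genotype tables (TSV/CSV), one row per individual:

```
sample_id, role, mother_id, species_hint, tl_mm, site, date, <LOCUS>_1, <LOCUS>_2, ...
```

Alleles are **pre-binned integer fragment sizes in bp**; `0` means missing.
Raw electropherogram processing and automated allele binning are out of
scope. A locus that does not amplify in one species is simply missing for
every member of that species and excluded from that species' computations.
`species_hint` is an optional external species call (e.g. from an mtDNA
assay); it never overrides the nuclear multilocus call — conflicts are
reported.

## CLI

```sh
litterkin simulate  --seed 1 --out-dir sim/            # synthetic study + truth.json
litterkin identify  --genotypes sim/genotypes.tsv --out calls.tsv
litterkin summarize --genotypes sim/genotypes.tsv --out popgen.tsv --seed 1
litterkin paternity --genotypes sim/genotypes.tsv --out-dir pat/
litterkin power     --genotypes sim/genotypes.tsv --out power.tsv --seed 1
litterkin fmm       --genotypes sim/genotypes.tsv --out fmm.json --seed 1
litterkin pipeline  --genotypes sim/genotypes.tsv --out-dir report/ --seed 1
```

`pipeline` runs identify → popgen → paternity → fmm (and optionally power
tables with `--with-power`), analysing the two species separately after
diagnosis; per-species allele frequencies come from classified adults only.

## Method notes

- **Species calls** need all informative diagnostic votes to agree; an F1
  hybrid call requires a mixed (one allele per species) genotype at *both*
  fixed loci and no pure vote elsewhere. The overlapping locus votes only
  through its private alleles and never drives hybrid calls.
- **Polyandry flag**: ≥3 paternal alleles at ≥1 locus, counted under the
  conservative minimum resolution of embryos that share both alleles with
  the mother.
- **Minimum sires**: exhaustive search over embryo-to-father partitions
  with per-locus feasibility pruning; all father-genotype solutions at the
  minimal count are enumerated (alleles restricted to the litter's paternal
  candidates plus a most-frequent-allele wildcard) and ranked by HWE prior
  × Mendelian transmission probability, normalized exactly over the full
  solution space.
- **HWE** is a seeded Monte-Carlo exact test (random re-pairing of the
  observed allele multiset) rather than a Markov chain; **LD** is a
  genotypic permutation G-test. **Skew** uses exact binomial (2 sires) or
  exact/Monte-Carlo multinomial (3+) tests against equal contributions.
- **Detection power** applies the pipeline's own polyandry flag to litters
  simulated from HWE parents, so power statements and empirical flags are
  mutually consistent. **FMM** corrects detection counts by per-litter
  power conditional on the observed mother genotype, on a 0.001 grid with
  a uniform prior (mode ≈ MLE) and a central 95% interval.

## Reference fixtures

`litterkin/data/` ships the default diagnostic panel plus two small
transcribed summary tables from the published smooth-hound study this
pipeline mirrors (32 sampled litters; 16 polyandrous litters with sire
counts and skews), used by the summary statistics tests and the acceptance
report. Per-litter top-sire shares use assigned-embryo denominators and are
rounded to whole percents before averaging.

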