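# rsvr

Compact rare-variant storage and Bayesian gene–disease association for
rare-disease cohorts.

The package bundles, end to end:

* **codec** — 64-bit integer variant identifiers (RSVR IDs) packing
  chromosome, position, allele lengths and the alternate allele so that IDs
  sort by genomic position; simple structural variants use the top bit as a
  discriminator.  Consequences are stored as a 64-bit bitmask (CSQ ID) with
  bit position encoding Sequence Ontology severity.
* **consequence** — SO term assignment for variant × transcript pairs from
  GTF transcript models and a FASTA reference (UTRs, introns, 2-bp splice
  windows, codon-level coding effects, frame rules).
* **annotation** — probabilistic minor allele frequency (PMAF) scores 0–3
  from one-sided binomial tests against population allele-count references,
  plus single-sample-VCF prefilters (quality pass rates, almost-surely-common
  tabulation) and the internal cohort allele-frequency filter.
* **reservoir** — a single-file SQLite schema holding only non-reference
  genotypes of rare variants, a build procedure with a per-stage count
  report, and the query layer (gene variant tables, carriers, participant
  classification, case sets).
* **association** — Bayesian comparison of a baseline model and six
  association models (dominant/recessive × high-impact/moderate-impact/5'UTR)
  with latent per-variant pathogenicity, conjugate beta-binomial risk
  strata, exact enumeration or seeded Monte Carlo, posterior probability of
  association (PPA), modal model and per-variant pathogenicity posteriors.
* **postprocess** — the three PPA re-run filters, per-disease-group
  deduplication, staged panel matching, cosegregation counting with a
  two-alt-read mosaicism rescue, and 0–3 plausibility scoring.
* **phenosim** — Resnik information-content similarity over an
  HPO-like ontology, a family-cluster permutation test, and step-down
  permutation-calibrated term enrichment.
* **simdata** — seeded synthetic references, pedigreed cohorts with planted
  dominant/recessive etiologies at configurable penetrance, and all
  annotation sources, so the full pipeline runs without external data.

## CLI

All stages are exposed under a single `rsvr` entry point:

```sh
rsvr simulate --outdir sim --seed 1 --plant GENE000:dominant:high:3:0.95
rsvr build --db r.db --vcf sim/cohort.vcf --samples sim/samples.tsv \
    --gtf sim/transcripts.gtf --fasta sim/reference.fa \
    --pop-counts sim/population_counts.tsv --cadd sim/cadd.tsv \
    --case-sets sim/case_sets.tsv --internal-maf 0.05
rsvr query --db r.db --gene GENE000 --impact-class high --pmaf-min 1
rsvr assoc --db r.db --case-set "Planted disease" --out assoc.tsv --seed 1
rsvr score --evidence evidence.tsv
rsvr phenosim cluster --obo sim/ontology.obo --terms sim/family_terms.tsv \
    --targets F0000,F0001,F0002,F0003 --n-perm 10000 --seed 1
```

`rsvr enc` / `rsvr dec` convert between text variants and RSVR IDs;
`rsvr seqfx`, `rsvr pmaf`, `rsvr depth` and `rsvr tabulate` expose the
annotation primitives.  Every run logs a JSON manifest (command line,
seeds, version) and accepts `--manifest PATH` to persist it.

Note the internal allele-frequency threshold defaults to 0.002, which
targets cohorts of tens of thousands of samples; on small (toy or
simulated) cohorts pass a proportionally larger `--internal-maf`.

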