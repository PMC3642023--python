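# famprior

Family-based whole-genome variant prioritization for multiplex pedigrees.

When a disease clusters in a two-generation family — two unaffected parents,
a large sibship, several affected children — the interesting variants are
*inherited*, not de novo. `famprior` implements the analysis toolkit for that
setting, built around a pedigree with two sequenced affected children
(probands) and SNP-array genotypes for the rest of the family:

* **Coding funnel** — reduce each proband's whole-genome call set to
  candidate genes: call-quality filter (homozygous ≥ 20, heterozygous ≥ 40 on
  the 10·log₁₀[P(true)/P(false)] scale), gene-based functional
  classification, a MAF ≤ 1% rarity rule across three reference databases,
  and a recessive gene model in which a gene qualifies with a homozygous or
  compound-heterozygous pair of qualifying variants; candidate genes are then
  intersected between the probands. A model-free alternative keeps the rare
  coding variants shared by both probands that SIFT (< 0.05), PolyPhen
  (> 0.85) and GERP++ (> 2) concordantly call deleterious.
* **IBD region selection** — phase marker transmissions in the nuclear
  family by exact minimal-recombination dynamic programming, derive the
  identity-by-descent state (0/1/2 shared parental haplotypes) for any
  sibling pair, and keep the regions where the probands are IBD = 2 while
  every unaffected sibling is IBD ≤ 1 with each proband. For full sibs the
  prior expectation is that 25% of the genome is IBD = 2.
* **CNV analysis** — post-filter array CNV calls (≥ 10 markers, mean
  inter-marker gap ≤ 50 kb, > 50% blacklist overlap removed), apply
  confident-call thresholds to read-depth calls (deletions > 10 kb,
  duplications > 200 kb, confidence > 300), group per-sample calls into
  family-level regions, label inheritance and disease segregation, and
  validate deletions from sequencing signals (normalized "sequence count"
  and B-allele frequency).
* **Non-coding funnel** — restrict to non-coding classes, apply the same
  rarity rule, and require both evolutionary constraint (a conserved element
  scoring > 2) and regulatory evidence (active-promoter or strong-enhancer
  chromatin states from a 15-state segmentation).
* **Synthetic family generator** — a seedable simulator that emits the whole
  study (PED, genotype TSV, proband VCFs, annotation tables, BED resources,
  CNV calls, pileups) with planted ground truth: the affected children are
  compound heterozygous at one planted gene, so every stage can be tested by
  parameter recovery.

## Worked example

Generate a synthetic study and run the pipeline end to end:

```bash
famprior simulate --seed 1 --out demo
famprior coding --vcf demo/proband_8.vcf --vcf demo/proband_10.vcf \
    --genes demo/genes.tsv --freqs demo/frequencies.tsv \
    --scores demo/scores.tsv --out demo/coding
famprior ibd --genotypes demo/genotypes.tsv --ped demo/family.ped --out demo/ibd
famprior cnv --calls demo/cnv_calls.tsv --ped demo/family.ped --out demo/cnv
```

which prints

```
wrote 15 files to demo; planted gene: GENE006
candidate genes: proband_8=1, proband_10=1; shared=1
candidate regions: 2 spanning 19,215,768 bp
family CNV regions: 2
```

The one shared recessive candidate gene is the planted gene (`GENE006`,
confirmed in `demo/coding/shared_genes.tsv`), the IBD-selected candidate
regions in `demo/ibd/candidate_regions.bed` contain its locus, and the two
planted inherited CNVs are grouped and labelled with their transmitting
parent in `demo/cnv/family_cnv_regions.tsv`. The funnel report
(`demo/coding/funnel_report.tsv`) shows the per-stage reduction, e.g. for
proband 8: 1,003 calls → 916 after the quality filter → 2 coding rare
variants → the single candidate gene.

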