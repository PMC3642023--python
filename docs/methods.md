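# Methods

## Coordinates and region algebra

All coordinates are 1-based and inclusive at both ends, the convention of
genotyping-array CNV tables (an interval chr13:26048387–26099109 spans
50,723 bases). BED files are converted to and from 0-based half-open form at
the I/O boundary and this conversion is round-trip tested. `RegionSet`
merges abutting intervals (end + 1 = next start) because the segment sets
produced by IBD inference are maximal runs; all set operations
(intersection, subtraction, union, point queries, overlap fractions) are
validated against a per-base brute-force oracle on toy genomes.

## Coding funnel

Variants enter with a call quality on the 10·log₁₀[P(true)/P(false)] scale;
homozygous calls below 20 and heterozygous calls below 40 are removed, and a
call with no quality at all is removed and counted separately because it
signals an upstream caller omission.

Functional classification uses transcript models with explicit exon and CDS
intervals. Precedence is exonic/splicing over UTR over intronic over
upstream/downstream over intergenic; a variant hitting several transcripts
takes the most deleterious class (stopgain > frameshift > stoploss >
splicing > nonsynonymous > nonframeshift > synonymous > …), which keeps the
funnel's first step inclusive. Exonic SNVs are classified by codon
translation against the model's spliced CDS sequence (standard codon table,
strand-aware); a model without a CDS sequence yields "nonsynonymous" for a
CDS SNV, again the inclusive choice. Indels are classified by length modulo
3. The splicing window defaults to ±2 bp (the canonical donor/acceptor
dinucleotides) and is configurable.

Rarity: a variant is removed when its minor allele frequency exceeds 1%
(strictly) in **any** configured reference database; a variant absent from
every database is kept. The three databases are applied as successive
removal stages so the funnel report shows each one's contribution.
Membership in a variant catalogue without frequencies (e.g. dbSNP) is
deliberately not a filter — rare pathogenic variants appear in such
catalogues.

Recessive model: a gene qualifies when one individual carries either one
homozygous qualifying variant (two identical mutated alleles satisfy the
"two deleterious mutations" requirement) or at least two distinct
heterozygous ones. Compound-heterozygous pairs are **not** phase-checked:
parental genotypes do not enter the funnel at this stage, so a cis pair can
survive; pedigree phasing can flag these post hoc.

Deleteriousness (the model-free route): SIFT < 0.05, PolyPhen > 0.85,
GERP++ > 2.0, applied to the rare coding variants shared by both probands.
Each missing score passes its own criterion by default
(`scores.missing_passes`), since frameshift and splicing variants typically
carry no SIFT/PolyPhen prediction; setting it false removes every unscored
variant, and the two settings bracket the output. PolyPhen 0.85 is the
default; 0.80 is a documented looser alternative reachable via config.
Multi-allelic VCF records are decomposed into bi-allelic variants on read.

## Transmission phasing and IBD

For each parent and chromosome, the alleles a heterozygous parent
transmitted to each child are deduced where possible (child homozygous, or
the other parent's genotype resolves the ambiguity). The assignment of the
parent's alleles to its two haplotypes along the chromosome is then chosen
to minimize the total number of implied crossovers across all children.
This is solved exactly by a dynamic program whose state is each child's most
recent known origin, so crossovers are counted between a child's own
consecutive informative markers even across uninformative gaps; the
tie-break prefers "no flip" and the haplotype labels are anchored so that
hapA carries the lexicographically smaller allele at the first informative
marker (the mirror labelling is cost-identical and IBD-equivalent). The
suite verifies the program against exhaustive enumeration of all phase
assignments on ≤ 12-marker families.

Mendelian-inconsistent genotypes abort with the marker and child named —
genotyping error is not modelled or silently repaired. Monomorphic markers
are skipped. The X chromosome is excluded by default because hemizygous
males break the two-haplotype model.

IBD state for a sibling pair at a marker is the number of parents from whom
both sibs inherited the same haplotype; runs of equal state merge into
segments with boundaries at the midpoint between flanking informative
markers (unbiased placement when the true crossover is unobserved) and ends
clipped to the first/last informative marker (no extrapolation). Candidate
regions are the proband pair's IBD = 2 set minus the union of IBD = 2
regions between any unaffected genotyped sibling and either proband.

The expected IBD = 2 fraction is estimated by simulating sib pairs under the
crossover model: crossovers per meiosis are Poisson over the chromosome's
genetic length with uniform positions and no interference, on a uniform
1 cM/Mb map over 22 autosomes of approximately human physical lengths
(~28.8 Morgans total). With 2,000 pairs the estimate resolves 25% to well
within one percentage point in about a second.

## CNV analysis

The array HMM caller and the read-depth caller are external; this package
implements everything downstream of their call tables. Post-filters: ≥ 10
supporting markers; mean inter-marker distance ≤ 50 kb, computed as
span/(n−1) over the n−1 gaps between n markers with span the distance
between the outermost markers (this reading makes a two-marker call 50 kb
apart pass exactly); removal when more than 50% of the call (fraction of the
call, not of the mask) lies in a blacklist region — the four immunoglobulin
loci (somatic rearrangement territory) ship with the package, centromere
masks are supplied by the user. The three post-filters commute, and the
suite asserts it. Confident read-depth calls: deletions > 10 kb and
duplications > 200 kb with confidence > 300.

Family-level grouping merges same-kind calls at ≥ 50% reciprocal overlap
(single linkage) and reports the union span. A child's CNV is labelled
inherited-from-father/mother when that parent carries the same family-level
region, de-novo-candidate when neither does, and inherited-from-either when
both do. Segregation is defined over children only: the region segregates
iff its child carriers are exactly the affected children; carrier parents
are exempt as obligate transmitters under incomplete penetrance.

Sequencing signals: "sequence count" is read depth normalized by the
sample's diploid baseline (runs of positions between SNVs are reported as
their mean), and B-allele frequency is alt/(ref+alt) from pileup counts at
SNV sites. A one-copy deletion shows depressed sequence count *and* the
collapse of the heterozygous BAF cluster, so `deletion_evidence` requires
mean sequence count < 0.75 and fewer than 10% of SNV sites with BAF in
[0.25, 0.75]; both thresholds are package defaults chosen for clear
separation at 50× coverage and are configurable. A region with no SNV sites
is decided on depth alone and flagged. At 50× over 60-kb regions the
classifier exceeds 0.95 sensitivity and specificity in seeded simulation.

## Non-coding funnel

The complement of the coding funnel: keep UTR/intronic/upstream/downstream/
intergenic/non-coding-gene classes (synonymous variants are exonic and enter
neither funnel), apply the same three-database rarity rule — per proband,
then intersect the probands' call sets — then require containment in a
conserved element with score > 2, then a chromatin state in the keep-set
(state 1 "active promoter", states 4–5 "strong enhancer" of a 15-state
lymphoblastoid segmentation; the state dictionary is configuration so other
segmentations can be swapped in). The element-score criterion is applied to
the containing element's score (one number per element), with a per-site
score column honoured when present.

## Synthetic family generator

The generator emulates the target study design: two parents, eight children
with one child lacking DNA, two affected children sequenced. Founder
haplotypes are drawn independently per marker (no linkage disequilibrium),
children are produced by the same Poisson/uniform crossover model used for
the IBD expectation, and the affected children are forced — by rejection
sampling of the relevant meioses, which leaves the crossover model intact —
to inherit both planted causal haplotypes, while every unaffected child
lacks at least one. Affection is fully penetrant *in the simulator* only;
the pipeline itself never assumes penetrance.

Default scale: four 20-Mb chromosomes at 1 cM/Mb, 2,000 markers, ~1,000
background variants per proband (30% with MAF > 1% to exercise the rarity
filter, 10% low-quality to exercise the quality filter), 30 genes, 50×
coverage — small enough that the full pipeline runs in roughly a second per
seed while leaving every filter with work to do. Background variant
positions are independent between probands except for a 20% shared pool;
reference alleles falling in a modelled CDS are taken from the gene's
sequence so classification is consistent. Pileups are sampled per site as
total ~ Poisson(depth·copy/2) and alt ~ Binomial(total, dose/copy).

What the simulator does **not** model — and hence what passing tests cannot
show about real data: linkage disequilibrium and realistic allele-frequency
spectra, genotyping and sequencing error, reference bias, segmental
duplication artifacts, multi-nucleotide and complex variants, and real
gene/conservation/chromatin annotation. Recovery of the planted gene in
≥ 95% of seeds demonstrates the pipeline's internal consistency, not its
sensitivity on real genomes.

Same seed, same config → byte-identical output trees; the suite asserts it.

## Problem sizes in the test suite

The default suite simulates the family at the scale above; the acceptance
checks use 2,000 sib pairs for the IBD expectation, 200 simulated regions
for deletion-evidence operating characteristics, and 50 generator seeds for
planted-gene recovery. All randomness flows through seeded
`numpy.random.Generator` instances.

## Known limitations

* Phasing assumes a two-founder nuclear family; half-sibs and
  multi-generation pedigrees are out of scope, as are linkage LOD scores and
  population-based (unrelated-sample) IBD.
* Genotyping error aborts phasing rather than being repaired; real array
  data would need an error-tolerant pre-pass.
* The compound-heterozygous test is unphased at funnel stage (see above).
* No liftover or reference-sequence handling; gene models must match the
  variant coordinate system.
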