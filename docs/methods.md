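# Methods

This note documents the models behind `ciliamap`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions a user relying on the results should know.

## The genetic model

The simulated organism has a diploid germline micronucleus (MIC) and a
polyploid somatic macronucleus (MAC) carrying `ploidy` copies of each locus
(default 45, the canonical *Tetrahymena* value). Only MIC alleles transmit
sexually; only MAC alleles are transcribed and sequenced.

**Mutagenesis.** The mutagenized parent carries a Poisson(`mutation_rate`)
number of background SNVs (default mean 200, a nitrosoguanidine-scale
load), positions uniform over the genome (placed chromosomes and unplaced
scaffolds alike, length-weighted), each a random substitution of the
reference base, all heterozygous. One causal stop-loss site is always
planted heterozygous; a background draw colliding with it or with a
previous draw is resampled from the same stream, keeping the run
deterministic.

**Crosses.** Gametes are formed per site independently — there is no
linkage map. This is a deliberate simplification: the screening procedure
never uses linkage information, and none is available for the emulated
design. It means simulated background candidates are *not* clustered
around the causal locus as they would be in a real cross, so the simulation
is easier than reality in exactly one respect: it cannot produce the
linked-passenger candidates that physical mapping is meant to discount.
The pipeline composes an outcross (mutagenized parent × wild type), picks
the first two F1 clones heterozygous at the causal site (`n_f1` = 24 drawn;
the chance of fewer than two suitable F1s is ~10⁻⁶), and mates them to
produce `n_f2` = 200 F2 clones, so the recessive phenotype segregates 1:3.

**MAC development and assortment.** A new MAC inherits `ploidy` copies per
site: homozygous sites at `ploidy`:0, heterozygous sites split
⌈ploidy/2⌉:⌊ploidy/2⌋ with the mutant allele taking the ceiling share — an
arbitrary but fixed tie-break chosen for reproducibility (at ploidy 45 the
initial state is 23 mutant : 22 wild type). Each amitotic division
replicates every site to 2×`ploidy` copies and deals the tracked daughter
`ploidy` of them without replacement, i.e. a hypergeometric partition —
the standard amitosis model. Under it the allele *fraction* is a
martingale, 0 and `ploidy` are absorbing, and the fixation probability of
an allele equals its current copy fraction; the test suite verifies all
three against Monte-Carlo and closed-form oracles.

**Selection of assortants.** Clones with exactly zero wild-type copies at
the causal site are "fully mutant": MIC homozygotes qualify from birth,
MIC heterozygotes only after assortment fixes the mutant allele. The
default `n_divisions` = 50 makes het-derived fixation a minority
contribution; it is exposed because the selected fraction, and hence how
many F2s must be screened, depends on it. `n_f2` = 200 guarantees the
25-clone pool exists with overwhelming probability (the homozygote quarter
alone gives a shortfall probability below 10⁻⁶).

**Pooling and sequencing.** The pool's allele fraction per site is the
unweighted mean over clones (equimolar pooling; stoichiometry is otherwise
unspecified in the emulated design). Per sample and site, depth is
Poisson(coverage) — defaults 70× for the pool and 256×/65×/73× for the
parental and two outcross strains — and each read's true allele (drawn
from the sample's pooled fraction) flips to a uniformly random other base
with probability `base_error`. Reads matching neither declared allele
count toward depth but not toward either allele's depth.

**Calling.** A call is MISSING below `min_depth` (10 reads); homozygous
when the major declared allele holds ≥ `hom_fraction` (0.95) of all reads;
heterozygous otherwise. Sites with no non-reference call in any sample are
not emitted, mirroring a variant caller's output. `base_error` defaults to
0.002, a realistic post-quality-filter Illumina substitution rate; the
binomial tail P(≥4 error reads | Bin(70, e)) then stays ≪10⁻³, so a fully
mutant pool at 70× is called HOM_ALT with probability >0.999 and the
causal site survives the four-sample screen in essentially every
replicate. At e = 0.01 that tail is ~0.6% per sample and the end-to-end
survival rate would drop to ~98–99%; the threshold pair (0.95, 10) plus
e = 0.002 is the package's calibrated operating point, set from this
closed-form bound.

## The screen

Two clauses, applied in a fixed order that the code enforces: first remove
every record with any MISSING call (screening a record that still has one
raises a contract error); then keep records in which every sample is
homozygous and the mutant pool's homozygous allele differs from **each**
reference strain's homozygous allele. Differences are judged on allele
*sequence*, not genotype code, so two HOM_ALT calls with different alt
indices but the same base are "shared". References are not required to
agree with one another, and are not required to be homozygous *reference*
— that stricter reading is available as
`ScreenConfig.require_hom_ref_references` for users whose references are
known to carry no fixed differences from the assembly. Both filters are
idempotent and return subsequences of their input.

Chromosome tallies count any chromosome outside the declared placed list
(e.g. unplaced scaffolds) under `"undefined"`. SNV density is
`n_snv × 1000 / mappable_size` (per kbp); `mappable_size` is a parameter
of the genome description, not inferred.

## Consequence annotation

Effects are classified against CDS-only gene models (splice and UTR
effects are out of scope) under a selectable NCBI genetic code, default
table 6 (ciliate nuclear): TAA and TAG encode glutamine and TGA is the
sole stop. The classification lattice is intergenic / intronic (inside a
gene's span but outside its CDS) / synonymous / missense / stop_gain /
stop_loss; minus-strand CDS are reverse-complemented before translation,
and a mirrored-gene property test pins strand symmetry. A reference-allele
disagreement with the genome raises an error naming the site. An internal
(non-terminal) reference stop codon indicates a broken gene model and is
reported as such rather than annotated.

**Stop-loss extension convention.** `extension_aa` counts every residue
added to the wild-type product: the read-through residue at the former
stop plus all in-frame sense codons up to, and excluding, the next
downstream stop. A stop immediately after the gene gives 1; the default
genome's causal gene is built with 179 sense codons before the next TGA,
giving 180. Running off the chromosome end yields an explicit
"no downstream stop" result (`extension_aa = None`), not an exception.

## Coexpression ranking

Expression profiles are 20-condition vectors (3 growing, 7 starvation, 10
conjugation time points). Each profile is normalized to its own maximum, so
only trace *shape* matters, then scored against each reference pathway
gene; a candidate's score is its best (default) or mean similarity over the
references. The default similarity is Pearson correlation of the
normalized values — shape similarity judged by eye corresponds most closely
to correlation after max normalization; cosine and Spearman are provided
for sensitivity analysis. A constant profile has undefined correlation and
scores 0 with a flag. Candidates without any profile are flagged
`no_profile` and placed after all scored candidates. Ties break by
descending similarity then ascending gene id — documented so ranked
reports are reproducible. The `low_expression` flag (raw maximum below
twice a user-supplied background level) is annotative only and never moves
a candidate; the background is a supplied scalar because no principled
genome-wide correction is computed here.

The generator's expression fixtures encode the intended use case: the
causal gene follows the mucocyst-pathway archetype at very low absolute
level (maximum ≈1.6 against a unit background, so it is flagged
low-expression yet still ranks first on shape), reference genes follow the
same archetype at high level, and decoys follow a growth-biased archetype
that anticorrelates with it. Multiplicative lognormal noise (σ = 0.08 per
condition) leaves the causal-vs-reference correlation near 0.99, a
by-construction margin; the ranking test verifies rank-1 recovery across
seeds rather than the exact score.

## What the simulation does and does not show

The generator reproduces the statistical skeleton of a pooled-F2 mapping
study: segregation ratios, assortment dynamics, pool allele fractions,
coverage and error effects on calls, and the candidate funnel. It does not
model linkage (see above), read-level artifacts (mapping bias, indels,
duplicates), copy-number variation of the MAC (the ~45 is fixed and
uniform across sites), strain polymorphisms between the reference lines,
or the two-mating provenance of a real 25-clone pool. Passing tests
therefore demonstrate that the *procedure* is implemented correctly and
recovers a planted signal under its stated assumptions — not that those
assumptions hold for any particular real data set.

Problem sizes were chosen to make the full property suite cheap: the
default synthetic genome is five 30-kb chromosomes plus two 4-kb scaffolds
(genes cover a realistic fraction, and density summaries use the placed
portion, 150 kb, as the mappable size). One end-to-end replicate takes
~0.3 s, so the 100-replicate recovery property and the acceptance script
each run in well under a minute.

## Numerical and reproducibility choices

All randomness flows from a single integer seed through
`numpy.random.SeedSequence.spawn`, one child stream per stage (genome,
mutagenesis, F1 cross, F2 cross, assortment, sequencing, expression), so a
stage can be replayed in isolation and identical seeds give byte-identical
reports. Monte-Carlo tests compare means within 3 standard errors at
stated sample sizes; the single-division assortment variance is checked
against the closed-form hypergeometric variance at 0.5% sampling error
with a 5% tolerance. Degenerate inputs are handled explicitly: empty
record lists write header-only VCFs, all-zero expression profiles are
valid but flagged, depth-0 calls are MISSING, and an empty clone pool or
an unset mapped chromosome raise typed errors.
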