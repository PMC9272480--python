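# Methods

## Scope and data model

The package analyses per-variant, per-transcript consequence annotations of
the kind a gnomAD export annotated with Ensembl VEP provides.  A variant is
identified by `(chrom, pos, ref, alt)` with VCF conventions: 1-based
positions, non-empty alleles over {A,C,G,T}, indels anchored on a shared
leading base, multi-allelic sites decomposed at ingestion so every
downstream stage sees biallelic records.  rsIDs are carried but never used
for identity, because aggregated databases reuse them across alternate
alleles.  Genomic and protein coordinates are 1-based inclusive at every
public boundary (VCF/UniProt convention); interval arithmetic inside the
package is 0-based half-open.

Cleaning follows the order a real export needs: exact-key de-duplication
(first occurrence wins; novel annotations from duplicates are merged —
whether to merge or discard is a genuine choice, merging is the default so
no annotation is silently lost), restriction to one transcript's
annotations (version suffixes stripped; the shipped MYBPC3 config carries
both the commonly printed 13-digit transcript string and the canonical
15-digit Ensembl ID as an alias, matched exactly after normalisation), and
removal of annotations attributed to overlapping or neighbouring genes.
The excluded-symbol lists are configuration, not constants, because overlap
sets change between annotation releases.  Every stage's input/output count
lands in a `CleaningReport`, so discrepancies of a single variant between
two summaries of the same snapshot (a real occurrence in published counts)
can be traced to a stage.

## Consequence classification

Terms map onto ten analysis buckets.  "Truncation" means stop-gain only;
frameshifts are reported separately even though both shorten the protein,
because the two arise from different mutational processes (substitution vs
indel) and the comparative figures treat them separately.  Multi-term
annotations resolve by a fixed severity priority modelled on Ensembl's
ranking: start_lost > stop_gained > frameshift > stop_lost > splice
donor/acceptor > in-frame indel > missense > protein_altering > synonymous
> splice_region > UTR > intron > up/downstream.  One deliberate deviation
from the pure severity order: `splice_region_variant` ranks *below*
`synonymous_variant` here, because it is a positional modifier — letting it
mask a coding synonymous call would misclassify exonic synonymous variants
as noncoding and corrupt the coding proportions.  Only the ±1/±2 intronic
positions count as the splice bucket; `splice_region_variant` alone falls
to noncoding.

## The internal annotator

`annotate_variant` is the in-repo stand-in for VEP that makes synthetic
cohorts annotatable offline.  Given a `GeneModel` (strand, ordered exons,
CDS bounds, locus sequence) it splices the CDS, reverse-complements on the
minus strand, substitutes, translates (standard nuclear code, NCBI table 1,
via Biopython), and emits the SO term, exon ordinal (transcription order),
codon change in VEP case markup (`gGg/gAg`), protein position and
amino-acid change.  Indels classify by length mod 3; the "affected" residue
of a frameshift is the reference amino acid at the first altered codon
(VEP's `Protein_position` convention), written as `REF/X`.  SNVs in the
first or last two bases of an intron become splice donor/acceptor calls,
strand-aware.  Like VEP, the annotator treats each variant independently;
compound effects of neighbouring variants on one codon are not modelled.
Same-length multi-base substitutions are classified by full-codon
replacement.  Deletions that straddle an exon boundary classify by their
coding overlap only (no added splice term) — a simplification relative to
VEP.

Correctness is established against two independent oracles in the tests:
a whole-protein retranslation oracle (mutate the raw locus string,
re-splice with Biopython, translate, diff) and a geometric classifier for
noncoding positions, over seeded random multi-exon models on both strands;
plus an exact strand-mirror invariance check.

## Genetic-code enumerations

Two exhaustive enumerations over all 64 × 9 single-base codon changes
supply mechanistic nulls: per amino acid, the number of single-base changes
reaching a stop codon (Trp 2/9 per codon, Tyr 2/9, maximal; Met, Ala, Asp,
Phe, His, Ile, Asn, Pro, Thr, Val 0); and the codon-position profile of
synonymous changes (126 of 134 at position 3).  These explain why Trp/Tyr
dominate premature-stop spectra and why synonymous variants concentrate at
third positions without invoking selection.

## Synthetic cohorts

The generator emulates what the real pipeline ingests, with known truth.

**Gene models.** A random clean ORF (ATG start, no internal stop, single
terminal stop) flanked by UTRs is cut into `n_exons` pieces (each ≥ 20 nt),
introns get GT…AG ends, and on the minus strand the locus is laid down
reverse-complemented.  Defaults are sized on the cardiac paralog: 1274
codons, tens of exons, kb-scale flanks.

**Mutation model.** `snv_fraction` 0.9 (indels are ~10% of short variants
in population data); transition:transversion ratio 2.0 (human genome-wide
value); indel lengths 1–6 with a monotone-decreasing distribution
concentrated on 1–2 nt; positions uniform over the locus or over the CDS.
CpG elevation multiplies the rate of C→T (and G→A on the other strand) at
CpG dinucleotides and applies to *site selection*, not just allele choice —
that is what makes arginine codons (CGN) hypermutable.  It defaults to off
(1.0) so the realised transition fraction equals the configured R/(R+1)
exactly; the analysis drivers use 8×, a realistic germline value, and under
it arginine rises to the top of raw stop-gain sources while Trp/Tyr still
lead after per-codon normalisation — the same reading the comparative
figures require.

**Two sampling regimes.**  *Undirected* draws positions by weight and
alleles from the mutation model; category proportions emerge from the gene
structure.  Recurrent alleles are allowed (rejecting used keys would
deplete the smaller transition pool faster and bias the realised Ts/Tv
downward on small loci).  *Directed* mode takes target coding-category
proportions and a noncoding fraction: the category is drawn first, then
transition-vs-transversion with P(ts) = R/(R+1), then a candidate site of
that class from the category's exhaustive pool (all 3L single-base CDS
changes, pre-classified by codon arithmetic), without replacement.  This
makes the realised transition fraction an exact Bernoulli per SNV,
independent of the category mix, and emits every variant key once — so
configured proportions and Ts/Tv survive the dedup stage and are both
recoverable from one cohort.  Default directed profile: 63% missense, 30%
synonymous, 1.5% + 1.5% frameshift/truncation, 2% in-frame, 2% splice among
coding; 75% noncoding overall (the paralog drivers use 90/75/62%).

**Ground truth** is recorded at generation time from codon arithmetic on
the spliced CDS — never read back from the annotator — and includes
category, codon positions, amino-acid change, protein position, exon and
(when an architecture is supplied) domain.  SIFT/PolyPhen labels for
synthetic missense variants are *sampled*, not predicted: independent
Bernoulli(damaging probability, default 0.3) draws for each predictor, with
scores placed in the predictor's published label ranges.  Re-implementing
the predictors is out of scope, so pathogenicity results on synthetic data
validate the *filter semantics*, not predictor behaviour.

**What a green synthetic test does not establish.**  Synthetic cohorts have
uniform-by-construction positional structure, no allele frequencies, no
coverage or population structure, no real hg19/hg38 sequence, and no
mutation-selection balance; domain/exon heterogeneity in real data is
exactly what the uniform null is *not*.  Green tests establish that the
machinery measures what it claims to measure, not that any biological
pattern is reproduced.

## Pathogenicity screen

"Likely pathogenic" is a computational label filter, not a clinical (ACMG)
classification.  The default rule is conservative: SIFT label in
{deleterious} AND PolyPhen label in {probably_damaging}.  Because the
underlying filter used in published summaries is typically unstated, all
four modes (sift_only, polyphen_only, either, both) are computed in every
run's audit log so any published profile can be bracketed.  Annotations
lacking both predictors are never pathogenic under any mode; since only
missense variants carry predictor scores, non-missense classes fall out of
the screen by construction — the run log notes this.

## Numerical and reporting choices

- Coding-category proportions are over non-noncoding annotations and sum
  to 1; the noncoding fraction is reported separately.
- Top-k substitution lists break ties by descending count, then
  lexicographic (ref, alt).
- Domain tables always carry both raw counts and per-100-aa rates: a short
  domain can be the densest hotspot without carrying the most variants.
- Domain intervals are 1-based inclusive and boundaries belong to the
  named region (`pos == end_aa` maps to that domain); gaps between named
  regions count as linker.  Architectures are input files, not hard-coded
  (`docs/uniprot_architecture_template.tsv` shows how to transcribe UniProt
  boundaries); the generator's architectures follow the family layout
  ([C0] PA C1 M C2…C10, Fn3 at C6/C7/C9), shrinking region sizes
  proportionally when a protein is too short for the drawn sizes.  The
  cardiac 28-aa C5 loop is representable (class `loop`, splitting C5) but
  not generated by default.
- Stochastic recovery tests use 3-binomial-SE bands; distribution nulls use
  chi-square goodness of fit at α = 0.01 with cells of expected count < 5
  merged; all seeds fixed a priori.
- Everything downstream of a seed is deterministic; identical seeds give
  byte-identical output files.

## Known limitations

Beyond the synthetic-realism caveats above: the annotator emits one term
per annotation (no secondary splice_region terms); indel normalisation is
anchor-convention only (no full left-alignment against the reference);
UTR-spanning and exon-boundary indels use simplified rules; the VEP dialect
parser recovers ref/alt from the `Uploaded_variation` column (the form VEP
emits for VCF input) and counts rows it cannot parse rather than guessing.
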