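# Methods

This note documents the models and procedures implemented in `carptrx`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Transcript catalog

A transcript is protein-coding when its longest *intact* ORF — an ATG
followed by sense codons and a stop, scanned in all six frames — encodes
at least `min_orf_aa` amino acids (default 50, the common 150-nt rule for
separating mRNAs from noncoding RNA in assembled transcriptomes).
`length_aa` is the encoded protein length: Met counted, stop excluded, so
an ORF spanning `end - start` nucleotides encodes `(end - start)/3 - 1`
residues. Ties between equally long ORFs go to the forward strand, then
the lowest start. Codons containing ambiguous bases abort the ORF in
progress: an N codon can be neither a confident start, stop, nor sense
codon, so no ORF may span it.

Splice-variant collapse treats "100% identity over 100 bp" as an exact
shared substring of ≥ `dedup_min_overlap` bp, detected with a k-mer index
(two sequences share a ≥ k-bp identical block iff they share a k-mer);
k-mers containing N never match. Transcripts sharing a block are clustered
transitively and each connected component is represented by its longest
member (ties: lexicographically smallest id). This is deterministic and
equivalent to the aligner-based rule at desk scale, without an aligner's
heuristics.

## Orthologs and Ks

Best hits use exhaustive local alignment with BLASTN-like scores (match
+1, mismatch −2, gap open −5, extend −2; all exposed in
`AlignmentScoring`), ties broken by longer alignment then target id. A
pair is orthologous when each member is the other's best hit and the
alignment covers ≥ `rbh_min_aln` bp (default 300). Coding regions are then
aligned globally at the protein level (BLOSUM62, gap open −10, extend −1)
and back-threaded to codons, so every protein gap is a codon gap and the
codon alignment re-translates to the protein alignment exactly.

Synonymous divergence uses Nei–Gojobori (1986) counting. Site counts: per
codon position, the fraction of the three single-base changes that
preserve the amino acid, with changes creating a stop codon counted as
nonsynonymous opportunities — the convention of the original method and of
the reference implementations in the field; S and N are averaged over the
two sequences and satisfy S + N = 3 × (ungapped codon columns).
Difference counts: codons differing at k positions contribute the average
over the k! single-step pathway orderings, excluding pathways through stop
codons (in the never-observed case that every ordering is blocked, all
orderings are used with stop steps counted as nonsynonymous). Jukes–Cantor
correction maps pS = Sd/S to Ks; proportions ≥ 3/4 are saturated and
flagged undefined rather than extrapolated. Columns with gaps, Ns or stop
codons are excluded from counting.

The Ks histogram uses half-open bins [k·w, (k+1)·w) of width
`ks_bin_width` (default 0.002), labelled by left edge; undefined estimates
are excluded and counted separately; the peak is the modal bin, ties to
the lower edge. The histogram reports *all* bins — when the distribution
has both a low-divergence component and a divergence peak, the caller
designates which bin is the speciation signal. Dating is T = peak Ks /
`clock_rate` with the default rate 3.51 × 10⁻⁹ substitutions per
synonymous site per year; ages in millions of years are *truncated* (not
rounded) to one decimal, the only convention that maps the canonical
0.008/0.006/0.01 peaks at that rate onto 2.2/1.7/2.8 My consistently. A
user-supplied Ks mode interval propagates linearly to an age range; no
estimation rule for the interval is imposed.

The paper trail for this stage involved a maximum-likelihood codon model;
this package deliberately substitutes NG86 counting because at Ks ≈ 0.008
counting and ML estimates are numerically indistinguishable, while the
counting estimator is exactly specifiable and testable against a
brute-force enumerator (the suite checks all 61 × 61 codon pairs
exhaustively).

## Pileups and allele multiplicity

A site enters classification when pooled coverage ≥ `min_coverage`
(default 5). A base is an allele when supported by ≥ `allele_min_reads`
reads (default 2) *and* ≥ `allele_min_fraction` of coverage (default
0.1); a pure count-≥1 rule would make tri-allelic calls error-dominated at
percent-level sequencing error. Allele-set size gives the class:
monomorphic, di-allelic, tri-allelic, higher. The population diversity
average divides total polymorphic sites by the number of transcripts
containing at least one polymorphic site, reported to one decimal.
Per-individual genotypes are computed only for microsatellites; site
calling operates on the pooled population pileup.

## Microsatellites

Maximal perfect tandem arrays of primitive 2–6-bp motifs on the forward
strand (transcripts are oriented), above per-unit repeat thresholds
(default {2: 8, 3: 5, 4: 5, 5: 5, 6: 5}); arrays whose motif is a power of
a shorter motif are reported once at the shortest unit; overlapping
candidates of different units resolve leftmost-longest. A locus passes the
flank rule iff both flanks are strictly longer than `ssr_min_flank`
(default 50 bp). The canonical motif (lexicographic minimum over
rotations) accompanies the as-found motif for class summaries.
Homopolymers, imperfect and compound repeats are out of scope.
Genotyping classifies each individual by its count of distinct allele
lengths (1 → homozygous, 2 → di-allelic, 3 → tri-allelic, possible only in
the triploid); a locus is tri-allelic when any individual shows three
alleles, and more alleles than the ploidy is rejected as a genotyping
artifact.

## Expression statistics

Enrichment: for each category, the upper-tail hypergeometric probability
of drawing ≥ k in-category genes in n foreground draws from N background
genes of which K carry the category. Following the original analysis,
significance is raw p < 0.05; a BH-adjusted column is included for modern
use but does not gate the `enriched` flag.

Differential expression compares two pooled libraries without biological
replicates. Lacking replicates, the package uses the exact conditional
two-proportion test: under the null, a gene's condition-A count given the
pair's sum is Binomial(sum, libA/(libA+libB)); two-sided p-values are
BH-adjusted across genes. A gene is a DEG at q ≤ `deg_fdr` (default
0.001) and |log2 fold| ≥ log2(`deg_min_fold`) (default 4) on CPM-normalised
expression. This is a documented stand-in for the negative-binomial
machinery of replicated designs: the test is exactly calibrated under
Poisson sampling and anticonservative under extra-Poisson dispersion,
which is precisely the limitation of any no-replicate design. All-zero
genes get p = 1 and are flagged, with no fold change.

DEG grouping is threshold-based because the source analysis's "high in
both" criterion is qualitative: Group I = CPM above `high_threshold`
(default 100, config-exposed) in both conditions; II-a / II-b = high in
exactly one; DEGs high in neither are left ungrouped. Average-linkage
hierarchical clustering on log2(CPM+1) profiles supplies the dendrogram
(written as newick) and leaf order.

ΔΔCq: per replicate ΔCq = Cq_target − Cq_reference; per gene and group,
ΔΔCq = mean ΔCq(group) − mean ΔCq(calibrator) and fold = 2^−ΔΔCq, so the
calibrator's fold is 1 by construction; replicate ΔCq values of the two
groups are compared with a two-sided t statistic. Equal amplification
efficiencies are assumed, as the comparative Cq method requires.

## Synthetic data

The generators produce inputs with recorded ground truth; all are seeded
and byte-reproducible.

**Ortholog evolver.** The ancestor is `n_codons` uniform-random sense
codons. Divergence is split evenly across the two lineages (the clock
assumption): per lineage, synonymous events are Poisson with mean
(target_ks/2) · S_anc and nonsynonymous events Poisson with mean
(target_ks/2) · ω · N_anc, each event a uniformly chosen eligible
single-base change; stop codons are never created. The expected number of
synonymous substitutions per synonymous site across the pair therefore
equals `target_ks`, verified against the generator's own event counter.
The process uses uniform base exchangeability (no transition/transversion
bias) — at the Ks regime of interest (≈ 0.008) the counting estimator is
insensitive to κ. No indels, no rate variation across sites, no codon-usage
bias: passing recovery tests shows estimator correctness under the model's
assumptions, not robustness to alignment error or compositional bias.

**Pileup simulator.** Per individual and site, read depth is
Poisson(coverage) — the real libraries' depth distribution is unknown, so
Poisson is a stand-in chosen to exercise the minimum-coverage filter —
and each read samples one chromosome copy uniformly, so each copy
contributes in expected proportion 1/ploidy; errors substitute a uniformly
chosen other base at the given per-base rate. Recovery checks run at mean
coverage 40: comfortably above the 5 × ploidy rule of thumb, where
multinomial sampling essentially never drops a 1/3-frequency allele below
the support filters (at mean coverage 15 such dropout occurs at ~2% of
sites, which is a property of allele sampling, not of the caller).

**Microsatellite planter.** Exact tandem arrays embedded in random flanks
that are rejection-sampled to contain no tandem array of 4+ repeats, so
the planted locus is the only signal; truth records coordinates and
whether the array passes the repeat and flank thresholds.

**Count simulator.** Condition-B means are condition-A means × planted
fold × library-size ratio. Counts are gamma-Poisson (negative binomial,
variance μ + d·μ²) for dispersion d > 0 and Poisson at d = 0. Error-control
checks use Poisson nulls because the exact conditional test is calibrated
only there; the knife-edge at a planted fold exactly equal to the 4-fold
cutoff (observed |log2FC| ≥ 2 holds with probability ~0.5 under any
sampling noise) is tested deterministically by feeding exact-mean counts
to the caller, and stochastic recovery checks plant folds of 8 and 16.

## Problem sizes and numerical choices

The recovery simulations run at 2,000 pairs × 1,000 codons (Ks peak),
2,000 + 10,000 sites (multiplicity and error tolerance), 10,050 genes
(DEG control), and 10-kb sequences (SSR oracle) — sizes at which every
stochastic check is stable across seeds while the whole suite runs in well
under a minute of compute per stage. Histogram binning adds a 10⁻⁹ epsilon
before flooring so values sitting on a bin edge (to float representation)
land in the bin they label. NG86 per-codon and per-codon-pair quantities
are precomputed into 61-entry and 61 × 61 lookup tables at import.

## Known limitations

Read QC, assembly, annotation against external databases, and
GO-term assignment are out of scope (category maps and count tables are
inputs). The all-vs-all best-hit search is exhaustive O(n·m) local
alignment — appropriate for desk-scale catalogs, not a BLAST replacement.
The DEG test inherits the limits of unreplicated designs; the enrichment
stage deliberately reports raw p-values as its primary flag. SSR detection
handles perfect repeats only. Ks dating assumes a constant synonymous
clock and an externally supplied rate; the mode interval is user input,
not estimated.
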