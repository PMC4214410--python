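# Methods

This note records the models, defaults and numerical choices behind each
stage, what the simulator does and does not emulate, and the known
limitations.

## Synthetic study design

The simulator generates one ancestral chromosome carrying `n_genes`
non-overlapping ORFs (ATG start, sense codons, one terminal stop) on random
strands, each guaranteed a 1-kb intergenic promoter window on its own
strand. From the ancestor it derives:

* **A second wild haplotype.** Heterozygous SNVs and short InDels
  (geometric lengths, capped at 10 bp) are planted at Poisson-distributed
  counts matching the configured per-kb rates (defaults 3.8 SNVs/kb — the
  wild-accession value; 0.6 InDels/kb, a typical fraction of the SNV rate
  since only the SNV component is reported for heterozygosity). Events keep
  a minimum spacing of 13 bp so that truth positions are unambiguous; this
  deviates from a pure Poisson process only at the percent level at these
  densities.
* **A wild and a cultivated lineage.** `divergence_snv_rate` (default
  6.9/kb) is the *genome-wide pairwise* substitution rate: coding
  substitutions planted under the selection regimes count toward it and an
  intergenic quota makes up the remainder, so the wild-vs-cultivar
  difference density equals the configured value. Every event is assigned
  to exactly one lineage. InDels (default 0.8/kb) are intergenic, keeping
  reading frames intact. A configurable fraction of genes is deleted per
  lineage (the lost locus is overwritten with random sequence of the same
  length, so coordinates remain comparable) or duplicated (a copy appended
  beyond the chromosome end).
* **Selection regimes.** Genes are assigned positive / negative / neutral
  regimes (default fractions 0.2/0.1/0.7) with target Ka/Ks of 3.0, 0.2 and
  1.0. For each gene the planner searches nearby substitution totals
  (Poisson mean `coding_subs_per_gene`, default 30) for the integer
  (nonsynonymous, synonymous) split whose Jukes–Cantor-corrected NG86 ratio
  is closest to the target, then places one substitution per codon by
  rejection sampling (classified against the current codon; stop-creating
  and start-codon proposals rejected). One substitution per codon keeps the
  pathway-averaged NG86 difference counts exactly equal to the quota. The
  default of ~30 substitutions per 900-bp gene is the smallest density at
  which integer splits can express a ratio of 1.0 within a few percent;
  much sparser divergence makes "neutral" unexpressible and is the reason
  the neutral class is defined with a tolerance band (below).
* **Promoter MITEs.** A planted element is a perfect terminal inverted
  repeat (TIR, 10–30 bp) around a random body (total 50–800 bp), inserted
  after a target-site motif that is duplicated on both flanks (TA
  dinucleotides preferred, the classical Stowaway/Tourist target). The
  insertion site is constrained so the element lies wholly inside the 1-kb
  window measured from the *shifted* gene start. Shared (ancestral)
  insertions are simulated by planting the same element at the same
  relative window offset in both genomes; lineage-specific insertions go to
  one genome only.
* **Reads, BAC clones, clone map.** Paired libraries are inward-oriented
  with normal insert sizes, drawn uniformly from both haplotypes, with a
  uniform per-base error rate (no quality model) and an optional chimera
  fraction (mate replaced by a random locus). Default tiers 300 bp / 3 kb /
  8 kb at 30×/10×/5×; the tier structure is configurable since real
  hierarchical libraries vary. BAC clones default to a 115-kb mean insert
  with the clone count sized to ten genome equivalents; the clone-order map
  abstracts fingerprinting entirely — clones are grouped into map contigs
  wherever coverage is contiguous and ordered by true midpoint, which is
  the only information the ordering step consumes.
* **Expression.** Negative-binomial counts (NB2: var = μ + αμ², default
  dispersion α = 0.05, 5 replicates per group) with log-normal per-gene
  baselines around 400; genes with a cultivar-specific promoter MITE have
  the cultivar mean shifted by `suppression_log2fc` (default −2).

What the simulator does *not* emulate: repeat landscapes and
heterochromatin, quality-score-dependent errors, polyploidy, GC bias,
coding InDels, and real fingerprint chemistry. Passing recovery tests
therefore demonstrate the estimators' correctness under clean collinear
conditions, not robustness to repeat-rich plant genomes.

## Assembly integration

Overlap discovery is seed-and-extend: shared 15-mers vote for a dovetail
shift per contig pair and orientation; the top shifts are verified by
edit-distance alignment (error ≤ `max_error` × overlap length, default 2%).
Redundancy filtering aligns each secondary contig (both strands, infix
mode) against its best seed-supported primary candidates and removes it
when edit distance ≤ length × (1 − min_identity × min_containment) —
containment and identity are folded into one effective threshold because an
infix alignment of the full contig measures exactly that product.
OLC merging uses only unambiguous edges (both contig ends of degree one),
breaks cycles at the lowest-identity overlap, and resolves disagreeing
overlap columns toward the deeper contig, then the lexicographically
smaller base. Overlap columns are counted on the left contig, so
InDel-containing overlaps keep its column count — adequate at the ≤2%
error rates accepted. Merged length equals Σ contig lengths − Σ used
overlap lengths by construction.

## Scaffolding

Reads are placed by 31-mer anchors unique in the reference across both
strands (canonical uniqueness); three anchor columns per read give strand,
a diagonal consistency check, and an InDel signal. A mate pair on two
different sequences votes for joining the ends the fragment runs off, with
per-pair gap = insert mean − distance to end A − distance to end B. Pairs
whose implied gap exceeds the insert mean or is more negative than
2 × read length + 4 × insert SD are discarded as chimera/mismap noise —
a true pair cannot produce such geometry — which is what keeps join
accuracy ≥ 95% at a 5% chimera fraction. Bundles below `min_support`
(default 3) are dropped; between bundles linking the same contig pair with
incompatible end combinations only the majority survives. Joining is
greedy by support with union-find cycle prevention, tier by tier with
ascending insert size; a later tier can only bridge across earlier joins.

Mega-scaffolding assigns each scaffold to the map contig holding the
majority of its BAC-end hits, orders scaffolds by median clone order index,
and orients them by the sign of the correlation between hit position and
clone order (≥3 hits and |r| > 0.3 required, else '+'). The clone map
outranks BAC links, which outrank mate pairs. The median-order scheme
resolves order only above the clone-insert scale: scaffolds should be
comparable to or larger than the 115-kb insert, which is the regime the
three mate-pair tiers produce. Pseudomolecule joins are fixed 500-N gaps;
within-scaffold gaps keep their clamped estimates (minimum 1 N) and are
written as AGP linkage gaps.

## Genome profiling

K-mer spectra use canonical 17-mers by default (k is configurable, odd,
11–31). The error cutoff is the first local minimum of the depth histogram
(1 for error-free reads, where the histogram rises monotonically), guarded
to at most a third of the peak. The size estimate divides k-mer instances
above the cutoff by a count-weighted centroid of the histogram around the
modal bin — the integer mode alone biases the estimate by up to half a
depth unit (±5% at 20×), which the centroid removes. A half-depth
heterozygous shoulder is reported when present but never double-counted.

Heterozygous calling: anchor-consistent reads feed an ungapped pileup, but
a placement is trusted only if the whole read matches the reference with at
most 6 mismatches — an InDel between the outermost anchor and the read end
leaves consistent diagonals yet a misaligned tail, which would otherwise
fabricate het SNVs downstream of every het InDel. Rejected placements,
single-anchor reads and anchor-inconsistent reads are realigned with edlib
and contribute gapped evidence. A het SNV requires depth ≥ 10 and a best
non-reference allele fraction in [0.2, 0.8]; het InDels are called the same
way from gapped-read votes merged within ±3 bp (gapped aligners place
equivalent InDels at slightly different anchors). Rates are per callable
(depth ≥ 10) kb. SNV precision and recall exceed 0.95 at 40×; InDel recall
is ≈0.6–0.7 — InDel-spanning reads are a minority and edit-distance
alignments split some multi-base events — a known limitation that does not
affect the SNV rate.

Assembly comparison intersects the unique-k-mer sets of the two genomes,
thins anchors to a 150-bp spacing, keeps the longest strictly increasing
chain, and aligns inter-anchor segments globally with affine gap costs
(match 1, mismatch −2, open −6, extend −0.5) — affine costs keep multi-base
InDels as single events, which edit-distance alignment splits. Rates are
per aligned (anchored-span) base. SNV output is symmetric under swapping
query and reference except for a small fraction of calls adjacent to
InDels, where gap-placement ties resolve differently per direction.

## Selection scanning

NG86 counting: per-codon synonymous site fractions (changes to stop codons
count as nonsynonymous), pathway-averaged differences over minimal
mutational paths (stop-containing paths excluded when any stop-free path
exists), Jukes–Cantor correction with a saturation flag at p ≥ 3/4. The
implementation is table-driven and is verified against an explicit
enumeration oracle on all 61×61 sense-codon pairs and against Biopython's
independent NG86 implementation. Codon alignments come from global protein
alignment (BLOSUM62, gap open −11, extend −1) back-translated to codons;
gap or N columns are excluded, and pairs under 30% translated identity are
skipped with a warning.

Orthologue clustering: cross-genome links require reciprocal best protein
matches at identity ≥ 0.35 and coverage ≥ 0.5 of the shorter sequence
(candidates prefiltered by shared 6-mer words); within-genome links at the
same thresholds attach duplicated copies, and single linkage closes the
clusters. Neutrality uses |Ka/Ks − 1| ≤ 0.1 by default — an exact-equality
neutral bin has measure zero, and the band matches the resolution the
planted substitution density can express.

## MITE detection and association

Candidate element boundaries come from exact `min_tir`-mer (default 10)
matches between a region and its reverse complement: any structurally
valid candidate whose TIR begins with an exact core of that length is
found this way, and a mismatch-penalised inward extension (score = matches
− 3 × mismatches ≥ `min_tir`, at most `max_tir_mismatch` = 2 mismatches)
then sets the reported TIR length. Requiring the exact boundary core plus
a duplicated flanking motif (TSD, 2–10 bp, longest first) and an element
length in 50–800 bp bounds the expected false-call rate on random sequence
at ≈0.04/kb — mismatches inside the first 10 TIR bases are not recoverable,
a deliberate specificity/sensitivity trade. Overlapping candidates resolve
longest-TIR-first, then leftmost. Because common target-site motifs (TA)
are reverse-complement palindromes, the element boundary is ambiguous up to
the TSD length; planted-cohort evaluations therefore allow ±6 bp of
boundary jitter, while clean constructed elements are located exactly.

Cross-genome presence matches insertions in orthologous windows by their
upstream flanking anchor (20 bp, ≤4 edits). Differential expression uses
median-of-ratios normalisation, a Welch t-test on log2(normalised + 1) and
Benjamini–Hochberg adjustment; the association between cultivar-specific
insertions and "lower" calls is tested one-sidedly by permuting insertion
labels over genes (199 permutations, p = (1 + #extreme)/200). The
t-on-log-counts test is deliberately simple and self-contained rather than
a negative-binomial GLM; at the simulated depths and replicate counts it is
well calibrated (type-I error ≤ α in the null checks).

## Pipeline and reproducibility

One global seed fans out to fixed per-stage streams via
`SeedSequence(seed, spawn_key=(stage_index,))`; changing one stage's seed
never perturbs another stage. Reruns with the same config reproduce every
output checksum. All internal coordinates are 0-based half-open; GFF3, VCF
and AGP are written 1-based inclusive, BED-like tables 0-based half-open.
`--threads` is accepted for interface compatibility and never changes
results.

Problem sizes: unit tests run on 30–100-gene chromosomes of 0.1–0.3 Mb;
recovery checks use 5-Mb genomes at 30–40× coverage and a 2-Mb three-tier
scaffolding study — sizes at which every estimator's target quantity is
measured with comfortable statistical margin on a single CPU. The
divergence-recovery runs disable presence/absence and copy-number events:
those plant legitimate extra variation (a deleted locus aligns as random
sequence) that is not part of the substitution-rate quantity under
measurement.
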