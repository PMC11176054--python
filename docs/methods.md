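# Methods

## The design under validation

Two inbred-by-inbred F1 hybrids carrying a MiMe genotype (*spo11-1 rec8
tam*-type triple mutant) produce unreduced, clonal gametes: each gamete is
genetically identical to its diploid parent, with no recombination and no
segregation. Crossing two such hybrids yields tetraploid "4-haplotype"
offspring carrying one full copy of each of the four grandparental
genomes. The package validates this design from short-read data in
reference coordinates: haplotype-unique markers, windowed B-allele
frequency and coverage, crossover and aneuploidy calls, marker-presence
percentages and gene dosage.

## Synthetic study conditions

The simulator's defaults are the package's fixed study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| layout | 12 chromosomes, ~774 Mb | tomato-scale genome; chr09 is 68.6 Mb |
| `snp_density` | 100 SNPs/Mb | founder-private sites per non-reference founder |
| `reference_private_density` | 100 SNPs/Mb | reference-divergence sites (below) |
| introgression | chr09 5–58 Mb, ×10 | wild-introgression block in the reference |
| `evidence_dropout` | 0.05 | per-replicate thinning of evidence call sets |
| `evidence_fp_per_mb` | 1.0 | false-positive SNPs per Mb per replicate |
| `crossover_rate` | 1.0 / chromosome | Poisson mean; obligate floor of 1 |
| `mean_depth` | 30× | sequencing depth of offspring |
| `error_rate` | 0.01 | per-read allele flip probability |
| `sharing_fraction` | 0.0 | fraction of private SNPs copied into another founder |
| `truncation_prob` | 0.0 | random terminal copy loss (off; injected explicitly) |

Two site classes are drawn as homogeneous point processes. *Founder-private*
sites carry the alternate allele in exactly one non-reference founder.
*Reference-divergence* sites are positions where the reference founder
itself carries the divergent allele, so every other founder reads as
homozygous-alt against the reference; these are what make reference-
haplotype markers possible (step (iii) below) and they are the class whose
density the reference's wild-introgression block multiplies — reproducing
the dense, ambiguous band on chr9 that motivates the 5–58 Mb exclusion.
Positions are sampled without replacement across founders, so alternate
alleles of different founders never collide unless `sharing_fraction > 0`,
a deliberate stressor for the uniqueness filters.

Chromosome truncation is modelled as removal of a terminal interval from
one chromatid. Real MiMe offspring show such losses at an appreciable rate
(the motivating material had deviations in 3 of 12 tetraploid offspring),
but the default probability is zero: losses are injected explicitly
(`TruncationSpec(forced=...)`) so that control genotypes stay clean and
every detection test has exact truth. Read counts at a site follow
`D ~ Poisson(d·c/ploidy)` and `alt ~ Binomial(D, p(1−e) + (1−p)e)` with
`c` the local copy number and `p` the local alt-copy fraction; zero-copy
regions therefore produce zero depth, and a lost copy shifts both depth
(×0.75 in a tetraploid) and AF (0.5 → 2/3 or 1/3 depending on which
haplotype lost).

One master seed drives everything through deterministically derived child
generators (`rng_from(seed, *stage_key)`), so identical configurations are
bit-reproducible.

## Marker derivation

All operations are position-level set algebra on biallelic SNP records.
Marker *inclusion* is strict — homozygous calls supported by two
independent evidence sets (intersection by position, allele and genotype
class) — while marker *exclusion* is permissive: any SNP reported at a
position in any other genome's data blocks that position, regardless of
allele. This asymmetry (require strong evidence to call, weak evidence to
veto) is what keeps ambiguous markers out even when evidence sets are
incomplete.

For a four-haplotype design (reference R, inbred I, hybrid haplotypes C/D):

1. **C (and symmetrically D)**: assembly-vs-reference SNPs of C matched by
   position and allele to *heterozygous* read SNPs of the C×D hybrid, minus
   every position in R's and I's SNP sets and in the sister haplotype's
   assembly SNPs.
2. **I**: homozygous dual-evidence SNPs of I minus every position seen in
   R, the hybrid reads, or either assembly.
3. **R**: positions homozygous-alt in *both* I and the hybrid reads — every
   non-reference haplotype carries the alternate allele, so
   reference-supporting reads diagnose the reference haplotype.

The exclusion regions (introgression) are applied last, to all four lists
by default (the region is ambiguous for every list; a per-haplotype
override exists). The four lists are pairwise position-disjoint by
construction and the container enforces it. A brute-force oracle
(`verify_marker_uniqueness`) checks every emitted marker against simulator
truth: alt-diagnostic markers must have exactly one carrier, ref-diagnostic
markers exactly all-but-the-reference.

## Windowed profiles

Sliding windows of `W = 1 Mb` advanced by `s = 50 kb`; a chromosome of
length `L ≥ W` has `floor((L−W)/s) + 1` windows (trailing partial window
dropped), shorter chromosomes get one whole-chromosome window. Window AF is
the *unweighted* mean of site AFs (`alt/(ref+alt)`, missing below
`min_depth = 1`); windows with fewer than `min_markers = 10` informative
sites are missing, not zero — a marker desert must not masquerade as a
state. Coverage is the window mean of site depths divided by the
genome-wide median of window means (median of the output is 1 by
construction). Coverage is computed at marker sites, not from alignments —
the pipeline deliberately consumes count tables, not BAMs.

## Inference

Window states are integer allele dosages: diploid `af < 0.15 → 0`,
`af > 0.85 → 2`, `|af−0.5| ≤ 0.15 → 1`; tetraploid snap-to-grid on
`{0, ¼, ½, ¾, 1}` within `t_dose = 0.08` (chosen so that the 2/3 plateau of
a 2+2→2+1 loss does *not* snap to ¾). Runs of ≥ `min_run = 5` identical
states seed segments; same-state seeds merge across ambiguous gaps.
Adjacent segments with different states yield one crossover call whose
interval is the span between the flanking segment boundaries (windows
overlap, so the span is sorted) and whose point estimate is the midpoint —
an interval, because with 1 Mb windows the breakpoint is only ever
approximate.

Aneuploidy requires the *joint* deviation — `|AF − expected| ≥ t_af = 0.10`
**and** `|cov − 1| ≥ t_cov = 0.15` — in merged runs of ≥ 5 windows, the AND
rule distinguishing true copy-number change from allelic artefacts.
Segment edges are refined to the centers of the outermost windows whose AF
deviation reaches half the plateau shift; with overlapping windows this
half-height crossing locates the true breakpoint to about one window step.
Loss direction comes from coverage; for a tetraploid loss the sign of the
AF shift names the lost haplotype (AF rising toward 2/3 means a copy of
the haplotype reading as 0 was lost).

Fitting order matters: aneuploidy is detected first and its windows are
masked before state segmentation, because within a copy-shifted region the
AF grid assumptions are wrong (2/3 lies between tetraploid states) and
would otherwise generate spurious crossovers. A sample is **clonal** if it
has zero crossover calls and ≥ 98% (`f_tol = 0.02`) of its classified
windows in the balanced state; **recombinant** with ≥ 1 crossover;
**anomalous** otherwise. Aneuploid segments are counted separately and
co-exist with a clonal label, as in a clonal genome with one truncated
chromosome.

All thresholds were fixed once against the default study conditions (depth
30, 1% error) — the formalization of an otherwise visual discrimination is
the point of this module — and are exposed on `InferenceParams`.

## Presence and dosage

A marker is *observed* when ≥ `min_supporting_reads = 1` reads carry its
diagnostic allele (ref-supporting reads for reference-haplotype markers).
Percent-found is computed over covered markers (uncovered markers are
excluded from the denominator but reported; a strict mode counts them as
absent). The four-haplotype decision accepts when all four percentages
reach `presence_floor = 90%`, a value comfortably between the two regimes:
carried haplotypes score ≳ 99% at any reasonable depth, while non-carried
haplotypes score only the error-read rate `1 − exp(−d·e)` (≈ 26% at
d = 30, e = 0.01; ≈ 9% at d = 10; exactly 0 at e = 0). With single-read
support this error floor is what "empty" means quantitatively; raising
`min_supporting_reads` to 2 drops it to ~4% at depth 30 at a small cost in
carried-haplotype recovery.

Expected dosage under clonal transmission is the number of carrier
grandparents (each contributes exactly one copy). Observed dosage pools
diagnostic-allele reads over all covered locus markers:
`copies = round(af × ploidy)` with ties rounded *down* — conservative
against overcalling resistance-gene copies. With ≥ 10 pooled markers at
depth 30, recovery of the true copy number is ≥ 99% across 0–4 copies.

## What the simulation does and does not show

The generator reproduces the features the methods rely on — founder-unique
and shared SNPs, introgression density, dual-evidence noise, clonal vs
meiotic transmission, copy-number-coupled depth and AF, binomial read
noise — and therefore shows that the set algebra, windowing and detection
logic are correct under those assumptions. It does **not** model: a
realistic crossover landscape (positions are uniform, no interference or
centromere suppression; tomato crossovers are strongly distalized),
alignment artefacts, mappability or GC bias in coverage, indels or
structural variants, linked-read or haplotype-phase information, or
segregation distortion. Passing tests accordingly validate the pipeline's
logic, not the error modes of any particular aligner or caller.

## Numerical and degenerate-input conventions

Positions are 1-based at the VCF/TSV boundary; all interval arithmetic
(BED, windows, chromatid segments) is 0-based half-open. Chromosome names
match exactly. Readers reject rather than coerce (negative counts,
duplicate keys, inverted intervals, non-SNP alleles); writers emit sorted,
deterministic output. Zero-depth count rows are retained with missing AF.
An all-zero-depth genome is an error in coverage normalization rather than
a silent division. Dosage ties round down; window-state ties cannot occur
(tolerance bands are strict subsets of half grid spacing).
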