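# polyhap

Validation toolkit for **polyploid genome design** crosses built on clonal
(MiMe, "mitosis instead of meiosis") gametes — the breeding scheme in which
two F1 hybrids each produce unreduced, unrecombined gametes so that their
tetraploid offspring carry the complete genomes of all four inbred
grandparents ("4-haplotype" plants).

Given short-read allele counts at SNP sites in reference coordinates, the
package answers the questions a breeder or genome engineer asks of such
material:

* **Which SNPs uniquely tag each haplotype?** Set-algebraic derivation of
  haplotype-unique markers for two- and four-haplotype designs, with
  dual-evidence intersection, position-level subtraction of every other
  genome's SNPs, and masking of wild-introgression regions (the chr9
  5–58 Mb *S. peruvianum* segment pattern) where dense divergence creates
  ambiguous markers.
* **Was transmission clonal or meiotic?** Per-sample B-allele-frequency
  profiles in 1 Mb windows stepped by 50 kb: a diploid F1 or a balanced
  2+2 tetraploid sits at AF 0.5 genome-wide; meiotic recombinants step
  between 0, 0.5 and 1, and each state change is called as a crossover
  with an uncertainty interval.
* **Is the karyotype intact?** Aneuploidy / chromosome-truncation detection
  from *joint* deviation of allele frequency and normalized read coverage
  (losing one of four copies shifts AF 0.5 → 2/3 and coverage 1 → 0.75),
  including which haplotype lost a copy.
* **Are all four genomes present, at what gene dosage?** Marker-recovery
  percentages per haplotype (the filled-vs-empty circle readout) and
  pooled-read dosage genotyping at loci of agronomic interest, where the
  expected copy number under clonal transmission is simply the number of
  carrier grandparents.

Because the real sequencing data are not needed to test any of this logic,
the package ships a forward simulator of the whole crossing scheme
(founders → hybrids → clonal/meiotic gametes → diploid or tetraploid
offspring → binomial read counts) with complete ground truth, used by the
test suite and the acceptance script.

## Model summary

At a marker site with `a` copies of the alternate-founder allele out of
local copy number `c`, read depth is `D ~ Poisson(d·c/ploidy)` for mean
depth `d`, and the alternate read count is `Binomial(D, p′)` with
`p′ = p(1−e) + (1−p)e`, `p = a/c`, `e` the per-read error. Window states
are the integer allele dosages nearest to the window mean AF
(`{0, ½, 1}` for diploids, `{0, ¼, ½, ¾, 1}` for tetraploids, within
configurable tolerance bands); crossovers are state changes between
confident window runs; aneuploidy requires `|AF − expected| ≥ t_af` **and**
`|cov − 1| ≥ t_cov` over a minimum run of windows. Meiotic gametes draw
`max(1, Poisson(λ))` crossovers per chromosome (obligate crossover) at
uniform positions.

## Worked example

Simulate a two-founder cross, derive markers, create a clonal tetraploid
that lost the terminal 9 Mb of one reference-founder copy of chr02, and fit
the transmission model:

```python
from polyhap import GenomeLayout, TransmissionModel, SimulationConfig
from polyhap.sim import simulate_founders, rng_from, TruncationSpec
from polyhap.pipelines import two_way_marker_pipeline, simulate_sample

layout = GenomeLayout((("chr01", 40_000_000), ("chr02", 30_000_000)))
config = SimulationConfig(layout=layout, founder_ids=("A", "B"),
                          snp_density=100, reference_private_density=100,
                          introgressions={}, seed=5)
panel = simulate_founders(config)
markers = two_way_marker_pipeline(panel, exclusion=None)

loss = TruncationSpec(forced=(("chr02", "A", "right", 9_000_000),))
sample = simulate_sample(panel, "clonal_tetraploid", ("A", "B"), "MiMe-6",
                         config, rng_from(5, 10, 0), truncation=loss)
results = TransmissionModel.from_markers(sample.counts, markers, layout,
                                         ploidy=4, haplotype_labels=("A", "B")).fit()
print(results.summary())
```

```
Transmission inference summary
==================================
sample:               MiMe-6
ploidy:               4
windows (W/s):        1000000/50000
windows profiled:     1362
genome mean AF:       0.5218
classification:       clonal
crossover calls:      0
aneuploid segments:   1
balanced-window frac: 1.0000
----------------------------------
aneuploidy (chrom start-end dir cov af_shift):
  chr02  21,150,000-30,000,000  loss  0.76  +0.167
```

The sample is clonal (no crossovers; every classified window at the
balanced 2-of-4 state once the anomalous region is set aside), and the
injected loss is recovered: coverage ratio ≈ 0.75, allele frequency shifted
by ≈ +1/6 to 2/3 (so the copy lost belongs to haplotype A, whose allele
reads as 0), with boundaries within one window step of the true 21 Mb
breakpoint. `results.crossover_frame()`, `results.aneuploidy_frame()` and
`polyhap.plotting.plot_results(results)` give the tabular and graphical
views.

The same stages are available from the shell:

```bash
polyhap simulate --config study.yaml --out-dir study/
polyhap markers  --mode two --target-evidence B.hifi.vcf B.short.vcf \
                 --reference-vcf A.hifi.vcf --haplotype B \
                 --layout layout.tsv --out markers.tsv
polyhap profile  --counts counts.tsv --markers markers.tsv --layout layout.tsv --out profiles.tsv
polyhap classify --counts counts.tsv --markers markers.tsv --layout layout.tsv --ploidy 4 --out calls.json
polyhap presence --counts counts.tsv --markers markers.tsv --out presence.tsv
polyhap dosage   --counts counts.tsv --markers markers.tsv --loci loci.tsv --design A,B,C,D --out dosage.tsv
```

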