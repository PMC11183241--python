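# Methods

This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic experiments do and do not
establish about real data.

## The analysis model

The package targets selection experiments in a (near-)haploid human cell
line: clones evolved to drug resistance are sequenced against their
cloned, sensitive parent, and somatic variants are prioritized for
causality.  Two signals identify drivers:

* **Fixation.** In a haploid clone a resistance driver sweeps to (near)
  100% of cells, so its allele fraction AF = AD/DP approaches 1.  The
  cascade keeps protein-altering variants with **AF > 0.85** (strict
  inequality) and DP ≥ 10.  The 0.85 threshold corresponds to the top
  2.5% of the allele-fraction distribution in this experimental design;
  `af_threshold_from_quantile` exposes the empirical-quantile calibration
  (linear-interpolation definition, numpy's default), and quantile mode
  uses `max(0.85, q̂_0.975)` so the cutoff never loosens below the fixed
  threshold.
* **Independent recurrence.** Selection finds the same gene repeatedly
  across independent lineages, usually through different alleles.  A gene
  below the AF cutoff is rescued when protein-altering variants occur in
  ≥ 2 *independent* lineages of the same drug, each at AF ≥ 0.30.
  Dependent clones (re-cloned from one selection) collapse to a single
  lineage — independence is the evidence, so the same amino-acid change
  in two independent lineages does count, while any number of hits inside
  one dependent-clone family counts once.  The 0.30 floor admits the
  mid-AF alleles this design is known to produce (rescued alleles near
  0.4–0.8) while excluding deep-subclonal noise; it is configurable, and
  `rescue_min_lineages=1` reproduces single-lineage candidate listing.

Drug-specificity is enforced at the **variant** level (a call present
under two different drugs is removed everywhere): identical calls across
drugs selected from the same parental background indicate pre-existing or
artifactual variation, not selection.  Gene-level specificity would also
discard genuinely pleiotropic resistance genes, so it was not used.

## Consequence annotation

A compact annotator reimplements the needed subset of a standard
consequence predictor, on protein-coding canonical transcripts only:

* canonical transcript = longest spliced CDS, ties by smallest
  transcript id;
* CDS features include the stop codon; protein length = CDS/3 − 1.
  API-level CDS size parameters count *translated* codons (a 2,295-bp
  request yields a 765-residue protein with a 2,298-bp CDS feature);
* splice acceptor/donor = 2 intronic bases at each intron edge (HIGH);
  splice region = intronic bases 3–8, reported together with the intron
  term (LOW);
* "intragenic" = inside the annotated gene span but outside every
  transcript — gene records deliberately include flanking
  promoter/UTR-like territory so this category is non-empty, mirroring
  reporting schemes that distinguish intronic from other within-gene hits;
* frameshift position = the first codon whose base composition changes;
  a frameshift whose first affected codon becomes a stop is reported as
  the combined frameshift-plus-stop-gained class;
* inframe indels are "disruptive" when they do not respect codon
  boundaries; standard nuclear genetic code throughout.

Impact tiers are a fixed total table (HIGH: frameshift, stop gained/lost,
start lost, splice acceptor/donor; MODERATE: missense, inframe indels;
LOW: synonymous, splice region; MODIFIER: intron, intragenic, intergenic,
UTR).  Unknown terms raise — the cascade must never default-pass a
consequence it does not understand.  Structural-interaction annotations
would require protein-structure inputs and are excluded.

## CNV calling

A deliberately simple surrogate for a production read-depth caller,
adequate for haploid baselines and paired controls:

* per-bin ratio r_i = (clone_i/median) / (parent_i/median) in 50-kb bins;
  bins with zero parent coverage are masked and never enter segments;
* segmentation by thresholds at the midpoints between integer copy
  states on the haploid baseline — gain > 1.5, loss < 0.5 — over runs of
  ≥ 3 bins, merging runs interrupted by a single masked bin;
  copy number = round(mean ratio × baseline), clipped to ≥ 2 for gains
  and to 0 for losses (baseline 2 inside declared diploid regions);
* significance: two-sided Mann–Whitney rank-sum of segment bins against
  the clone's non-segment bins, Benjamini–Hochberg across the clone's
  segments, keeping q < 0.05.  All-tied inputs give p = 1, never an
  exception.  The test and correction are explicit choices (the upstream
  convention "corrected p < 0.05" does not pin them down) and are
  configurable;
* recurrent regions: per drug and status, a breakpoint sweep keeps
  elementary intervals supported by ≥ 2 but strictly fewer than all
  clones of that drug — events in every clone more likely reflect
  artifacts shared with the parent.  Genome fraction in the summary is
  the sum of event sizes over genome size (events are counted per clone,
  so overlapping events in different clones both contribute).

WES samples are handled by masking: bins without parent coverage (capture
gaps) are masked through the `min_parent_count` parameter, which is why
WES profiles yield more, shorter segments than WGS on the same events.

## Window-clustering statistic

For n mutations uniformly and independently placed on a protein of L
residues, the count inside a fixed window of w residues is
Binomial(n, w/L); `window_cluster_pvalue` returns the exact upper tail
P(X ≥ k).  This is the simplest defensible null for "k of n truncating
mutations fall in one w-residue span".  A `scan` mode estimates by seeded
Monte Carlo the sharper question "any window of length w collects ≥ k"
(default 100,000 draws); the scan probability always dominates the
fixed-window one.  The fixed-window tail for (n=22, L=765, w=30, k=6) is
1.58 × 10⁻⁴ — order 10⁻⁴; published figures for this quantity depend on
the (often unstated) choice of null and are not reproduced digit-for-digit
by design.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes, at
desk scale:

| parameter | default | rationale |
|---|---|---|
| genome | 4 chromosomes × 12.5 Mb | desk-scale stand-in for a 3.1-Gb genome |
| genes | 1000, CDS 300–1500 bp, ≤ 3 exons | coding fraction ~1.8%, the human order of magnitude |
| diploid region | 500 kb on the last chromosome (~1%) | residual diploid fragment of the near-haploid karyotype |
| drugs × selections | 5 × 3 independent | at least three independent selections per drug |
| passengers/clone λ | 1500 (Poisson) | per-clone somatic load of a months-long selection |
| passenger AF | Beta(0.8, 3) truncated to (0, 0.999] | reproduces a spectrum almost entirely below 0.85 with rare high-AF passengers (~0.6% emitted above 0.85 after read sampling) |
| indel fraction | 0.05 | indels are a small minority of somatic calls |
| driver AF | 1.0 (AD = DP exactly) | haploid sweep is deterministic; sub-1 targets use Binomial(DP, AF) |
| site depth | NB, mean 60, size 50 (CV ≈ 19%) | realistic short-read site-depth overdispersion; mean depth is a choice, not a measured value |
| coverage bins | 50 kb; NB size 100; CNV multiplies the mean by copy number | matches the 50-kb window convention |
| WES | emission restricted to exome mask ± 100 bp; off-target coverage 0.5% | capture flank holds splice-adjacent calls |
| heterozygous passengers | AF target 0.5 in diploid regions, GT 0/1 | chr15-fragment analog |

Dependent lineages are declared as clone groups sharing one lineage id;
all clones of a lineage carry the *identical* driver record.  A "raw"
mode (`raw_parent_variants > 0`) emits parent variants inside the clone
calls so the parent-subtraction step can be exercised; the default mode
emits parent-subtracted calls directly, as a paired somatic caller would.

Everything is driven by `numpy` Generators spawned from the single config
seed (per-clone streams keyed by CRC32 of the clone id), so identical
seeds give byte-identical output files.

**What passing tests show — and what they do not.**  Under these
conditions every planted driver is recovered (drivers at AF 1.0 with
DP ≥ 10 survive the cascade by construction) and pooled gene-level
precision across 20 seeds is ≥ 0.8, the residual false positives being
high-AF passengers (the Beta tail) and rare cross-lineage passenger
collisions.  The generator does not model mutational signatures, mapping
artifacts, contamination, subclonal population structure, or
copy-number–coupled allele fractions (a driver inside an amplification
can sit below 0.5 even in a haploid line); real-data precision therefore
depends on upstream calling quality in ways these simulations cannot
certify.  Read-level simulation (FASTQ/BAM) is out of scope.

## Numerical conventions and degenerate inputs

* VCF/GFF3 coordinates are 1-based inclusive; bins/BED and in-memory
  interval sets are 0-based half-open; conversions live in one module.
* AF is computed by exact rational division; quantiles use linear
  interpolation; report floats are written with `%.6g` so re-runs are
  byte-identical.
* Indels are left-aligned (anchor-base convention) before parent/clone
  set subtraction.
* Empty inputs propagate as empty tables with headers and exit success;
  zero-depth AF requests, unknown consequence terms, reference
  mismatches, and mismatched bin grids raise typed errors naming the
  offending position or constraint.
* Candidate and report tables are sorted (drug, gene) with a stable sort;
  ties in canonical-transcript selection break lexicographically.

## Known limitations

* The annotator covers the consequence subset used by the cascade, not a
  full predictor (no regulatory features, no NMD, no structure-aware
  categories).
* The CNV caller is threshold-based; it is not bit-compatible with
  production segmentation tools and does not reconstruct breakpoints from
  read pairs, call allele-specific copy number, or estimate purity.
* Recurrence significance is rule-based (lineage counting), not a
  genome-wide enrichment test; with ~20,000 real genes and few lineages
  per drug, formal per-gene significance is rarely attainable anyway.
* The secondary report lists CNV-overlapping genes only among genes that
  already carry a protein-altering variant below the AF cutoff; genes
  implicated *solely* by copy number appear in the CNV gene-overlap
  output instead.
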