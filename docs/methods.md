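# Methods

This note documents the models, statistics, parameter choices and known
limitations behind `circsponge`.

## Expression model

A circRNA is evidenced only by reads spanning its back-splice junction, so
its expression unit is back-spliced reads per million back-spliced reads:
`RPM_ij = 10^6 · C_ij / N_j`, with `C_ij` the junction reads of circRNA *i*
in sample *j* and `N_j = Σ_i C_ij`. The denominator is deliberately the
total over *back-spliced* reads only (not all mapped reads); columns with
`N_j = 0` are returned as zero with a warning. Two consequences worth
knowing: every non-degenerate RPM column sums to exactly 10^6, and the
normalization is compositional — a large shift in a few abundant circRNAs
moves the apparent expression of all others. The junction counter itself
substitutes junction-spanning k-mer matching (default 20 nt per side,
`min_overhang` 5, `max_mismatches` 1) for a genome aligner: at desk scale it
is exact, fully specified, and independently verifiable against a
sliding-window Hamming oracle. A read counts at most once per circRNA; a
read matching several circRNAs increments each, which keeps `N_j` consistent
with the per-circRNA definition.

## Differential expression

Fold change uses group-mean RPM with a symmetric pseudocount:
`FC = (RPM_test + c)/(RPM_ref + c)`. The default `c` is half the smallest
nonzero RPM in the dataset, which keeps log2FC finite and pushes
presence/absence circRNAs into the extreme |log2FC| ≈ 18–20 regime that
total-count-normalized junction data produce (e.g. a circRNA absent in one
group at `c ≈ 1.9` RPM gives log2FC ≈ 19).

The per-circRNA p-value defaults to a pooled exact conditional binomial
test: conditioning on `m = C_ref + C_test` (replicates pooled), the test
group's total is Binomial(`m`, `N_test/(N_ref+N_test)`) under the null; the
two-sided exact p-value follows. This suits very sparse junction counts,
where replicate-level tests have almost no information. Its assumption is
that replicate variability is modest relative to counting noise — valid for
pooled-tissue replicates, anticonservative for highly dispersed ones, which
is why a Welch t-test on `log2(RPM + c)` across replicates is available as
`welch_log`. Multiple testing uses the Benjamini–Hochberg step-up
(implemented directly from the definition and cross-checked in tests
against both a brute-force evaluation and statsmodels). A circRNA is called
up when `q < alpha` and `log2FC > 1`, down when `q < alpha` and
`log2FC < −1`, strictly; otherwise ns. The stated "down when log2FC below
the threshold" convention is interpreted symmetrically (< −1), matching the
absolute-value criterion.

Trend classes over the three timepoints are computed on the 3-vector of
group-mean RPM, Z-scored with the population (n = 3) standard deviation:
strictly increasing, strictly decreasing, peaked (middle above both ends)
or dipped (middle below both ends). Exact ties are refused rather than
silently binned — on continuous RPM they indicate degenerate input.

## Parental genes

The both-ends rule: a gene is parental to a circRNA only when both junction
ends lie within that one gene. `coordinate` mode tests the junction
coordinates directly; `anchor` mode locates the two 20-nt anchors flanking
the junction by sequence search (exact, then ≤ 1 mismatch) inside each
gene's span, standing in for the original anchor-read alignment. Strand
concordance between circRNA and gene is required by default and can be
relaxed (`require_strand=False`) since upstream discovery pipelines differ
on this. Ties between overlapping genes are broken by largest base-pair
overlap, then lexicographic gene id, so assignment is order-invariant.

## miRNA target prediction

Candidates come from a seed scan: offsets where the target (sense strand)
contains the exact Watson–Crick reverse complement of miRNA positions 2–8;
optionally one G:U is tolerated in the seed. Each candidate window (the
full putative site plus a 30-nt upstream flank) is scored three ways:

1. **Alignment score** — Smith–Waterman local alignment of the window
   against the miRNA read 3′→5′, scoring +5 per Watson–Crick pair, +1 per
   G:U, −3 per mismatch, affine gaps −9 open / −4 extend, with pair scores
   doubled at seed positions 2–8 (perfect 22-nt duplex = 145). The cutoff
   (default 140) is expressed on the 22-nt scale and rescaled to each
   miRNA's maximum attainable score.
2. **Duplex minimum free energy** — dynamic programming over intermolecular
   duplex structures (Watson–Crick + wobble pairs, stacks, bulges/internal
   loops up to 6 unpaired bases per strand, no intramolecular pairing) on a
   bundled plain-text nearest-neighbor table at 37 °C
   (`data/rna_duplex_params.tsv`; Watson–Crick stack values after Xia et
   al. 1998, wobble and loop terms approximate in the spirit of Mathews et
   al. 1999, duplex initiation +4.09 kcal/mol). Threshold: ≤ −14 kcal/mol.
   The table is the single source of energies — tests hand-sum from the
   same file. The classifier stage that some hybridization pipelines stack
   on top of the energy model is not reproduced; the energy threshold is
   the documented stand-in.
3. **Penalty score** — a plant-style position-weighted penalty (mismatch 1,
   G:U 0.5, gap 2; doubled at miRNA positions 2–13) over a global alignment
   of the site; threshold ≤ 4, lower is better.

Numeric parity with the original third-party binaries is a non-goal; the
published scoring ideas are reimplemented with configurable parameters, and
a final target requires passing **all three** thresholds (`pass_all`), so
tightening any one threshold can only shrink the hit set. circRNA targets
are scanned on the junction-spanning sequence, which is exactly where
sponge sites are planted by the generator; full-circle scanning with a
seam-bridging copy is not performed because junction sequences are the only
circRNA sequence this pipeline carries.

## ceRNA networks

Nodes are restricted to features differentially expressed in the relevant
comparison; edges to `pass_all` hits; the graph is strictly tripartite
(circRNA → miRNA → mRNA) and validated on every build. By default an edge
does not require opposite expression directions — the construction is pure
targeting — but `require_anticorrelation=True` keeps only sign-opposed
pairs, which is the stricter ceRNA expectation; the filtered edge set is
always a subset of the unfiltered one. Sub-networks: miRNA-centric (the
miRNA, its circRNA sponges, its mRNA targets) and pathway-restricted (keep
mRNAs annotated to the terms, then miRNAs with a surviving mRNA edge, then
circRNAs with a surviving miRNA edge). Axes are all (circRNA, miRNA, mRNA)
triples with both edges present, so a hub miRNA with fan-in *a* and fan-out
*b* contributes *a·b* axes. miRNA- and mRNA-layer differential calls are
supplied as tables (in a real study they come from companion sRNA-seq and
mRNA-seq analyses); the generator emits planted stand-ins.

## Enrichment and validation statistics

Term enrichment is the upper-tail hypergeometric probability
`P[X ≥ k]` for `X ~ Hypergeom(N, K, n)` per term, BH-adjusted across terms.
The background defaults to all genes of the annotation table and should be
overridden with the full gene universe when the table covers only annotated
genes. No ontology-graph propagation is performed — the table is taken as
given, so numeric agreement with enrichment runs against live annotation
databases is out of scope by design.

qPCR follows Livak: per-sample ΔCt = Ct_target − Ct_reference, ΔΔCt =
mean ΔCt(test) − mean ΔCt(control), relative expression 2^−ΔΔCt, with a
two-sided t-test on the per-sample ΔCt values (Welch by default; pooled
Student's optional, matching the common reporting convention). Well pairing
beyond sample identity is not modeled. The dual-luciferase comparison forms
per-well firefly/Renilla ratios and applies the same two-sided t-test
between mimic and negative-control groups per construct; the statistic is
invariant to rescaling both channels. Degenerate noise-free inputs (zero
variance in both groups) return p = 1 for equal means rather than NaN.

## Synthetic data generator

The generator emulates the study conditions, not any particular dataset:

* **Design**: 3 groups × 3 replicates (`Ac4/Ac5/Ac6` naming when
  `n_groups=3`), 150 circRNAs over 100 non-overlapping genes on one
  synthetic chromosome, 12 miRNAs, 250-nt 3′UTRs, junction half-length
  k = 30 so a 22-nt MRE can span the back-splice seam.
* **Counts**: negative binomial with mean 10 junction reads per circRNA per
  sample and size 20 (variance/mean = 1 + μ/size = 1.5 at the default
  mean). Junction counts are low and mildly overdispersed; size 20
  corresponds to a biological CV of ~0.22, appropriate for replicates that
  are pools of many individual guts.
* **Planted effects**: a fraction `frac_de` (default 0.2) of circRNAs per
  consecutive comparison, |log2FC| = 3, with *balanced* up/down direction
  counts. Direction is planted by boosting the later groups (up) or the
  earlier groups (down) by 2^3, which keeps the expected per-group library
  size equal — emulating depth-matched libraries. This matters: boosting
  only one side shifts every null circRNA's RPM through the compositional
  denominator and would manufacture spurious calls that no depth-matched
  experiment shows. A fraction of DE circRNAs (default 0.1) are planted as
  complete dropouts (all-zero in the appropriate groups) to exercise the
  extreme-|log2FC| pseudocount regime.
* **MREs**: planted sites are exact reverse complements of their miRNA
  (optional mismatches fall outside the seed-pairing region), written into
  the genome so junction sequences and UTR FASTA remain genome-consistent.
  miRNA generation rejects candidates whose seed complement occurs inside
  another miRNA's planted site, and a deterministic scrub pass mutates
  every unplanned seed-complement occurrence in the genome and across
  back-splice seams, so planted-site counts (e.g. the hub's fan-in of 15)
  are exact rather than approximate.
* **Truth**: planted DE ids and directions, dropouts, axes, hub membership,
  host genes, pathway assignment and MRE offsets are all returned (and
  written as `truth.json`), enabling recovery tests with no reference to
  internal state.

One `numpy` Generator seeded from `SynthConfig.seed` drives everything;
identical configuration and seed give a byte-identical bundle.

What the generator does **not** emulate: read-level sequencing error,
splicing isoforms, GC or length biases, unbalanced library depths,
minus-strand MRE planting, and correlated replicate structure. Passing
recovery tests therefore demonstrate the correctness of the implemented
statistics and the internal consistency of the pipeline under its stated
assumptions — not performance on real libraries, where normalization bias,
dispersion estimation and target-prediction specificity are all harder.

## Numerical and design choices

* Coordinates are 0-based half-open internally and in BED-like files; GFF3
  is converted at the boundary (1-based inclusive on disk).
* T/U normalization happens once at ingestion; scoring code assumes the RNA
  alphabet internally, genome-side code the DNA alphabet.
* Exact-zero p-value underflow from the binomial test is floored at 1e-300
  before BH adjustment (the adjustment requires p > 0).
* Alignment traceback prefers diagonal, then a gap in the target, then a
  gap in the miRNA; all tie-breaks (parental genes, enrichment ordering,
  edge-list export) are deterministic so whole-pipeline reruns are
  byte-identical. The manifest stores the configuration hash and row
  counts, never timestamps.
* Problem sizes in the test suite and acceptance script (e.g. 2000 null
  circRNAs × 5 seeds for error-rate checks, 800 circRNAs for recovery, 200
  for parental accuracy, duplexes ≤ 8 nt for exhaustive structure
  enumeration) were chosen as the smallest sizes at which the Monte-Carlo
  bounds are stable.

## Known limitations

* The pooled binomial test ignores replicate dispersion; with strongly
  overdispersed replicates its p-values are anticonservative (use
  `welch_log`, or an external NB framework, in that regime).
* RPM is compositional; strongly unbalanced differential load between
  groups biases null fold changes (the generator's depth-matched planting
  documents exactly this sensitivity).
* Target predictor parameters are conventional defaults, not calibrated
  against experimental binding data; the duplex parameter table is
  approximate where wobble/loop terms are concerned.
* Multi-chromosome genomes, overlapping genes and fusion/read-through
  parental assignment are out of scope.
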