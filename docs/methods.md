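# Methods

This note documents the models, parameter choices and numerical decisions
behind `floraltse`, and what the synthetic-data tests do and do not show
about real data.

## The synthetic universe

The generator emulates the data-generating process of a 454-era de novo
floral transcriptome study of a Cleomaceae focal taxon (Th) compared
against four rosid reference transcriptomes: *Arabidopsis thaliana* (At),
*Brassica rapa* (Br), *Carica papaya* (Cp) and *Populus trichocarpa* (Pt).

**Gene families on the tree.** Each of `n_families` (default 2,000) gene
families is born on one branch of the root-to-focal path of the fixed
topology `(Pt,(Cp,(Th,(At,Br))))` and independently lost on eligible
branches below (never severing the focal taxon, whose transcripts define
the families).  Default birth probabilities — root 0.75, malvids stem 0.05,
core-Brassicales stem 0.08, focal terminal 0.12 — and a per-branch loss
probability of 0.01 were chosen once to echo the subset proportions such
studies report (focal-specific ≈ 11 %, core-Brassicales-specific ≈ 3 %,
Brassicales-specific ≈ 1.4 %).  Presence flags follow deterministically
from the events.

**Lengths and abundances.** Focal CDS lengths are log-normal
(median ≈ 1.1 kb, σ_log = 0.35, clipped to [300, 8000] nt) with an
exponential 3' UTR (mean 250 nt).  Transcript abundances are i.i.d.
log-normal (μ = 2, σ = 1.5 in natural log — spanning roughly three orders
of magnitude, as floral RNA-seq does), with a 20 % unexpressed fraction.

**Partial assembly.** Each family also carries the length of its ortholog
reference gene model, `ref_cds_length ≥ th_cds_length`: 70 % of families
are fully covered, the rest cover a Uniform(0.3, 1) fraction of the model.
This encodes a central feature of shallow 454 assemblies — a contig can
represent only part of a gene while read counts are normalized to the full
ortholog model under TSE1 and to the short contig under TSE2.  It is the
mechanism that makes contig-based expression read systematically higher,
and the package's tests verify exactly that (median TSE2/TSE1 normalized
ratio ≈ 1.1–1.3 under the defaults).

**Reads.** Read origin is drawn proportional to abundance × transcript
length (a fragmentation model — more template mass yields more fragments;
this is also why TSE read counts estimate molar abundance only after
length normalization).  Read length is Normal(316, 90) truncated to
[50, transcript length], matching 454 read-length statistics; reads are
split at random into two replicate libraries, mirroring a split
picotiterplate run.  Base-call errors are *not* simulated: alignment is out
of scope, so hit-table noise (miss and spurious rates, below) is the error
model.

**Contigs.** One contig per expressed family carrying the full transcript
(`utr_padding: true_utr`; CDS only with `none`).  A configured fraction
(default 0.01, echoing the ~1 % chimera rates reported for such
assemblies) of the expressed families is concatenated pairwise into
chimeric contigs that *replace* both constituents' own contigs, so reads
from two genes genuinely pool on one contig under TSE2.

**Hit tables.** True similarity hits draw log₁₀ e-values uniformly from
(−180, −11); spurious hits from (−12, −2), straddling the 1e-10 detection
threshold so that roughly 20 % of spurious hits pass it.  Bitscores are
anti-monotone in e-value.  Per-taxon true hits are dropped with probability
`miss_rate` and spurious hits appear with probability `spurious_rate` per
contig and taxon.  Annotation hit tables (contig ↔ reference model) are
emitted symmetrically so reciprocal-best-hit selection is exercised in both
directions.

**Read mapping.** A read maps to a target model iff its midpoint falls in
the portion of its transcript that the target carries: the CDS for ortholog
models (UTR reads find no protein-space hit), everything for UTR-padded
contigs.  The midpoint rule keeps the expected count exactly proportional
to abundance × covered length, which the recovery tests rely on.

**qPCR design.** The housekeeping reference (the *ACT7* analogue) is a
well-assembled (complete, non-chimeric), highly expressed family — the
98th abundance percentile rather than the maximum, so the validation panel
of 14 genes can straddle it across the ratio range ~0.05–10 on a log-spaced
grid.  Two panel genes are planted discordant (qPCR sees 8-fold less
template than the reads suggest), emulating read cross-mapping within large
gene families.  Dilution series follow `Cq = intercept − log_E(template)`
over 1:50…1:50,000; replicate Cq values are Normal(mean, 0.15).  The
calibrator group is an equimolar template (genomic DNA), which is what
makes efficiency-corrected ΔΔCq folds recover abundance ratios exactly —
with a biological calibrator sample the per-gene calibrator abundances
would enter the fold.

## Analysis-side decisions

* **Best-hit tie-break** (bitscore → e-value → subject id) makes selection a
  total order; RBH output is therefore a deterministic partial matching,
  invariant to row order.
* **Chimera heuristic**: ≥ 2 distinct genes, segments ≥ 100 nt,
  e-value ≤ 1e-10, pairwise overlap ≤ 30 nt, greedy interval selection by
  end coordinate.  Flagged contigs are excluded from TSE2 by default
  (configurable), since pooled multi-gene reads inflate contig expression.
* **"Mappable million"** is counted per strategy: reads with ≥ 1 retained
  hit under the active reference set.  This keeps TSE1 and TSE2 each
  internally consistent; the two denominators differ (UTR-only reads map
  under TSE2 but not TSE1) and cancel in reference-normalized ratios.
* **Rarefaction** offers both the closed form (default; exact, log-gamma,
  stable at N = 10⁶ with Nᵢ up to 10⁴) and 1,000-replicate resampling
  (validated against the closed form to 3 SE at every grid point).  The
  default grid is 50 even depths from 0 to N.  The verbal "curve flattens
  into a plateau" criterion is quantified as tail-decile slope < θ = 10⁻³
  genes/read.  Note that a *merged* library's curve is not pointwise above
  its inputs' curves at equal depth — pooling dilutes per-read discovery —
  only its endpoint richness dominates; the tests assert the correct
  property.
* **Presence** in a comparator taxon is hit-existence at the e-value
  cutoff (1e-10), with no coverage or identity requirement, and is
  one-directional (no reciprocity demanded).
* **Dollo reconstruction** places the single birth on the edge above the
  MRCA of present leaves and one loss per maximal absent clade below; this
  is provably the unique minimal single-gain explanation on the fixed tree
  (verified against exhaustive enumeration for all 16 masks).  Planted
  gain/loss *rates* are only partially identifiable from presence masks: a
  root birth whose Pt copy was lost reconstructs as a malvids birth with no
  loss.  Recovery tests therefore compare reconstructed counts against the
  analytically enumerated expectation of the reconstruction, not against
  raw planted events.
* **Cross-platform comparison** is strictly qualitative: microarray
  presence (any stage ≥ detection threshold, a required config value) vs
  RNA-seq presence (read count ≥ 1 by default), linked through the RBH
  matching; genes without a partner are reported as unmapped and never
  enter the differential lists.
* **qPCR validation regression** is computed on reference-normalized fold
  ratios, linear scale by default (log10 optional); the reference gene
  itself is left out (it would contribute a forced (1,1) point).  Outliers
  are identified data-driven as the largest absolute residuals (two by
  default) and the fit is repeated without them, mirroring how discordant
  large-family genes are handled in practice.
* **ANOVA degenerate case**: all-equal values across groups return
  (F, p) = (0, 1) rather than NaN.

## Pipeline and reproducibility

Stages run in dependency order (synth → annotate → expression → rarefaction
→ lineages → crossx → qpcr), communicate only through plain-text files
(FASTA, `outfmt 6` TSV, TSV tables, JSON), and fan per-stage RNG streams
out of one global seed via `SeedSequence(seed, stage_index)` — so disabling
one stage never shifts another's draws, and a fixed (config, seed) yields
byte-identical TSV/JSON outputs.  Floats are written with `%.6g`; JSON with
sorted keys.

The bundled demonstration configuration uses 2,000 families and 10⁵ reads
in two replicate libraries — enough for the recovery statistics to be
stable (Spearman(truth, TSE1 RPKM) ≈ 0.96; focal-specific precision and
recall 1.0 noise-free and ≥ 0.9 at 5 % missed / 1 % spurious hits) while a
full end-to-end run stays around twenty seconds on one CPU.  Tests use the
same scales or smaller.

## What passing tests do and do not show

The generator plants exactly the structures the pipeline infers, with noise
only where configured, so recovery tests demonstrate the *correctness of
the inference logic*, not performance on real data.  In particular: real
454 homopolymer errors, assembly fragmentation beyond the planted chimeras
and partial models, paralogous gene families (cross-mapping is emulated
only as a planted qPCR discordance), alignment-score idiosyncrasies, and
microarray probe hybridization biases are all outside the model.  Absolute
mapping rates and subset counts from the demo are properties of the
synthetic universe, not estimates for any real organism.

## Known limitations

* Orthology is one-to-one by construction (RBH); many-to-many families are
  not modelled or inferred.
* TSE2 quantification assigns a chimera's pooled counts to its single RBH
  gene; probabilistic multi-mapping (EM) is a non-goal.
* Rarefaction does not extrapolate beyond the observed depth (no Chao/ACE).
* The qPCR module starts from Cq values; raw fluorescence processing is
  instrument territory.
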