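# Methods

## Coordinate model

All internal coordinates are 0-based, half-open. GTF exon features
(1-based inclusive) and fixedStep wiggle starts (1-based) are converted
once, at the readers. The method is dominated by small fixed offsets —
50-nt windows, a 50-nt gap, 25-nt radii, ≤ 1-nt linkage — so keeping a
single arithmetic convention is the main defence against silent ±1
drift. Positions of single bases (a PAS, a TSS, an EST terminus) are
base offsets, not half-open bounds: a + strand transcript whose last
exon is `[1500, 2001)` has its PAS at 2000.

Score tracks are sparse per-chromosome arrays with role-dependent
missing-data semantics declared at load time: conservation tracks
(PhyloP has alignment gaps) treat absent bases as *missing* and report
means over present bases together with the fraction present; coverage
tracks treat absent bases as depth 0 and reject negative depths.

## PTE detection

EST termini are clustered by transitive single linkage at
`linkage_distance` (default 1 nt): 100, 101, 102 form one cluster even
though the outer pair differs by 2. The cluster representative is the
modal member position, ties resolved towards the larger coordinate (the
statistic the rest of the pipeline anchors on; any member would do to
within the linkage radius, the mode is simply the best point estimate
of the underlying cleavage site). EST orientations are ignored
throughout — EST libraries mix strands, so only positions are evidence.

Filtering order is support → exon → splice-site → merge → classify.
The order matters only for the merge: merging after the noise filters
means "most distal survivor" is chosen among plausible ends rather than
among raw noise. Constants (defaults): `min_support` 4,
`splice_site_exclusion` 25 nt taken as an inclusive radius around the
exon-edge bases of spliced-EST junctions, `merge_distance` 25 nt
(clusters chained at pairwise distance < 25 collapse to one survivor),
`max_gene_distance` 1 Mb.

Two points were genuinely open and are resolved as follows:

* **"Most distal" during merging.** Distality needs a direction before
  the PTE has an identity. We resolve it against the transcription
  direction of the nearest reference transcript (within 1 Mb); when no
  gene is near or equidistant genes disagree on strand, the
  highest-support cluster survives (ties towards the larger
  coordinate). This keeps the merge deterministic and
  reference-frame-consistent with the later classification.
* **Intron-contained PTEs.** A PTE inside the intron(s) of same-strand
  transcript(s) is labelled a putative PAS on that strand (distance 0):
  the containing gene is transcribed towards every position in its own
  intron, and the biological reading is the PAS of an alternative last
  exon. Containment in opposite-strand overlapping genes is
  undetermined and excluded from downstream scoring. Distance to a
  non-containing transcript is measured to its nearest end coordinate.

## Conservation Drop Index

For an anchor base p with the outside direction pointing right
(+ strand 3′ end, − strand 5′ end), with window w = 50 and gap g = 50:
T = [p−w+1, p+1), NT = [p+g+1, p+g+1+w); the mirrored geometry
otherwise. The anchor base itself is transcribed and belongs to T. The
gap skips the downstream sequence element, which is itself moderately
conserved and would otherwise dilute the drop.

Missing conservation bases are excluded from window means rather than
imputed; a window with fewer than `min_value_fraction` (default 0.5)
defined bases marks the whole CDI undefined, and undefined CDIs are
excluded from FDR curves. Windows truncated at chromosome bounds are
flagged, not raised. Classified PTEs are scored with the polarity of
their identity (putative PAS → 3′ geometry on the classifying gene's
strand, putative TSS → 5′); undetermined PTEs get both inside-left and
inside-right orientations reported as a pair, since no polarity can be
assigned.

CDI is invariant to adding a constant to the track and equivariant
under scaling — it measures a *drop*, not an absolute level, so tracks
with different baselines are comparable.

## Extension candidates and Coverage Difference

"Same structure" between a reference and a projected orthologous
transcript means a coordinate-identical last intron — same chromosome,
strand, donor and acceptor, no fuzz (fuzzy matching would need a
tolerance with no principled value; shared splice sites are typically
exact when projection succeeds). The ortho PAS must be strictly more
distal; `--min-extension` exposes a floor (default 1 nt). Up spans from
the base after the annotated PAS through the proposed PAS; Down is the
next Up-length bases, truncated (and flagged) at chromosome ends;
candidates whose Down would be empty are dropped. Several orthologs may
extend one reference transcript; each pair is a candidate, and
`--collapse most-distal` keeps the farthest per reference transcript.

Coverage is binarized at depth ≥ 1 before the percentages, which makes
CD invariant to sequencing depth above saturation and lets multiple
tissue tracks pool by simple depth summation (a base is covered in the
pool iff covered anywhere). Pooling is the default; `--per-tissue`
emits one CD table per track instead.

## Support and FDR

A putative PAS is supported when any validating transcript has its PAS
within `pas_tolerance` (default 25 nt, 0 for a literal same-position
reading — 25 matches the positional wobble the merge step already
grants) of the candidate *and* that transcript's last intron equals any
intron of any examined-database transcript. Multiple validating
databases are OR-combined. Every distinct observed score becomes one
cutoff (`score ≥ cutoff`; ties collapse to one point), so the curve's
final point equals the overall unsupported fraction. These FDRs
overestimate: a real but universally unannotated PAS counts as a false
discovery.

## Synthetic scenarios

The generator lays `n_genes` (default 30) three-exon genes along one
chromosome (exons 150–400 nt, introns 500–1500 nt, slots padded so
every planted site is nearest its own gene) and gives
`n_true_extended` (default 20) of them a true distal PAS 500–2000 nt
past the annotated end. Evidence defaults: conservation
Normal(μ_in = 1.5, σ = 0.5) over transcribed spans and
Normal(μ_out = −0.5, σ = 0.5) elsewhere — a 2.0 step at true ends, a
strong vertebrate-style signal; EST ends Poisson(λ = 8) with ≤ 1 nt
jitter per planted site plus 0.5/kb uniform decoy ends and two spliced
ESTs per gene; coverage Bernoulli(p_in = 0.9) inside transcribed spans
versus p_out = 0.02 outside; every true extension echoed by an ortho
model and 30 % of non-extended genes given a decoy ortho extension.
Flank decoy EST clouds are planted downstream and upstream of every
gene to exercise both classifier branches with known truth.
Conservation is a per-base step process, not a phylogeny; ESTs and
coverage carry no sequence, hexamer or read-level error structure — so
passing tests demonstrate the *logic* (geometry, filters, statistics,
ranking) under the stated signal model, not performance on real tracks,
where conservation baselines wander and coverage is bursty.

Scenario sizes in the test and acceptance harnesses (30 genes /
~400 kb; 200 genes for the null-CDI calibration check) are chosen as
the smallest instances at which every branch of the pipeline is
exercised and binomial/Normal error bands are tight enough to be
informative.

## Numerical choices and degenerate inputs

* Window means and percentages are plain float64 sums; oracle tests
  pin them to 1e−12 against per-base Python loops.
* Empty inputs flow through: no ESTs → empty tables, exit 0; empty
  FDR input → empty curve; no predictions → recovery FDR undefined
  (None), never 0.
* Deterministic tie-breaks everywhere: cluster representative → larger
  coordinate; merge fallback → (support, position); nearest transcript
  → (distance, start, id); conflicting equidistant labels →
  undetermined.
* All generator randomness flows from one `numpy` `default_rng(seed)`;
  identical config + seed reproduce outputs byte-for-byte.

## Known limitations

* Support queries scan validating PASs per chromosome linearly — fine
  for annotation-scale inputs (≤ 10⁵ transcripts), not tuned beyond.
* The 25-nt constants (merge, splice exclusion, PAS tolerance) are
  conventions inherited from EST-era practice, exposed as flags but not
  re-estimated from data.
* bigWig, BAM and PSL are not parsed; inputs arrive as text formats.
* The FDR is an empirical point estimate; no confidence intervals.
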