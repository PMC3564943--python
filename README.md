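# pas-scout

Discovery of unannotated 3′ gene ends (cleavage/polyadenylation sites,
PASs) from comparative genomics and transcriptome evidence.

Reference gene catalogues still miss many genuine 3′UTRs, including
multi-kilobase brain-specific extensions; any read-counting analysis
that trusts the annotation then misassigns or discards the signal that
maps past the recorded gene end. `pas-scout` is a small library + CLI
for annotators and RNA-seq analysts that combines four orthogonal lines
of evidence to propose and vet unannotated PASs:

1. **EST-end clustering.** Both genomic termini of every EST alignment
   are clustered by single linkage at ≤ 1 nt; clusters with ≥ 4
   supporting ends that avoid annotated exons and EST splice sites are
   *potential mature transcript extremes* (PTEs), classified as
   putative PAS or TSS by the orientation of the nearest gene (≤ 1 Mb).
2. **Conservation Drop Index.** Selection maintains the transcribed
   3′UTR but not the sequence beyond it, so per-base conservation
   (PhyloP-style tracks) collapses just downstream of a real PAS. With
   T the 50-nt window inside the mature transcript ending at the
   candidate and NT the 50-nt window starting 50 nt outside (the gap
   skips the downstream sequence element),

   ```
   CDI = mean(T) − mean(NT)
   ```

3. **Coverage Difference.** An orthologous transcript that shares a
   gene's last intron but ends farther downstream proposes a 3′UTR
   extension; RNA-seq coverage arbitrates. With Up the interval from
   the annotated to the proposed PAS and Down the equal-length interval
   immediately beyond, and a base "covered" iff depth ≥ 1,

   ```
   CD = %covered(Up) − %covered(Down)      ∈ [−100, 100]
   ```

   CD = 100 means a fully transcribed extension with a silent flank;
   CD = 0 means no transcriptional change at the proposed end.
4. **Empirical FDR.** A putative PAS is *supported* when an independent
   database holds a transcript ending at the same position (± 25 nt)
   whose last intron matches an intron of the examined database.
   Sweeping every observed CDI/CD as a cutoff yields an FDR curve,
   FDR(c) = unsupported fraction among candidates scoring ≥ c.

A deterministic synthetic-scenario generator
(`pas_scout.synthetic`) emits complete, truth-labelled inputs in the
standard formats (GTF, BED12, fixedStep WIG, bedGraph), so the whole
pipeline is testable without downloads.

## Worked example

Generate a synthetic genome (a ~400 kb scale-model chromosome with 30
genes, 20 of which carry an unannotated distal PAS) and run the full
pipeline:

```
pas-scout simulate --seed 11 --out sim
pas-scout run-all --ests sim/ests.bed12 --reference sim/ref.gtf \
    --ortho sim/ortho.bed12 --conservation sim/cons.wig \
    --coverage sim/cov.bedgraph --out out
```

`out/manifest.json` then reports (numbers from this exact invocation):
893 EST alignments → 1786 extremes → 1127 raw clusters → 74 PTEs after
the support/exon/splice-site filters and 25-nt merge, classified into
45 putative PASs and 29 putative TSSs. `out/cd.tsv` holds 21 extension
candidates sorted by CD; the top row,

```
g000.t1  ortho_g000  chrSim  +  9307  10630  1323  90.78  1.51  89.27
```

reads: gene `g000.t1` (annotated PAS at base 9307) is extended 1323 nt
to a proposed PAS at 10630; 90.8 % of the extension is covered by reads
versus 1.5 % of the downstream flank, CD ≈ 89.3 — transcription really
stops at the proposed end. `out/fdr_cdi.tsv` is the CDI-ranked FDR
curve; its top-ranked cutoffs (CDI ≈ 2.2) have FDR 0.0, and the FDR
rises towards the overall unsupported fraction at the most permissive
cutoff, reproducing the characteristic "higher score, lower FDR" shape.

Each stage is also exposed separately (`pas-scout pte`, `cdi`,
`extend`, `fdr`) and as library functions with the same semantics.

## Notes

Depth input is consumed as bedGraph; convert BAM with e.g.
`bedtools genomecov -bga`. bigWig/PSL/BAM parsing is out of scope.
See `docs/methods.md` for the model, parameter defaults and
limitations.
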