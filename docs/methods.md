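# Methods

`lncsieve` implements a comparative-genomics pipeline for nominating
putatively functional long non-coding RNAs (lncRNAs) from full-length
transcript sets, and a synthetic-data forge that makes every stage testable
against planted ground truth. This note documents the models, the defaults
and why they were chosen, the numerical conventions, and the limits of what
the synthetic experiments demonstrate.

## The discovery model

A transcript qualifies as an lncRNA candidate when it

1. maps to its home genome at >= 99% identity and >= 99% coverage,
2. is at least 200 nt long (the conventional operational lower bound for
   "long" non-coding RNA), and
3. is not exhausted by known protein-coding annotation: its exonic footprint
   must not lie entirely within CDS exons, nor within CDS plus UTR exons
   while actually overlapping CDS. UTR-only, intron-only, intergenic and
   mixed (annotation-straddling) transcripts all pass.

Candidates are then classified by genomic origin relative to the gene with
the largest footprint overlap (`utr_only`, `intron_only`, `mixed`), or by
proximity when there is no overlap (`near_gene` within 1000 nt, else
`intergenic`). Ties between genes go to the larger overlap, then the
lexicographically smaller gene id, so classification is a deterministic
total function. Antisense-UTR configurations — a candidate running opposite
to a gene, overlapping only its UTRs, with no CDS exon of any gene on either
strand — are reported separately because they suggest post-transcriptional
regulation of the host mRNA by complementary hybridization.

### Spliced mapping

The mapper is a seed-and-chain spliced aligner for clean full-length cDNA:
exact 15-mers are indexed per chromosome, merged into gapless anchors along
diagonals, chained collinearly by dynamic programming, and refined into exon
blocks; a genomic gap >= 20 nt beyond the query gap opens an intron, and the
splice point within the ambiguous region is chosen to maximize matches.
Identity is matches over aligned transcript bases; coverage is aligned bases
over transcript length. Both 99% thresholds are configurable.

The toy genomes carry no splice-site motifs, so exon boundaries can be
ambiguous by a few nucleotides when flanking bases repeat. The lncRNA gate
therefore tolerates `gate_slop_nt` (default 5) nucleotides of footprint
outside the annotation before a containment test fails; without this, a
perfectly mapped mRNA control whose boundary wobbles by 2 nt would leak
through the gate.

### Internal priming

Oligo-dT priming at genomic A-rich tracts produces spurious 3' ends. The
published screens examine a 50-bp genomic window downstream of the mapped 3'
end but do not define "poly(A)-rich"; we adopt a dual criterion common in
the cDNA artifact literature: A-fraction >= 0.65 over the window, or a run
of >= 8 consecutive A (reverse-complement logic on the minus strand; a
window truncated by the chromosome end is evaluated as-is). Both thresholds
are configurable. On random 50% GC windows the false-flag rate is measured
at ~0.1-0.3%, comfortably below 1%.

## Orthology and selection signals

Candidate intervals are projected into partner genomes through a pairwise
synteny map: endpoints are linearly interpolated inside the covering block
(largest overlap wins), mirrored for inverted blocks, padded by 5000 nt and
clipped. The candidate sequence is then locally aligned against both strands
of the window.

The local aligner is Smith-Waterman with affine gaps (match +1, mismatch -2,
gap open -5, gap extend -2; a gap of length k costs open + k*extend).
Significance is the Karlin-Altschul expectation E = K*m*n*exp(-lambda*S),
with lambda solved from sum p_s exp(lambda*s) = 1 and K evaluated through
the lattice convolution series

    K = exp(-2*Sigma) * lambda*delta / ((1 - exp(-lambda*delta)) * H),

delta being the gcd of the score support and H the relative entropy. For the
default scheme at uniform base frequencies this reproduces the published
ungapped BLASTN constants (lambda = 1.333, K = 0.621); the protein scheme
(BLOSUM62 at Robinson background frequencies) reproduces lambda = 0.3176,
K = 0.134. Applying ungapped constants to gapped scores is the standard
approximation; a permutation-based empirical p-value is available as a
validation hook. Two significance thresholds are first-class: e < 1e-6
("significant sequence homology" for summary tallies) and e < 0.01
(ortholog deduction for the evolutionary analyses). Preservation across
species is reported as a fixed-order code over {H, M, D, C}, home species
always included.

### Flanking-conservation contrast

For each deduced ortholog pair, buffer regions immediately up- and
downstream of the candidate, each of the candidate's own length, are
projected and searched the same way; a buffer is "conserved" when its best
hit reaches e < 0.01. The reported contrast is the global-alignment identity
of the lncRNA pair versus the mean global identity of conserved buffers
("not conserved" when neither aligns). Global alignment is Needleman-Wunsch
(match +1, mismatch -2, linear gap -2) and identity counts matches over all
alignment columns including gap columns — stated explicitly because
published tables rarely define the denominator. Note the e < 0.01 threshold
admits roughly 1-2% chance buffer hits by construction; such hits carry very
low global identity and do not disturb the contrast ordering.

### Coding potential (six-frame ORFs + NG86)

Each conserved candidate and its deduced ortholog are conceptually
translated in all six frames; the longest ATG-initiated, stop-terminated ORF
per frame is kept (a stop-free-stretch alternative is available). ORF pairs
with >= 10 aa on both sides are gated by protein-level local alignment
(BLOSUM62, affine gaps, e < 0.01); the highest-scoring gated pair is
back-translated over its gapless alignment columns into a codon pair and
scored with the Nei-Gojobori (1986) counting estimator: per-codon synonymous
site fractions averaged over both sequences (changes to stop codons count as
nonsynonymous, so S + N = 3 per codon exactly), multi-position codon
differences averaged over all mutational pathways excluding those through
stop codons, and Jukes-Cantor correction d = -(3/4)ln(1 - 4p/3). Ks = 0
yields an undefined ratio (a flag, never infinity); p >= 3/4 yields a
saturation flag. The implementation agrees with an independent NG86
implementation (Biopython's `cal_dn_ds`) to 6 decimals on forged pairs.

Ratios are banded as purifying < 0.5 <= neutral <= 1.5 < diversifying. The
counting estimator suffices for band-level claims; codon-model maximum
likelihood is out of scope. Note that NG86 under a transition-biased neutral
substitution process is known to skew below 1; the forge's codon-aware
generator controls synonymous/nonsynonymous counts directly, so recovery is
assessed against the realized, not nominal, ratio.

## Structure screen

A self-contained analogue of probability-based screens such as RNAz, built
from two defined ingredients:

* **Stability z-score.** The fold score is maximum-weight nested base
  pairing (AU/GU/GC weights 2/1/3, minimum hairpin loop 3) with isolated
  pairs disallowed — every helix is >= 2 stacked pairs. The no-lonely-pair
  rule matters: unrestricted base-pair maximization scores random sequences
  nearly as high as perfect hairpins (a random 78-mer reaches ~63 of a
  hairpin's 90), destroying discrimination; requiring stacks restores it.
  The score is normalized against dinucleotide-preserving shuffles
  (Altschul-Erickson Euler-path method; all 16 dinucleotide counts preserved
  exactly) as z = (observed - mean)/sd. Degenerate shuffle distributions
  (e.g. homopolymers) report z = 0 with a flag.
* **Structural conservation index (SCI).** The consensus fold is computed on
  the global alignment of the ortholog pair: a column pair may close only if
  the bases of both sequences can pair (gap columns never pair), with weight
  equal to the mean of the two individual pair weights, so compensatory
  double substitutions (G:C -> A:T) retain their support. SCI is the
  consensus score over the mean of the individual fold scores: 1 for
  identical sequences, near 1 for compensatory pairs, typically < 0.5 for a
  scrambled partner (seed-dependent; always observed below the
  classification threshold).

A candidate is "structured" when z >= 2 and SCI >= 0.7 (both configurable;
chosen to separate forged positives from forged negatives cleanly). This is
an analogue of, not a reimplementation of, the SVM-based "RNA class
probability > 0.5" classification; no thermodynamic nearest-neighbor model
and no pseudoknots.

## Cancer-gene enrichment

Hosts are the distinct genes that lncRNA candidates overlap or sit beside;
the 2x2 table counts cancer-annotated hosts (k of n) against
cancer-annotated genes genome-wide (K of N). Two statistics are reported:

* Pearson chi-square with Yates continuity correction on the disjoint table
  [(k, n-k), (K-k, (N-n)-(K-k))], df = 1, two-sided; the uncorrected
  statistic is also reported. On the study table (10, 57, 2147, 23621) the
  corrected test gives p = 0.0463 and the uncorrected p = 0.0262; the
  published value (0.047) corresponds to the corrected convention, which is
  therefore the default.
* The exact hypergeometric probability. The published 0.018 matches the
  point mass P(X = k) = 0.0188 (the upper tail P(X >= k) = 0.0314 does
  not), so the point mass is the reported "hypergeometric probability"; the
  proper one-sided tail is computed alongside and used for the power
  calibration, since it is the statistically meaningful enrichment test.

## The synthetic-data forge

The forge builds a home genome ("M", the reference species whose transcripts
are mined) and one or more partner genomes derived from it by controlled
mutation. Defaults define the study conditions: 2 chromosomes x 100 kb at
42% GC, 20 protein-coding genes (3 exons: 5'UTR exon, CDS exon, CDS+3'UTR
exon; 135 codons; introns 650/400 nt; 3'UTR 450 nt, long enough to host
UTR-only plants), and 15 planted lncRNAs — 3 UTR-only, 3 intron-only,
2 mixed (3'UTR straddling the gene end), 2 near-gene (150-700 nt from a
gene), 3 intergenic, 1 spliced intergenic (two exons), 1 antisense UTR
plant — sized 280-340 nt. Half the genes also emit their mRNA as a gate
control. Every feature draws from its own RNG stream (seeded from the forge
seed plus the feature id), so adding features does not perturb earlier ones
and a fixed seed yields byte-identical datasets.

Partner genomes apply, per region: codon-aware CDS mutation toward a target
Ka/Ks (at most one substitution per codon, so realized counts match endpoint
pathway accounting; targets 0.1/0.2/0.3 cycled across genes at synonymous
divergence Ks ~ 0.25); neutral substitution of UTRs/introns at 12%;
candidate lncRNA intervals at 8-20% (identity targets drawn from
0.80-0.92); 45% divergence in filler; fresh random sequence for
non-conserved lncRNA orthologs (75% of plants are conserved) and for
"not conserved" flank labels; and small indels (rate 5e-4) in filler only,
so all feature coordinates in the partner are tracked exactly. Substitutions
carry a 2:1 transition bias. The synteny map is one whole-chromosome block
per chromosome; the 5-kb projection pad absorbs the small indel drift.
Flank-conservation labels are controlled only for intergenic plants, whose
buffers lie wholly in filler; gene-hosted plants inherit their gene-context
conservation, which is biologically sensible but means their flanks can be
as conserved as the lncRNA.

Several ground-truth labels are guarantees rather than expectations: the
50-nt window downstream of every non-decoy plant is resampled until the
priming filter is negative (and decoy windows are built positive); forged
structured pairs resample their stem until the stability z-score clears 3.5;
forged unstructured pairs reject draws with z > 0.8 (random 100-mers
occasionally contain genuine hairpins); and codon pairs planted as "neutral"
can be drawn with their realized Ka/Ks certified inside [0.65, 1.35], since
a finite 300-codon pair realizes a ratio scattered around the nominal target
with spread ~0.2. Without these guarantees the labels are wrong for a few
percent of seeds, which would make planted-recovery claims luck-dependent.

Cancer labels are drawn at 50% for lncRNA-host genes versus 10% background.
At the default 20 genes this yields an illustrative table only; the
enrichment power calibration uses 200-gene label sets, where the tail test
detects the planted enrichment in >= 95% of seeds.

### What the forge does and does not emulate

It emulates the structural relationships the pipeline's logic depends on:
orthologous gene architecture, origin classes with exact coordinates,
controlled sequence divergence, priming decoys, coding orthologs with known
selection pressure, and conserved/non-conserved flanks. It does not emulate
mammalian repeat content, splice-site motifs, transcription noise, GC
isochores, or realistic intergenic conservation landscapes. Passing the
planted-recovery suite therefore demonstrates that the pipeline's decisions
are correct with respect to its stated rules — not that those rules would
achieve any particular precision on real cDNA corpora, where mapping
ambiguity, paralogy and annotation error dominate.

## Numerical and reporting conventions

* Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
  BED12 are converted at the I/O boundary only.
* N bases are allowed in genomes and score as mismatches everywhere.
* Deterministic tie-breaks throughout: best mapping by match count then
  first in chromosome/strand order; best local hit by score, then identity,
  then smaller target start; ORF ties by smaller start offset; fold
  traceback prefers pairing, then the smaller index.
* All pipeline randomness (shuffle z-scores) is seeded per candidate id from
  the run seed; no output carries timestamps, so rerunning a dataset with
  the same seed reproduces the report bundle byte for byte.
* Problem sizes used by the test suite and the acceptance script — 100 kb
  toy chromosomes, 300-codon Ka/Ks pairs over 20 seeds, 100-replicate nulls,
  60-100 shuffles per z-score — keep a full run in the minutes range on one
  CPU while leaving the statistical margins (e.g. NG86 recovery error
  <= 0.07 against a +-0.15 band) wide.

## Known limitations

* The aligner stand-ins are contract-level replacements for BLAST/GMAP, not
  performance-equivalent tools; the mapper assumes clean, indel-free
  transcripts and the k-mer index is held in memory.
* Karlin-Altschul constants from the ungapped scheme are applied to gapped
  scores (standard but approximate; e-values near a threshold should not be
  over-interpreted).
* For spliced candidates the deduced ortholog is the best local hit, which
  typically covers one exon; the reported pair identity then understates
  conservation of the full transcript.
* The structure screen's fold model is a weighted stacked-pairing score, not
  free energy; its thresholds are calibrated on forged data only.
* The hypergeometric point mass matches the published convention but is not
  itself a tail test; use the reported P(X >= k) for inference.
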