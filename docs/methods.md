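# Methods

## Coordinates and cut arithmetic

All internal coordinates are 0-based half-open; user-facing TSV reports
are 1-based inclusive. A cut position is an **inter-base** coordinate:
the SpCas9 blunt cut falls between plus-strand positions `cut-1` and
`cut`, located 3 nt 5′ of the PAM on the protospacer strand (so
`cut = pam_start − 3` on `+`, `pam_end + 3` on `−`). With both cuts
inter-base, the predicted deletion Δ = `cut_down − cut_up` equals
exactly the number of base pairs removed by perfect rejoining,
independent of the strands the two guides sit on.

## Guide discovery

Both strands of a region are scanned for `N{L}‑NGG`; the default
L = 19 reflects a cloning scheme requiring 19-mers (L ∈ [17, 25] by
flag). Spacers are not required to start with G — the expression
cassette supplies the transcription-start G — though a flag can enforce
it. Windows containing `N` are discarded: an ambiguous base can be
neither confidently matched nor cloned. GC content is computed over the
spacer only; the selection window (40–70%, inclusive) matches common
activity heuristics.

## On-target scoring

Scorers are pluggable callables `(context, pam_index, spacer_len) → [0,1]`.
The default is a **logistic position-weight model**: each (offset, base)
pair relative to the PAM contributes an additive log-odds weight from a
packaged TSV table, passed through `1/(1+e^{−s})`. The table encodes
standard qualitative preferences (G favored immediately PAM-proximal, T
disfavored in the proximal region, C favored at the PAM variable base);
it is an own-design default, not a reimplementation of any one published
weight set, and can be swapped without touching selection logic. A
constant-0.5 `null` scorer exists for tests and score-free selection.

The pair score is the **sum** of the two individual scores. With the
default thresholds (individual ≥ 0.2, pair ≥ 0.4) the sum rule is the
only combination under which the two thresholds coincide at the
boundary, which is why it is the declared default. Comparisons are
inclusive.

## Off-target search

The search is a vectorized sliding-window byte comparison over each
contig and its reverse complement. For mismatch-only search every
window of spacer length followed by NGG is kept when its Hamming
distance to the spacer is ≤ k (k ≤ 4; beyond 4 the counts are not
biologically meaningful for SpCas9 and the call is rejected). `N` never
matches any spacer base, so a window is silently skipped once its N
count exceeds the budget — conservative in gappy assemblies.

Bulge search additionally tries every internal single-gap placement: an
extra genome base (DNA bulge, site length L+1) or a skipped genome base
(RNA bulge, L−1), with ≤ 3 substitutions. One interpretation is kept
per PAM position, preferring no bulge over a bulge, then fewer
substitutions, then DNA before RNA, then the leftmost gap. Sites
already reachable mismatch-only at the same substitution budget are not
re-reported by the bulge search. Correctness of both searches is
*defined* by independent brute-force oracles in the test suite
(`tests/oracles.py`), which re-scan every window and gap placement in
pure python; the package scanners are asserted set-equal to them across
seeded genomes.

The selection policy caps per-level counts (defaults 0/0/0/3/30 at
0–4 mismatches, inclusive), with the on-target occurrence excluded from
counts but retained in the hit list, flagged, with its coordinates. The
level-4 cap is applied per guide. Hits are classed exonic / intronic /
intergenic by interval query: exon membership wins; inside a gene but
outside every exon is intronic (introns are derived, never required in
the GFF3); all else intergenic.

## Pair design

Candidate guides are gathered whose cuts fall within the flank search
width of the deletion-window edges — cuts may sit inside the window near
its edges, since in practice selected guides lie within the gene body.
Filtering order is GC → score → off-target policy, with per-stage
elimination counts reported, so a failed design attributes every loss to
a stage. Ranking is a total order: pair score (desc), total off-target
count (asc), number of C PAM-variable bases (desc — a "preferred"
ranking bonus, never a hard filter), Δ (desc), leftmost coordinates.
The default flank width of 1 kb is an arbitrary, configurable choice.

## Amplicon interpretation

Clones arrive as exact assembled Sanger sequences; there is no
sequencing-error or chromatogram model (a deliberate non-goal), so edit
calling uses an exact maximal prefix/suffix decomposition rather than a
scoring aligner: the reference/amplicon difference reduces to one
replacement event (deleted reference segment, inserted amplicon
segment). Pure indels are then **left-normalized** (VCF convention) and
the microhomology span — how far the event can slide right and stay
equivalent — is reported, since deletions through repeats have many
equivalent placements and a convention is required for exact
comparisons. Orientation is auto-corrected by comparing shared-flank
lengths of the amplicon and its reverse complement; an amplicon sharing
< 15 nt with either flank is rejected as foreign.

Classification: a gap ≥ 50 bp whose (slid) placement covers both cut
sites is a large deletion, with any junction insertion < 50 bp reported
verbatim; a smaller event touching exactly one cut site is an indel at
that guide; anything else — including long "insertions" that actually
reflect two separate events — is complex. In-silico PCR uses exact
matching over the 3′-terminal 12 nt of a primer with ≤ 1 mismatch in
the 5′ remainder, a deterministic stand-in for wet PCR specificity;
nested PCR amplifies inner products from outer products only.

Zygosity per plant combines clone calls with the amplicon band pattern:
only wild-type evidence → non-edited; no wild-type evidence and ≤ 2
distinct edited alleles → homozygous/biallelic (aa); both bands with
exactly one edited allele and an edited-clone fraction within a
configurable window (default 0.2–0.8) → heterozygous/monoallelic (Aa);
more than two distinct alleles, an out-of-window fraction, or
band/clone contradictions → chimeric (chi). The fraction window is a
declared operational convention — wet-lab practice does not pin down a
chimera rule — and is the single most assumption-laden parameter in the
genotyping stage. Transgene status is a marker PCR producing the
expected product length ± 20 bp (tolerance configurable).

## Summary arithmetic

Editing rate = 100 × edited/regenerated; class frequencies use the
pooled total of edited lines as denominator; phenotype reduction =
100 × (WT − line)/WT, signed (negative = worse than wild type). All are
rounded **half-up** to one decimal — verified against every printed
cell of the source editing table. The infected-leaf-area reduction
column of the source greenhouse table is *not* reproducible from its
printed means (two lines printing the same area mean show different
reductions, so the original authors computed on unrounded means and
rounded afterwards); this module therefore computes reductions from
user-supplied raw means and makes no claim about that table's printed
cells. Statistical testing (ANOVA, LSD) is out of scope; the report
carries a free-text significance column.

## Synthetic fixtures

`simulate_genome` draws uniform-ACGT background (GC skew configurable,
since off-target incidence depends on composition), stamps protospacer
+PAM sites and off-target sites realizing exactly the requested
mismatch positions and bulges, then sweeps each planted spacer
exhaustively (substitutions ≤ 4, bulge ≤ 3 substitutions) and resamples
the background on any accidental near-match, up to 100 attempts.
Off-target PAM variable bases are drawn from {A, C, T}: a GGG PAM would
open a second, shifted NGG frame and blur planted-site bookkeeping.
Regeneration from one seed is byte-identical.

`simulate_edited_amplicons` removes exactly the inter-cut segment for
deletion scenarios; junction insertions are random bases constrained so
their ends cannot realign to the flanking sequence, keeping truth
breakpoints exact under the left-alignment convention; indel scenarios
modify a single cut site. What the generator does *not* emulate —
sequencing noise, chimeric reads, PCR recombination artifacts, real
genome repeat structure and base composition — bounds what green tests
mean: they demonstrate algorithmic correctness on clean inputs, not
robustness to noisy chromatograms or to repeat-rich genomes.

## Problem sizes

The default test and verification runs use toy genomes of 2–6 kb
(20 seeded replicates for the oracle-equivalence checks), 3 kb
references with ~80 simulated clones for round-trip recovery, and
synthetic loci of ~2 kb for the published pair arithmetic. These sizes
were chosen so the brute-force oracles — quadratic-ish pure python —
remain the binding constraint, while the vectorized scanners handle
megabase inputs comfortably.

## Known limitations

- Off-target search is exhaustive scanning; for repeated whole-genome
  screens a seeded index would be preferable, though results are
  defined to be identical.
- Primer matching and PCR product prediction ignore melting
  temperature, secondary structure and competitive amplification.
- The default activity scorer is a coarse position-weight model; for
  ranking-critical applications register a trained scorer.
- Genotype classification assumes clone counts approximate allele
  ratios; heavily biased cloning will push true heterozygotes into the
  chimeric class.
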