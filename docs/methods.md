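# Methods

`srnakit` implements the classic two-library plant small-RNA-seq analysis:
read cleaning and tag collapsing, genome annotation, known-miRNA matching,
novel hairpin-miRNA discovery, TPM normalisation with an exact count test
and a five-way regulation classification, plant target-site scoring, and
stem-loop qPCR concordance. A synthetic-data generator with full ground
truth makes every stage testable end to end. This note records the models,
the defaults and the design decisions that were genuinely open.

## Read cleaning

An sRNA insert (15–30 nt) is shorter than the sequencing read, so every
genuine read contains a prefix of the 3' adapter
(`TGGAATTCTCGGGTGCCAAGG`). The adapter is located by seed-and-extend: the
first 8 adapter bases are scanned left to right allowing 1 mismatch, and
the match is extended over the remaining read allowing at most 2
mismatches over the matched adapter prefix. The leftmost position
satisfying both bounds wins. Reads with no detectable adapter are
discarded as artifacts; this choice is auditable through the rejection
tally (accepted / no_adapter / too_short / too_long / polyA / has_N).
Inserts are kept when 15–30 nt (both bounds configurable; a 14-nt lower
bound is a supported variant), not poly(A) (≥80% A) and free of N. U is
normalised to T at every ingest boundary; all internal comparisons are in
the DNA alphabet. Collapsing produces one tag per distinct insert with
per-library counts; accepted + rejected always equals the input count.

## Mapping and annotation

Tags are aligned to the genome with a substitution-only model (no indels;
tags are 15–30 nt) on both strands, `max_mismatch` ∈ {0, 1, 2}. Exact
matching uses a seed table; mismatch search uses the pigeonhole principle
over three tag pieces, so it is exhaustive for ≤2 substitutions, and it is
tested against a vectorised sliding-window oracle. The pipeline default is
0 mismatches: with the generator's low error rate, erroneous tags are rare
singletons and mapping them would only relabel noise.

Each tag receives exactly one category by a fixed precedence cascade —

    known miRNA > rRNA > tRNA > snRNA > snoRNA > repeat
    > exon > intron > un-annotated

with exon/intron split sense/antisense by strand agreement. Ties within a
tier break by longest feature overlap, then lexicographic feature ID.
Multimapping tags are classified once from their fewest-mismatch
alignment and their counts are not split, so category totals partition
each library exactly. The precedence order itself is a documented
convention (mutually exclusive accounting requires *some* order); the
repeat-before-exon choice follows the usual ncRNA-first screening
practice.

## Known-miRNA matching and expression counting

A tag is assigned to a known mature miRNA when lengths differ by ≤2 nt and
the 5'-anchored comparison over the overlap has ≤2 substitutions; the
fewest-mismatch mature wins, ties by name order. The implementation is
vectorised and checked against a plain Hamming-scan oracle.

Expression of a mature (known or novel) uses an end-tolerant rule: a tag
contributes only if it covers and exactly matches the mature core
(positions 4..L−3, 1-based) and accumulates at most 3
mismatching/overhanging nucleotides over the two terminal 3-nt windows
combined. The 3-nt budget is read as a *combined* budget over both ends
(the stricter of the two readings of "three mismatches on the end of 5'
and 3'"); a per-end budget would be a one-line change. Uncovered terminal
positions (end-trimmed isomiRs) do not consume budget. Each tag
contributes to at most one mature.

## Folding

The reference backend is a deterministic maximum-weight base-pairing
dynamic program with a fixed energy table — G:C −3, A:U −2, G:U −1
kcal/mol — plus a helix-stacking bonus of −1 kcal/mol for each pair
stacked directly on another, minimum hairpin loop 3 nt, no penalty for
unpaired bases. The stacking term matters: it is the dominant stabilising
contribution in real RNA thermodynamics, and without it a designed stem
ties with the same number of scattered pairs, making the traceback
ambiguous. Traceback is pair-first and deterministic. A thermodynamic
backend (ViennaRNA, when importable) is available behind the same
`FoldResult` contract; all tests and the acceptance script use only the
built-in backend so results are reproducible with no external software.

## Novel-miRNA discovery

Un-annotated aligned tags are clustered per chromosome and strand with a
maximum inter-tag gap of 10 nt. Within a cluster the most abundant tag
anchors a candidate mature; its supporting reads are the read mound within
±3 nt of its ends. Clusters are peeled iteratively (up to 8 mounds) so
that independent loci bridged into one cluster by scattered background
reads are still found separately. Candidate precursor windows around the
anchor are drawn at three flank sizes (25, 75, 300 nt; symmetric plus two
asymmetric windows each, the asymmetric ones padded 10 nt so the anchor
never sits on the window terminus), deduplicated, and trimmed to ≤360 nt
around the mature before folding. The 300-nt flank and 10-nt gap follow
common discovery-tool defaults; no published value pins them.

Six criteria qualify a candidate, all thresholds config-exposed:

1. un-annotated genomic origin;
2. the mature lies wholly on one arm of the window's predicted structure —
   evaluated over the mature's duplex-forming span (its own 2-nt 3'
   overhang is unpaired in the duplex and free to pair elsewhere, so it is
   excluded), requiring paired positions, no mature-internal pairs and all
   partners on one side;
3. the mature/miRNA* duplex shows 2-nt 3' overhangs — the star interval is
   derived from a direct duplex search (below) and must fit inside the
   window;
4. duplex quality: ≤4 unpaired mature positions and no asymmetric bulge
   >2 nt ("no large internal loops or bulges" quantified per the standard
   plant-miRNA annotation criteria);
5. fold free energy ≤ −18 kcal/mol, applied to the whole folded window
   (whether the published threshold applied to the precursor or the duplex
   is ambiguous; the whole-window reading is used);
6. ≥5 supporting reads. Support is checked before any folding, so
   unsupported piles cost nothing.

Criteria 3–4 come from a direct antiparallel duplex search of the mature
against the window (ungapped first, then a single internal bulge ≤2 nt),
rather than from the fold traceback: co-optimal structures make traceback
pairing registration unstable, while the duplex search asks the actual
Dicer-geometry question. Criterion 2 stays fold-based because it is what
separates genuine stem-loops from windows that merely contain a chance
near-complement. The fold arm and duplex arm must agree.

On the synthetic study conditions this combination recovers 100% of
planted hairpins and passes <5% of dinucleotide-shuffled windows across
many seeds. Discovery precision on background read piles is intentionally
not tuned: loci qualifying by chance are reported as candidates, mirroring
how such catalogues behave on real data.

## Differential expression

TPM = count / total clean reads × 10⁶. Exactly-zero expressions are
replaced by 0.01 *after* normalisation, affecting only log2FC and display.
The exact test conditions on the count x in the control library: the
probability of y counts in the treatment library is

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which equals the negative-binomial pmf NB(y; x+1, N1/(N1+N2)) and is
evaluated in log space via log-gamma (verified against exact rational
arithmetic to 12 significant digits for x+y ≤ 100, and against
`scipy.stats.nbinom` as an independent oracle). The default p-value is the
doubled smaller tail min(1, 2·min(P[Y≤y], P[Y≥y])); one-sided alternatives
are available because the published description does not disambiguate.
The upper tail is summed directly in log space when the 1−CDF complement
would cancel. Note the point mass satisfies
p(y|x; N1,N2) = (N1/N2)·p(x|y; N2,N1): it is exactly symmetric only for
equal library totals, so classification under library swap is symmetric up
to direction labels except at p-values straddling α.

Classification: *significant* requires |log2FC| ≥ 1 AND p < 0.05;
*slight* requires 0.25 ≤ |log2FC| < 1 with no p condition; everything else
is *unobvious*. miRNAs below 2 TPM in both libraries are removed first
(retained iff max TPM ≥ 2, boundary inclusive). p-values are always
computed from raw counts, never substituted TPMs. No multiple-testing
correction is applied in the primary analysis (single library per
condition); a Benjamini–Hochberg column is optional.

## Target prediction

Ungapped penalty scoring over every transcript window of miRNA length,
miRNA position i (5'→3') pairing transcript position site_end−1−i:
mismatch 1.0, G:U wobble 0.5, penalties doubled at miRNA positions 2–13,
hits kept at score ≤4.0. All constants are config-exposed: they are the
conventional plant-miRNA scoring values, adopted because the source
methodology names the convention without restating numbers. Gapped sites
are out of scope by default so the exhaustive-enumeration oracle stays
exact. Transcript hits collapse to distinct genes via a user-supplied
transcript→gene map; unmapped transcripts count as their own gene with a
warning.

## qPCR concordance

ΔCt = Ct_miRNA − Ct_U6 per condition, replicates averaged on the Ct scale
before differencing (convention; the source is silent). ΔΔCt = ΔCt_treat −
ΔCt_control, qPCR direction = sign(−ΔΔCt). Concordance is the percentage
of miRNAs whose qPCR direction matches the sign of the RNA-seq log2FC;
zero directions and unpaired miRNAs are excluded from the denominator.

## Synthetic data

The generator emulates the *structure* of a plant sRNA-seq experiment, not
its full biology. A single-contig random genome (default 120 kb) carries
non-overlapping planted features (rRNA/tRNA/snRNA/snoRNA/repeat and
exon–intron gene blocks), 25 known + 20 novel miRNA hairpins, and 10 decoy
loci (dinucleotide-shuffled precursors, Altschul–Erikson style). Designed
precursors are mature + loop + star (arm chosen per locus): the star is
the reverse complement of all but the last two mature bases plus a 2-nt
extension, giving exact 2-nt 3' overhangs; loops are ≥4 nt of non-pairing
bases. Matures whose designed precursor does not fold with the mature on
one arm (strongly self-complementary sequences) are redrawn, so every
planted locus is a genuine hairpin by construction.

Reads are insert + 3' adapter + random fill at 50 nt, constant Q40
quality (no published quality model). Insert lengths mix 21-nt (22%) and
24-nt (45%) modes with the rest uniform over 15–30 nt, matching the
canonical bimodal sRNA length profile; matures start with U with
probability 0.8 (5'-U bias). Per-locus counts are Poisson around expected
values (negative binomial optional; the exact test itself assumes Poisson
tag sampling). Per-base error rate 0.002. Category read budgets follow a
realistic composition (miRNA 11%, rRNA 7.5%, repeat 15.5%, un-annotated
48%, ...). The un-annotated budget is split between ~400 discrete
background loci and uniform singletons, so discovery faces both punctate
decoy piles and diffuse noise. Known/novel loci share the miRNA budget by
log-normal weights with a floor of 25 expected control reads per locus, so
every planted locus is sequencable at the default 2×10⁵ depth. Planted
log2FC effects cycle through the three regulation tiers with magnitudes
drawn inside each tier (strong ±[1.3, 2.3], slight ±[0.35, 0.85], null
±[0, 0.15]) — away from the 0.25/1.0 boundaries so tier membership stays
identifiable under count noise. Everything is driven by one seeded
generator; identical configurations give byte-identical output.

What passing tests therefore show: the pipeline's logic, calibration and
recovery behaviour under Poisson sampling with clean annotation and a
designed hairpin geometry. What they do not show: robustness to real
sequencing chemistry, RNA modification/degradation artifacts, genome
mis-annotation, multi-mapping repeat families at realistic scale, or
biological isomiR complexity beyond ±1-nt 3' shifts.

## Problem sizes

The default study conditions — 120 kb genome, 45 planted miRNA loci,
2×10⁵ reads per library — run the full pipeline in about a minute and are
the scale at which the recovery properties (≥90% novel-locus recovery,
≥80% strong-tier assignment, ≥95% shuffle rejection) are asserted. The
null calibration of the exact test uses 10⁴ Poisson replicates at rate
1000; its doubled-tail rejection fraction at α = 0.05 sits near 0.048
(slightly conservative, as expected for a discrete exact test).

## Known limitations

- The reference fold's energy scale is a weighted pairing count, not a
  nearest-neighbour thermodynamic model; the −18 kcal/mol threshold is
  interpreted on that scale. Long windows almost always clear it, so the
  energy criterion mostly rejects short or pairing-poor windows; the
  structural criteria carry the discrimination.
- Novel-candidate precision is modest by design (candidate lists, not
  confirmed annotations); ranking candidates by duplex mismatches or star
  read support would be the natural extension.
- Multimapping tags are counted once at their best alignment; count
  splitting is out of scope.
- The discovery stage assumes punctate read mounds; diffuse siRNA-like
  coverage merged into giant clusters is handled by iterative peeling with
  a fixed cap (8 mounds per cluster).
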