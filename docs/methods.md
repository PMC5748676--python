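# Methods

## The locus model

A tandem snoRNA cluster is represented relative to an anchor gene.
Internally every interval is 0-based half-open (BED convention); 1-based
coordinates appear only in rendered reports.  "Downstream" means the
anchor's direction of transcription; distances are measured edge-to-edge
from the anchor's 3′ end to the transcript's proximal edge.  The measurement
point only affects the distance values, not the ordering, which is all that
downstream stages consume.  On a minus-strand cluster every sequence is
reverse-complemented into sense orientation on input, making the whole
pipeline strand-agnostic: a mirrored locus produces byte-identical
sense-space results.  Transcripts upstream of the anchor are tolerated,
logged, and numbered after all downstream copies.

## Pairwise identity and alignment

Percent identity between two copies is computed over an optimal global
alignment under an affine gap model (default: match +1, mismatch −1, gap
open −4, gap extend −1; a gap of length L costs `open + L·extend`).
Columns inside terminal gap overhangs are excluded from the denominator so
that length differences between near-identical tandem copies are not
penalized; identity is symmetric and equals 1 exactly for identical
sequences.  The dynamic program breaks ties deterministically (diagonal,
then vertical, then horizontal during traceback), which makes every
downstream report bit-reproducible.  Scoring defaults are conventional for
near-identical nucleotide paralogs and are configurable; the test suite
checks the aligner against exhaustive enumeration on short pairs and against
an independent library implementation on longer ones.

The multiple aligner is progressive: pairwise distances (1 − fractional
column identity) feed a UPGMA guide tree with lexicographic tie-breaks, and
profiles are merged by a profile–profile extension of the same dynamic
program (column score = mean pairwise character score; an existing gap
scores `gap_extend` against a character and 0 against a gap).  Distances are
computed over lexicographically sorted identifiers, so the output is
invariant under input permutation.  Ungapping any output row recovers the
input sequence exactly.  Externally produced alignments (aligned FASTA or
Clustal) are first-class substitutes, since different aligners can shift
which sites end up ambiguity-coded; every report records which path produced
its alignment.

## Grouping

Thresholds are inclusive (≥) throughout, matching the convention of "95%
homology or more".  Three strategies:

* `anchor_seeded` — Group I = copies at ≥ `group1_identity` (default 0.95)
  to transcript number 1.  The residue is clustered greedily: repeatedly
  pick the template maximizing group size at `residual_identity` (default
  0.80, ties to the smallest transcript number), extract that group, stop
  when only singletons remain; those are `ungrouped`.  Extracted groups are
  labeled II, III, … by the genomic position of their first member.
* `largest_group` — identical, except Group I's template is itself chosen to
  maximize the 95% group (the convention used for clusters whose annotated
  numbering does not follow genomic order).
* `single_group` — all copies become Group I iff every pairwise identity is
  ≥ `group1_identity`; otherwise the error names the worst pair.

Greedy largest-first extraction is one deterministic formalization of
"clusters of high homology with tandem appearance"; on well-separated
simulated groups it recovers the planted partition exactly (see
Limitations for what "well-separated" must mean quantitatively).

## Consensus

Per alignment column with base frequencies f(b) over all rows (gaps count in
the denominator): columns with gap fraction > `column_drop_gap_fraction`
(0.50) are dropped; else a single base is emitted if max f(b) ≥
`consensus_threshold` (0.90); otherwise the IUPAC code of all bases with
f(b) ≥ `ambiguity_floor` (0.10), falling back to all observed bases when
none reaches the floor.  Columns with gap fraction ≥ `indel_threshold`
(0.10) are flagged in/del (flagged, not dropped, below 50%).  The 10% floor
(rather than "all observed bases") keeps a single variant copy in a 17–30
row alignment from inflating ambiguity codes, and parallels the 10% in/del
rule.  One consequence worth noting: when exactly one base reaches the floor
but not the threshold (e.g. A at 86.7% with two minor bases at 6.7%), the
rule emits that base, so an unambiguous symbol does not by itself certify a
≥ 90% column; the per-column frequency table is always emitted alongside.
Ambiguous input bases (N) count in the denominator but toward no base.

## Homology statistics

Strict homology of two consensus symbols means identical characters (W vs W
is strict); non-strict means intersecting IUPAC base sets, which generalizes
the one-directional "concrete base under an ambiguity code" reading
symmetrically, including ambiguous-vs-ambiguous sites.  A gap matches
nothing in either mode.  For pairwise comparison the two consensus strings
are globally aligned with non-strict compatibility scored as a match; every
reference nucleotide site is then classified (perfect / non-strict-only /
mismatch / gap) and tallied with the reference consensus length as
denominator — reference sites aligned to gaps count as non-homologous, and
query insertions add no sites.  In/del-flagged columns are counted like any
other reference site.  Cross-species conservation progressively aligns all
consensus strings and counts columns where every species is non-strictly
compatible with the reference symbol (non-strict) or all symbols are
identical and non-gap (strict).  Non-strict ≥ strict holds by construction.

## Box annotation

Default motifs are the canonical C/D-box definitions (C and C′: RTGATGA,
D and D′: CTGA) with positional windows — C in the 5′ third, D in the 3′
sixth, D′/C′ in the interior — and mismatch allowances of 2 (7-mers) and 1
(4-mers).  Detection takes the fewest-mismatch hit per window, leftmost on
ties; hits violating the C < D′ < C′ < D ordering are discarded as absent.
"Perfectly homologous" boxes are judged within the cluster: a copy counts
iff all four boxes equal the cluster's modal (most frequent, lexicographic
tie-break) box sequences, since the published tallies compare copies within
each species' cluster rather than against a literature consensus.  Both the
motif set and the windows are configurable.

## Synthetic loci

The generator plants a root ancestor (default 98 nt) with realized box
motifs at canonical positions (resampled if a perfect off-position motif
occurrence could out-compete a planted box under the leftmost rule), derives
one ancestor per group by substitution at `between_group_sub_rate` (default
0.15), and draws each copy star-wise from its group ancestor at
`within_group_sub_rate` (default 0.02).  Substitutions are uniform over the
three alternative bases (Jukes–Cantor-like); box sites mutate at
`box_mutation_rate` (default 0.01, chosen so that roughly 80% of copies keep
perfect boxes, the proportion seen in annotated clusters); indels initiate
at `indel_rate` (default 0.002) with geometric lengths and never enter box
spans, so the planted box truth stays contiguous.  Copies are laid tandem
with 800–2000 bp spacers downstream of a 200 bp anchor, giving a ~50 kb
cluster for 30 copies, the observed order of magnitude.  Presets:
human-like (groups 9/15/6, plus strand), mouse-like (17 copies,
within-group rate 0.002 — "nearly identical", so the single-group condition
holds with margin — minus strand), rabbit-like (two groups plus two planted
outliers at substitution rate 0.35, which sit below the 80% residual
threshold against everything).  Expected within-group pairwise identity is
≈ (1 − w)²; all artifacts are byte-reproducible from the seed.

What the generator does **not** emulate: serial duplication phylogenies
(within a group all copies are exchangeable), gene conversion, composition
bias, pseudogenized copies, assembly gaps, and host-gene exon structure.
Passing tests therefore certify the algorithms' behavior on cleanly
structured input, not performance on real annotation noise.

## Numerical and degenerate-input choices

Floating-point ties in the aligner are resolved with a 1e-9 tolerance and
the fixed move preference; guide-tree ties join the lexicographically
smallest cluster pair; consensus base ties take the alphabetically first
base (only reachable below the threshold).  Empty sequences, empty
alignments, ragged rows, duplicate identifiers, mixed strands, missing
anchors and orphan locus rows are rejected with messages naming the
offending records.  A single-sequence "alignment" is returned trivially with
a warning.

## Limitations

* Exact recovery of planted groups requires the realized pairwise
  identities to clear the thresholds, not just their expectations.  At the
  human-like default (within-group rate 2%, ~98 nt), expected within-group
  identity is 0.9604 with a standard deviation near 0.02, so individual
  pairs fall below the 0.95 Group-I threshold routinely and exact recovery
  of the full partition is the exception rather than the rule; the
  mouse-like preset (0.002) clears its threshold with margin.  The grouping
  is behaving as specified — the thresholds, not the algorithm, define
  membership at the boundary.
* Consensus lengths and ambiguity-site counts depend on the multiple
  alignment; substituting an external aligner can shift which sites are
  ambiguity-coded, which is why reports always name the alignment source.
* The homology statistic carries no significance model; counts are
  descriptive.
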