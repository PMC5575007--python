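# Methods

## The motif model

An ARN triplet is a 3-mer whose first position is adenine (A-site),
whose second is a purine (R-site), and whose third is unconstrained
(N-site). An abasic residue, written `0`, is accepted **only** at the
N-site: the N base points away from the protein surface, and the
abasic probe designs delete exactly that base, so `AA0` classifies as
ARN while `A0A` and `0AA` do not.

A search *layout* is an ordered tiling of three element kinds — ARN
triplet (3 nt), non-functional triplet (NF, any 3-mer, 3 nt) and single
gap (1 nt) — subject to three structural rules:

1. layouts begin and end with an ARN element (boundary junk carries no
   binding content and would blur reported coordinates);
2. no two NF elements directly abut, and no two gaps directly abut
   ("non-adjacent" is read as *not directly abutting*: `NF·GAP·NF` is
   legal because the gap restores a backbone spacer, `NF·NF` is not);
3. gaps never sit at layout boundaries (for any ambiguity class).

The pattern engine enumerates, for given element counts, every distinct
layout satisfying these rules, in deterministic lexicographic order.
Ambiguity classes reproduce the explorative families the refined
definition was distilled from: consecutive-ARN only, NF triplets
without gaps, gaps adjacent to ARN triplets, gaps anywhere, and the
combined class.

The **refined motif definition** used for scanning is: at least 4 ARN
triplets within a single match spanning at most 20 nt, with at most 2
NF triplets and at most 2 single gaps. The window is exactly saturable:
4·3 + 2·3 + 2·1 = 20. The maximum gap count is not fixed by the
narrative description ("separated single gaps"); we default it to 2,
matching the gap budget of the generation phase and the window
identity, and expose it as a parameter.

## Scanning and merging

The scanner extends element tilings depth-first from every position
that opens an ARN triplet, enforcing the count, adjacency, window and
boundary constraints incrementally, and records each valid (start, end)
interval. Only *maximal* intervals (not strictly contained in another
valid match) are reported, since merging makes sub-matches redundant.
Among alternative tilings of one interval, metadata comes from the
tiling with the most ARN triplets, then fewest gaps, then the
lexicographically earliest element string; the interval itself never
depends on this tie-break.

Overlapping matches (≥ 1 nt shared) merge into motif *regions*, the
reported unit. Book-ended matches stay separate: published surveys
report multiple distinct regions per molecule, so abutment alone is not
treated as continuity. Long regions (e.g. OxyS 59–86, 28 nt) arise only
through merging of overlapping ≤ 20-nt matches.

mRNA 5′ windows are scanned with the same engine under a relaxed
`n_arn_min = 3` default, reflecting that mRNAs carry generally shorter
(ARN)_X regions which were originally located by inspection; this
relaxation is a stand-in for that visual step and is exposed as a
parameter, not hard-coded.

## Seed search

A seed is either (a) seven consecutive Watson–Crick pairs in
antiparallel orientation, reported as the maximal perfect duplex
containing them (a flag restores all minimal 7-mers), or (b) six
consecutive pairs, one bulged nucleotide on either strand, then two
pairs; both reading orders (6+gap+2 and 2+gap+6 along the sRNA) are
searched because duplex complementarity fixes neither, and the bulged
strand is recorded. Bulged hits wholly contained in a reported perfect
duplex are suppressed by default. G:U wobble pairing is off by default
(the seed definition speaks of complementarity, not wobble) and
available behind a flag. Abasic residues never pair. Maximal perfect
duplexes are found as maximal runs along anti-diagonals (the sum of
paired indices is constant in an antiparallel duplex).

## Coordinates

Everything is 1-based inclusive; only BED export is 0-based half-open.
A sequence carries an `offset` — the native coordinate of its first
residue — so scans of printed fragments report parent-molecule
coordinates. mRNA windows use signed numbering without a position 0
(−1 abuts +1); distances and spacings across the origin are computed on
a collapsed integer line, so the spacing between regions ending at −55
and starting at −10 is 44 nt. Unannotated 5′ UTRs default to −80; the
coding side of the window extends to +80.

## Architecture mapping

- **Hairpins**: innermost stem-loops are parsed from dot-bracket
  strings as contiguously stacked helices whose enclosed region
  contains no brackets. Structures are consumed, never predicted; a
  minimal maximum-pairing folder exists in the test suite solely to
  fabricate plausible inputs.
- **Context**: a motif region is "embraced" when hairpins exist
  strictly on both sides; it is flagged mostly-unpaired at ≥ 90%
  unpaired positions.
- **Poly(U) tail**: operationalized as the 3′-most run of ≥ 4
  consecutive U overlapping the 3′-terminal 15 nt (both configurable;
  the tail has no published quantitative definition). The reported
  distance is the number of nucleotides strictly between region end and
  the first tail U.
- **Bipartite motifs**: consecutive region pairs in one mRNA window are
  reported with their spacing; a configurable 40–80 nt band flags
  candidates around the observed ~60 nt spacing. The band is a
  presentation aid, never a filter.
- **Conservation**: motif A/R positions are mapped through an
  alignment; per-column conservation is the fraction of rows matching
  the site class ({A} or {A,G}), computed over non-gap rows with gap
  columns flagged; *persistence* is the fraction of rows (without gaps
  at A/R columns) whose sequence still satisfies every site class. The
  0.8 "conserved" labeling threshold is presentation-only.
- **Folding constraints**: motif regions export as Vienna-style
  constraint lines (`x` = forced unpaired) for external engines.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with exact ground truth:

- background composition defaults to A = 0.20 (C/G/U ≈ 0.27/0.27/0.26),
  with an option to depress A to 0.10; A-rich backgrounds breed
  spurious motif hits, and that false-positive rate is itself a
  reportable output via the shuffle null, not an assertion.
- planted motifs draw a uniformly random valid layout for the requested
  (ARN, NF, gap) counts; R-sites are A with probability 0.8 (the
  observed preference), N-sites follow a configurable distribution.
  Any window containing 4 planted ARN triplets carries at most the
  layout's 2 NF and 2 gaps, so its span is ≤ 20 nt and recovery by the
  scanner is exact by construction (asserted at 100%).
- modular sRNAs are built as stem-loop | motif | spacer | poly(U) with
  the 3′ stem-loop embedded inside the spacer, so the planted
  motif-to-tail distance (drawn uniformly from the observed 20–40 nt
  band) is exactly what the poly(U) measurement recovers. Flanks use
  C/G (loops C/G/U) so the motif is the only A-rich feature; the motif
  is resampled so its final triplet cannot seed a frame-shifted ARN
  triplet into the flank, making the scanned region identical to the
  planted interval. Seed sequences can be embedded in loops.
- the dinucleotide shuffle preserves all 16 dinucleotide counts and
  both terminal residues via a randomized Eulerian trail through the
  dinucleotide multigraph (rejection-sampled adjacency shuffles).
- simulated homolog alignments mutate per column i.i.d.; protected
  positions (e.g. planted A/R sites) mutate at a reduced rate
  (default ×0.1), emulating purifying selection. The reference row
  stays ungapped so reference-coordinate mapping is total.

All generation uses integer-seeded `numpy` generators; equal seeds give
identical output, and the CLI requires an explicit seed.

What passing synthetic tests do **not** show: real backgrounds are not
i.i.d. (codon structure, composition skews), real structures deviate
from the planted two-hairpin idealization, and real homolog alignments
contain indels and rate heterogeneity the column-i.i.d. model lacks.
Recovery rates on generated data are therefore upper bounds on
real-data behaviour, not estimates of it.

## Problem sizes and verification

Oracle-equivalence checks run the scanner against an independent
exhaustive layout-sliding oracle on 1,000 seeded random sequences of
length ≤ 40 with A-content varied between 0.15 and 0.55, and the seed
search against exhaustive duplex enumeration (≤ 1 bulge) on 200 seeded
pairs of length ≤ 30 — sizes at which exhaustive enumeration is exact
and fast. Planted-motif recovery uses 500 sequences (seed 11) and 50
planted architectures. The cohort-report regression uses the published
67-sRNA survey's per-molecule region coordinates as a fixture for the
reporting layer; re-deriving those regions from sequence requires an
external sequence resource and is out of scope for the offline suite.

## Known limitations

- No statistical significance for matches: the screen is purely
  combinatorial, and the shuffle-based background rate is descriptive.
- No thermodynamics: seeds are combinatorial complementarity, without
  ΔG, accessibility or kissing-complex geometry.
- Hairpin parsing reads contiguously stacked helices only; bulged stems
  are reported as separate hairpins.
- The mRNA `n_arn_min = 3` default approximates a visual annotation
  step and should be tuned per application.
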