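# arnscan

Combinatorial **(ARN)_X motif** scanning, sRNA–mRNA seed search and
motif-architecture mapping for Hfq-dependent riboregulation in bacteria.

## The problem

The bacterial RNA chaperone Hfq is a homohexameric ring whose *distal*
face binds A-rich RNA as repeated three-nucleotide units, one per
subunit: an **A-site** that accepts only adenine, an **R-site** that
accepts a purine (A or G, with a preference for A), and an **N-site**
whose base is flipped towards the solvent and is unconstrained —
the *ARN triplet*. Runs of such triplets, **(ARN)_X motifs**, occur in
the 5′ UTRs of Hfq-regulated mRNAs and in a distinct subset of small
regulatory RNAs (sRNAs) such as OxyS, where they are functionally
essential. Because natural motifs are interrupted by non-conforming
triplets and single-nucleotide insertions, finding them takes an exact
but degenerate pattern search rather than a simple regular expression.

`arnscan` implements that search as a reusable, tested pipeline:

- **pattern engine** — permutes every admissible arrangement of ARN
  triplets, tolerated non-functional (NF) triplets and single gaps into
  explicit pattern layouts;
- **motif scanner** — finds every *maximal* match of the refined motif
  definition (≥ 4 ARN triplets within a ≤ 20-nt match span, ≤ 2
  non-adjacent NF triplets, ≤ 2 separated single gaps, matches bounded
  by ARN triplets) and merges overlapping matches into motif regions;
- **seed finder** — locates minimal sRNA–mRNA complementarity: 7
  consecutive Watson–Crick pairs, or 6 pairs + a single-nucleotide bulge
  + 2 pairs (wobble optional);
- **architecture mapper** — relates motif regions to hairpins in
  dot-bracket structures, the 3′ poly(U) tail, signed mRNA 5′-window
  coordinates (no position 0), bipartite-motif spacing and homolog
  conservation, and emits Vienna-style constraint strings for external
  folding engines;
- **synthetic data** — generators with exact ground truth (planted
  motifs, modular stem-loop|motif|stem-loop|poly(U) sRNAs,
  composition-preserving shuffles, simulated homolog alignments) so the
  whole pipeline is verifiable offline.

All coordinates are 1-based inclusive; sequences may carry an offset so
matches on fragments report in the parent molecule's numbering, and
mRNA windows use signed coordinates where −1 is adjacent to +1.

## Worked example

The OxyS-derived 30-mer (full-length positions 57–86,
`UCAACUCGAAUAACUAAAGCCAACGUGAAC`) carries the best-characterised sRNA
(ARN)_X motif:

```python
from arnscan import find_matches, merge_matches
from arnscan.oligos import OXYS_ARN

for m in find_matches(OXYS_ARN):
    print(m.interval.start, m.interval.end, m.element_string(),
          m.n_arn, m.n_nonfunctional, m.n_gaps)
for r in merge_matches(find_matches(OXYS_ARN)):
    print("region", r.interval.start, r.interval.end, r.max_arn)
```

prints

```
59 76 ANAANA 4 2 0
65 80 AANAgA 4 1 1
68 86 ANAgANA 4 2 1
region 59 86 4
```

Three maximal ≤ 20-nt matches (element strings: `A` = ARN triplet,
`N` = non-functional triplet, `g` = single gap) overlap and merge into
one region spanning positions **59–86** of full-length OxyS — the
published coordinates of its motif. The preceding `UC` cannot open a
match (matches must begin with an ARN triplet), which pins the start to
59; each individual match respects the 20-nt span bound, and only
merging produces the 28-nt region.

The same scan from the shell:

```
arnscan scan --fasta srnas.fa --out report.tsv --bed report.bed
arnscan seeds --srna srnas.fa --mrna targets.fa --out seeds.tsv
arnscan arch --fasta srnas.fa --structure srnas.db --out arch.tsv
arnscan simulate --preset oxys-like --n 100 --seed 42 --out sim/
arnscan run --config run.yaml
```

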