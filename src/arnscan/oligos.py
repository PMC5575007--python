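"""Published oligonucleotide designs used as worked-example inputs.

These are the probe sequences from the biochemical characterisation of
Hfq distal-site binding: homopolymeric and (AAN)-repeat probes, the
OxyS-derived fragment carrying its (ARN)_X motif (nucleotides 57-86 of
full-length OxyS, hence the coordinate offset), the abasic variant in
which the presumed N-site bases are removed ('0' = abasic), and the
fhlA fusion oligo joining the two (ARN)_X regions of the fhlA 5' UTR
(-78..-65 fused directly to -14..+5; intervening residues replaced).
"""

from __future__ import annotations

from .seqio import RnaSequence

__all__ = [
    "A20",
    "A30",
    "AA0",
    "AAC",
    "AAU",
    "AAG",
    "OXYS_ARN",
    "OXY0",
    "FHLA_FUSION",
]

A20 = RnaSequence(id="A20", residues="A" * 20)
A30 = RnaSequence(id="A30", residues="A" * 30)

# (AAN)_6 AA repeat probes; '0' deletes the N-site base (abasic)
AA0 = RnaSequence(id="AA0", residues="AA0" * 6 + "AA")
AAC = RnaSequence(id="AAC", residues="AAC" * 6 + "AA")
AAU = RnaSequence(id="AAU", residues="AAU" * 6 + "AA")
AAG = RnaSequence(id="AAG", residues="AAG" * 6 + "AA")

# OxyS nucleotides 57-86; matches report in full-length OxyS numbering
OXYS_ARN = RnaSequence(
    id="oxyS_arn", residues="UCAACUCGAAUAACUAAAGCCAACGUGAAC", offset=57
)

# abasic N-site variant of the above; published as a 29-mer (one residue
# shorter than its parent oligo) and reproduced here verbatim
OXY0 = RnaSequence(
    id="oxy0", residues="UCAA0UC0AA0AA0UAA0GCCAA0GU0AA", offset=57
)

# the two fhlA (ARN)_X regions fused; local coordinates 1-33
FHLA_FUSION = RnaSequence(
    id="fhlA_arn", residues="CUAAUAAAAUUCUACCUAGAAGAACAAAAUGUC"
)
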