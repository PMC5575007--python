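import numpy as np
import pytest

from arnscan.seqio import RnaSequence


@pytest.fixture
def oxys_oligo():
    from arnscan.oligos import OXYS_ARN

    return OXYS_ARN


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_rna(rng, length, p_a=0.25):
    rest = (1 - p_a) / 3
    return "".join(
        rng.choice(list("ACGU"), size=length, p=[p_a, rest, rest, rest])
    )


@pytest.fixture
def random_rna_factory():
    return random_rna


@pytest.fixture
def write_tmp_fasta(tmp_path):
    def _write(records, name="in.fa"):
        path = tmp_path / name
        lines = []
        for rec in records:
            if isinstance(rec, RnaSequence):
                off = f" offset={rec.offset}" if rec.offset != 1 else ""
                lines.append(f">{rec.id}{off}\n{rec.residues}")
            else:
                lines.append(f">{rec[0]}\n{rec[1]}")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
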