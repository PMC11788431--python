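import numpy as np
import pytest

from screenhit.library import CONTROL_GENE, GuideLibrary, GuideRecord


def _mutate(seq: str, positions, alphabet="ACGT") -> str:
    out = list(seq)
    for p in positions:
        out[p] = alphabet[(alphabet.index(out[p]) + 1) % 4]
    return "".join(out)


@pytest.fixture
def mutate():
    return _mutate


@pytest.fixture
def toy_library() -> GuideLibrary:
    """Ten distinct guides over three genes plus one non-targeting control."""
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = set()
    while len(seqs) < 10:
        seqs.add(bases[rng.integers(0, 4, 20)].tobytes().decode())
    seqs = sorted(seqs)
    genes = ["GENEA"] * 4 + ["GENEB"] * 3 + ["GENEC"] * 2 + [CONTROL_GENE]
    return GuideLibrary.from_records(
        GuideRecord(f"g{i}", gene, seq)
        for i, (gene, seq) in enumerate(zip(genes, seqs))
    )


def write_fastq(path, reads, prefix="TT", suffix="GTTTTAGAGC"):
    """Plain-text FASTQ fixture: one record per read string."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@r{i}\n{read}\n+\n{'I' * len(read)}\n")
    return path


@pytest.fixture
def fastq_writer():
    return write_fastq
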