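import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write a FASTA file from (id, sequence) pairs; returns its path."""

    def _write(records, name="genomes.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return str(path)

    return _write
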