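import numpy as np
import pytest

from idpcohort import ProteinRecord
from idpcohort.dataset_io import STANDARD_AA


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length, accession="P1"):
    seq = "".join(rng.choice(list(STANDARD_AA), size=length))
    return ProteinRecord(accession, accession, seq)


@pytest.fixture
def make_fasta(tmp_path):
    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with path.open("w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path
    return _write
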