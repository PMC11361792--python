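import numpy as np
import pytest

from rnaloc.records import RnaRecord
from rnaloc.structure import nussinov_fold


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGU") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def random_valid_dotbracket(rng: np.random.Generator, length: int) -> str:
    """Random nested dot-bracket string built by a push/pop walk."""
    chars = []
    open_positions = 0
    for i in range(length):
        remaining = length - i
        if open_positions >= remaining:
            chars.append(")")
            open_positions -= 1
            continue
        r = rng.random()
        if r < 0.3 and remaining > open_positions + 1:
            chars.append("(")
            open_positions += 1
        elif r < 0.55 and open_positions > 0:
            chars.append(")")
            open_positions -= 1
        else:
            chars.append(".")
    chars.extend(")" * open_positions)
    return "".join(chars[:length])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def folded_records():
    """A handful of labelled, folded records for model-level tests."""
    gen = np.random.default_rng(11)
    records = []
    for i in range(12):
        seq = random_sequence(gen, int(gen.integers(40, 80)))
        rec = RnaRecord(id=f"r{i}", sequence=seq,
                        labels=gen.integers(0, 2, 6))
        rec.set_structure("nussinov", nussinov_fold(seq))
        records.append(rec)
    return records
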