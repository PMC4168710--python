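import random

import pytest

from ctxmerge.fastq_io import SequencingRead


@pytest.fixture
def rng():
    return random.Random(20240901)


def random_read(rng, length, alphabet="ACGT", identifier="r"):
    seq = "".join(rng.choice(alphabet) for _ in range(length))
    quals = [rng.randint(0, 41) for _ in range(length)]
    return SequencingRead(identifier, seq, quals)
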