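import numpy as np
import pytest

from loopgrammar.core import GenomeSequence, Interval
from loopgrammar.motifs import PositionWeightMatrix
from loopgrammar.simulate import builtin_pwm, make_genome


@pytest.fixture(scope="session")
def znf_pwm():
    return builtin_pwm("znf143_like")


@pytest.fixture(scope="session")
def ctcf_pwm():
    return builtin_pwm("ctcf_like")


@pytest.fixture(scope="session")
def random_genome_10kb():
    return make_genome(10_000, seed=42)


@pytest.fixture
def tiny_genome():
    return GenomeSequence({"c1": "ACGT" * 375})  # 1.5 kb


@pytest.fixture
def two_col_pwm():
    """W=2 example PWM: col1 favours A, col2 favours G."""
    probs = np.array(
        [
            [0.7, 0.05],
            [0.1, 0.05],
            [0.1, 0.85],
            [0.1, 0.05],
        ]
    )
    return PositionWeightMatrix("toy", probs)


def make_interval(chrom="c1", start=0, end=10, strand=".", name=".", score=0.0):
    return Interval(chrom, start, end, strand=strand, name=name, score=score)
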