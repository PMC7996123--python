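import pytest

from climmigsim import build_storyline, run


@pytest.fixture(scope="session")
def s1_trace():
    return run(build_storyline("S1"))


@pytest.fixture(scope="session")
def s2_trace_1pct():
    return run(build_storyline("S2", spillover=0.01))


@pytest.fixture(scope="session")
def s2_trace_0pct():
    return run(build_storyline("S2", spillover=0.0))


@pytest.fixture(scope="session")
def s2_trace_2pct():
    return run(build_storyline("S2", spillover=0.02))


@pytest.fixture(scope="session")
def s3_trace_b25():
    return run(build_storyline("S3", barrier=0.25))


@pytest.fixture(scope="session")
def s3_trace_b50():
    return run(build_storyline("S3", barrier=0.5))


@pytest.fixture(scope="session")
def s4_trace_q50():
    return run(build_storyline("S4", quality=0.5))
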