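import pytest

import pkmodsel as pk


@pytest.fixture(scope="session")
def grid11():
    """The study grid: 11 times on [0.01, 100], log-symmetric around 1."""
    return pk.make_time_grid(11, 100.0)


@pytest.fixture(scope="session")
def lambdas11(grid11):
    return pk.make_lambda_grid(grid11)


@pytest.fixture(scope="session")
def table1():
    """The evenly spaced candidate masks for M = 11, K = 1..11."""
    return {
        1: "00000100000",
        2: "10000000001",
        3: "10000100001",
        4: "10010001001",
        5: "10010101001",
        6: "10101010101",
        7: "10110101101",
        8: "11011011011",
        9: "11011111011",
        10: "11111011111",
        11: "11111111111",
    }
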