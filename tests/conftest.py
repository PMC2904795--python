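import logging

import pytest
from hypothesis import strategies as st

from nglycode import GlycanCode, all_codes


@pytest.fixture(scope="session")
def full_code_space() -> list[GlycanCode]:
    """All 38,416 valid codes, built once per session."""
    return list(all_codes())


@pytest.fixture(autouse=True)
def _quiet_plausibility_warnings():
    """Bulk sweeps over the code space hit the branch-on-extra-mannose
    warning thousands of times; keep it out of captured logs."""
    logger = logging.getLogger("nglycode.structure")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


def code_strategy() -> st.SearchStrategy[GlycanCode]:
    """Hypothesis strategy over the full valid code space."""
    return st.builds(
        GlycanCode.from_digits,
        st.integers(3, 6),
        st.integers(0, 1),
        st.integers(0, 1),
        st.tuples(*[st.integers(0, 6)] * 4),
    )
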