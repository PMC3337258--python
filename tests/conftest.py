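import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from goalont import build_goal, classify, mefv_fixture, taar4_fixture


@pytest.fixture(scope="session")
def taar4_result():
    return build_goal(taar4_fixture())


@pytest.fixture(scope="session")
def taar4_deployment(taar4_result):
    return classify(taar4_result.goal)


@pytest.fixture(scope="session")
def mefv_result():
    return build_goal(mefv_fixture())


@pytest.fixture(scope="session")
def mefv_deployment(mefv_result):
    return classify(mefv_result.goal)
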