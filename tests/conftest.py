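import pytest

from rafnet.crs import parse_crs

# Toy chemistries used throughout: TOY1 has a mutually catalytic pair,
# TOY2 a single food-catalyzed reaction, TOY3 extends TOY2 with a
# downstream reaction catalyzed by the first product.
TOY1_TEXT = """\
elements: c, ab
food: a, b
r1: a + b -> ab [c]
r2: a -> c [ab]
"""

TOY2_TEXT = """\
elements: ab
food: a, b
r1: a + b -> ab [a]
"""

TOY3_TEXT = """\
elements: ab, abb
food: a, b
r1: a + b -> ab [a]
r2: ab + b -> abb [ab]
"""


@pytest.fixture
def toy1():
    return parse_crs(TOY1_TEXT)


@pytest.fixture
def toy2():
    return parse_crs(TOY2_TEXT)


@pytest.fixture
def toy3():
    return parse_crs(TOY3_TEXT)
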