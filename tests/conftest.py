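import pandas as pd
import pytest

import nutriflow as nf


@pytest.fixture()
def tiny_world():
    """Exhaustive-oracle-scale world: 5 countries x 3 products x 2 years."""
    return nf.generate(nf.scale_down_preset("tiny", seed=11))


@pytest.fixture()
def small_world():
    return nf.generate(nf.scale_down_preset("small", seed=7))


@pytest.fixture()
def resolver(tiny_world):
    return nf.ContentResolver(tiny_world.physical, tiny_world.virtual,
                              tiny_world.trade)


def make_trade(rows):
    """rows: (year, exporter, importer, product, mass)."""
    return pd.DataFrame(rows, columns=["year", "exporter", "importer",
                                       "product", "mass"])


def make_physical(rows):
    """rows: (product, n, p) in kg/t."""
    return pd.DataFrame(rows, columns=["product", "n", "p"])


def make_virtual(rows):
    """rows: (country, product, n, p) in kg/t."""
    return pd.DataFrame(rows, columns=["country", "product", "n", "p"])


@pytest.fixture()
def wheat_world():
    """Hand-sized fixture: 3 countries, one product, one re-export hop.

    A exports 100 t wheat to B; B re-exports 20 t onward to C (declared
    re-export record).  Physical N 20 kg/t, P 4 kg/t.  Virtual N
    contents A/B/C = 30/50/45 kg/t, P = 6/10/9.
    """
    trade = make_trade([
        (2000, "AAA", "BBB", "wheat", 100.0),
    ])
    reexp = pd.DataFrame(
        [(2000, "BBB", "CCC", "wheat", 20.0)],
        columns=["year", "intermediate", "destination", "product", "mass"])
    physical = make_physical([("wheat", 20.0, 4.0)])
    virtual = make_virtual([
        ("AAA", "wheat", 30.0, 6.0),
        ("BBB", "wheat", 50.0, 10.0),
        ("CCC", "wheat", 45.0, 9.0),
    ])
    return trade, reexp, physical, virtual
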