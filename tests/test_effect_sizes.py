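import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contestmeta import effect_sizes as es
from contestmeta.dataio import EffectRecord
from tests.conftest import make_record


@pytest.mark.parametrize(
    "t, df, expected",
    [
        (0.0, 10, 0.0),
        (2.0, 16, 2.0 / math.sqrt(20.0)),  # 0.4472...
        (-2.0, 16, -2.0 / math.sqrt(20.0)),
    ],
)
def test_r_from_t(t, df, expected):
    assert es.r_from_t(t, df) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "f, dfe, direction, expected",
    [
        (0.0, 10, "+", 0.0),
        (4.0, 16, "+", 2.0 / math.sqrt(20.0)),  # F = t^2 consistency
        (4.0, 16, "-", -2.0 / math.sqrt(20.0)),
    ],
)
def test_r_from_f(f, dfe, direction, expected):
    assert es.r_from_f(f, dfe, direction) == pytest.approx(expected, abs=1e-12)


def test_conversion_errors():
    with pytest.raises(es.EffectSizeError):
        es.r_from_t(1.0, 0)
    with pytest.raises(es.EffectSizeError):
        es.r_from_f(-1.0, 10, "+")
    with pytest.raises(es.EffectSizeError):
        es.r_from_f(4.0, 10, "positive")


@pytest.mark.parametrize(
    "r, expected",
    [(0.0, 0.0), (0.5, 0.549306), (-0.5, -0.549306)],
)
def test_fisher_z_values(r, expected):
    assert es.fisher_z(r) == pytest.approx(expected, abs=1e-6)


def test_fisher_z_rejects_degenerate_r():
    for r in (1.0, -1.0, 0.99995):
        with pytest.raises(es.EffectSizeError):
            es.fisher_z(r)


@pytest.mark.parametrize("n, expected", [(4, 1.0), (103, 0.01), (20, 1 / 17)])
def test_z_variance(n, expected):
    assert es.z_variance(n) == pytest.approx(expected, rel=1e-12)


def test_z_variance_undefined_below_n4():
    for n in (3, 2, 0):
        with pytest.raises(es.EffectSizeError):
            es.z_variance(n)


@given(st.floats(-0.99, 0.99))
@settings(derandomize=True, max_examples=60)
def test_fisher_z_inverts_through_tanh(r):
    assert math.tanh(es.fisher_z(r)) == pytest.approx(r, abs=1e-12)


@given(st.floats(-0.99, 0.99), st.floats(-0.99, 0.99))
@settings(derandomize=True, max_examples=60)
def test_fisher_z_is_odd_and_increasing(a, b):
    assert es.fisher_z(-a) == pytest.approx(-es.fisher_z(a), abs=1e-12)
    if a < b:
        assert es.fisher_z(a) < es.fisher_z(b)


@given(st.floats(-50, 50), st.integers(1, 500))
@settings(derandomize=True, max_examples=60)
def test_r_from_t_algebraic_identity(t, df):
    # r^2 + df/(t^2+df) = 1 identically
    r = es.r_from_t(t, df)
    assert r * r + df / (t * t + df) == pytest.approx(1.0, abs=1e-12)
    assert -1 < r < 1


def test_r_from_raw_pairwise_complete():
    x = [1.0, 2.0, 3.0, 4.0, np.nan, 6.0]
    y = [1.1, 2.3, 2.8, 4.2, 5.0, np.nan]
    r, n = es.r_from_raw(x, y)
    assert n == 4  # two pairs dropped
    expected = np.corrcoef(x[:4], y[:4])[0, 1]
    assert r == pytest.approx(expected, abs=1e-12)


def test_r_from_raw_rejects_perfect_correlation_via_derive():
    x = tuple(float(i) for i in range(5))
    y = tuple(2.0 * xi for xi in x)
    rec = EffectRecord(
        effect_id="raw1", article_id="a", species="Sp_x", study_type="field",
        role="loser", stat_kind="raw", raw_x=x, raw_y=y, n=5,
    )
    with pytest.raises(es.EffectSizeError, match="unbounded"):
        es.derive_effect(rec)


@pytest.mark.parametrize(
    "fields, z, v",
    [
        (dict(stat_kind="r", stat_value=0.3, n=28), 0.309520, 0.04),
        (dict(stat_kind="t", stat_value=2.0, df=16, n=18), 0.481212, 1 / 15),
        (dict(stat_kind="F", stat_value=4.0, df=16, n=18, sign="-"), -0.481212, 1 / 15),
    ],
)
def test_derive_effect_chains_conversions(fields, z, v):
    rec = EffectRecord(
        effect_id="e1", article_id="a", species="Sp_x", study_type="field",
        role="loser", **fields,
    )
    derived = es.derive_effect(rec)
    assert derived.z == pytest.approx(z, abs=1e-5)
    assert derived.v == pytest.approx(v, rel=1e-12)


def test_derive_effect_idempotent():
    rec = es.derive_effect(make_record("e1", "winner", r=-0.25, n=40))
    again = es.derive_effect(rec)
    assert again == rec
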