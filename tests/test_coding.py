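"""Boundary-exact coding of impairments and outcomes, with missingness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ictrans import coding


def raw_row(**kw):
    base = dict(walk_speed=1.0, weight_loss=0, muac=25.0, vision_problem=0,
                hearing_problem=0, cogscore=33.0, eurod=0, exhaustion=0, low_energy=0)
    base.update(kw)
    return pd.DataFrame([base])


@pytest.mark.parametrize(
    "kw, domain, expected",
    [
        ({"walk_speed": 0.79}, "locomotion", True),
        ({"walk_speed": 0.8}, "locomotion", False),  # strict <0.8 m/s
        ({"eurod": 4}, "psychological", True),
        ({"eurod": 3}, "psychological", False),  # >3 of 12 symptoms
        ({"muac": 21.9, "weight_loss": 0}, "nutrition", True),
        ({"muac": 22.0, "weight_loss": 0}, "nutrition", False),  # strict <22 cm
        ({"cogscore": 29.4}, "cognition", True),
        ({"cogscore": 29.5}, "cognition", False),  # strict <29.5
        ({"vision_problem": 1}, "vision", True),
        ({"hearing_problem": 1}, "hearing", True),
    ],
)
def test_threshold_boundaries(kw, domain, expected):
    out = coding.code_impairments(raw_row(**kw))
    assert bool(out.loc[0, domain]) is expected


@pytest.mark.parametrize(
    "kw, domain",
    [
        ({"walk_speed": np.nan}, "locomotion"),
        ({"cogscore": np.nan}, "cognition"),
        ({"eurod": np.nan}, "psychological"),
        ({"vision_problem": np.nan}, "vision"),
        ({"weight_loss": np.nan, "muac": np.nan}, "nutrition"),
        ({"weight_loss": 0, "muac": np.nan}, "nutrition"),  # false OR unknown = unknown
    ],
)
def test_missing_raw_gives_missing_indicator(kw, domain):
    out = coding.code_impairments(raw_row(**kw))
    assert pd.isna(out.loc[0, domain])


def test_nutrition_single_confirmed_criterion_suffices():
    # a confirmed criterion is not erased by a missing co-criterion
    out = coding.code_impairments(raw_row(weight_loss=1, muac=np.nan))
    assert bool(out.loc[0, "nutrition"]) is True
    out = coding.code_impairments(raw_row(weight_loss=np.nan, muac=20.0))
    assert bool(out.loc[0, "nutrition"]) is True


@pytest.mark.parametrize(
    "kw, message",
    [
        ({"walk_speed": -0.2}, "walk_speed"),
        ({"eurod": 13}, "eurod"),
        ({"muac": 0.0}, "muac"),
    ],
)
def test_range_validation_names_field_and_row(kw, message):
    with pytest.raises(coding.ValidationError, match=message) as err:
        coding.code_impairments(raw_row(**kw))
    assert "0" in str(err.value)  # offending row index reported


def frailty_frame(wl, ex, sw, le):
    return pd.DataFrame([{"weight_loss": wl, "exhaustion": ex, "slow_walk": sw, "low_energy": le}])


@pytest.mark.parametrize(
    "components, expected",
    [
        ((1, 1, 0, 0), True),  # two of four suffice
        ((0, 0, 0, 0), False),
        ((1, 0, 0, 0), False),  # one is not enough
        ((1, 1, 1, 1), True),
    ],
)
def test_frailty_two_or_more_of_four(components, expected):
    out = coding.code_frailty(frailty_frame(*components))
    assert bool(out.iloc[0]) is expected


def test_frailty_missing_component_gives_missing():
    out = coding.code_frailty(frailty_frame(1, 1, np.nan, 0))
    assert pd.isna(out.iloc[0])  # even though >=2 already confirmed, rule needs all four


@pytest.mark.parametrize("score, threshold, expected", [(10, 8, True), (8, 8, True), (0, 8, False)])
def test_disability_threshold_inclusive(score, threshold, expected):
    out = coding.code_disability(pd.Series([score]), threshold)
    assert bool(out.iloc[0]) is expected


def test_disability_missing_score():
    assert pd.isna(coding.code_disability(pd.Series([np.nan]), 8).iloc[0])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.floats(0, 2), st.integers(0, 1), st.floats(15, 30),
                          st.floats(20, 34), st.integers(0, 12)),
                min_size=1, max_size=8))
def test_batch_equals_rowwise(rows):
    """Coding n rows at once equals coding each row alone (order-independent,
    idempotent deterministic map)."""
    df = pd.DataFrame(rows, columns=["walk_speed", "weight_loss", "muac", "cogscore", "eurod"])
    df["vision_problem"] = 0
    df["hearing_problem"] = 1
    batch = coding.code_impairments(df)
    for i in range(len(df)):
        single = coding.code_impairments(df.iloc[[i]])
        pd.testing.assert_frame_equal(single, batch.iloc[[i]])


def test_indicator_csv_roundtrip(tmp_path):
    df = pd.DataFrame({
        "id": [0, 1, 2],
        **{c: pd.array([True, False, pd.NA], dtype="boolean") for c in coding.indicator_columns()},
    })
    path = tmp_path / "ind.csv"
    coding.write_indicator_csv(df, path, header_lines=["test header"])
    assert open(path).readline().startswith("# ")
    back = coding.read_indicator_csv(path)
    for c in coding.indicator_columns():
        assert back[c].tolist() == df[c].tolist()
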