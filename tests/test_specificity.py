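"""Specificity statistics, voting classifier and triage bands.

The tau/Gini/counts implementations are checked against independent
straight-loop oracles coded here, and their scale invariance is a
hypothesis property.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tissueatlas import (
    ExpressionMatrix,
    assign_tsg_tissue,
    classify,
    coefficient_of_variation,
    counts_score,
    gini,
    score_matrix,
    tau,
    tpm_bands,
    variability_bands,
)

# --- independent straight-loop oracles ------------------------------------


def tau_oracle(x):
    mx = max(x)
    total = 0.0
    for xi in x:
        total += 1.0 - xi / mx
    return total / (len(x) - 1)


def gini_oracle(x):
    n = len(x)
    acc = 0.0
    for xi in x:
        for xj in x:
            acc += abs(xi - xj)
    raw = acc / (2.0 * n * n * (sum(x) / n))
    return min(1.0, raw * n / (n - 1))


def counts_oracle(x, threshold):
    n = len(x)
    m = sum(1 for xi in x if xi >= threshold)
    return (n - m) / (n - 1)


# --- tau -------------------------------------------------------------------


@pytest.mark.parametrize(
    "x,expected",
    [((5, 5, 5, 5), 0.0), ((9, 0, 0, 0), 1.0), ((8, 2, 2, 2), 0.75)],
)
def test_tau_reference_values(x, expected):
    assert tau(x) == pytest.approx(expected)


def test_tau_undefined_for_all_zero():
    assert math.isnan(tau((0.0, 0.0, 0.0)))


# --- gini ------------------------------------------------------------------


@pytest.mark.parametrize(
    "x,expected",
    [((3, 3, 3, 3), 0.0), ((1, 0, 0, 0), 1.0), ((3, 1), 0.5)],
)
def test_gini_reference_values(x, expected):
    assert gini(x) == pytest.approx(expected)


# --- counts ----------------------------------------------------------------


@pytest.mark.parametrize(
    "x,threshold,expected",
    [
        (tuple([2.0] * 11), 1.0, 0.0),
        ((5, 0, 0, 0), 1.0, 1.0),
        ((5, 0.5, 0, 2), 1.0, 2.0 / 3.0),
    ],
)
def test_counts_reference_values(x, threshold, expected):
    assert counts_score(x, threshold) == pytest.approx(expected)


def test_counts_undefined_below_threshold_everywhere():
    assert math.isnan(counts_score((0.1, 0.2), threshold=1.0))


# --- oracle equivalence and properties --------------------------------------


def test_scores_match_straight_loop_oracles(rng):
    X = rng.uniform(0, 100, size=(500, 11))
    X[rng.random(X.shape) < 0.2] = 0.0
    X = X[X.max(axis=1) > 0]
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(len(X))],
                      columns=[f"t{i}" for i in range(11)])
    scores = score_matrix(ExpressionMatrix(df), threshold=1.0)
    for gene, row in df.iterrows():
        x = list(row)
        assert scores.loc[gene, "tau"] == pytest.approx(tau_oracle(x), abs=1e-12)
        assert scores.loc[gene, "gini"] == pytest.approx(gini_oracle(x), abs=1e-12)
        m = sum(1 for xi in x if xi >= 1.0)
        if m > 0:
            assert scores.loc[gene, "counts"] == pytest.approx(
                counts_oracle(x, 1.0), abs=1e-12
            )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    x=st.lists(st.floats(0.01, 1e4), min_size=3, max_size=12),
    c=st.floats(0.01, 100.0),
)
def test_tau_gini_scale_invariant(x, c):
    xs = np.asarray(x)
    assert tau(xs * c) == pytest.approx(tau(xs), abs=1e-9)
    assert gini(xs * c) == pytest.approx(gini(xs), abs=1e-9)


def test_extreme_vectors_score_zero_and_one():
    uniform = pd.DataFrame([[4.0] * 6], index=["u"], columns=list("abcdef"))
    single = pd.DataFrame([[9.0] + [0.0] * 5], index=["s"], columns=list("abcdef"))
    su = score_matrix(ExpressionMatrix(uniform))
    ss = score_matrix(ExpressionMatrix(single))
    assert su.loc["u", ["tau", "gini", "counts"]].tolist() == pytest.approx([0, 0, 0])
    assert ss.loc["s", ["tau", "gini", "counts"]].tolist() == pytest.approx([1, 1, 1])


# --- classifier --------------------------------------------------------------


def _scores_frame(rows):
    df = pd.DataFrame(rows, columns=["tau", "gini", "counts"])
    df["defined"] = True
    return df


@pytest.mark.parametrize(
    "row,label",
    [
        ((0.9, 0.85, 0.5), "TSG"),
        ((0.1, 0.15, 0.5), "HKG"),
        ((0.5, 0.5, 0.5), "UNCLASSIFIED"),
        ((0.8, 0.8, 0.8), "UNCLASSIFIED"),  # boundary is strict
        ((0.2, 0.2, 0.2), "UNCLASSIFIED"),
    ],
)
def test_voting_rule(row, label):
    out = classify(_scores_frame([row]))
    assert out["label"].iloc[0] == label


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=3, max_size=3))
def test_tsg_hkg_mutually_exclusive(row):
    out = classify(_scores_frame([row]))
    assert not (out["votes_high"].iloc[0] >= 2 and out["votes_low"].iloc[0] >= 2)


def test_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        classify(_scores_frame([(0.5, 0.5, 0.5)]), high=0.2, low=0.8)


def test_undefined_gene_unclassified():
    df = _scores_frame([(np.nan, np.nan, np.nan)])
    df["defined"] = False
    assert classify(df)["label"].iloc[0] == "UNCLASSIFIED"


# --- TSG tissue attribution ---------------------------------------------------


def test_assign_tsg_tissue_max_and_tie(small_matrix, caplog):
    df = small_matrix.data.copy()
    df.loc["tie"] = 0.0
    df.loc["tie", ["brain", "heart"]] = 7.0
    m = ExpressionMatrix(df)
    out = assign_tsg_tissue(m, ["g3", "tie"])
    assert out["g3"] == "muscle"
    assert out["tie"] == "brain"  # first in column order


def test_assign_tsg_tissue_unknown_gene(small_matrix):
    with pytest.raises(KeyError):
        assign_tsg_tissue(small_matrix, ["nope"])


def test_tsg_tissue_recovery_on_atlas(atlas):
    matrix, truth = atlas
    planted = {g: t for t, genes in truth.tsg_map.items() for g in genes}
    out = assign_tsg_tissue(matrix, list(planted))
    agree = np.mean([out[g] == planted[g] for g in planted])
    assert agree >= 0.95


# --- CV and bands -------------------------------------------------------------


def test_cv_reference_and_invariance():
    assert coefficient_of_variation((2, 4, 6)) == pytest.approx(0.5)
    assert coefficient_of_variation((3, 3, 3)) == 0.0
    assert coefficient_of_variation((20, 40, 60)) == pytest.approx(0.5)


def test_variability_bands_quartile_split():
    cvs = pd.Series(np.arange(1.0, 101.0), index=[f"g{i}" for i in range(100)])
    bands = variability_bands(cvs)
    counts = bands.value_counts()
    assert abs(counts["low"] - 25) <= 1
    assert abs(counts["high"] - 25) <= 1
    assert abs(counts["moderate"] - 50) <= 2


def test_variability_bands_degenerate_all_moderate():
    bands = variability_bands(pd.Series([0.3] * 8))
    assert (bands == "moderate").all()


def test_planted_hkgs_fall_in_low_band(atlas):
    matrix, truth = atlas
    cvs = pd.Series(
        [coefficient_of_variation(row) for row in matrix.values],
        index=matrix.gene_ids,
    )
    bands = variability_bands(cvs)
    assert (bands.loc[truth.hkg_ids] == "low").mean() > 0.8


def test_tpm_band_boundaries():
    df = pd.DataFrame(
        [[0.5, 1.0, 10.0, 50.0, 50.1, 200.0]],
        index=["g"], columns=list("abcdef"),
    )
    bands = tpm_bands(ExpressionMatrix(df))
    assert bands.loc["g"].tolist() == [
        "excluded", "b1_10", "b1_10", "b10_50", "gt50", "gt50",
    ]


def test_tpm_band_counts_match_scan(rng):
    X = rng.uniform(0, 120, size=(50, 6))
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(50)], columns=list("abcdef"))
    bands = tpm_bands(ExpressionMatrix(df)).to_numpy().ravel()
    flat = X.ravel()
    assert (bands == "excluded").sum() == (flat < 1).sum()
    assert (bands == "b1_10").sum() == ((flat >= 1) & (flat <= 10)).sum()
    assert (bands == "b10_50").sum() == ((flat > 10) & (flat <= 50)).sum()
    assert (bands == "gt50").sum() == (flat > 50).sum()
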