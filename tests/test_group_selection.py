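"""Contrasting-group selection, separation testing, and GEBV correlograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dasekit.group_selection import (
    GroupSelectionError,
    classify_correlation_signs,
    gebv_correlation_matrix,
    select_contrast_groups,
    verify_group_separation,
)


def animal_table(gebvs, sires, ids=None, trait="T"):
    ids = ids or [f"A{i}" for i in range(len(gebvs))]
    return pd.DataFrame({"animal_id": ids, "sire_id": sires, trait: gebvs})


class TestSelectContrastGroups:
    def test_unconstrained_selection_takes_extremes(self):
        animals = animal_table(list(range(40)), [f"S{i}" for i in range(40)])
        g = select_contrast_groups(animals, "T", n_per_group=20)
        assert set(g.high) == {f"A{i}" for i in range(20, 40)}
        assert set(g.low) == {f"A{i}" for i in range(20)}
        assert min(animals.set_index("animal_id").loc[list(g.high), "T"]) >= max(
            animals.set_index("animal_id").loc[list(g.low), "T"]
        )

    def test_greedy_sire_constraint_hand_trace(self):
        # GEBVs 5..0 with sires AAABBB: High takes 5(A) then skips 4,3 (A
        # saturated) and takes 2(B); Low scans from the bottom, takes 0(B),
        # skips 1(B), skips 2 (already in High), takes 3(A).
        animals = animal_table(
            [5, 4, 3, 2, 1, 0], ["A", "A", "A", "B", "B", "B"],
            ids=["a5", "a4", "a3", "a2", "a1", "a0"],
        )
        g = select_contrast_groups(animals, "T", n_per_group=2, max_per_sire=1)
        assert set(g.high) == {"a5", "a2"}
        assert set(g.low) == {"a0", "a3"}

    def test_infeasible_reports_filled_slots(self):
        animals = animal_table(list(range(39)), ["S"] * 39)
        with pytest.raises(GroupSelectionError, match="need 40"):
            select_contrast_groups(animals, "T", n_per_group=20)
        with pytest.raises(GroupSelectionError, match="filled 1/2"):
            select_contrast_groups(animals.head(10), "T", n_per_group=2, max_per_sire=1)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        animals = animal_table(rng.normal(size=30), [f"S{i % 8}" for i in range(30)])
        g1 = select_contrast_groups(animals, "T", n_per_group=5, max_per_sire=1)
        g2 = select_contrast_groups(
            animals.sample(frac=1, random_state=1).reset_index(drop=True),
            "T", n_per_group=5, max_per_sire=1,
        )
        assert g1.high == g2.high and g1.low == g2.low

    def test_groups_are_disjoint_and_sized(self):
        rng = np.random.default_rng(5)
        animals = animal_table(rng.normal(size=50), [f"S{i % 25}" for i in range(50)])
        g = select_contrast_groups(animals, "T", n_per_group=10, max_per_sire=1)
        assert len(set(g.high)) == len(set(g.low)) == 10
        assert not set(g.high) & set(g.low)
        assert g.t_pvalue < 0.05  # clearly separated random normals


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    gebvs=st.lists(
        st.floats(-10, 10, allow_nan=False, allow_subnormal=False), min_size=12, max_size=40
    ),
    n_sires=st.integers(4, 12),
    max_per_sire=st.integers(1, 3),
)
def test_selection_invariants_hold_for_arbitrary_inputs(gebvs, n_sires, max_per_sire):
    """Disjoint equal-sized groups that respect the sire cap, whatever the input."""
    animals = animal_table(gebvs, [f"S{i % n_sires}" for i in range(len(gebvs))])
    n_per_group = 3
    try:
        g = select_contrast_groups(animals, "T", n_per_group, max_per_sire)
    except GroupSelectionError:
        return  # infeasible inputs are rejected explicitly, never mangled
    assert len(g.high) == len(g.low) == n_per_group
    assert not set(g.high) & set(g.low)
    sires = animals.set_index("animal_id")["sire_id"]
    for side in (g.high, g.low):
        assert sires.loc[list(side)].value_counts().max() <= max_per_sire


class TestVerifyGroupSeparation:
    def test_identical_samples_give_p_one(self):
        p, degenerate = verify_group_separation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)
        assert not degenerate

    def test_matches_closed_form_pooled_t(self):
        high = np.array([2.0, 2.1, 1.9])
        low = np.array([0.0, 0.1, -0.1])
        # independent closed-form pooled-variance t and Student CDF
        n1, n2 = len(high), len(low)
        sp2 = ((n1 - 1) * high.var(ddof=1) + (n2 - 1) * low.var(ddof=1)) / (n1 + n2 - 2)
        t = (high.mean() - low.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        expected = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        p, _ = verify_group_separation(high, low)
        assert p == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_unequal_means_is_degenerate(self):
        p, degenerate = verify_group_separation([1.0, 1.0], [0.0, 0.0])
        assert p == 0.0
        assert degenerate


class TestCorrelationMatrix:
    def test_known_values_and_symmetry(self):
        gebv = pd.DataFrame(
            {
                "animal_id": list("abcde"),
                "x": [1, 2, 3, 4, 5],
                "y": [2, 1, 4, 3, 5],
                "neg": [-1, -2, -3, -4, -5],
            }
        )
        corr = gebv_correlation_matrix(gebv)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)
        assert corr.loc["x", "y"] == pytest.approx(0.8)
        assert np.array_equal(corr.to_numpy(), corr.to_numpy().T)

    def test_constant_trait_reported_missing(self):
        gebv = pd.DataFrame(
            {"animal_id": list("abcd"), "x": [1, 2, 3, 4], "flat": [7, 7, 7, 7]}
        )
        corr = gebv_correlation_matrix(gebv)
        assert np.isnan(corr.loc["x", "flat"])
        signs = classify_correlation_signs(corr)
        assert signs.loc["x", "flat"] == "missing"
        assert signs.loc["x", "x"] == "positive"
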