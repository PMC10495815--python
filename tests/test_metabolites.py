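"""Dynamic-tolerance accurate-mass annotation and ion filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import syncomics as sc
from syncomics.metabolites import (
    C13_SHIFT,
    PROTON,
    filter_annotated_ions,
    mass_tolerance,
    quantile_normalize,
)

HEXOSE = 180.06339


class TestMassTolerance:
    def test_anchor_points(self):
        assert mass_tolerance(50.0) == pytest.approx(1e-3, abs=1e-12)
        assert mass_tolerance(1000.0) == pytest.approx(5e-3, abs=1e-12)

    def test_linear_midpoint(self):
        assert mass_tolerance(525.0) == pytest.approx(3e-3, abs=1e-12)

    def test_clamped_outside_acquisition_range(self):
        assert mass_tolerance(10.0) == mass_tolerance(50.0)
        assert mass_tolerance(2000.0) == mass_tolerance(1000.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(50, 1000), st.floats(50, 1000))
    def test_non_decreasing(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert mass_tolerance(lo) <= mass_tolerance(hi) + 1e-15


class TestCandidateEnumeration:
    def test_protonated_hexose(self):
        cand = sc.enumerate_candidate_mz(HEXOSE, "positive")
        mh = cand[(cand["adduct"] == "[M+H]") & (cand["n_13c"] == 0)]["mz"].iloc[0]
        assert mh == pytest.approx(181.07067, abs=1e-5)

    def test_deprotonated_hexose(self):
        cand = sc.enumerate_candidate_mz(HEXOSE, "negative")
        mh = cand[(cand["adduct"] == "[M-H]") & (cand["n_13c"] == 0)]["mz"].iloc[0]
        assert mh == pytest.approx(179.05611, abs=1e-5)

    def test_isotope_shift_on_singly_charged(self):
        cand = sc.enumerate_candidate_mz(HEXOSE, "positive").set_index(["adduct", "n_13c"])
        d = cand.loc[("[M+H]", 1), "mz"] - cand.loc[("[M+H]", 0), "mz"]
        assert d == pytest.approx(C13_SHIFT, abs=1e-9)

    def test_doubly_deprotonated_is_half_mass(self):
        cand = sc.enumerate_candidate_mz(HEXOSE, "negative").set_index(["adduct", "n_13c"])
        assert cand.loc[("[M-2H]", 0), "mz"] == pytest.approx((HEXOSE - 2 * PROTON) / 2, abs=1e-9)


class TestQuantileNormalization:
    def test_order_statistic_means(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}, index=list("xyz"))
        pol = pd.Series("negative", index=mat.index)
        out = quantile_normalize(mat, pol)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_are_fixed_point(self):
        mat = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]}, index=list("xyz"))
        pol = pd.Series("negative", index=mat.index)
        out = quantile_normalize(mat, pol)
        pd.testing.assert_frame_equal(out, mat)

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.lists(st.floats(0, 1e6, allow_nan=False), min_size=4, max_size=4),
            min_size=3,
            max_size=12,
        )
    )
    def test_columns_share_one_multiset(self, rows):
        # tie-free columns: ties are averaged within a column and then no
        # longer share the exact reference multiset
        mat = pd.DataFrame(rows, columns=list("abcd"))
        for col in mat.columns:
            # offset larger than the value range makes each column injective
            mat[col] = mat[col].to_numpy() + np.arange(len(mat)) * 2e6
        pol = pd.Series("negative", index=mat.index)
        out = quantile_normalize(mat, pol)
        ref = np.sort(out["a"].to_numpy())
        for col in "bcd":
            np.testing.assert_allclose(np.sort(out[col].to_numpy()), ref, rtol=1e-9)

    def test_polarities_normalized_independently(self):
        mat = pd.DataFrame(
            {"a": [1.0, 2.0, 100.0, 200.0], "b": [3.0, 4.0, 300.0, 400.0]},
            index=list("wxyz"),
        )
        pol = pd.Series(["negative", "negative", "positive", "positive"], index=mat.index)
        out = quantile_normalize(mat, pol)
        assert out.loc[["w", "x"]].max().max() < out.loc[["y", "z"]].min().min()


class TestAnnotation:
    def refs(self):
        return pd.DataFrame(
            {
                "metabolite_id": ["hexose"],
                "name": ["hexose"],
                "monoisotopic_mass": [HEXOSE],
                "pathway_ids": ["path001"],
            }
        )

    def test_hexose_ion_annotated_within_tolerance(self):
        ions = pd.DataFrame(
            {"ion_id": ["i1"], "mz": [179.0561], "polarity": ["negative"]}
        )
        ann = sc.annotate_ions(ions, self.refs())
        assert len(ann) == 1
        assert ann.iloc[0]["adduct"] == "[M-H]"
        assert abs(ann.iloc[0]["delta_mda"]) <= mass_tolerance(179.0561) * 1e3

    def test_far_ion_gets_no_annotation(self):
        ions = pd.DataFrame({"ion_id": ["i1"], "mz": [300.0], "polarity": ["negative"]})
        assert sc.annotate_ions(ions, self.refs()).empty

    def test_annotation_independent_of_ion_order(self, truth, small_community, noise_free):
        refs = sc.build_metabolite_reference(n_metabolites=15, seed=3)
        ions = sc.simulate_layer_observations(
            truth, small_community, "metabolome", 0, noise_free, seed=3, metabolite_refs=refs
        )
        a = sc.annotate_ions(ions, refs)
        b = sc.annotate_ions(ions.iloc[::-1], refs)
        key = ["ion_id", "metabolite_id", "adduct", "n_13c"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )


class TestIonFiltering:
    def test_pure_isotopologue_ions_removed(self):
        samples = ["s1", "s2", "s3"]
        ions = pd.DataFrame(
            {
                "ion_id": ["mono", "iso"],
                "mz": [179.05611, 179.05611 + C13_SHIFT],
                "polarity": ["negative", "negative"],
                "s1": [100.0, 5.0],
                "s2": [110.0, 6.0],
                "s3": [120.0, 7.0],
            }
        )
        ann = pd.DataFrame(
            {
                "ion_id": ["mono", "iso"],
                "metabolite_id": ["hexose", "hexose"],
                "adduct": ["[M-H]", "[M-H]"],
                "n_13c": [0, 1],
                "delta_mda": [0.0, 0.0],
            }
        )
        retained, rep = filter_annotated_ions(ions, ann, samples)
        assert list(retained["ion_id"]) == ["mono"]
        assert list(rep["ion_id"]) == ["mono"]

    def test_tic_correlation_picks_representative(self):
        samples = ["s1", "s2", "s3", "s4", "s5"]
        tracking = [10.0, 20.0, 30.0, 40.0, 50.0]  # follows TIC
        flat = [30.0, 31.0, 29.0, 30.5, 30.0]
        ions = pd.DataFrame(
            {
                "ion_id": ["good", "bad", "big"],
                "mz": [179.056, 181.071, 500.0],
                "polarity": ["negative", "positive", "negative"],
                **{
                    s: [tracking[i], flat[i], 1000.0 + 100 * i]
                    for i, s in enumerate(samples)
                },
            }
        )
        ann = pd.DataFrame(
            {
                "ion_id": ["good", "bad"],
                "metabolite_id": ["hexose", "hexose"],
                "adduct": ["[M-H]", "[M+H]"],
                "n_13c": [0, 0],
                "delta_mda": [0.5, 0.1],
            }
        )
        retained, rep = filter_annotated_ions(ions, ann, samples)
        assert rep.set_index("metabolite_id").loc["hexose", "ion_id"] == "good"
        # unannotated 'big' ion dropped
        assert set(retained["ion_id"]) == {"good"}

    def test_each_metabolite_maps_to_at_most_one_ion(
        self, truth, small_community, noise_free
    ):
        refs = sc.build_metabolite_reference(n_metabolites=25, seed=5)
        ions = sc.simulate_layer_observations(
            truth, small_community, "metabolome", 0, noise_free, seed=5, metabolite_refs=refs
        )
        samples = list(truth.abundance.columns)
        ann = sc.annotate_ions(ions, refs)
        retained, rep = filter_annotated_ions(ions, ann, samples)
        assert rep["metabolite_id"].is_unique
        assert len(retained) <= len(ions)


def test_simulation_recall_with_third_of_tolerance_mass_error(
    truth, small_community
):
    """At mass-error sigma = tol/3 the annotator recovers nearly every ion and
    never accepts a match outside tolerance."""
    refs = sc.build_metabolite_reference(n_metabolites=40, seed=9)
    noise = sc.NoiseParams(mass_error_scale=1 / 3, intensity_sigma=0.0)
    ions = sc.simulate_layer_observations(
        truth, small_community, "metabolome", 0, noise, seed=9, metabolite_refs=refs
    )
    ann = sc.annotate_ions(ions, refs)
    real = ions[ions["true_metabolite"] != ""]
    hits = ann.merge(
        real[["ion_id", "true_metabolite"]], on="ion_id"
    ).query("metabolite_id == true_metabolite")
    recall = hits["ion_id"].nunique() / real["ion_id"].nunique()
    assert recall >= 0.99
    mz = ions.set_index("ion_id")["mz"]
    tol_mda = mass_tolerance(mz.loc[ann["ion_id"]].to_numpy()) * 1e3
    assert (ann["delta_mda"].abs().to_numpy() <= tol_mda + 1e-9).all()
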