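"""Normalization, group statistics, rank-sum tests and classification."""

import json
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensmut.integrate_report import (
    DESCRIPTORS,
    DescriptorProfile,
    classify_unknown,
    group_medians,
    normalize_series,
    profiles_from_descriptor_rows,
    quadrant_projection,
    radar_export,
    rank_sum_test,
)
from ensmut.mutation_catalog import load_descriptor_table, packaged_path


@pytest.fixture(scope="module")
def table2_profiles():
    return profiles_from_descriptor_rows(
        load_descriptor_table(packaged_path("descriptors"))
    )


class TestNormalizeSeries:
    def test_max_division(self):
        norm, flags = normalize_series([2.0, 4.0, 1.0])
        assert norm == pytest.approx([0.5, 1.0, 0.25])
        assert not flags.any()

    def test_cap_truncates_and_flags(self):
        norm, flags = normalize_series([22.0, 10.175], cap=20.35)
        assert norm[0] == 1.0 and flags[0]
        assert norm[1] == pytest.approx(0.5) and not flags[1]

    def test_all_zero_series_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            norm, _ = normalize_series([0.0, 0.0])
        assert np.allclose(norm, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1000.0), min_size=1, max_size=30
        )
    )
    def test_idempotent_without_cap(self, values):
        once, _ = normalize_series(values)
        twice, _ = normalize_series(once)
        assert np.allclose(once, twice)
        assert once.max() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=50.0), min_size=1, max_size=30
        ),
        st.floats(min_value=1.0, max_value=30.0),
    )
    def test_cap_bounds_and_order(self, values, cap):
        norm, flags = normalize_series(values, cap=cap)
        assert (norm >= 0).all() and (norm <= 1).all()
        assert np.array_equal(flags, np.asarray(values) > cap)
        # capped entries map to exactly 1
        assert np.allclose(norm[flags], 1.0)


class TestGroupMedians:
    def test_packaged_folding_mi_median(self, table2_profiles):
        summaries = group_medians(table2_profiles, ("folding",))
        assert summaries[0].medians["total_dihedral_mi"] == pytest.approx(
            0.181
        )

    def test_packaged_activity_ddg_median(self, table2_profiles):
        summaries = group_medians(table2_profiles, ("activity",))
        assert summaries[0].medians["ddg_norm"] == pytest.approx(0.208)

    def test_single_member_group(self):
        p = DescriptorProfile(
            "A1G", "A", "solo",
            dict(zip(DESCRIPTORS, [0.1, 0.2, 0.3, 0.4])),
        )
        s = group_medians([p], ("solo",))[0]
        assert s.medians == dict(zip(DESCRIPTORS, [0.1, 0.2, 0.3, 0.4]))

    def test_medians_recomputable_independently(self, table2_profiles):
        summaries = group_medians(table2_profiles, ("folding", "activity"))
        for s in summaries:
            members = [
                p for p in table2_profiles
                if p.group == s.group and not p.active_site
            ]
            vals = sorted(p.values["total_dihedral_mi"] for p in members)
            n = len(vals)
            expected = (
                vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
            )
            assert s.medians["total_dihedral_mi"] == pytest.approx(
                expected, abs=1e-12
            )

    def test_empty_group_warns(self, table2_profiles):
        with pytest.warns(UserWarning, match="no members"):
            out = group_medians(table2_profiles, ("nonexistent",))
        assert out == []


class TestRankSum:
    def test_fully_separated_exact_p(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_exact_equals_enumeration_for_small_groups(self):
        rng = np.random.default_rng(60)
        for n_a in (2, 3, 4, 5):
            for n_b in (2, 3, 5):
                if n_a + n_b > 10:
                    continue
                pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
                a, b = pooled[:n_a], pooled[n_a:]
                u_obs, p_obs = rank_sum_test(a, b)
                # independent enumeration over all group-a rank subsets
                n = n_a + n_b
                us = []
                for c in combinations(range(1, n + 1), n_a):
                    us.append(sum(c) - n_a * (n_a + 1) / 2)
                us = np.array(us)
                total = comb(n, n_a)
                p_ref = min(
                    1.0,
                    2 * min(
                        (us <= u_obs).sum() / total,
                        (us >= u_obs).sum() / total,
                    ),
                )
                assert p_obs == pytest.approx(p_ref, abs=1e-12)

    def test_asymptotic_close_to_exact_at_6_plus_6(self):
        rng = np.random.default_rng(61)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        _, p_exact = rank_sum_test(a, b)  # 12 values, no ties -> exact
        from scipy import stats

        p_asym = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(p_exact - p_asym) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestClassification:
    def test_profile_at_median_distance_zero(self, table2_profiles):
        summaries = group_medians(table2_profiles, ("folding", "activity"))
        target = summaries[0]
        p = DescriptorProfile(
            "X1Y", "A", "unclassified", dict(target.medians)
        )
        group, dist = classify_unknown(p, summaries)
        assert group == "folding"
        assert dist["folding"] == pytest.approx(0.0, abs=1e-12)

    def test_tie_reported_not_resolved(self):
        summaries = group_medians(
            [
                DescriptorProfile("A1G", "A", "g1",
                                  dict(zip(DESCRIPTORS, [0.0, 0.5, 0.5, 0.5]))),
                DescriptorProfile("A2G", "A", "g2",
                                  dict(zip(DESCRIPTORS, [1.0, 0.5, 0.5, 0.5]))),
            ],
            ("g1", "g2"),
        )
        probe = DescriptorProfile(
            "A3G", "A", "unclassified",
            dict(zip(DESCRIPTORS, [0.5, 0.5, 0.5, 0.5])),
        )
        group, dist = classify_unknown(probe, summaries)
        assert group is None
        assert dist["g1"] == pytest.approx(dist["g2"])

    def test_g801d_distances_match_hand_computation(self, table2_profiles):
        summaries = group_medians(table2_profiles, ("folding", "activity"))
        g801d = next(p for p in table2_profiles if p.mutation == "G801D")
        _, dist = classify_unknown(g801d, summaries)
        for s in summaries:
            expected = np.sqrt(
                sum(
                    (g801d.values[d] - s.medians[d]) ** 2 for d in DESCRIPTORS
                )
            )
            assert dist[s.group] == pytest.approx(expected, abs=1e-12)


class TestQuadrantsAndRadar:
    @pytest.mark.parametrize(
        "mi,b2b,expected",
        [
            (0.9, 0.9, "high-MI/high-b2b"),
            (0.5, 0.5, "high-MI/high-b2b"),  # boundary -> high by >= rule
            (0.1, 0.9, "low-MI/high-b2b"),
            (0.49, 0.2, "low-MI/low-b2b"),
        ],
    )
    def test_quadrant_labels(self, mi, b2b, expected):
        p = DescriptorProfile(
            "A1G", "A", "folding",
            dict(zip(DESCRIPTORS, [mi, 0.5, 0.5, b2b])),
        )
        assert quadrant_projection([p])["A1G"] == expected

    def test_radar_export_shape(self, tmp_path, table2_profiles):
        summaries = group_medians(table2_profiles, ("folding", "activity"))
        out = tmp_path / "radar.json"
        payload = radar_export(table2_profiles, summaries, out)
        disk = json.loads(out.read_text())
        assert disk["axes"] == list(DESCRIPTORS)
        assert len(disk["mutations"]) == 43
        assert len(disk["group_medians"]) == 2
        for m in disk["mutations"]:
            assert len(m["values"]) == 4
            assert all(0.0 <= v <= 1.0 for v in m["values"])

    def test_out_of_range_profile_refused(self):
        with pytest.raises(ValueError):
            DescriptorProfile(
                "A1G", "A", "folding",
                dict(zip(DESCRIPTORS, [1.5, 0.5, 0.5, 0.5])),
            )


class TestBuildProfiles:
    def test_pipeline_assembly_with_flags(self):
        import pandas as pd

        from ensmut.integrate_report import build_profiles
        from ensmut.mutation_catalog import MutationRecord
        from ensmut.stability import EnsembleDdgResult

        catalog = [
            MutationRecord("A", 5, "P", "A", "folding", 10.0, 20.0, "Loop", ()),
            MutationRecord("L", 7, "S", "A", "activity", 20.0, 10.0, "Loop", ()),
            MutationRecord("H", 9, "L", "A", "activity", 15.0, 4.0,
                           "Active site", ()),
        ]
        ddg = [
            EnsembleDdgResult("A5P", np.array([25.0, 25.0]), np.arange(2)),
            EnsembleDdgResult("L7S", np.array([2.0, 4.0]), np.arange(2)),
            EnsembleDdgResult("H9L", np.array([0.5, 0.7]), np.arange(2)),
        ]
        mi = pd.DataFrame(
            {"residue_index": [5, 7, 9], "total_mi": [2.0, 4.0, 1.0]}
        )
        b2b = pd.DataFrame(
            {"residue_index": [5, 7, 9], "score": [0.3, 0.6, 0.9]}
        )
        profiles = build_profiles(
            ddg, mi, b2b, catalog, cap=20.35, active_site_residues=(9,)
        )
        by_name = {p.mutation: p for p in profiles}
        assert by_name["A5P"].values["ddg_norm"] == 1.0
        assert "ddg_norm" in by_name["A5P"].capped
        assert by_name["L7S"].values["total_dihedral_mi"] == 1.0
        assert by_name["H9L"].values["total_dihedral_mi"] == 0.0
        assert by_name["H9L"].active_site

    def test_empty_catalog_empty_profiles(self):
        from ensmut.integrate_report import build_profiles

        assert build_profiles([], {}, {}, []) == []
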