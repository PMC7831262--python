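"""POC normalisation, control QC, 3-SD dual-channel hit calling, enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from phenoscreen import (
    call_hits,
    class_enrichment,
    control_stats,
    hypertrophy_assess,
    poc_normalize,
    reconcile_screens,
    screen_qc,
)
from phenoscreen.errors import (
    DegenerateControlError,
    InputConsistencyError,
    InsufficientReplicatesError,
)
from phenoscreen.platescreen import ChannelSummary, ControlSummary


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) by rational combinatorial sum (independent of scipy)."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    )
    return Fraction(total, denom)


class TestPocNormalize:
    @pytest.mark.parametrize(
        "controls, value, expected",
        [
            ([100, 100, 100], 150, 150.0),
            ([100, 100, 100], 100, 100.0),
            ([90, 110], 120, 120.0),
        ],
    )
    def test_hand_values(self, controls, value, expected):
        assert poc_normalize([value], controls)[0] == pytest.approx(expected)

    @given(
        st.lists(st.floats(1.0, 1e4, allow_nan=False), min_size=2, max_size=30)
    )
    def test_controls_average_exactly_100(self, controls):
        assert np.mean(poc_normalize(controls, controls)) == pytest.approx(
            100.0, rel=1e-9
        )

    def test_degenerate_control_mean(self):
        with pytest.raises(DegenerateControlError):
            poc_normalize([1.0], [0.0, 0.0])

    def test_single_control_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            poc_normalize([1.0], [100.0])


class TestControlStats:
    def test_hand_formula(self, small_plate):
        s = control_stats(small_plate, "control_1x")
        ch = s.channels["nuclei_count"]
        assert ch.mean == pytest.approx(100.0)
        assert ch.sd == pytest.approx(np.sqrt(250 / 3))
        assert ch.cv == pytest.approx(np.sqrt(250 / 3) / 100)
        assert not ch.degenerate

    def test_two_point_sd(self):
        ch = ChannelSummary.from_values([90, 110])
        assert ch.sd == pytest.approx(14.142, abs=1e-3)
        assert ch.cv == pytest.approx(0.14142, abs=1e-5)

    def test_degenerate_flag(self):
        assert ChannelSummary.from_values([100, 100, 100]).degenerate

    @given(st.permutations([90.0, 110.0, 95.0, 105.0, 130.0]))
    def test_permutation_invariant(self, values):
        ch = ChannelSummary.from_values(values)
        assert ch.mean == pytest.approx(106.0)
        assert ch.sd == pytest.approx(np.std([90, 110, 95, 105, 130], ddof=1))

    def test_insufficient_wells(self, small_plate):
        with pytest.raises(InsufficientReplicatesError):
            control_stats(small_plate.iloc[:1], "control_1x")


def _summary(mean, sd, n=10):
    ch = {
        c: ChannelSummary(n=n, mean=mean, sd=sd, cv=sd / mean, degenerate=sd == 0)
        for c in ("nuclei_count", "gfp_area")
    }
    return ControlSummary(role="x", channels=ch)


class TestScreenQC:
    def test_hand_formula(self):
        qc = screen_qc(_summary(100, 10), _summary(200, 10))
        assert qc.ssmd["nuclei_count"] == pytest.approx(100 / np.sqrt(200))
        assert qc.ssmd["nuclei_count"] == pytest.approx(7.071, abs=1e-3)
        assert qc.signal_to_noise["nuclei_count"] == pytest.approx(10.0)

    def test_equal_means_zero_ssmd(self):
        qc = screen_qc(_summary(100, 10), _summary(100, 5))
        assert qc.ssmd["gfp_area"] == 0.0

    def test_swap_flips_sign(self):
        a, b = _summary(100, 10), _summary(180, 14)
        assert screen_qc(a, b).ssmd["nuclei_count"] == pytest.approx(
            -screen_qc(b, a).ssmd["nuclei_count"]
        )

    def test_both_sds_zero_error(self):
        with pytest.raises(DegenerateControlError):
            screen_qc(_summary(100, 0), _summary(200, 0))


class TestCallHits:
    def test_dual_channel_rule(self, small_plate):
        calls = call_hits(small_plate).set_index("compound_id")
        assert calls.loc["strong", "is_hit"]
        assert calls.loc["nuclei_only", "hit_nuclei"]
        assert not calls.loc["nuclei_only", "is_hit"]
        assert not calls.loc["null", "is_hit"]

    def test_boundary_is_not_a_hit(self, small_plate):
        s = control_stats(small_plate, "control_1x")
        thr_n = s.channels["nuclei_count"].mean + 3 * s.channels["nuclei_count"].sd
        thr_a = s.channels["gfp_area"].mean + 3 * s.channels["gfp_area"].sd
        plate = small_plate.astype({"nuclei_count": float, "gfp_area": float})
        plate.loc[plate["compound_id"] == "null", ["nuclei_count", "gfp_area"]] = (
            thr_n, thr_a,
        )
        calls = call_hits(plate).set_index("compound_id")
        assert not calls.loc["null", "is_hit"]
        assert calls.loc["null", "boundary_tie"]

    def test_poc_matches_normalization(self, small_plate):
        calls = call_hits(small_plate).set_index("compound_id")
        assert calls.loc["strong", "poc_nuclei"] == pytest.approx(160.0)
        assert calls.loc["strong", "poc_area"] == pytest.approx(160.0)
        assert calls.loc["strong", "hypertrophy_ratio"] == pytest.approx(1.0)

    def test_degenerate_controls_error(self, small_plate):
        plate = small_plate.copy()
        plate.loc[plate["role"] == "control_1x", "nuclei_count"] = 100
        with pytest.raises(DegenerateControlError):
            call_hits(plate)

    def test_per_plate_pooling_mode(self, small_plate):
        two = pd.concat(
            [small_plate, small_plate.assign(plate_id=2)], ignore_index=True
        )
        screen_calls = call_hits(two, pooling="screen")
        plate_calls = call_hits(two, pooling="plate")
        assert len(screen_calls) == len(plate_calls) == 6
        assert sorted(screen_calls.loc[screen_calls["is_hit"], "compound_id"]) == sorted(
            plate_calls.loc[plate_calls["is_hit"], "compound_id"]
        )


@given(scale=st.floats(1e-3, 1e3, allow_nan=False))
def test_hit_calls_invariant_to_channel_rescaling(scale):
    """The 3-SD criterion is affine-equivariant: multiplying one channel's
    units by any positive factor changes no flag."""
    rows = []
    for i, (n, a) in enumerate(zip([90, 110, 95, 105], [360, 440, 380, 420])):
        rows.append((1, f"A{i + 1}", "control_1x", None, 0.0, n, a))
    rows.append((1, "C1", "compound", "up", 1.0, 150, 800))
    rows.append((1, "C2", "compound", "flat", 1.0, 101, 401))
    plate = pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "compound_id", "conc_um",
                       "nuclei_count", "gfp_area"],
    )
    base = call_hits(plate)
    scaled = plate.assign(gfp_area=plate["gfp_area"] * scale)
    rescaled = call_hits(scaled)
    pd.testing.assert_frame_equal(
        base[["compound_id", "hit_nuclei", "hit_area", "is_hit"]],
        rescaled[["compound_id", "hit_nuclei", "hit_area", "is_hit"]],
    )


class TestReconcileScreens:
    def test_seven_plus_six_sharing_one_gives_twelve(self):
        s1 = ["pred", "thiazovivin", "mk0431", "incb024360", "guanabenz",
              "odanacatib", "na_butyrate"]
        s2 = ["pred", "dex", "u1", "u2", "u3", "u4"]
        res = reconcile_screens([s1, s2])
        assert res["per_screen_counts"] == [7, 6]
        assert res["n_unique"] == 12
        assert res["intersection"] == ["pred"]

    def test_identical_lists(self):
        res = reconcile_screens([["a", "b"], ["a", "b"]])
        assert res["union"] == res["intersection"] == ["a", "b"]

    def test_disjoint_lists(self):
        res = reconcile_screens([["a", "b"], ["c"]])
        assert res["n_unique"] == 3
        assert res["intersection"] == []

    def test_duplicates_rejected(self):
        with pytest.raises(InputConsistencyError):
            reconcile_screens([["a", "a"]])

    @given(
        st.lists(
            st.sets(st.integers(0, 20), max_size=10).map(sorted),
            min_size=1, max_size=4,
        )
    )
    def test_cardinality_ordering(self, lists):
        res = reconcile_screens(lists)
        counts = res["per_screen_counts"]
        assert len(res["intersection"]) <= min(counts)
        assert min(counts) <= res["n_unique"] <= sum(counts)


def _library(N, K, class_name="GC"):
    ids = [f"c{i}" for i in range(N)]
    classes = [class_name if i < K else "other" for i in range(N)]
    return pd.DataFrame({"compound_id": ids, "class": classes})


class TestClassEnrichment:
    def test_screen_geometry_value_fixed_by_oracle(self):
        lib = _library(400, 4)
        hits = ["c0", "c1"] + [f"c{i}" for i in range(100, 110)]  # k=2 of n=12
        res = class_enrichment(lib, hits, "GC")
        oracle = float(hypergeom_tail_oracle(400, 4, 12, 2))
        assert res.p_tail == pytest.approx(oracle, rel=1e-12)
        assert res.p_tail == pytest.approx(0.00479757, abs=1e-8)

    def test_k_zero_gives_one(self):
        lib = _library(50, 5)
        res = class_enrichment(lib, [f"c{i}" for i in range(10, 16)], "GC")
        assert res.class_hits == 0
        assert res.p_tail == 1.0

    def test_whole_library_in_class_gives_one(self):
        lib = _library(20, 20)
        res = class_enrichment(lib, ["c0", "c1", "c2"], "GC")
        assert res.p_tail == pytest.approx(1.0)

    def test_hit_outside_library_rejected(self):
        with pytest.raises(InputConsistencyError):
            class_enrichment(_library(10, 2), ["zzz"], "GC")

    def test_unknown_class_rejected(self):
        with pytest.raises(InputConsistencyError):
            class_enrichment(_library(10, 2), ["c0"], "steroid")

    @pytest.mark.parametrize("N", [5, 9, 16])
    def test_exhaustive_oracle_small_libraries(self, N):
        for K in range(0, N + 1):
            lib = _library(N, K)
            for n in range(1, N + 1):
                hits = [f"c{i}" for i in range(n)]
                res = class_enrichment(lib, hits, "GC") if K else None
                if K == 0:
                    continue
                k = res.class_hits
                oracle = float(hypergeom_tail_oracle(N, K, n, k))
                assert res.p_tail == pytest.approx(oracle, rel=1e-10)


class TestHypertrophy:
    def test_ratio_one_not_flagged(self):
        calls = pd.DataFrame(
            {"compound_id": ["pred"], "poc_nuclei": [200.0], "poc_area": [200.0]}
        )
        out = hypertrophy_assess(calls)
        assert out["hypertrophy_ratio"].iloc[0] == pytest.approx(1.0)
        assert not out["hypertrophy_flag"].iloc[0]

    def test_ratio_two_flagged(self):
        calls = pd.DataFrame(
            {"compound_id": ["x"], "poc_nuclei": [150.0], "poc_area": [300.0]}
        )
        out = hypertrophy_assess(calls)
        assert out["hypertrophy_ratio"].iloc[0] == pytest.approx(2.0)
        assert out["hypertrophy_flag"].iloc[0]

    def test_zero_nuclei_reported_undefined(self):
        calls = pd.DataFrame(
            {"compound_id": ["x"], "poc_nuclei": [0.0], "poc_area": [50.0]}
        )
        out = hypertrophy_assess(calls)
        assert out["undefined_ratio"].iloc[0]
        assert np.isnan(out["hypertrophy_ratio"].iloc[0])
        assert not out["hypertrophy_flag"].iloc[0]

    @given(poc=st.floats(1.0, 1e4, allow_nan=False))
    def test_equal_pocs_always_ratio_one(self, poc):
        calls = pd.DataFrame(
            {"compound_id": ["x"], "poc_nuclei": [poc], "poc_area": [poc]}
        )
        assert hypertrophy_assess(calls)["hypertrophy_ratio"].iloc[0] == pytest.approx(1.0)
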