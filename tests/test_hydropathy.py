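import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dotscreen.hydropathy import (
    KYTE_DOOLITTLE,
    InvalidResidueError,
    build_reporter,
    filter_substrates,
    group_profile,
    kd_values,
    swap_prefix,
)

AA = st.sampled_from(sorted(KYTE_DOOLITTLE))
SEQ = st.text(alphabet=sorted(KYTE_DOOLITTLE), min_size=1, max_size=30)


class TestKdValues:
    def test_extremes_of_the_scale(self):
        assert kd_values("I").tolist() == [4.5]
        assert kd_values("R").tolist() == [-4.5]

    def test_known_track(self):
        np.testing.assert_allclose(kd_values("MKF"), [1.9, -3.9, 2.8])

    def test_invalid_residue_names_position(self):
        with pytest.raises(InvalidResidueError, match=r"'X' at position 3"):
            kd_values("MKXF")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kd_values("")

    @settings(max_examples=50, derandomize=True)
    @given(SEQ)
    def test_values_within_scale_bounds(self, seq):
        vals = kd_values(seq)
        assert len(vals) == len(seq)
        assert np.all(vals >= -4.5) and np.all(vals <= 4.5)


class TestGroupProfile:
    def test_hand_checked_mean(self):
        # brute-force oracle: position-1 mean of Ile (4.5) and Ala (1.8)
        prof = group_profile(["II", "AA"])
        assert prof.mean_kd[0] == pytest.approx((4.5 + 1.8) / 2)
        assert prof.mean_kd[0] == pytest.approx(3.15)
        assert prof.n.tolist() == [2, 2]

    def test_single_sequence_has_zero_sem(self):
        prof = group_profile(["MKFLIV"])
        np.testing.assert_array_equal(prof.sem_kd, 0.0)
        np.testing.assert_allclose(prof.mean_kd, kd_values("MKFLIV"))

    def test_identical_sequences_roundtrip_kd_values(self):
        prof = group_profile(["MAGIC"] * 5)
        np.testing.assert_allclose(prof.mean_kd, kd_values("MAGIC"))
        np.testing.assert_array_equal(prof.sem_kd, 0.0)

    def test_duplication_preserves_mean_and_shrinks_sem(self):
        rng = np.random.default_rng(1)
        seqs = [
            "".join(rng.choice(sorted(KYTE_DOOLITTLE), 12)) for _ in range(10)
        ]
        base = group_profile(seqs)
        dup = group_profile(seqs + seqs)
        np.testing.assert_allclose(dup.mean_kd, base.mean_kd)
        # sample SD makes the shrink sqrt((n-1)/(2n-1)), ~1/sqrt(2) at n=10
        np.testing.assert_allclose(
            dup.sem_kd, base.sem_kd / np.sqrt(2), rtol=0.05
        )

    def test_coverage_nonincreasing_with_variable_lengths(self):
        prof = group_profile(["MKFLIVMKFL", "MKF", "MKFLI"])
        assert prof.n.tolist() == [3, 3, 3, 2, 2, 1, 1, 1, 1, 1]
        assert np.all(np.diff(prof.n) <= 0)

    def test_max_len_truncates(self):
        prof = group_profile(["M" * 40], max_len=25)
        assert len(prof) == 25

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_profile([])

    def test_window_smoothing_optional(self):
        raw = group_profile(["IRIRIRIR"])
        smooth = group_profile(["IRIRIRIR"], window=3)
        assert np.abs(smooth.mean_kd[1:-1]).max() < np.abs(raw.mean_kd).max()


class TestSwapPrefix:
    def test_three_residue_swap(self):
        assert swap_prefix("MKFAB", "MQRCD", 3) == ("MQRAB", "MKFCD")

    def test_zero_k_is_identity(self):
        assert swap_prefix("MKF", "MQR", 0) == ("MKF", "MQR")

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            swap_prefix("MK", "MQRST", 3)

    @settings(max_examples=100, derandomize=True)
    @given(SEQ, SEQ, st.integers(0, 30))
    def test_involution_and_length_preservation(self, s1, s2, k):
        if k > min(len(s1), len(s2)):
            with pytest.raises(ValueError):
                swap_prefix(s1, s2, k)
            return
        v1, v2 = swap_prefix(s1, s2, k)
        assert (len(v1), len(v2)) == (len(s1), len(s2))
        assert swap_prefix(v1, v2, k) == (s1, s2)


class TestBuildReporter:
    def test_record_carries_sp_and_reporter_body(self):
        rec = build_reporter("MKFLIV", donor_id="Pdi1")
        assert rec.sp_sequence == "MKFLIV"
        assert rec.body == ("mCherry", "AviTag")
        assert rec.reporter_id == "Pdi1-reporter"

    def test_empty_sp_rejected(self):
        with pytest.raises(ValueError):
            build_reporter("")

    def test_invalid_sp_rejected(self):
        with pytest.raises(InvalidResidueError):
            build_reporter("MKZ")


def _annotations(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "has_sp", "has_tmd", "has_mts", "sp_sequence"]
    )


class TestFilterSubstrates:
    @pytest.mark.parametrize(
        "has_sp,has_tmd,has_mts,expected",
        [
            (True, False, False, True),   # SP alone qualifies
            (False, True, False, True),   # TMD alone qualifies
            (True, True, False, True),    # both qualify
            (True, False, True, False),   # MTS disqualifies
            (False, False, False, False),
        ],
    )
    def test_candidate_rule(self, has_sp, has_tmd, has_mts, expected):
        pairs = pd.DataFrame({"prey_id": ["p1"], "category": ["both"]})
        ann = _annotations([("p1", has_sp, has_tmd, has_mts, "MKF")])
        out = filter_substrates(pairs, ann)
        assert bool(out.loc[0, "is_candidate"]) is expected

    def test_missing_annotation_flagged_not_dropped(self):
        pairs = pd.DataFrame(
            {"prey_id": ["p1", "p2"], "category": ["both", "both"]}
        )
        ann = _annotations([("p1", True, False, False, "MKF")])
        out = filter_substrates(pairs, ann)
        assert len(out) == 2
        assert out.set_index("prey_id").loc["p2", "annotation_missing"]
        assert not out.set_index("prey_id").loc["p2", "is_candidate"]

    def test_partition_conserves_input(self):
        rng = np.random.default_rng(0)
        n = 40
        pairs = pd.DataFrame(
            {
                "prey_id": [f"p{i}" for i in range(n)],
                "category": rng.choice(["both", "prefers_A", "excluded"], n),
            }
        )
        ann = _annotations(
            [
                (f"p{i}", bool(rng.integers(2)), bool(rng.integers(2)),
                 bool(rng.integers(2)), "MKF")
                for i in range(0, n, 2)  # half the preys annotated
            ]
        )
        out = filter_substrates(pairs, ann)
        n_candidate = out["is_candidate"].sum()
        n_missing = out["annotation_missing"].sum()
        n_non = (~out["is_candidate"] & ~out["annotation_missing"]).sum()
        assert n_candidate + n_missing + n_non == n

    def test_duplicate_annotation_rejected(self):
        pairs = pd.DataFrame({"prey_id": ["p1"], "category": ["both"]})
        ann = _annotations(
            [("p1", True, False, False, "MKF"), ("p1", True, False, False, "MKF")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            filter_substrates(pairs, ann)


class TestSyntheticGroupSeparation:
    def test_distinct_n_terminal_targets_separate_profiles(self):
        """Groups generated with different position-1..3 hydropathy targets
        must separate by more than twice the pooled SEM there."""
        from dotscreen.simulate import generate_sp_set

        groups = generate_sp_set(
            200, 15,
            {"A": [-1.0, -1.0, -1.0] + [2.5] * 12,
             "B": [2.0, 2.0, 2.0] + [2.5] * 12},
            seed=4,
        )
        pa = group_profile(groups["A"], label="A")
        pb = group_profile(groups["B"], label="B")
        for p in range(3):
            gap = abs(pa.mean_kd[p] - pb.mean_kd[p])
            pooled = np.sqrt(pa.sem_kd[p] ** 2 + pb.sem_kd[p] ** 2)
            assert gap > 2 * pooled
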