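import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dielshift import DielMatrix, OrthologGroup
from dielshift.rescheduling import (
    ConstantSeriesError,
    ReschedulingCall,
    call_rescheduled,
    spearman_rho,
)
from dielshift.window_enrichment import EnrichmentCall

GRID_2H = tuple(float(h) for h in range(0, 24, 2))


class TestSpearmanRho:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3, 4), (1, 2, 3, 4), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            # average-rank vectors (1, 2.5, 2.5, 4) and (1, 3, 2, 4)
            ((1, 2, 2, 4), (1, 3, 2, 4), 4.5 / np.sqrt(22.5)),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.integers(0, 5), min_size=3, max_size=20))
    def test_symmetric(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = rng.integers(0, 5, len(xs))
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return
        assert spearman_rho(xs, ys) == pytest.approx(spearman_rho(ys, xs), abs=1e-14)

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y), abs=1e-12)
        assert spearman_rho(x, y**3) == pytest.approx(spearman_rho(x, y), abs=1e-12)

    def test_constant_series_raises(self):
        with pytest.raises(ConstantSeriesError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_antiphase_cosines_give_exactly_minus_one(self):
        from dielshift.synthetic_data import generate_profile

        rng = np.random.default_rng(0)
        x = generate_profile(0.0, 1.0, 2.0, 0.0, GRID_2H, rng)   # dawn peak
        y = generate_profile(12.0, 1.0, 2.0, 0.0, GRID_2H, rng)  # dusk peak
        assert spearman_rho(x, y) == -1.0
        assert spearman_rho(x, x + 1.0) == 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [2, 1])


def enrichment_call(gene, phase):
    sig = phase != "neither"
    p = 1e-6 if sig else 0.8
    return EnrichmentCall(
        gene_id=gene,
        dusk_sum=450 if phase == "dusk" else 50,
        dawn_sum=450 if phase == "dawn" else 50,
        p_dusk=p if phase == "dusk" else 0.9,
        p_dawn=p if phase == "dawn" else 0.9,
        q_dusk=p if phase == "dusk" else 0.9,
        q_dawn=p if phase == "dawn" else 0.9,
        phase=phase,
    )


# five-point series with known Spearman correlations against (1,2,3,4,5):
BASE = (1.0, 2.0, 3.0, 4.0, 5.0)
REVERSED = (5.0, 4.0, 3.0, 2.0, 1.0)        # rho = -1
RHO_M05 = (5.0, 2.0, 4.0, 1.0, 3.0)          # rho = -0.5
RHO_M06 = (4.0, 5.0, 1.0, 3.0, 2.0)          # rho = -0.6 exactly (boundary)
GRID_5 = (0.0, 2.0, 4.0, 6.0, 8.0)


def trio_setup(cam_row, a_row, b_row, phases=("dusk", "dawn", "dawn")):
    matrices = {
        "cam": DielMatrix("cam", GRID_5, ("k1",), np.asarray([cam_row])),
        "c3a": DielMatrix("c3a", GRID_5, ("a1",), np.asarray([a_row])),
        "c3b": DielMatrix("c3b", GRID_5, ("b1",), np.asarray([b_row])),
    }
    calls = {
        "cam": {"k1": enrichment_call("k1", phases[0])},
        "c3a": {"a1": enrichment_call("a1", phases[1])},
        "c3b": {"b1": enrichment_call("b1", phases[2])},
    }
    og = OrthologGroup("OG1", {"cam": ("k1",), "c3a": ("a1",), "c3b": ("b1",)})
    return og, calls, matrices


class TestCallRescheduled:
    def test_opposite_windows_and_strong_anticorrelation_pass(self):
        og, calls, matrices = trio_setup(BASE, REVERSED, REVERSED)
        (res,) = call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"])
        assert res.criterion1_pass and res.criterion2_pass and res.rescheduled
        assert res.rho_cam_c3 == {"c3a": -1.0, "c3b": -1.0}
        assert res.rho_c3_c3 == 1.0

    def test_weak_anticorrelation_with_one_ortholog_fails(self):
        # rho(cam, a) = -0.5 does not clear the < -0.6 threshold
        og, calls, matrices = trio_setup(BASE, RHO_M05, REVERSED)
        (res,) = call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"])
        assert res.criterion1_pass
        assert not res.criterion2_pass and not res.rescheduled

    def test_boundary_rho_exactly_minus_point_six_fails(self):
        og, calls, matrices = trio_setup(BASE, RHO_M06, REVERSED)
        (res,) = call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"])
        assert res.rho_cam_c3["c3a"] == pytest.approx(-0.6, abs=1e-12)
        assert not res.criterion2_pass

    def test_cam_phase_neither_fails_regardless_of_correlations(self):
        og, calls, matrices = trio_setup(
            BASE, REVERSED, REVERSED, phases=("neither", "dawn", "dawn")
        )
        (res,) = call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"])
        assert not res.criterion1_pass and not res.rescheduled

    def test_disagreeing_c3_phases_never_rescheduled(self):
        og, calls, matrices = trio_setup(
            BASE, REVERSED, REVERSED, phases=("dusk", "dawn", "dusk")
        )
        (res,) = call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"])
        assert not res.criterion1_pass and not res.rescheduled

    def test_swapping_c3_labels_leaves_verdict_unchanged(self):
        og, calls, matrices = trio_setup(BASE, RHO_M05, REVERSED)
        (fwd,) = call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"])
        (rev,) = call_rescheduled(og, calls, matrices, "cam", ["c3b", "c3a"])
        assert fwd.rescheduled == rev.rescheduled
        assert fwd.criterion1_pass == rev.criterion1_pass
        assert fwd.criterion2_pass == rev.criterion2_pass
        assert fwd.rho_cam_c3 == rev.rho_cam_c3

    def test_group_missing_a_species_is_skipped(self):
        og, calls, matrices = trio_setup(BASE, REVERSED, REVERSED)
        og = OrthologGroup("OG1", {"cam": ("k1",), "c3a": ("a1",)})
        assert call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"]) == []

    def test_multi_gene_group_evaluates_every_combination(self):
        matrices = {
            "cam": DielMatrix("cam", GRID_5, ("k1", "k2"), np.asarray([BASE, RHO_M05])),
            "c3a": DielMatrix("c3a", GRID_5, ("a1",), np.asarray([REVERSED])),
            "c3b": DielMatrix("c3b", GRID_5, ("b1", "b2"),
                              np.asarray([REVERSED, RHO_M05])),
        }
        calls = {
            "cam": {"k1": enrichment_call("k1", "dusk"), "k2": enrichment_call("k2", "dusk")},
            "c3a": {"a1": enrichment_call("a1", "dawn")},
            "c3b": {"b1": enrichment_call("b1", "dawn"), "b2": enrichment_call("b2", "dawn")},
        }
        og = OrthologGroup(
            "OG1", {"cam": ("k1", "k2"), "c3a": ("a1",), "c3b": ("b1", "b2")}
        )
        combos = call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"])
        assert len(combos) == 4  # 2 cam × 1 × 2
        assert any(c.rescheduled for c in combos)  # (k1, a1, b1) passes
        assert not all(c.rescheduled for c in combos)

    def test_constant_profile_combination_excluded(self):
        og, calls, matrices = trio_setup(BASE, (2.0,) * 5, REVERSED)
        assert call_rescheduled(og, calls, matrices, "cam", ["c3a", "c3b"]) == []

    def test_rescheduled_flag_must_be_conjunction(self):
        with pytest.raises(ValueError):
            ReschedulingCall(
                "OG1", "cam", "k1", {"a": "a1", "b": "b1"}, "dusk",
                {"a": "dawn", "b": "dawn"}, {"a": -0.9, "b": -0.9}, 0.9,
                criterion1_pass=True, criterion2_pass=False, rescheduled=True,
            )
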