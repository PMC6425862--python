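import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dielshift.preprocess import NormalizedProfile, normalize_diel, rotate_profiles
from dielshift.window_enrichment import (
    TimeWindow,
    WindowCounts,
    bh_fdr,
    call_phase,
    fisher_right_tail,
    window_sums,
)
from dielshift import DielMatrix

GRID_2H = tuple(float(h) for h in range(0, 24, 2))
DUSK = TimeWindow("dusk", frozenset({10.0, 12.0, 14.0}))
DAWN = TimeWindow("dawn", frozenset({22.0, 24.0, 2.0}))  # 24 canonicalizes to 0


def profile(counts, gene_id="g", grid=GRID_2H):
    counts = np.asarray(counts, dtype=int)
    return NormalizedProfile(gene_id, grid[: len(counts)], counts, int(counts.sum()))


def right_tail_oracle(a, b, c, d):
    """Exact rational enumeration of the hypergeometric right tail."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    total = Fraction(0)
    for k in range(a, min(r1, c1) + 1):
        total += Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), math.comb(n, c1))
    return total


class TestTimeWindow:
    def test_hour_24_canonicalized(self):
        assert DAWN.hours == frozenset({22.0, 0.0, 2.0})

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            TimeWindow("noon", frozenset({12.0}))


class TestWindowSums:
    def test_uniform_counts_give_equal_sums(self):
        (w,) = window_sums([profile([7] * 12)], DUSK, DAWN)
        assert (w.dusk_sum, w.dawn_sum) == (21, 21)

    def test_12h_rotation_swaps_the_two_sums(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 50, 12)
        m = DielMatrix("sp", GRID_2H, ("g",), counts[None, :].astype(float))
        rotated = rotate_profiles(m, 12.0)
        (w,) = window_sums([profile(counts)], DUSK, DAWN)
        (wr,) = window_sums([profile(rotated.values[0].astype(int))], DUSK, DAWN)
        assert (wr.dusk_sum, wr.dawn_sum) == (w.dawn_sum, w.dusk_sum)

    def test_counts_only_at_noonish_hour_leave_dawn_empty(self):
        counts = np.zeros(12, dtype=int)
        counts[GRID_2H.index(12.0)] = 99
        (w,) = window_sums([profile(counts)], DUSK, DAWN)
        assert (w.dusk_sum, w.dawn_sum) == (99, 0)

    def test_window_hour_absent_from_grid_rejected(self):
        with pytest.raises(ValueError, match="14"):
            window_sums([profile([1] * 6, grid=tuple(float(h) for h in range(0, 24, 4)))],
                        DUSK, DAWN, species_id="sp")

    def test_overlapping_windows_rejected(self):
        overlapping = TimeWindow("dawn", frozenset({12.0, 22.0, 2.0}))
        with pytest.raises(ValueError, match="overlap"):
            window_sums([profile([1] * 12)], DUSK, overlapping)


class TestFisherRightTail:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((3, 1, 1, 3), 17 / 70),   # sum over tables with first cell >= 3
            ((0, 5, 5, 0), 1.0),       # first cell at its minimum given margins
            ((5, 0, 0, 5), 1 / 252),   # single most extreme table
        ],
    )
    def test_worked_tables(self, table, expected):
        assert fisher_right_tail(*table) == pytest.approx(expected, rel=1e-7)

    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) >= 1))
    def test_matches_exact_enumeration(self, table):
        assert fisher_right_tail(*table) == pytest.approx(
            float(right_tail_oracle(*table)), abs=1e-12
        )

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 400, 4))
            if a + b + c + d == 0:
                continue
            ours = fisher_right_tail(a, b, c, d)
            theirs = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_strictly_decreasing_in_first_cell_for_fixed_margins(self):
        # margins: row1 = 10, col1 = 8, n = 20; support of the first cell
        r1, c1, n = 10, 8, 20
        support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        ps = [fisher_right_tail(a, r1 - a, c1 - a, n - r1 - c1 + a) for a in support]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_right_tail(-1, 2, 3, 4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_right_tail(0, 0, 0, 0)


class TestBHFDR:
    def test_step_up_example(self):
        res = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.2], alpha=0.05)
        assert [r for _, r in res] == [True, True, True, True, False]

    def test_single_pvalue(self):
        assert bh_fdr([0.01]) == [(0.01, True)]

    def test_all_ones_rejects_nothing(self):
        assert all(not r for _, r in bh_fdr([1.0] * 10))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 100)))
            ours = bh_fdr(p, alpha=0.05)
            reject, q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose([qi for qi, _ in ours], q, atol=1e-12)
            assert [r for _, r in ours] == list(reject)

    def test_rejections_superset_of_bonferroni(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 0.2, 40)
        bh_reject = {i for i, (_, r) in enumerate(bh_fdr(p, 0.05)) if r}
        bonf_reject = {i for i in range(len(p)) if p[i] <= 0.05 / len(p)}
        assert bonf_reject <= bh_reject

    def test_qvalues_satisfy_step_up_monotonicity(self):
        # re-running the running-min enforcement on sorted q-values changes nothing
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 100)
        q = np.array([qi for qi, _ in bh_fdr(p)])
        q_sorted = q[np.argsort(p, kind="stable")]
        assert np.array_equal(np.minimum.accumulate(q_sorted[::-1])[::-1], q_sorted)

    def test_out_of_range_pvalue_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def cosine_matrix(peaks, amplitude=3.0, species="sp"):
    t = np.asarray(GRID_2H)
    rows = np.vstack(
        [1.0 + amplitude * (1.0 + np.cos(2 * np.pi * (t - pk) / 24.0)) / 2.0 for pk in peaks]
    )
    return DielMatrix(species, GRID_2H, tuple(f"g{i}" for i in range(len(peaks))), rows)


class TestCallPhase:
    def test_flat_profiles_are_all_neither(self):
        counts = [WindowCounts(f"g{i}", 250, 250) for i in range(100)]
        assert all(c.phase == "neither" for c in call_phase(counts))

    def test_planted_dusk_gene_called_dusk_among_flat_background(self):
        counts = [WindowCounts(f"bg{i}", 250, 250) for i in range(100)]
        counts.append(WindowCounts("planted", 450, 50))  # 90% of counts at dusk
        calls = {c.gene_id: c for c in call_phase(counts)}
        assert calls["planted"].phase == "dusk"
        assert calls["planted"].q_dusk <= 0.05
        assert all(c.phase == "neither" for g, c in calls.items() if g != "planted")

    def test_12h_rotation_swaps_dawn_and_dusk_labels(self):
        rng = np.random.default_rng(9)
        m = cosine_matrix(rng.uniform(0, 24, 200))
        m = DielMatrix(m.species_id, m.timepoints, m.gene_ids,
                       m.values * np.exp(rng.normal(0, 0.2, m.values.shape)))
        rotated = rotate_profiles(m, 12.0)

        def phases(matrix):
            counts = window_sums(normalize_diel(matrix), DUSK, DAWN)
            return {c.gene_id: c.phase for c in call_phase(counts)}

        swapped = {"dawn": "dusk", "dusk": "dawn", "neither": "neither"}
        before = phases(m)
        after = phases(rotated)
        assert after == {g: swapped[p] for g, p in before.items()}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            call_phase([])
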