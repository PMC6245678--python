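"""Segment-domain Hampel filtering, checked against an independent
brute-force oracle (explicit sorts, mean-of-middle medians, scaled-MAD
threshold rule)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgmaf.hampel import (
    hampel_apply,
    hampel_params,
    hfbe,
    reconstruct,
    rhfbe,
    run_segment_filter,
)
from ecgmaf.segmentation import SegmentBuffer
from ecgmaf.signal_io import QRSAnnotation


# --------------------------- brute-force oracle ---------------------------

def brute_median(vals):
    s = sorted(vals)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def brute_hampel(rows, seg, m):
    """Column-by-column median/MAD bounds and conditional replacement."""
    rows = [list(r) for r in rows]
    ncol = len(rows[0])
    out = list(seg)
    for i in range(ncol):
        col = [r[i] for r in rows]
        med = brute_median(col)
        mad = 1.4826 * brute_median([abs(v - med) for v in col])
        hub, hlb = med + m * mad, med - m * mad
        if not (hlb <= seg[i] <= hub):
            out[i] = med
    return out


def make_buffer(rows):
    l = len(rows[0])
    buf = SegmentBuffer(w=len(rows), l_min=min(l, 7), l_max=l)
    for r in rows:
        buf.push(np.asarray(r, dtype=float), l)
    return buf


# ------------------------------- params ----------------------------------

class TestHampelParams:
    def test_constant_column(self):
        buf = make_buffer([[1.0]] * 5)
        p = hampel_params(buf, m=3)
        assert p.median_col[0] == 1.0
        assert p.mad_col[0] == 0.0
        assert p.hub[0] == p.hlb[0] == 1.0

    def test_hand_computed_outlier_column(self):
        buf = make_buffer([[1.0], [2.0], [3.0], [4.0], [100.0]])
        p = hampel_params(buf, m=3)
        assert p.median_col[0] == 3.0
        assert p.mad_col[0] == pytest.approx(1.4826)
        assert p.hub[0] == pytest.approx(7.4478)
        assert p.hlb[0] == pytest.approx(-1.4478)

    def test_even_row_count_mean_of_middle(self):
        buf = make_buffer([[1.0], [2.0], [3.0], [4.0]])
        assert hampel_params(buf, m=3).median_col[0] == 2.5

    def test_too_few_rows_raises(self):
        buf = make_buffer([[1.0], [2.0]])
        with pytest.raises(ValueError):
            hampel_params(buf, m=3)

    def test_bounds_identity(self, rng):
        buf = make_buffer(rng.standard_normal((6, 12)))
        p = hampel_params(buf, m=2.5)
        np.testing.assert_allclose(p.hub, p.median_col + 2.5 * p.mad_col, atol=0)
        np.testing.assert_allclose(p.hlb, p.median_col - 2.5 * p.mad_col, atol=0)


class TestHampelApply:
    def test_median_segment_unchanged(self, rng):
        buf = make_buffer(rng.standard_normal((7, 10)))
        p = hampel_params(buf, m=3)
        out, mask = hampel_apply(p.median_col.copy(), p)
        np.testing.assert_array_equal(out, p.median_col)
        assert not mask.any()

    def test_gross_outlier_replaced_by_median(self):
        buf = make_buffer([[1.0], [2.0], [3.0], [4.0], [100.0]])
        p = hampel_params(buf, m=3)
        out, mask = hampel_apply(np.array([100.0]), p)
        assert out[0] == 3.0
        assert mask[0]

    def test_degenerate_mad_flags_any_deviation(self):
        buf = make_buffer([[2.0, 2.0]] * 5)
        p = hampel_params(buf, m=3)
        out, mask = hampel_apply(np.array([2.0, 2.1]), p)
        assert out[1] == 2.0 and mask[1] and not mask[0]

    def test_mask_equals_bound_violations(self, rng):
        buf = make_buffer(rng.standard_normal((9, 15)))
        p = hampel_params(buf, m=1.0)
        seg = rng.standard_normal(15)
        _, mask = hampel_apply(seg, p)
        np.testing.assert_array_equal(mask, (seg < p.hlb) | (seg > p.hub))

    def test_idempotent(self, rng):
        buf = make_buffer(rng.standard_normal((8, 20)))
        p = hampel_params(buf, m=1.5)
        seg = 3 * rng.standard_normal(20)
        once, _ = hampel_apply(seg, p)
        twice, _ = hampel_apply(once, p)
        np.testing.assert_array_equal(once, twice)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_rows = int(rng.integers(3, 16))
        n_cols = int(rng.integers(5, 51))
        rows = rng.standard_normal((n_rows, n_cols))
        seg = 2 * rng.standard_normal(n_cols)
        m = float(rng.uniform(0.5, 4.0))
        buf = make_buffer(rows)
        p = hampel_params(buf, m)
        ours, _ = hampel_apply(seg, p)
        np.testing.assert_array_equal(ours, brute_hampel(rows, seg, m))


class TestHfbeRhfbe:
    def test_clean_beat_against_clean_buffer_nearly_unchanged(self, rng):
        # Replacements, if any, swap a sample for the column median of
        # near-identical rows, so deviations stay at the noise scale.
        row = np.sin(np.linspace(0, 2 * np.pi, 30))
        buf = make_buffer([row + 0.01 * rng.standard_normal(30) for _ in range(6)])
        out = hfbe(buf, row.copy(), m=3)
        np.testing.assert_allclose(out, row, atol=0.05)

    def test_identical_buffer_and_beat_identity(self):
        row = np.linspace(-1, 1, 25)
        buf = make_buffer([row.copy() for _ in range(5)])
        np.testing.assert_array_equal(hfbe(buf, row.copy(), m=3), row)
        buf2 = make_buffer([row.copy() for _ in range(5)])
        np.testing.assert_array_equal(rhfbe(buf2, row.copy(), m=3), row)

    def test_artefact_bump_removed(self, rng):
        template = np.sin(np.linspace(0, 2 * np.pi, 40))
        rows = [template + 0.02 * rng.standard_normal(40) for _ in range(8)]
        buf = make_buffer(rows)
        corrupted = template + 0.02 * rng.standard_normal(40)
        corrupted[10:20] += 5.0
        out = hfbe(buf, corrupted, m=3)
        rmse_before = np.sqrt(np.mean((corrupted - template) ** 2))
        rmse_after = np.sqrt(np.mean((out - template) ** 2))
        assert rmse_after < 0.5 * rmse_before

    def test_hfbe_stores_raw_rhfbe_stores_filtered(self, rng):
        template = np.sin(np.linspace(0, 2 * np.pi, 40))
        rows = [template + 0.02 * rng.standard_normal(40) for _ in range(6)]
        corrupted = template.copy()
        corrupted[5:15] += 5.0
        buf_h = make_buffer(rows)
        buf_r = make_buffer(rows)
        hfbe(buf_h, corrupted.copy(), m=3)
        rhfbe(buf_r, corrupted.copy(), m=3)
        assert np.max(buf_h.matrix()[-1]) > 4.0   # raw bump stored
        assert np.max(buf_r.matrix()[-1]) < 2.0   # cleaned row stored

    def test_recursive_outperforms_on_bursty_streams(self):
        """With consecutive corrupted beats, conditioning on filtered
        history keeps the buffer statistics clean."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            template = np.sin(np.linspace(0, 2 * np.pi, 40))
            stream = [template + 0.02 * rng.standard_normal(40) for _ in range(40)]
            corrupt_idx = set()
            start = int(rng.integers(8, 25))
            for i in range(start, start + 8):  # sustained burst
                stream[i] = stream[i].copy()
                lo = int(rng.integers(0, 25))
                stream[i][lo : lo + 12] += rng.uniform(2, 5)
                corrupt_idx.add(i)

            def run(recursive):
                buf = SegmentBuffer(w=8, l_min=7, l_max=40)
                err = 0.0
                for i, s in enumerate(stream):
                    if len(buf) < 3:
                        buf.push(s, 40)
                        continue
                    out = rhfbe(buf, s.copy(), m=3) if recursive else hfbe(buf, s.copy(), m=3)
                    if i in corrupt_idx:
                        err += np.mean((out - template) ** 2)
                return err

            wins += run(True) <= run(False)
        assert wins >= 13  # recursive at least as good in a clear majority


class TestReconstruct:
    def test_no_segments_is_identity(self, rng):
        x = rng.standard_normal(100)
        ann = QRSAnnotation(r_peaks=[50], per_beat_l=[20])
        np.testing.assert_array_equal(reconstruct(x, ann, {}), x)

    def test_single_segment_changes_only_its_window(self, rng):
        x = rng.standard_normal(200)
        ann = QRSAnnotation(r_peaks=[100], per_beat_l=[40])
        seg = np.zeros(40)
        out = reconstruct(x, ann, {0: seg})
        np.testing.assert_array_equal(out[80:120], 0.0)
        np.testing.assert_array_equal(out[:80], x[:80])
        np.testing.assert_array_equal(out[120:], x[120:])

    def test_overlap_resolved_in_favor_of_later_beat(self):
        x = np.zeros(100)
        ann = QRSAnnotation(r_peaks=[40, 60], per_beat_l=[40, 40])
        out = reconstruct(x, ann, {0: np.full(40, 1.0), 1: np.full(40, 2.0)})
        assert out[25] == 1.0   # only in first window [20, 60)
        assert out[45] == 2.0   # overlap [40, 60) -> later beat wins
        assert out[85] == 0.0   # untouched tail


def test_run_segment_filter_cold_start_passthrough(rng):
    x = rng.standard_normal(300)
    ann = QRSAnnotation(r_peaks=[60, 110, 160], per_beat_l=[50, 50, 50])
    out = run_segment_filter(x, ann, fs=50, w=8, m=3.0, recursive=True)
    np.testing.assert_array_equal(out, x)  # never reaches 3 buffered rows
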