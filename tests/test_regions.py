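"""Moving-window search: residue lines, detection, sub-window optimization."""

import numpy as np
import pytest

from scmwpls.grid import RegionSet, SpectralRegion
from scmwpls.pls import max_lv_for_region, pls1_fit, ssr
from scmwpls.regions import (
    detect_informative_regions,
    mwplsr,
    scmwpls_best_subwindow,
    scmwpls_combine,
)
from tests.conftest import jaccard, make_spectra_set, planted_signal_problem

_TIE = 1e-12


def naive_best_subwindow(spectra, y, region, k_max=10):
    """Independent exhaustive enumeration with per-candidate pls1_fit.

    Same dimensionality rule and tie-break (fewer channels, then higher
    start) as the production path, but none of its batching machinery.
    """
    cols = spectra.columns_for(region)
    S = spectra.absorbance[:, cols]
    n, p = S.shape
    k_cap = max_lv_for_region(S, y, k_cap=k_max)
    wn = spectra.wavenumbers()[cols]
    best = None
    for w in range(1, p + 1):
        for start in range(p - w + 1):
            k = min(k_cap, w, n - 1)
            rmsec = pls1_fit(S[:, start : start + w], y, k).rmsec
            if best is None or rmsec < best[0] - _TIE:
                best = (rmsec, SpectralRegion(wn[start], wn[start + w - 1]), k)
    return best[1], best[2], best[0]


class TestMWPLSR:
    def test_position_count(self, rng):
        spectra = make_spectra_set(rng.normal(size=(25, 100)))
        lines = mwplsr(spectra, rng.normal(size=25), window_size=20, k_max=10)
        assert lines.n_positions == 81

    def test_ten_residue_lines(self, rng):
        spectra = make_spectra_set(rng.normal(size=(25, 40)))
        lines = mwplsr(spectra, rng.normal(size=25), window_size=20, k_max=10)
        assert lines.loss.shape[1] == 10

    def test_entries_match_per_window_fits(self, rng):
        spectra = make_spectra_set(rng.normal(size=(15, 32)))
        y = rng.normal(size=15)
        lines = mwplsr(spectra, y, window_size=12, k_max=5)
        X = spectra.absorbance
        for pos in (0, 7, 20):
            for k in (1, 3, 5):
                direct = np.log10(ssr(X[:, pos : pos + 12], y, k))
                assert lines.loss[pos, k - 1] == pytest.approx(direct, abs=1e-8)

    def test_loss_monotone_in_lv(self, rng):
        spectra = make_spectra_set(rng.normal(size=(25, 60)))
        lines = mwplsr(spectra, rng.normal(size=25), window_size=20, k_max=10)
        assert np.all(np.diff(lines.loss, axis=1) <= 1e-10)

    def test_window_must_exceed_kmax(self, rng):
        spectra = make_spectra_set(rng.normal(size=(25, 60)))
        with pytest.raises(ValueError, match="exceed"):
            mwplsr(spectra, rng.normal(size=25), window_size=10, k_max=10)

    def test_short_segment_skipped_with_warning(self, rng):
        from scmwpls.grid import SpectraSet

        regions = RegionSet.from_string("8000-7688, 7000-6960")  # 40 + 6
        spectra = SpectraSet(
            8.0, regions, rng.normal(size=(25, 46)), [f"s{i}" for i in range(25)]
        )
        with pytest.warns(UserWarning, match="skipped"):
            lines = mwplsr(spectra, rng.normal(size=25), window_size=20, k_max=10)
        assert lines.n_positions == 21  # only the 40-channel segment

    def test_windows_never_span_the_gap(self, rng):
        from scmwpls.grid import SpectraSet

        regions = RegionSet.from_string("8000-7768, 7000-6768")  # 30 + 30
        spectra = SpectraSet(
            8.0, regions, rng.normal(size=(25, 60)), [f"s{i}" for i in range(25)]
        )
        lines = mwplsr(spectra, rng.normal(size=25), window_size=20, k_max=5)
        assert lines.n_positions == 22  # 11 per segment
        # every start leaves room for the full window inside its segment
        for pos in range(lines.n_positions):
            reg = lines.window_region(pos)
            assert any(seg.contains(reg) for seg in regions)


class TestDetection:
    def test_planted_channels_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            spectra, y, (lo, hi) = planted_signal_problem(rng)
            lines = mwplsr(spectra, y, window_size=20, k_max=10)
            detected = detect_informative_regions(lines)
            wn = spectra.wavenumbers()
            planted = RegionSet([SpectralRegion(wn[lo], wn[hi])])
            if len(detected) and jaccard(detected, planted) >= 0.5:
                hits += 1
        assert hits >= 15

    def test_pure_noise_gives_near_empty_result(self, rng):
        spectra = make_spectra_set(rng.normal(size=(40, 120)))
        y = rng.normal(size=40)
        lines = mwplsr(spectra, y, window_size=20, k_max=10)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            detected = detect_informative_regions(lines, quantile_threshold=0.10)
        covered = sum(r.n_points(8) for r in detected)
        assert covered <= 0.3 * 120

    def test_manual_mode_returns_regions_verbatim(self, rng):
        spectra = make_spectra_set(rng.normal(size=(25, 60)))
        lines = mwplsr(spectra, rng.normal(size=25), window_size=20, k_max=10)
        manual = RegionSet.from_string("9200-5408, 4976-4008")
        out = detect_informative_regions(lines, manual_regions=manual)
        assert str(out) == "9200-5408, 4976-4008"


class TestBestSubwindow:
    def test_single_channel_region(self, rng):
        spectra = make_spectra_set(rng.normal(size=(10, 20)))
        y = rng.normal(size=10)
        region = SpectralRegion(7920, 7920)
        out, lv, rmsec = scmwpls_best_subwindow(spectra, y, region)
        assert str(out) == "7920-7920"
        assert lv == 1

    @pytest.mark.parametrize("p", [8, 12, 15])
    def test_matches_exhaustive_oracle(self, p):
        rng = np.random.default_rng(p)
        spectra = make_spectra_set(rng.normal(size=(20, p)))
        y = rng.normal(size=20)
        region = spectra.regions.regions[0]
        got = scmwpls_best_subwindow(spectra, y, region)
        want = naive_best_subwindow(spectra, y, region)
        assert str(got[0]) == str(want[0])
        assert got[1] == want[1]
        assert got[2] == pytest.approx(want[2], abs=1e-10)

    def test_beats_full_region_fit(self, rng):
        spectra = make_spectra_set(rng.normal(size=(30, 25)))
        y = rng.normal(size=30)
        region = spectra.regions.regions[0]
        _, _, rmsec = scmwpls_best_subwindow(spectra, y, region)
        X = spectra.absorbance
        k_cap = max_lv_for_region(X, y, k_cap=10)
        full = pls1_fit(X, y, min(k_cap, X.shape[1], 29)).rmsec
        assert rmsec <= full + 1e-12

    def test_planted_two_channel_signal_found(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            n = 60
            y = rng.normal(size=n)
            X = 0.1 * rng.normal(size=(n, 60))
            X[:, 30] += y
            X[:, 31] += 0.8 * y
            spectra = make_spectra_set(X)
            region = spectra.regions.regions[0]
            out, _, _ = scmwpls_best_subwindow(spectra, y, region)
            wn = spectra.wavenumbers()
            if out.high_cm1 >= wn[30] >= out.low_cm1 and out.high_cm1 >= wn[31] >= out.low_cm1:
                hits += 1
        assert hits >= 18

    def test_zero_width_region_errors(self, rng):
        spectra = make_spectra_set(rng.normal(size=(10, 20)))
        with pytest.raises(ValueError):
            scmwpls_best_subwindow(
                spectra, rng.normal(size=10), SpectralRegion(9000, 8900)
            )


def naive_greedy_combine(spectra, y, regions, k_max=10, min_improvement=0.02):
    """Independent re-implementation of the greedy combination with plain
    per-candidate fits (no batching): step A best sub-interval of the first
    region; step B+ base plus best sub-interval (or nothing) of each next,
    adopted only on a meaningful (>= min_improvement relative) gain."""
    ordered = sorted(regions, key=lambda r: -r.high_cm1)
    base_region, _, base_rmsec = naive_best_subwindow(
        spectra, y, ordered[0], k_max
    )
    base_cols = list(spectra.columns_for(base_region))
    base_set = [base_region]
    n = spectra.n_samples
    for region in ordered[1:]:
        cols = spectra.columns_for(region)
        S = spectra.absorbance[:, cols]
        wn = spectra.wavenumbers()[cols]
        Xb = spectra.absorbance[:, base_cols]
        k_cap = max_lv_for_region(Xb, y, k_cap=k_max)
        p = S.shape[1]
        best = None
        for w in range(1, p + 1):
            for start in range(p - w + 1):
                X = np.hstack([Xb, S[:, start : start + w]])
                k = min(k_cap, X.shape[1], n - 1)
                rmsec = pls1_fit(X, y, k).rmsec
                if best is None or rmsec < best[0] - _TIE:
                    best = (rmsec, start, w)
        if best is not None and best[0] < base_rmsec * (1 - min_improvement) - _TIE:
            rmsec, start, w = best
            picked = SpectralRegion(wn[start], wn[start + w - 1])
            base_set.append(picked)
            base_cols = list(base_cols) + list(
                spectra.columns_for(picked)
            )
            base_rmsec = rmsec
    return base_set, base_rmsec


class TestCombine:
    def test_single_region_equals_best_subwindow(self, rng):
        spectra = make_spectra_set(rng.normal(size=(20, 15)))
        y = rng.normal(size=20)
        region = spectra.regions.regions[0]
        sub = scmwpls_best_subwindow(spectra, y, region)
        combined = scmwpls_combine(spectra, y, RegionSet([region]))
        assert str(combined.optimized_regions) == str(RegionSet([sub[0]]))
        assert combined.final_rmsec == pytest.approx(sub[2], abs=1e-10)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_two_region_combination_matches_naive_greedy(self, seed):
        rng = np.random.default_rng(seed)
        from scmwpls.grid import SpectraSet

        regions = RegionSet.from_string("8000-7912, 7000-6912")  # 12 + 12
        spectra = SpectraSet(
            8.0, regions, rng.normal(size=(20, 24)), [f"s{i}" for i in range(20)]
        )
        y = rng.normal(size=20)
        result = scmwpls_combine(spectra, y, regions)
        naive_set, naive_rmsec = naive_greedy_combine(spectra, y, list(regions))
        from scmwpls.grid import merge_regions

        assert str(result.optimized_regions) == str(merge_regions(naive_set, 8.0))
        assert result.final_rmsec == pytest.approx(naive_rmsec, abs=1e-9)

    def test_trace_rmsec_non_increasing_and_refit_consistent(self, rng):
        from scmwpls.grid import SpectraSet

        regions = RegionSet.from_string("8000-7880, 7500-7380, 7000-6880")
        spectra = SpectraSet(
            8.0, regions, rng.normal(size=(25, 48)), [f"s{i}" for i in range(25)]
        )
        y = rng.normal(size=25)
        result = scmwpls_combine(spectra, y, regions)
        trace = [rec["rmsec"] for rec in result.rmsec_trace]
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        cols = spectra.columns_for(result.optimized_regions)
        refit = pls1_fit(spectra.absorbance[:, cols], y, result.lv_used)
        assert refit.rmsec == pytest.approx(result.final_rmsec, abs=1e-10)

    def test_noise_only_regions_discarded(self):
        """Signal planted in one of four regions: the optimized combination
        keeps (a sub-interval of) the signal region only.

        Sample size is chosen so chance in-sample gains from appending noise
        channels (~ w/2n) sit below the meaningful-improvement threshold;
        otherwise no greedy RMSEC rule could ever drop a region.
        """
        kept_only_signal = 0
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            from scmwpls.grid import SpectraSet

            regions = RegionSet.from_string(
                "8000-7944, 7500-7444, 7000-6944, 6500-6444"
            )
            n = 400
            X = 0.5 * rng.normal(size=(n, 32))
            y = rng.normal(size=n)
            # signal lives in the third region's columns (16..23)
            X[:, 16:24] += np.outer(y, np.hanning(8))
            spectra = SpectraSet(8.0, regions, X, [f"s{i}" for i in range(n)])
            result = scmwpls_combine(spectra, y, regions, order_policy="by_rmsec")
            inside = all(
                SpectralRegion(7000, 6944).contains(r)
                for r in result.optimized_regions
            )
            kept_only_signal += inside
        assert kept_only_signal >= 8

    def test_empty_region_set_errors(self, rng):
        spectra = make_spectra_set(rng.normal(size=(10, 20)))
        with pytest.raises(ValueError):
            scmwpls_combine(spectra, rng.normal(size=10), RegionSet([]))
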