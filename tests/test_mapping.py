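import numpy as np
import pandas as pd
import pytest

from m2seq import (auto_select_window, detect_candidate_region, fit_windows,
                   screen_candidates, zero_center)
from m2seq.mapping import CandidateRegion
from tests.conftest import indexed_frame


def naive_windows(positions, values, n):
    """Independent double-loop moving-average oracle."""
    out = []
    for i in range(len(positions) - n + 1):
        first, last = positions[i], positions[i + n - 1]
        out.append(((first + last) // 2, sum(values[i:i + n]) / n, first, last))
    return out


class TestFitWindows:
    def test_single_window_mean_and_midpoint(self):
        dsi = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        frame = indexed_frame(dsi)
        (curve,) = fit_windows(frame, 10)
        assert len(curve.points) == 1
        pt = curve.points.iloc[0]
        assert pt["mean_dsi"] == pytest.approx(np.mean(dsi), abs=1e-12)
        assert pt["midpoint_bp"] == (frame["pos"].iloc[0] + frame["pos"].iloc[9]) // 2

    def test_twelve_snvs_window_ten_gives_three_points(self):
        rng = np.random.default_rng(5)
        dsi = rng.uniform(-1, 1, 12)
        frame = indexed_frame(dsi)
        (curve,) = fit_windows(frame, 10)
        expected = naive_windows(frame["pos"].tolist(), dsi.tolist(), 10)
        assert len(curve.points) == len(expected) == 3
        for pt, (mid, mean, first, last) in zip(curve.points.itertuples(), expected):
            assert pt.midpoint_bp == mid
            assert pt.mean_dsi == pytest.approx(mean, abs=1e-12)
            assert (pt.first_bp, pt.last_bp) == (first, last)

    def test_constant_dsi_gives_constant_curves(self):
        frame = indexed_frame([-0.4] * 25)
        (curve,) = fit_windows(frame, 10)
        assert np.allclose(curve.points["mean_dsi"], -0.4)
        assert np.allclose(curve.points["mean_adsi"], 0.4)

    def test_short_chromosome_yields_empty_curve(self):
        (curve,) = fit_windows(indexed_frame([0.1] * 5), 10)
        assert len(curve.points) == 0

    def test_indels_and_removed_variants_excluded(self):
        snv = indexed_frame([0.5] * 12)
        indel = indexed_frame([0.9] * 3, start=50_000, vclass="INDEL")
        removed = indexed_frame([0.9] * 3, start=90_000, status="STEP2_REMOVED")
        frame = pd.concat([snv, indel, removed], ignore_index=True)
        (curve,) = fit_windows(frame, 10)
        assert len(curve.points) == 3  # only the 12 PASS SNVs contribute
        assert np.allclose(curve.points["mean_dsi"], 0.5)

    def test_window_too_small_is_config_error(self):
        with pytest.raises(ValueError):
            fit_windows(indexed_frame([0.1] * 10), 1)

    def test_windows_never_span_chromosomes(self):
        a = indexed_frame([0.2] * 10, chrom="Chr01")
        b = indexed_frame([0.8] * 10, chrom="Chr02")
        curves = fit_windows(pd.concat([a, b], ignore_index=True), 10)
        assert [c.chrom for c in curves] == ["Chr01", "Chr02"]
        assert [len(c.points) for c in curves] == [1, 1]


class TestZeroCenter:
    def test_arithmetic_example(self):
        frame = indexed_frame([0.2, 0.2, 0.2, 1.0])
        adjusted, mean = zero_center(frame)
        assert mean == pytest.approx(0.4)
        assert adjusted["adsi"].tolist() == pytest.approx([0.2, 0.2, 0.2, 0.6])
        assert adjusted["dsi"].mean() - mean == pytest.approx(0.0 - mean + 0.4, abs=1e-9)

    def test_symmetric_dsi_unchanged(self):
        frame = indexed_frame([-0.3, 0.3, -0.1, 0.1])
        adjusted, mean = zero_center(frame)
        assert mean == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(adjusted["adsi"], frame["adsi"], atol=1e-12)

    def test_adjusted_mean_is_zero(self):
        rng = np.random.default_rng(3)
        frame = indexed_frame(rng.uniform(0, 1, 500))
        adjusted, mean = zero_center(frame)
        assert abs((frame["dsi"] - mean).mean()) < 1e-9

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            zero_center(indexed_frame([]))


class TestAutoSelectWindow:
    @pytest.mark.parametrize("n,expected", [(800, 10), (4000, 20), (12000, 40)])
    def test_density_rule(self, n, expected):
        assert auto_select_window(n) == expected


class TestDetectRegion:
    def test_triangular_bump_brackets_half_height(self):
        dsi = [0.05] * 30 + [0.2, 0.4, 0.6, 0.8, 1.0, 0.8, 0.6, 0.4, 0.2] + [0.05] * 30
        frame = indexed_frame(dsi)
        regions = detect_candidate_region(fit_windows(frame, 5), "adsi", 0.5)
        region = regions[0]
        peak_pos = frame["pos"].iloc[34]  # apex of the bump
        assert region.start_bp <= peak_pos <= region.end_bp
        # region must not swallow the flat baseline
        assert region.end_bp - region.start_bp < (frame["pos"].iloc[-1] - frame["pos"].iloc[0]) / 2

    def test_two_equal_peaks_listed_and_tiebroken(self):
        bump = [0.1] * 10 + [1.0] * 5 + [0.1] * 10
        a = indexed_frame(bump, chrom="Chr02")
        b = indexed_frame(bump, chrom="Chr01")
        curves = fit_windows(pd.concat([a, b], ignore_index=True), 5)
        regions = detect_candidate_region(curves, "adsi", 0.5)
        assert len(regions) == 2
        assert regions[0].peak_value == pytest.approx(regions[1].peak_value)
        assert regions[0].chrom == "Chr01"  # equal width: lowest chromosome wins

    def test_empty_curves_error(self):
        curves = fit_windows(indexed_frame([0.1] * 3), 10)
        with pytest.raises(ValueError):
            detect_candidate_region(curves)


def region(chrom="Chr01", start=1, end=10**9):
    return CandidateRegion(chrom=chrom, start_bp=start, end_bp=end,
                           peak_midpoint_bp=(start + end) // 2, peak_value=1.0,
                           n_windows=1)


class TestScreenCandidates:
    def _frame(self, rows):
        """rows: (pos, mut_ref, mut_alt, wt_ref, wt_alt, fc, vclass)"""
        frames = []
        for pos, mr, ma, wr, wa, fc, vclass in rows:
            f = indexed_frame([0.0], start=pos, vclass=vclass)
            f.loc[0, ["mut_ref_depth", "mut_alt_depth", "wt_ref_depth", "wt_alt_depth"]] = (
                mr, ma, wr, wa
            )
            mut_idx = ma / (mr + ma)
            wt_idx = wa / (wr + wa)
            f.loc[0, ["snp_index_mut", "snp_index_wt"]] = (mut_idx, wt_idx)
            f.loc[0, "dsi"] = mut_idx - wt_idx
            f.loc[0, "adsi"] = abs(mut_idx - wt_idx)
            f.loc[0, "functional_class"] = fc
            if vclass == "INDEL":
                f.loc[0, ["ref", "alt"]] = ("CT", "C")
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_frameshift_deletion_with_unit_mutant_index_passes(self):
        # mutant depths (0, 22), wild-type index 0.39 -> ADSI 0.61 > 0.5
        frame = self._frame([(100, 0, 22, 61, 39, "frameshift", "INDEL")])
        cands = screen_candidates(region(), frame)
        assert len(cands) == 1
        assert cands[0].snp_index_mut == 1.0
        assert cands[0].adsi == pytest.approx(0.61)
        assert cands[0].vclass == "INDEL"

    def test_mutant_index_below_one_excluded(self):
        frame = self._frame([(100, 1, 19, 61, 39, "missense", "SNV")])  # 0.95
        assert screen_candidates(region(), frame) == []

    def test_synonymous_excluded_despite_numbers(self):
        frame = self._frame([
            (100, 0, 22, 80, 20, "synonymous", "SNV"),
            (200, 0, 22, 80, 20, "missense", "SNV"),
        ])
        cands = screen_candidates(region(), frame)
        assert [c.functional_class for c in cands] == ["missense"]

    def test_without_annotations_numeric_criteria_only(self):
        frame = self._frame([(100, 0, 22, 61, 39, None, "SNV")])
        frame["functional_class"] = None
        cands = screen_candidates(region(), frame)
        assert len(cands) == 1

    def test_adsi_at_most_half_excluded(self):
        frame = self._frame([(100, 0, 22, 50, 50, "missense", "SNV")])  # adsi 0.5
        assert screen_candidates(region(), frame) == []

    def test_variants_outside_region_ignored(self):
        frame = self._frame([(100, 0, 22, 61, 39, "missense", "SNV")])
        assert screen_candidates(region(chrom="Chr09"), frame) == []


class TestWindowMeanInequality:
    def test_adsi_window_mean_dominates_dsi_magnitude(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            frame = indexed_frame(rng.uniform(-1, 1, rng.integers(10, 200)))
            n = int(rng.integers(2, 9))
            if len(frame) < n:
                continue
            (curve,) = fit_windows(frame, n)
            assert (
                curve.points["mean_adsi"] + 1e-12 >= curve.points["mean_dsi"].abs()
            ).all()
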