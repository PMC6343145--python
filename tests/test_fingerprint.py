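import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dilongqc as dq
from dilongqc import fingerprint as fp
from dilongqc.signal import Chromatogram, Peak, PeakTable


def make_table(batch_id, peaks):
    """peaks: list of (rt, area)."""
    return PeakTable(
        batch_id=batch_id,
        peaks=[
            Peak(apex_rt=rt, height=area * 8.0, area=area, left_bound=rt - 0.2,
                 right_bound=rt + 0.2, snr=100.0)
            for rt, area in peaks
        ],
    )


class TestMatchCommonPeaks:
    def test_identical_tables_give_identity_clustering(self):
        peaks = [(3.2, 10.0), (9.35, 50.0), (13.4, 20.0)]
        tables = [make_table(f"b{i}", peaks) for i in range(3)]
        cpt = dq.match_common_peaks(tables)
        assert cpt.n_peaks == 3
        assert np.allclose(cpt.mean_rts, [3.2, 9.35, 13.4])
        assert np.all(cpt.prevalence == 1.0)

    def test_nearby_apexes_merge_to_mean_rt(self):
        # hand-derived: 9.35 and 9.41 within tolerance merge, mean 9.38
        tables = [make_table("a", [(9.35, 10.0)]), make_table("b", [(9.41, 12.0)])]
        cpt = dq.match_common_peaks(tables, rt_tolerance=0.1)
        assert cpt.n_peaks == 1
        assert cpt.mean_rts[0] == pytest.approx(9.38)
        assert cpt.prevalence[0] == 1.0

    def test_distant_apexes_stay_separate(self):
        tables = [make_table("a", [(9.35, 10.0)]), make_table("b", [(9.80, 12.0)])]
        cpt = dq.match_common_peaks(tables, rt_tolerance=0.1)
        assert cpt.n_peaks == 2
        assert np.allclose(cpt.prevalence, 0.5)

    def test_authentic_study_has_all_five_nucleosides_ubiquitous(self, study42):
        _, _, _, _, _, tables = study42
        cpt = dq.match_common_peaks(tables[:22])
        ubiquitous = cpt.mean_rts[cpt.prevalence >= 1.0]
        expected = [dq.DEFAULT_RTS[a] for a in dq.ANALYTES if a != "adenosine"]
        assert len(ubiquitous) == 5
        assert np.allclose(sorted(ubiquitous), expected, atol=0.05)

    def test_empty_table_list_rejected(self):
        with pytest.raises(ValueError):
            dq.match_common_peaks([])


class TestSelectReferencePeak:
    def test_default_strategy_picks_largest_ubiquitous_peak(self, study42):
        _, _, _, _, _, tables = study42
        cpt = dq.match_common_peaks(tables[:22])
        ref = dq.select_reference_peak(cpt)
        assert cpt.mean_rts[ref] == pytest.approx(9.35, abs=0.05)

    def test_single_common_peak_is_selected(self):
        tables = [make_table("a", [(9.35, 10.0)]), make_table("b", [(9.36, 12.0)])]
        cpt = dq.match_common_peaks(tables)
        assert dq.select_reference_peak(cpt) == 0

    def test_fixed_rt_strategy_agrees_with_default_on_fixture(self, study42):
        _, _, _, _, _, tables = study42
        cpt = dq.match_common_peaks(tables[:22])
        assert dq.select_reference_peak(cpt) == dq.select_reference_peak(cpt, "fixed-rt:9.35")

    def test_no_ubiquitous_peak_is_an_error(self):
        tables = [make_table("a", [(9.35, 10.0)]), make_table("b", [(9.80, 12.0)])]
        cpt = dq.match_common_peaks(tables, rt_tolerance=0.1)
        with pytest.raises(ValueError):
            dq.select_reference_peak(cpt)


class TestRelativeMetrics:
    def _cpt(self):
        tables = [
            make_table("a", [(3.20, 50.0), (9.35, 100.0)]),
            make_table("b", [(3.20, 30.0), (9.35, 100.0)]),
        ]
        return dq.match_common_peaks(tables)

    def test_reference_column_is_exactly_one(self):
        cpt = dq.relative_metrics(self._cpt(), ref_index=1)
        assert np.all(cpt.rrts[:, 1] == 1.0)
        assert np.all(cpt.rpas[:, 1] == 1.0)

    def test_rrt_and_rpa_are_ratios_to_reference(self):
        cpt = dq.relative_metrics(self._cpt(), ref_index=1)
        assert cpt.rrts[0, 0] == pytest.approx(3.20 / 9.35, abs=1e-9)  # 0.342
        assert cpt.rpas[0, 0] == pytest.approx(0.5)
        assert cpt.rpas[1, 0] == pytest.approx(0.3)

    def test_zero_reference_area_names_batch(self):
        tables = [
            make_table("a", [(3.20, 50.0), (9.35, 100.0)]),
            make_table("missing_ref", [(3.20, 30.0)]),
        ]
        cpt = dq.match_common_peaks(tables)
        with pytest.raises(ValueError, match="missing_ref"):
            dq.relative_metrics(cpt, ref_index=1)


class TestMeanFusion:
    def _chrom(self, values, batch_id="x"):
        t = 0.5 * np.arange(len(values))
        return Chromatogram(time=t, intensity=np.asarray(values, float), batch_id=batch_id)

    def test_identical_traces_fuse_to_themselves(self):
        c = self._chrom([0, 1, 5, 1, 0])
        assert np.allclose(dq.mean_fusion([c, c, c]), c.intensity)

    def test_two_traces_average_pointwise(self):
        a = self._chrom([0, 2, 4, 6, 8])
        b = self._chrom([8, 6, 4, 2, 0])
        assert np.allclose(dq.mean_fusion([a, b]), [4, 4, 4, 4, 4])

    def test_balanced_duplication_does_not_change_fusion(self):
        a = self._chrom([0, 1, 5, 1, 0])
        b = self._chrom([2, 3, 1, 3, 2])
        assert np.allclose(dq.mean_fusion([a, a, b, b]), dq.mean_fusion([a, b]))

    def test_mismatched_grids_rejected(self):
        a = self._chrom([0, 1, 2])
        b = Chromatogram(time=np.array([0.0, 1.0, 2.0]), intensity=np.zeros(3))
        with pytest.raises(ValueError):
            dq.mean_fusion([a, b])


class TestSimilarity:
    def _chrom(self, values):
        t = 0.5 * np.arange(len(values))
        return Chromatogram(time=t, intensity=np.asarray(values, float))

    def test_self_similarity_is_one(self):
        c = self._chrom([0, 1, 5, 1, 0])
        assert dq.similarity(c, c.intensity) == pytest.approx(1.0)

    def test_correlation_is_scale_invariant(self):
        c = self._chrom([0, 1, 5, 1, 0])
        assert dq.similarity(c, 2.0 * c.intensity) == pytest.approx(1.0)

    def test_closed_form_pearson_on_fixed_vectors(self):
        c = self._chrom([1, 2, 3, 4, 5])
        assert dq.similarity(c, np.array([2.0, 4, 6, 8, 10])) == pytest.approx(1.0)
        assert dq.similarity(c, np.array([5.0, 4, 3, 2, 1])) == pytest.approx(-1.0)

    def test_zero_variance_trace_is_undefined(self):
        c = self._chrom([3, 3, 3, 3, 3])
        assert np.isnan(dq.similarity(c, np.array([0.0, 1, 2, 3, 4])))

    def test_cosine_mode(self):
        c = self._chrom([1, 0, 0])
        assert dq.similarity(c, np.array([0.0, 1.0, 0.0]), mode="cosine") == pytest.approx(0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_pearson_matches_brute_force_covariance(self, seed):
        # independent oracle: two-pass covariance / variance computation
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.5 * x
        chrom = Chromatogram(time=np.arange(50.0), intensity=x)
        mx, my = x.mean(), y.mean()
        cov = np.sum((x - mx) * (y - my))
        brute = cov / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
        assert dq.similarity(chrom, y) == pytest.approx(brute, abs=1e-12)


class TestCharacteristicPeaks:
    def test_authentic_study_yields_five(self, study42):
        _, _, _, _, corrected, tables = study42
        model, _ = dq.build_fingerprint(corrected[:22], tables[:22])
        assert len(model.characteristic_peaks) == 5

    def test_adulterant_studies_yield_six(self, study42):
        _, _, _, _, corrected, tables = study42
        for lo, hi in [(22, 31), (31, 42)]:
            model, _ = dq.build_fingerprint(corrected[lo:hi], tables[lo:hi])
            assert len(model.characteristic_peaks) == 6

    def test_threshold_one_excludes_peak_missing_in_any_batch(self):
        tables = [
            make_table("a", [(3.2, 10.0), (9.35, 50.0)]),
            make_table("b", [(9.35, 40.0)]),
        ]
        cpt = dq.match_common_peaks(tables)
        assert dq.characteristic_peaks(cpt, prevalence_threshold=1.0) == [1]
        assert dq.characteristic_peaks(cpt, prevalence_threshold=0.5) == [0, 1]


class TestBatchProperties:
    def test_permutation_invariance_of_fingerprint(self, study42):
        _, _, _, _, corrected, tables = study42
        sub_c, sub_t = corrected[:6], tables[:6]
        model_a, cpt_a = dq.build_fingerprint(sub_c, sub_t)
        order = [3, 0, 5, 1, 4, 2]
        model_b, cpt_b = dq.build_fingerprint(
            [sub_c[i] for i in order], [sub_t[i] for i in order]
        )
        assert np.allclose(cpt_a.mean_rts, cpt_b.mean_rts)
        assert np.allclose(model_a.mean_vector, model_b.mean_vector)
        assert np.allclose(sorted(cpt_a.areas.sum(axis=0)), sorted(cpt_b.areas.sum(axis=0)))

    def test_member_batches_beat_pure_noise_similarity(self, default_params):
        # a batch correlates better with its own set's fusion than noise does
        for seed in range(20):
            design = dq.StudyDesign(
                batches=tuple((f"b{i}", "P. aspergillum") for i in range(4)), seed=seed
            )
            chroms, _, _ = dq.generate_study(design, params=default_params)
            corrected = [dq.correct_baseline(c) for c in chroms]
            vec = dq.mean_fusion(corrected)
            rng = np.random.default_rng(10_000 + seed)
            noise = Chromatogram(
                time=corrected[0].time,
                intensity=rng.normal(0.0, 0.05, corrected[0].time.size),
            )
            noise_sim = dq.similarity(noise, vec)
            for c in corrected:
                assert dq.similarity(c, vec) > noise_sim

    def test_authentic_similarity_floor_across_seeds(self, default_params):
        # the paper-scale condition: min similarity of 22 authentic batches
        # stays above 0.811 in at least 95 of 100 seeded studies
        hits = 0
        design_species = tuple((str(i), "P. aspergillum") for i in range(1, 23))
        for seed in range(100):
            design = dq.StudyDesign(batches=design_species, seed=seed)
            chroms, _, _ = dq.generate_study(design, params=default_params)
            corrected = [dq.correct_baseline(c) for c in chroms]
            vec = dq.mean_fusion(corrected)
            sims = [dq.similarity(c, vec) for c in corrected]
            hits += min(sims) >= 0.811
        assert hits >= 95


def test_fingerprint_model_round_trips_through_json(tmp_path, study42):
    _, _, _, _, corrected, tables = study42
    model, _ = dq.build_fingerprint(corrected[:22], tables[:22])
    path = tmp_path / "model.json"
    model.save(path)
    back = dq.FingerprintModel.load(path)
    assert back.reference_peak_index == model.reference_peak_index
    assert back.characteristic_peaks == model.characteristic_peaks
    assert np.allclose(back.mean_vector, model.mean_vector)
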