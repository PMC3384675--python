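"""Correlator: POF definition, FFT vs spatial oracle, peaks, detection."""

import numpy as np
import pytest

import optalign as oa
from optalign.codec import ObjectImage, SceneImage


def _random_scene(rng, w=100, h=100):
    seq = oa.random_database(w * h, rng)
    return SceneImage(oa.encode(seq, width=w).pixels, db_offset=0), seq


def _embed(rng, start, qlen, w=100, h=100):
    """Scene whose [start, start+qlen) window is the query."""
    scene, seq = _random_scene(rng, w, h)
    return scene, oa.encode(seq[start : start + qlen], width=w)


class TestPof:
    def test_unit_magnitude_on_support(self, rng):
        obj = oa.encode(oa.random_database(500, rng), width=100)
        filt = oa.pof(obj, 100, 100)
        mag = np.abs(filt)
        nz = mag > 0
        assert nz.any()
        np.testing.assert_allclose(mag[nz], 1.0, atol=1e-12)

    def test_impulse_gives_constant_zero_phase_filter(self):
        obj = ObjectImage(np.array([[1]]), length=1)
        filt = oa.pof(obj, 8, 8)
        np.testing.assert_allclose(filt, np.ones((8, 8)), atol=1e-12)

    def test_all_zero_object_yields_zero_filter_not_nan(self):
        obj = ObjectImage(np.zeros((2, 4), dtype=int), length=8)
        with pytest.warns(UserWarning):
            filt = oa.pof(obj, 4, 4)
        assert np.all(filt == 0) and not np.isnan(filt).any()

    def test_object_larger_than_frame_rejected(self):
        obj = oa.encode("ACGT" * 30, width=10)
        with pytest.raises(ValueError):
            oa.pof(obj, 10, 5)

    def test_deterministic_given_object(self, rng):
        obj = oa.encode(oa.random_database(200, rng), width=50)
        a = oa.pof(obj, 50, 50)
        b = oa.pof(obj, 50, 50)
        assert np.array_equal(a, b)


class TestCorrelate:
    def test_matched_filter_equals_bruteforce_spatial_correlation(self, rng):
        """FFT-domain CMF correlation == direct circular cross-correlation."""
        for _ in range(5):
            scene_px = rng.integers(0, 256, (8, 8))
            obj_px = rng.integers(0, 256, (3, 8))
            scene = SceneImage(scene_px, db_offset=0)
            obj = ObjectImage(obj_px, length=24)
            plane = oa.correlate(scene, oa.matched_filter(obj, 8, 8)).values
            padded = np.zeros((8, 8))
            padded[:3] = obj_px
            brute = np.zeros((8, 8))
            for dy in range(8):
                for dx in range(8):
                    acc = 0.0
                    for y in range(8):
                        for x in range(8):
                            acc += scene_px[(y + dy) % 8, (x + dx) % 8] * padded[y, x]
                    brute[dy, dx] = acc  # IFFT(S * conj(O)) carries no 1/N
            np.testing.assert_allclose(plane, brute, rtol=1e-9)

    def test_zero_filter_gives_zero_plane(self, rng):
        scene, _ = _random_scene(rng, 10, 10)
        plane = oa.correlate(scene, np.zeros((10, 10), dtype=complex))
        assert np.all(plane.values == 0)

    def test_dimension_mismatch_rejected(self, rng):
        scene, _ = _random_scene(rng, 10, 10)
        with pytest.raises(ValueError):
            oa.correlate(scene, np.zeros((5, 5), dtype=complex))

    def test_plane_nonnegative_and_scene_shaped(self, rng):
        scene, seq = _random_scene(rng, 20, 20)
        obj = oa.encode(seq[:60], width=20)
        plane = oa.correlate(scene, oa.pof(obj, 20, 20))
        assert plane.values.shape == (20, 20)
        assert (plane.values >= 0).all()

    def test_peak_at_embedding_offset_first_half_columns(self, rng):
        """Exact-copy embeddings localize at (row, col) of the start base."""
        for _ in range(40):
            r = int(rng.integers(0, 45))
            c = int(rng.integers(0, 40))  # clear of the row-split boundary
            start = r * 100 + c
            scene, obj = _embed(rng, start, 500)
            peak = oa.find_peak(oa.correlate(scene, oa.pof(obj, 100, 100)))
            assert (peak.row, peak.col) == (r, c)


class TestFindPeak:
    def test_single_nonzero_cell(self):
        values = np.zeros((5, 5))
        values[3, 1] = 2.0
        peak = oa.find_peak(values)
        assert (peak.row, peak.col, peak.intensity) == (3, 1, 2.0)

    def test_constant_plane_tie_breaks_to_origin(self):
        peak = oa.find_peak(np.ones((4, 6)))
        assert (peak.row, peak.col) == (0, 0)

    def test_agreement_with_exhaustive_scan(self, rng):
        for _ in range(10):
            values = rng.random((100, 100))
            peak = oa.find_peak(values)
            best = max(
                ((values[r, c], -r, -c) for r in range(100) for c in range(100)),
            )
            assert (peak.row, peak.col) == (-best[1], -best[2])
            assert peak.intensity == best[0]


class TestDetect:
    def test_exact_embedding_localizes_exactly_in_first_half_of_row(self, rng):
        for _ in range(15):
            start = int(rng.integers(0, 45)) * 100 + int(rng.integers(0, 40))
            scene, obj = _embed(rng, start, 700)
            det = oa.detect(scene, obj, threshold=0.0)
            assert det.present
            assert det.est_start_base == start
            assert not det.shift_flag

    def test_second_half_start_errs_by_zero_or_one_row(self, rng):
        """Starts in the second half of a row: 0 or +width localization error."""
        shifted = 0
        for _ in range(30):
            start = int(rng.integers(0, 45)) * 100 + int(rng.integers(50, 100))
            scene, obj = _embed(rng, start, 700)
            det = oa.detect(scene, obj, threshold=0.0)
            assert det.shift_flag
            assert det.est_start_base - start in (0, 100)
            shifted += det.est_start_base != start
        assert shifted > 0  # the one-pixel vertical shift does occur

    def test_shift_correct_subtracts_one_row(self, rng):
        start = 10 * 100 + 80
        scene, obj = _embed(rng, start, 700)
        plain = oa.detect(scene, obj, threshold=0.0)
        corrected = oa.detect(scene, obj, threshold=0.0, shift_correct=True)
        assert corrected.est_start_base == plain.est_start_base - 100

    def test_infinite_threshold_never_present(self, rng):
        scene, obj = _embed(rng, 0, 500)
        assert not oa.detect(scene, obj, threshold=np.inf).present

    def test_negative_threshold_rejected(self, rng):
        scene, obj = _embed(rng, 0, 500)
        with pytest.raises(ValueError):
            oa.detect(scene, obj, threshold=-1.0)


class TestSearch:
    def test_planted_query_found_exactly_once(self, rng):
        db = oa.random_database(300_000, rng)
        start = 123_432  # first-half column: single unsplit peak
        obj = oa.encode(db[start : start + 400], width=100)
        scenes = oa.tile_database(db, 100, 100, overlap=400)
        detections = oa.search(scenes, obj, threshold=800.0)
        assert len(detections) == len(scenes)
        hits = [d for d in detections if d.present]
        assert len(hits) == 1
        assert hits[0].est_start_base == start

    def test_insufficient_overlap_rejected(self, rng):
        db = oa.random_database(30_000, rng)
        scenes = oa.tile_database(db, 100, 100, overlap=100)
        obj = oa.encode(db[:500], width=100)
        with pytest.raises(ValueError, match="overlap"):
            oa.search(scenes, obj, threshold=100.0)

    def test_empty_scene_list(self, rng):
        obj = oa.encode("ACGT", width=4)
        assert oa.search([], obj, threshold=1.0) == []


class TestBatchPeaks:
    def test_matches_per_scene_correlation(self, rng):
        db = oa.random_database(25_000, rng)
        scenes = oa.tile_database(db, 100, 100, overlap=500)
        obj = oa.encode(db[300:800], width=100)
        filt = oa.pof(obj, 100, 100)
        intens, rows, cols = oa.batch_peaks(oa.scene_spectra(scenes), filt)
        for i, scene in enumerate(scenes):
            peak = oa.find_peak(oa.correlate(scene, filt))
            assert (rows[i], cols[i]) == (peak.row, peak.col)
            assert intens[i] == pytest.approx(peak.intensity, rel=1e-12)
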