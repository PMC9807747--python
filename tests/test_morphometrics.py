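"""Axes, circularity, Feret extents, distribution summaries, correlation."""

import numpy as np
import pytest
from scipy import ndimage

import toromorph as tm
from toromorph.morphometrics import MeasurementError


def disk(radius, n=64):
    yy, xx = np.mgrid[:n, :n] - (n - 1) / 2.0
    return (np.hypot(yy, xx) <= radius).astype(np.uint8)


class TestMeasureParticle:
    def test_filled_circle(self):
        rec = tm.measure_particle(disk(20), pixel_size=10.0)
        assert rec.major_nm == pytest.approx(400, rel=0.02)
        assert rec.minor_nm == pytest.approx(400, rel=0.02)
        assert rec.circularity > 0.95

    def test_rectangle_matches_second_moment_closed_form(self):
        """A solid w x h rectangle has moment axes w*2/sqrt(3), h*2/sqrt(3)."""
        mask = np.zeros((80, 80), dtype=np.uint8)
        mask[20:50, 10:70] = 1          # h=30, w=60
        rec = tm.measure_particle(mask, pixel_size=1.0)
        assert rec.major_nm == pytest.approx(60 * 2 / np.sqrt(3), rel=0.01)
        assert rec.minor_nm == pytest.approx(30 * 2 / np.sqrt(3), rel=0.01)
        assert rec.feret_max_nm == pytest.approx(np.hypot(60, 30), rel=0.02)
        assert rec.feret_min_nm == pytest.approx(30, abs=1.0)

    def test_default_ellipsoid_projection_axes(self):
        img = tm.project_at_angle(tm.build_ellipsoid(), 0.0, 8.0)
        rec = tm.measure_particle(img.pixels > 0, pixel_size=8.0)
        assert rec.major_nm == pytest.approx(710, abs=8.0)
        assert rec.minor_nm == pytest.approx(280, abs=8.0)

    def test_largest_component_selected(self):
        mask = np.zeros((60, 60), dtype=np.uint8)
        mask[5:10, 5:10] = 1            # small blob
        mask[20:50, 20:50] = 1          # large blob
        rec = tm.measure_particle(mask, pixel_size=1.0)
        assert rec.area_nm2 == pytest.approx(900, rel=0.01)

    def test_empty_mask_raises_with_id(self):
        with pytest.raises(MeasurementError, match="p7"):
            tm.measure_particle(np.zeros((30, 30)), 10.0, particle_id="p7")

    def test_rotation_equivariance_right_angle(self):
        mask = np.zeros((70, 70), dtype=np.uint8)
        mask[20:40, 10:60] = 1
        a = tm.measure_particle(mask, 1.0)
        b = tm.measure_particle(np.rot90(mask), 1.0)
        assert a.major_nm == b.major_nm and a.minor_nm == b.minor_nm

    def test_rotation_equivariance_arbitrary_angle(self):
        ell = tm.project_at_angle(tm.build_ellipsoid(), 0.0, 8.0).pixels > 0
        rot = ndimage.rotate(ell.astype(float), 33.0, reshape=True, order=1) > 0.5
        a = tm.measure_particle(ell, 8.0)
        b = tm.measure_particle(rot, 8.0)
        assert b.major_nm == pytest.approx(a.major_nm, abs=8.0)
        assert b.minor_nm == pytest.approx(a.minor_nm, abs=8.0)

    def test_scale_equivariance(self):
        mask = disk(15)
        a = tm.measure_particle(mask, 10.0)
        b = tm.measure_particle(mask, 20.0)
        assert b.major_nm == pytest.approx(2 * a.major_nm)
        assert b.area_nm2 == pytest.approx(4 * a.area_nm2)
        assert b.circularity == a.circularity

    def test_fill_holes_reports_outer_diameter_of_annulus(self):
        ring = disk(25) & ~disk(12)
        filled = tm.measure_particle(ring, 1.0, fill_holes=True)
        hollow = tm.measure_particle(ring, 1.0, fill_holes=False)
        assert filled.major_nm == pytest.approx(50, abs=1.5)
        assert hollow.major_nm > filled.major_nm   # moment axes inflate on rings


def test_hole_diameter_of_annulus():
    ring = disk(25) & ~disk(12)
    assert tm.measure_hole(ring, 1.0) == pytest.approx(24, abs=1.5)
    assert tm.measure_hole(disk(20), 1.0) == 0.0


class TestSummaries:
    def _records(self, majors, circs):
        return [
            tm.MorphometricRecord(
                particle_id=i, major_nm=m, minor_nm=m / 2, circularity=c,
                area_nm2=1.0, feret_max_nm=m, feret_min_nm=m / 2,
            )
            for i, (m, c) in enumerate(zip(majors, circs))
        ]

    def test_single_record_flags_undefined_r(self):
        s = tm.summarize(self._records([500.0], [0.8]))
        assert s.n == 1 and s.major_mean == 500.0 and s.major_sd == 0.0
        assert s.pearson_r is None and s.flags

    def test_mean_sd_match_two_pass_recomputation(self):
        rng = np.random.default_rng(0)
        majors = rng.normal(519, 90, 40)
        circs = rng.uniform(0.4, 1.0, 40)
        s = tm.summarize(self._records(majors, circs))
        mean = sum(majors) / 40
        sd = np.sqrt(sum((m - mean) ** 2 for m in majors) / 39)
        assert s.major_mean == pytest.approx(mean)
        assert s.major_sd == pytest.approx(sd)

    def test_perfectly_anticorrelated_pairs(self):
        majors = [300.0, 400.0, 500.0, 600.0]
        circs = [0.9, 0.8, 0.7, 0.6]
        assert tm.correlate(self._records(majors, circs)) == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_printed_pairs(self):
        majors = [310.0, 420.0, 485.0, 560.0, 650.0]
        circs = [0.91, 0.78, 0.81, 0.62, 0.55]
        mx, my = np.mean(circs), np.mean(majors)
        num = sum((c - mx) * (m - my) for c, m in zip(circs, majors))
        den = np.sqrt(sum((c - mx) ** 2 for c in circs)
                      * sum((m - my) ** 2 for m in majors))
        assert tm.correlate(self._records(majors, circs)) == pytest.approx(num / den)

    def test_constant_field_flagged_not_zero(self):
        with pytest.raises(ValueError, match="constant"):
            tm.correlate(self._records([500.0] * 5, [0.5, 0.6, 0.7, 0.8, 0.9]))

    def test_elongation_coupled_cohort_anticorrelates(self):
        """Cohorts in which longer particles are more elongated show a
        negative circularity-major-axis correlation, as in the real data."""
        rng = np.random.default_rng(1)
        majors = rng.normal(519, 90, 200)
        minors = np.clip(rng.normal(329, 40, 200), 100, None)
        recs = []
        for i, (M, m) in enumerate(zip(majors, np.minimum(minors, majors))):
            ecc = m / M
            circ = np.clip(ecc + rng.normal(0, 0.05), 0.05, 1.0)
            recs.append(tm.MorphometricRecord(
                particle_id=i, major_nm=M, minor_nm=m, circularity=circ,
                area_nm2=1.0, feret_max_nm=M, feret_min_nm=m,
            ))
        assert tm.correlate(recs) < -0.3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tm.summarize([])
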