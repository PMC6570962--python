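"""Synthetic scenes: analytic truth, determinism, pipeline recovery."""
from __future__ import annotations

import json
import math
from collections import Counter

import numpy as np
import pytest

from pelletmorph.errors import ConfigurationError
from pelletmorph.imaging_io import Calibration, ClassificationConfig, RunConfig
from pelletmorph.pipeline import process_image
from pelletmorph.synthgen import (
    SceneSpec,
    SyntheticShapeSpec,
    make_shape,
    make_test_tree,
    render_scene,
    standard_scene,
)


def _process(record, um_per_px=1.0, **kwargs):
    config = RunConfig(
        input_root=".", output_root=".", calibration=Calibration(um_per_px), **kwargs
    )
    return process_image(record, config)


class TestShapeTruth:
    def test_disc_truth_is_ideal_pellet(self):
        spec = SyntheticShapeSpec("disc", {"radius": 15.0}, (50.0, 50.0))
        truth = spec.truth()
        assert truth.area_um2 == pytest.approx(706.858, abs=1e-3)
        assert truth.morphology_number == 1.0
        assert truth.solidity == 1.0
        assert truth.expected_class(ClassificationConfig()) == "pellet"

    def test_rectangle_truth_dispersed(self):
        spec = SyntheticShapeSpec("rectangle", {"width": 20.0, "height": 10.0}, (50.0, 50.0))
        truth = spec.truth()
        assert truth.area_um2 == 200.0
        assert truth.feret_max_um == pytest.approx(math.hypot(20, 10))
        assert truth.feret_min_um == 10.0
        assert truth.expected_class(ClassificationConfig()) == "dispersed"

    def test_small_disc_is_artefact(self):
        truth = SyntheticShapeSpec("disc", {"radius": 5.0}, (20.0, 20.0)).truth()
        assert truth.area_um2 == pytest.approx(78.54, abs=0.01)
        assert truth.expected_class(ClassificationConfig()) == "artefact"

    def test_cross_truth_matches_closed_form(self):
        truth = SyntheticShapeSpec(
            "cross", {"length": 30.0, "thickness": 10.0}, (50.0, 50.0)
        ).truth()
        assert truth.area_um2 == 500.0
        assert truth.solidity == pytest.approx(5 / 7)

    def test_ellipse_truth(self):
        truth = SyntheticShapeSpec("ellipse", {"a": 20.0, "b": 10.0}, (50.0, 50.0)).truth()
        assert truth.area_um2 == pytest.approx(math.pi * 200)
        assert truth.aspect_ratio == 2.0
        assert truth.morphology_number == pytest.approx(0.5**1.5)

    def test_blob_truth_tagged_derived(self):
        spec = SyntheticShapeSpec(
            "blob", {"discs": [(0.0, 0.0, 8.0), (6.0, 0.0, 8.0)]}, (40.0, 40.0)
        )
        truth = spec.truth()
        assert truth.derived
        assert truth.solidity < 1.0  # union of two discs is concave
        single = math.pi * 64
        assert single < truth.area_um2 < 2 * single


class TestRasterConvergence:
    @pytest.mark.parametrize("radius, tol", [(30.0, 0.02), (150.0, 0.005)])
    def test_disc_area_and_feret_converge(self, radius, tol):
        # the pixel-corner hull of a centre-rasterized disc approximates a
        # disc of diameter 2r + 1 (half a pixel of dilation on each side),
        # so that is the convention's convergence target for the Feret
        cal = Calibration(1.0)
        canvas = (int(2 * radius) + 20, int(2 * radius) + 20)
        centre = (canvas[1] / 2, canvas[0] / 2)
        spec = SyntheticShapeSpec("disc", {"radius": radius}, centre)
        rr, cc = make_shape(spec, cal, canvas)
        assert rr.size == pytest.approx(math.pi * radius**2, rel=tol)
        from pelletmorph.segmentation import label_particles
        from pelletmorph.shape_metrics import compute_metrics

        mask = np.zeros(canvas, dtype=bool)
        mask[rr, cc] = True
        met = compute_metrics(label_particles(mask)[0], cal)
        assert met.feret_max == pytest.approx(2 * radius + 1, rel=tol)


class TestRenderScene:
    def test_same_seed_is_byte_identical(self):
        spec = standard_scene(seed=5, noise_sigma=8.0)
        rec1, _ = render_scene(spec)
        rec2, _ = render_scene(spec)
        assert rec1.raster.tobytes() == rec2.raster.tobytes()

    def test_manifest_lists_every_shape_once(self):
        spec = standard_scene(seed=0)
        _, manifest = render_scene(spec)
        assert len(manifest) == len(spec.shapes)
        classes = Counter(m["expected_class"] for m in manifest)
        assert classes == {"pellet": 4, "dispersed": 5, "artefact": 2}
        assert sum(m["touches_border"] for m in manifest) == 1

    def test_border_shape_without_permission_is_error(self):
        cal = Calibration(1.0)
        spec = SceneSpec(
            canvas_px=(64, 64),
            calibration=cal,
            shapes=[SyntheticShapeSpec("disc", {"radius": 10.0}, (64.0, 32.0))],
        )
        with pytest.raises(ConfigurationError, match="border"):
            render_scene(spec)

    def test_overlap_without_permission_is_error(self):
        cal = Calibration(1.0)
        spec = SceneSpec(
            canvas_px=(64, 64),
            calibration=cal,
            shapes=[
                SyntheticShapeSpec("disc", {"radius": 10.0}, (30.0, 30.0)),
                SyntheticShapeSpec("disc", {"radius": 10.0}, (35.0, 30.0)),
            ],
        )
        with pytest.raises(ConfigurationError, match="overlap"):
            render_scene(spec)


class TestSceneRecovery:
    def test_counts_recovered_from_clean_scene(self):
        record, _ = render_scene(standard_scene(seed=2))
        result, _, n_artefacts = _process(record)
        counts = Counter(m.class_label for m in result.particles)
        assert counts == {"pellet": 3, "dispersed": 5}
        assert n_artefacts == 2  # border disc excluded before classification

    def test_border_disc_alone_yields_no_particles(self):
        cal = Calibration(1.0)
        spec = SceneSpec(
            canvas_px=(64, 64),
            calibration=cal,
            shapes=[SyntheticShapeSpec("disc", {"radius": 12.0}, (64.0, 32.0))],
            allow_border_overlap=True,
        )
        record, _ = render_scene(spec)
        result, _, n_artefacts = _process(record)
        assert result.particles == [] and n_artefacts == 0

    def test_class_counts_robust_to_noise(self):
        # automatic thresholding alone must absorb σ = 10 grey levels of
        # additive noise (a percentile contrast stretch is skipped: on a
        # sparse-foreground scene it would amplify background noise)
        clean_record, _ = render_scene(standard_scene(seed=3, noise_sigma=0.0))
        noisy_record, _ = render_scene(standard_scene(seed=3, noise_sigma=10.0))
        clean = Counter(
            m.class_label
            for m in _process(clean_record, contrast_saturation=0.0)[0].particles
        )
        noisy = Counter(
            m.class_label
            for m in _process(noisy_record, contrast_saturation=0.0)[0].particles
        )
        assert clean == noisy


class TestMakeTestTree:
    def test_layout_and_manifest(self, tmp_path):
        manifest = make_test_tree(tmp_path, n_subdirs=2, images_per_subdir=3, seed=1)
        pngs = sorted(p.relative_to(tmp_path).as_posix() for p in tmp_path.rglob("*.png"))
        assert len(pngs) == 6
        assert pngs[0].startswith("s01/") and pngs[-1].startswith("s02/")
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert set(on_disk["subdirs"]) == {"s01", "s02"}
        for sub in manifest["subdirs"].values():
            assert 0 <= sub["expected_pellet_fraction_pct"] <= 100

    def test_all_pellet_composition_gives_100_percent(self, tmp_path):
        manifest = make_test_tree(
            tmp_path, n_subdirs=1, images_per_subdir=2,
            composition={"pellet": 3}, seed=4,
        )
        assert manifest["subdirs"]["s01"]["expected_pellet_fraction_pct"] == 100.0

    def test_seeded_rerun_is_identical(self, tmp_path):
        make_test_tree(tmp_path / "a", n_subdirs=1, images_per_subdir=2, seed=9)
        make_test_tree(tmp_path / "b", n_subdirs=1, images_per_subdir=2, seed=9)
        for p in sorted((tmp_path / "a").rglob("*.png")):
            q = tmp_path / "b" / p.relative_to(tmp_path / "a")
            assert p.read_bytes() == q.read_bytes()

    def test_zero_subdirs_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError):
            make_test_tree(tmp_path, n_subdirs=0)
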