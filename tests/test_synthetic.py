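"""Lattice generation, rendering regimes and patch datasets."""

import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

from pnnmesh import (
    LatticeParams,
    LatticePlacementError,
    MeshContour,
    NoiseModel,
    Regime,
    RenderParams,
    generate_lattice,
    make_patch_dataset,
    polarity_index,
    render_scene,
    simplify_contour,
    split_dataset,
)


class TestGenerateLattice:
    def test_single_mesh_inside_small_domain(self):
        lat = generate_lattice(
            LatticeParams(n_meshes=1, mean_mesh_diameter=20, domain_size=(64, 64)), seed=0
        )
        assert lat.n_meshes == 1
        (cx, cy), = lat.centroids()
        assert 0 <= cx <= 64 and 0 <= cy <= 64

    def test_seeded_determinism(self):
        params = LatticeParams(n_meshes=10, domain_size=(256, 256))
        a = generate_lattice(params, seed=5)
        b = generate_lattice(params, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.meshes, b.meshes))
        assert a.adjacency == b.adjacency

    def test_interiors_do_not_overlap_rasterized_oracle(self, small_lattice):
        """Brute force: rasterise every polygon interior at 1 px and check
        pairwise mask intersections are empty."""
        w, h = small_lattice.domain_size
        masks = []
        for m in small_lattice.meshes:
            grid = np.zeros((h, w), dtype=bool)
            rr, cc = draw_polygon(m[:, 1], m[:, 0], shape=(h, w))
            grid[rr, cc] = True
            masks.append(grid)
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                # rasterisation tolerance: shared borders may collide on
                # boundary pixels, interiors must not (allow a 1-px seam)
                overlap = masks[i] & masks[j]
                assert overlap.sum() <= max(masks[i].sum(), masks[j].sum()) * 0.02

    def test_vertex_counts_concentrate_on_4_to_7(self):
        lat = generate_lattice(
            LatticeParams(n_meshes=80, mean_mesh_diameter=24, domain_size=(512, 512)), seed=1
        )
        counts = [len(m) for m in lat.meshes]
        frac_4_7 = np.mean([4 <= c <= 7 for c in counts])
        assert frac_4_7 >= 0.8
        # pentagons/hexagons are the most frequent classes
        from collections import Counter

        common = Counter(counts).most_common(2)
        assert {c for c, _ in common} <= {5, 6, 7}

    def test_impossible_request_reports_maximum(self):
        with pytest.raises(LatticePlacementError, match=r"only \d+ meshes"):
            generate_lattice(
                LatticeParams(n_meshes=500, mean_mesh_diameter=30, domain_size=(128, 128)),
                seed=0,
            )

    def test_annulus_restricts_centroids(self):
        lat = generate_lattice(
            LatticeParams(
                n_meshes=12, mean_mesh_diameter=20, domain_size=(300, 300),
                annulus=((150, 150), 60, 130),
            ),
            seed=0,
        )
        d = np.hypot(*(lat.centroids() - [150, 150]).T)
        assert (d > 40).all() and (d < 140).all()

    @pytest.mark.parametrize("kw", [
        dict(n_meshes=0), dict(mean_mesh_diameter=3), dict(jitter=1.5),
        dict(domain_size=(0, 100)),
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            LatticeParams(**kw)


class TestRenderScene:
    def test_seeded_determinism_bit_identical(self, small_lattice):
        params = RenderParams.for_regime("blurred")
        a = render_scene(small_lattice, params, seed=3)
        b = render_scene(small_lattice, params, seed=3)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.target_mask, b.target_mask)

    def test_ridge_peak_on_rasterized_edge(self, small_lattice):
        """Noise-free, blur-free: the brightest pixel along a transect
        crossing one mesh edge lies on the rasterised edge."""
        params = RenderParams(
            regime=Regime.HIGH_CONTRAST, psf_sigma=0.0, noise_model=NoiseModel.NONE
        )
        scene = render_scene(small_lattice, params, seed=0)
        from pnnmesh.render import rasterize_edges

        edges = rasterize_edges(small_lattice, scene.image.shape)
        # transect: pick an edge pixel away from the border, scan across
        ys, xs = np.nonzero(edges)
        inner = (xs > 20) & (xs < 230) & (ys > 20) & (ys < 230)
        y0, x0 = ys[inner][0], xs[inner][0]
        transect = scene.image[y0, x0 - 6 : x0 + 7].astype(int)
        peak_offset = np.argmax(transect) - 6
        assert edges[y0, x0 + peak_offset]

    def test_polar_vertex_to_edge_ratio(self):
        lat = generate_lattice(
            LatticeParams(n_meshes=9, mean_mesh_diameter=30, domain_size=(200, 200)), seed=2
        )
        params = RenderParams.for_regime("polar", vertex_boost=2.0).noiseless()
        scene = render_scene(lat, params, seed=0)
        img = scene.clean
        verts = lat.vertices()
        mids = []
        for m in lat.meshes:
            closed = np.vstack([m, m[:1]])
            for a, b in zip(closed[:-1], closed[1:]):
                if np.hypot(*(b - a)) >= 10.0:  # midpoints of non-degenerate edges
                    mids.append(0.5 * (a + b))
        mids = np.array(mids)

        from pnnmesh.polarity import _sample_bilinear

        def sample(points):
            keep = (points[:, 0] > 3) & (points[:, 0] < 196) & (points[:, 1] > 3) & (points[:, 1] < 196)
            bg = params.background_level * 65535.0
            return np.mean(_sample_bilinear(img, points[keep]) - bg)

        ratio = sample(verts) / sample(mids)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_polar_regime_realizes_polarity_index(self):
        """Closing the generator/metric loop: rendered polar meshes score a
        polarity index within 10% of vertex_boost."""
        lat = generate_lattice(
            LatticeParams(n_meshes=9, mean_mesh_diameter=30, jitter=0.2,
                          diameter_cv=0.05, domain_size=(200, 200)), seed=2
        )
        params = RenderParams.for_regime("polar", vertex_boost=2.0, background_level=0.0).noiseless()
        scene = render_scene(lat, params, seed=0)
        # central mesh, vertices well inside the image; the index is defined
        # on simplified contours whose vertices are geometric corners
        idx = int(np.argmin(np.hypot(*(lat.centroids() - [100, 100]).T)))
        contour = simplify_contour(MeshContour(lat.meshes[idx]))
        prof = polarity_index(scene.clean, contour)
        assert prof.polarity_index == pytest.approx(2.0, rel=0.10)

    def test_three_plane_stack_falloff(self, small_lattice):
        params = RenderParams(
            n_zplanes=3, zplane_falloff=0.5, noise_model=NoiseModel.NONE,
            background_level=0.0,
        )
        scene = render_scene(small_lattice, params, seed=0)
        assert scene.image.shape[0] == 3
        z0 = scene.image[1].astype(float)
        for k in (0, 2):
            ratio = scene.image[k].astype(float).sum() / z0.sum()
            assert ratio == pytest.approx(0.5, rel=0.02)

    def test_bad_bit_depth_rejected(self):
        with pytest.raises(ValueError):
            RenderParams(bit_depth=12)

    def test_vertex_boost_outside_polar_rejected(self):
        with pytest.raises(ValueError):
            RenderParams(regime=Regime.BLURRED, vertex_boost=2.0)


class TestPatchDataset:
    def test_one_patch_per_interior_mesh(self):
        lat = LatticeParams(n_meshes=10, mean_mesh_diameter=24, domain_size=(384, 384))
        rend = RenderParams.for_regime("high_contrast")
        ds = make_patch_dataset(1, lat, rend, patch_size=128, seed=0)
        assert len(ds) + ds.n_skipped == 10
        assert all(s.image.shape == (128, 128) for s in ds.samples)
        assert all(s.target.shape == (128, 128) for s in ds.samples)

    def test_border_meshes_skipped(self):
        # large meshes on a domain barely bigger than the patch: many skips
        lat = LatticeParams(n_meshes=12, mean_mesh_diameter=40, domain_size=(200, 200))
        rend = RenderParams.for_regime("high_contrast")
        ds = make_patch_dataset(1, lat, rend, patch_size=128, seed=0)
        assert ds.n_skipped > 0
        assert len(ds) + ds.n_skipped == 12

    def test_patch_smaller_than_mesh_rejected(self):
        lat = LatticeParams(n_meshes=5, mean_mesh_diameter=40, domain_size=(256, 256))
        rend = RenderParams.for_regime("high_contrast")
        with pytest.raises(ValueError):
            make_patch_dataset(1, lat, rend, patch_size=64, seed=0)

    def test_dataset_hash_reproducible(self):
        lat = LatticeParams(n_meshes=10, mean_mesh_diameter=24, domain_size=(384, 384))
        rend = RenderParams.for_regime("blurred")
        a = make_patch_dataset(1, lat, rend, patch_size=128, seed=4)
        b = make_patch_dataset(1, lat, rend, patch_size=128, seed=4)
        assert a.content_hash() == b.content_hash()

    def test_center_mesh_contour_inside_patch(self, tiny_dataset):
        for s in tiny_dataset.samples:
            v = s.contour.vertices
            assert (v >= 0).all() and (v <= 128).all()

    def test_target_mask_is_center_mesh_only(self, tiny_dataset):
        """The target traces one closed ring around the patch centre."""
        from pnnmesh import mask_to_contour, compute_geometry

        s = tiny_dataset.samples[0]
        c = mask_to_contour(s.target.astype(float), (64, 64))
        true_area = compute_geometry(s.contour).area_px2
        assert compute_geometry(c).area_px2 == pytest.approx(true_area, rel=0.10)


class TestSplitDataset:
    def test_80_20_protocol(self, tiny_dataset):
        n = len(tiny_dataset)
        train, test = split_dataset(tiny_dataset, 0.8, seed=0)
        assert len(train) == round(0.8 * n)
        assert len(train) + len(test) == n
        ids = {s.mesh_id for s in train.samples} | {s.mesh_id for s in test.samples}
        assert len(ids) == n  # disjoint union, no duplicates

    def test_exact_split_at_n1000(self):
        # sample-level protocol check on a synthetic index set
        from pnnmesh.dataset import SyntheticDataset, PatchSample

        dummy = [
            PatchSample(
                image=np.zeros((2, 2), np.float32), target=np.zeros((2, 2), np.uint8),
                mesh_index=i, scene_index=0, contour=None, mesh_id=str(i),
            )
            for i in range(1000)
        ]
        ds = SyntheticDataset(samples=tuple(dummy), patch_size=2, seed=0)
        train, test = split_dataset(ds, 0.8, seed=123)
        assert (len(train), len(test)) == (800, 200)

    def test_empty_dataset_rejected(self):
        from pnnmesh.dataset import SyntheticDataset

        with pytest.raises(ValueError):
            split_dataset(SyntheticDataset(samples=(), patch_size=8, seed=0))

    def test_fraction_one_puts_all_in_train(self, tiny_dataset):
        train, test = split_dataset(tiny_dataset, 1.0, seed=0)
        assert len(train) == len(tiny_dataset) and len(test) == 0
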