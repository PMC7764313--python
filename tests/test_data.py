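"""Data pipeline tests: manifest dialect round trips, oversampling arithmetic,
patch extraction geometry, bilinear resizing and rigid augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ardtnet as a
from ardtnet.data import save_image


def _record(rng, h=100, w=120, image_id="ISIC_0000001", label=1):
    return a.ImageRecord(image_id, rng.random(size=(h, w, 3)).astype(np.float32), label)


# ---------------------------------------------------------------------------
# manifest

class TestManifest:
    def _write_dataset(self, tmp_path, rows, rng):
        for image_id, *_ in rows:
            save_image(tmp_path / f"{image_id}.png", rng.random(size=(16, 16, 3)))
        csv_path = tmp_path / "labels.csv"
        csv_path.write_text("\n".join(",".join(map(str, r)) for r in rows) + "\n")
        return csv_path

    def test_read_preserves_row_order(self, tmp_path, rng):
        rows = [(f"ISIC_000000{i}", i % 2) for i in range(3)]
        csv_path = self._write_dataset(tmp_path, rows, rng)
        m = a.read_manifest(csv_path, tmp_path)
        assert [r.image_id for r in m.records] == [r[0] for r in rows]

    def test_paper_polarity_flips_labels(self, tmp_path, rng):
        # CSV 0 means melanoma in the paper dialect -> canonical positive (1)
        csv_path = self._write_dataset(tmp_path, [("ISIC_0000000", 0), ("ISIC_0000001", 1)], rng)
        m = a.read_manifest(csv_path, tmp_path, polarity="paper")
        assert [r.task1_label for r in m.records] == [1, 0]
        m2 = a.read_manifest(csv_path, tmp_path, polarity="standard")
        assert [r.task1_label for r in m2.records] == [0, 1]

    def test_nonbinary_label_raises_with_row(self, tmp_path, rng):
        csv_path = self._write_dataset(tmp_path, [("ISIC_0000000", 2)], rng)
        with pytest.raises(ValueError, match="row 1"):
            a.read_manifest(csv_path, tmp_path)

    def test_missing_image_names_id(self, tmp_path, rng):
        csv_path = tmp_path / "labels.csv"
        csv_path.write_text("ISIC_9999999,0\n")
        with pytest.raises(FileNotFoundError, match="ISIC_9999999"):
            a.read_manifest(csv_path, tmp_path)

    def test_write_read_roundtrip(self, tmp_path, rng):
        records = [a.ImageRecord(f"ISIC_000000{i}",
                                 rng.random(size=(12, 12, 3)).astype(np.float32),
                                 i % 2, (i // 2) % 2) for i in range(6)]
        m = a.Manifest(records, label_polarity="paper")
        for r in records:
            save_image(tmp_path / f"{r.image_id}.png", r.pixels)
        a.write_manifest(tmp_path / "m.csv", m)
        m2 = a.read_manifest(tmp_path / "m.csv", tmp_path, polarity="paper")
        assert [r.image_id for r in m2.records] == [r.image_id for r in records]
        assert [r.task1_label for r in m2.records] == [r.task1_label for r in records]
        assert [r.task2_label for r in m2.records] == [r.task2_label for r in records]

    def test_header_is_skipped(self, tmp_path, rng):
        save_image(tmp_path / "ISIC_0000000.png", rng.random(size=(8, 8, 3)))
        csv_path = tmp_path / "m.csv"
        csv_path.write_text("image_id,task_1\nISIC_0000000,1\n")
        assert len(a.read_manifest(csv_path, tmp_path)) == 1


# ---------------------------------------------------------------------------
# oversampling

class TestOversampling:
    def test_two_class_balancing(self):
        labels = np.array([0, 0, 1, 1, 1, 1, 1])
        idx = a.balance_indices(labels, seed=0)
        vals, counts = np.unique(labels[idx], return_counts=True)
        assert dict(zip(vals.tolist(), counts.tolist())) == {0: 5, 1: 5}
        # every class-0 original appears at least twice (floor(5/2) = 2)
        uniq, n = np.unique(idx[labels[idx] == 0], return_counts=True)
        assert set(uniq) == {0, 1} and n.min() >= 2

    def test_already_balanced_is_fixed_point(self):
        labels = np.array([0, 1, 0, 1])
        idx = a.balance_indices(labels, seed=3)
        assert sorted(idx.tolist()) == [0, 1, 2, 3]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            a.balance_indices(np.array([], dtype=int), seed=0)

    @given(st.lists(st.integers(0, 2), min_size=3, max_size=40).filter(lambda l: len(set(l)) >= 2),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_balanced_totality_and_conservation(self, labels, seed):
        labels = np.array(labels)
        idx = a.balance_indices(labels, seed)
        _, counts = np.unique(labels[idx], return_counts=True)
        assert counts.max() == counts.min() == np.bincount(labels).max()
        # distinct source indices per class unchanged
        for cls in np.unique(labels):
            assert set(idx[labels[idx] == cls]) == set(np.flatnonzero(labels == cls))

    def test_manifest_oversampling_keeps_provenance(self, rng):
        records = [_record(rng, image_id=f"ISIC_{i:07d}", label=int(i < 2)) for i in range(7)]
        m = a.Manifest(records)
        balanced = a.oversample_balance(m, seed=1)
        assert len(balanced) == 10
        labels = balanced.labels()
        assert (labels == 1).sum() == (labels == 0).sum() == 5
        assert {r.source_id for r in balanced.records} == {r.image_id for r in records}
        # ids stay unique so the balanced manifest is itself a valid manifest
        ids = [r.image_id for r in balanced.records]
        assert len(set(ids)) == len(ids)

    def test_determinism(self):
        labels = np.array([0] * 3 + [1] * 11)
        np.testing.assert_array_equal(a.balance_indices(labels, 42), a.balance_indices(labels, 42))


# ---------------------------------------------------------------------------
# patches

class TestPatches:
    def test_default_protocol_counts_and_size(self, rng):
        rec = _record(rng, h=450, w=600)
        ps = a.extract_patches(rec, seed=0)
        assert len(ps) == 60
        assert all(p.shape == (224, 224, 3) for p in ps.patches)
        assert [s for s in ps.scale_of_each].count(1 / 5) == 15

    def test_single_patch(self, rng):
        rec = _record(rng, h=100, w=100)
        ps = a.extract_patches(rec, scales=(0.5,), per_scale=1, out_size=32, seed=0)
        assert len(ps) == 1 and ps.patches[0].shape == (32, 32, 3)

    def test_crop_side_rounding(self, rng):
        # shorter side 450, scale 1/5 -> 90-pixel crops before resizing
        rec = _record(rng, h=450, w=600)
        ps = a.extract_patches(rec, scales=(1 / 5,), per_scale=5, out_size=90, seed=1)
        # out_size equals crop side, so each patch is an exact sub-image
        for p in ps.patches:
            assert p.shape == (90, 90, 3)

    def test_crops_contain_center(self, rng):
        # mark the center pixel; every crop must include it
        rec = _record(rng, h=64, w=64)
        rec.pixels[32, 32] = 7.0  # out-of-range marker value
        ps = a.extract_patches(rec, scales=(0.5,), per_scale=20, out_size=32, seed=3)
        for p in ps.patches:
            assert np.isclose(p, 7.0, atol=1e-5).any()

    def test_determinism_under_seed(self, rng):
        rec = _record(rng)
        p1 = a.extract_patches(rec, seed=11, out_size=32)
        p2 = a.extract_patches(rec, seed=11, out_size=32)
        for x, y in zip(p1.patches, p2.patches):
            np.testing.assert_array_equal(x, y)

    def test_too_small_image_raises(self, rng):
        with pytest.raises(ValueError, match="too small"):
            a.extract_patches(_record(rng, h=20, w=20), seed=0)


class TestBilinearResize:
    def test_constant_stays_constant(self):
        patch = np.full((5, 7, 3), 0.37, dtype=np.float32)
        out = a.bilinear_resize(patch, 13)
        np.testing.assert_allclose(out, 0.37, atol=1e-6)

    def test_identity_when_size_matches(self, rng):
        patch = rng.random(size=(16, 16, 3)).astype(np.float32)
        np.testing.assert_array_equal(a.bilinear_resize(patch, 16), patch)

    def test_monotone_gradient_preserved(self):
        patch = np.array([[0.0, 1.0], [0.0, 1.0]], dtype=np.float32)
        out = a.bilinear_resize(patch, 4)
        assert out.shape == (4, 4)
        assert (np.diff(out, axis=1) >= -1e-7).all()
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-7)
        np.testing.assert_allclose(out[:, -1], 1.0, atol=1e-7)

    def test_corner_alignment(self, rng):
        patch = rng.random(size=(9, 9)).astype(np.float32)
        out = a.bilinear_resize(patch, 5)
        for (i, j), (u, v) in zip([(0, 0), (0, 4), (4, 0), (4, 4)],
                                  [(0, 0), (0, 8), (8, 0), (8, 8)]):
            assert out[i, j] == pytest.approx(patch[u, v], abs=1e-6)


class TestAugment:
    def test_pixel_multiset_preserved(self, rng):
        patch = rng.random(size=(8, 8, 3)).astype(np.float32)
        for seed in range(10):
            out = a.augment(patch, seed)
            np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(patch.ravel()))

    def test_identity_draw_possible(self, rng):
        patch = rng.random(size=(6, 6, 3)).astype(np.float32)
        outs = [a.augment(patch, s) for s in range(40)]
        assert any(np.array_equal(o, patch) for o in outs)
        assert any(not np.array_equal(o, patch) for o in outs)

    def test_double_horizontal_flip_is_identity(self, rng):
        patch = rng.random(size=(5, 5, 3)).astype(np.float32)
        np.testing.assert_array_equal(patch[:, ::-1][:, ::-1], patch)

    def test_rejects_non_square(self, rng):
        with pytest.raises(ValueError):
            a.augment(rng.random(size=(4, 6, 3)), seed=0)
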