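import dataclasses

import numpy as np
import pytest

import speckquant as sq
from speckquant.speckles import DegenerateVolumeError, SpeckleRecord


# ---------------------------------------------------------------- oracles


def flood_fill_components(binary):
    """Recursive 26-connected labeling by explicit stack-based flood fill."""
    binary = np.asarray(binary).astype(bool)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(q, binary.shape)):
                    if binary[q] and not labels[q]:
                        labels[q] = current
                        stack.append(q)
    return labels


def exhaustive_otsu(values, nbins=256):
    """Scan every histogram split for the maximal between-class variance."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_k, best_v = 0, -1.0
    total = counts.sum()
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / (counts[: k + 1].sum())
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / (counts[k + 1 :].sum())
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:  # strict improvement keeps the lower threshold on ties
            best_k, best_v = k, v
    return centers[best_k]


def partition_signature(labels):
    """Connected-component partition as a set of frozensets of voxel coords."""
    return {
        frozenset(zip(*np.nonzero(labels == lab))) for lab in np.unique(labels) if lab > 0
    }


# ---------------------------------------------------------------- background


class TestBackgroundCorrection:
    def test_constant_volume_maps_to_zero(self):
        out = sq.correct_background(np.full((4, 32, 32), 50.0), radius_px=5)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_output_non_negative_on_random_input(self):
        rng = np.random.default_rng(0)
        out = sq.correct_background(rng.uniform(0, 100, (3, 40, 40)), radius_px=5)
        assert out.min() >= 0

    def test_spot_preserved_ramp_suppressed(self):
        zz, yy, xx = np.mgrid[0:5, 0:64, 0:64]
        ramp = 2.0 * xx.astype(float)  # strong linear shading
        spot = 100.0 * np.exp(
            -0.5 * (((zz - 2) / 1.5) ** 2 + ((yy - 32) / 1.5) ** 2 + ((xx - 32) / 1.5) ** 2)
        )
        out = sq.correct_background(ramp + spot, radius_px=8)
        assert abs(out[2, 32, 32] - 100.0) / 100.0 < 0.10
        far = out[:, :, :16]  # pure ramp region
        assert far.max() < 0.05 * 100.0

    def test_oversized_structuring_element_rejected(self):
        with pytest.raises(ValueError):
            sq.correct_background(np.zeros((2, 16, 16)), radius_px=8)


# ---------------------------------------------------------------- Otsu


class TestOtsu:
    def test_two_delta_masses_separate(self):
        vol = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)]).reshape(10, 10, 10)
        t = sq.threshold_otsu_3d(vol)
        assert 10.0 < t < 200.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.integers(0, 256, size=(8, 8, 8)).astype(float)
        assert sq.threshold_otsu_3d(vol) == pytest.approx(exhaustive_otsu(vol), abs=1e-9)

    def test_constant_shift_moves_threshold_by_constant(self):
        rng = np.random.default_rng(5)
        vol = rng.normal(50, 20, (6, 16, 16))
        bin_width = np.ptp(vol) / 256
        t0 = sq.threshold_otsu_3d(vol)
        t1 = sq.threshold_otsu_3d(vol + 37.0)
        assert abs(t1 - (t0 + 37.0)) <= bin_width + 1e-9

    def test_constant_volume_is_degenerate(self):
        with pytest.raises(DegenerateVolumeError):
            sq.threshold_otsu_3d(np.full((3, 4, 4), 7.0))


# ---------------------------------------------------------------- labeling


class TestLabeling3D:
    def test_empty_volume_has_no_objects(self):
        labeled, records = sq.label_components_3d(
            np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4))
        )
        assert labeled.max() == 0 and records == []

    def test_corner_adjacency_joins_voxels(self):
        binary = np.zeros((3, 3, 3), bool)
        binary[0, 0, 0] = binary[1, 1, 1] = True
        _, records = sq.label_components_3d(binary, np.ones((3, 3, 3)))
        assert len(records) == 1 and records[0].voxel_count == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_matches_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        binary = rng.random((6, 6, 6)) < 0.3
        labeled, _ = sq.label_components_3d(binary, np.ones((6, 6, 6)))
        assert partition_signature(labeled) == partition_signature(
            flood_fill_components(binary)
        )

    def test_centroid_and_mean_intensity_measured_on_original(self):
        binary = np.zeros((3, 4, 4), bool)
        binary[1, 1, 1] = binary[1, 1, 2] = True
        intensity = np.zeros((3, 4, 4))
        intensity[1, 1, 1], intensity[1, 1, 2] = 10.0, 30.0
        _, records = sq.label_components_3d(binary, intensity)
        assert records[0].centroid == (1.0, 1.0, 1.5)
        assert records[0].mean_intensity == 20.0


# ---------------------------------------------------------------- filtering


def _rec(size, rid=1):
    return SpeckleRecord("c", rid, size, 1.0, (0.0, 0.0, 0.0))


class TestFilter:
    def test_min_one_is_identity(self):
        records = [_rec(s, i) for i, s in enumerate((1, 2, 5))]
        assert sq.filter_speckles(records, 1) == records

    def test_size_floor_applied(self):
        records = [_rec(s, i) for i, s in enumerate((1, 2, 5))]
        assert [r.voxel_count for r in sq.filter_speckles(records, 2)] == [2, 5]

    def test_invalid_floor_rejected(self):
        with pytest.raises(ValueError):
            sq.filter_speckles([], 0)

    def test_size_filter_halves_false_positives_on_simulated_fields(self, batch):
        from speckquant.evaluate import match_points
        from speckquant.speckles import detect_speckles

        # run without the pre-smoothing so single-voxel noise objects occur
        fp_unfiltered = fp_filtered = 0
        for res, truth in batch[:5]:
            tru_pts = truth.speckle_table[
                truth.speckle_table.channel == "malat1"
            ][["centroid_z", "centroid_y", "centroid_x"]].to_numpy()
            for min_vox in (1, 3):
                recs = detect_speckles(
                    res.stack.channels["malat1"],
                    "malat1",
                    min_voxels=min_vox,
                    smooth_sigma_px=0.0,
                )
                pts = np.array([r.centroid for r in recs])
                matched = {i for i, _ in match_points(pts, tru_pts, 3.0)}
                n_fp = len(recs) - len(matched)
                if min_vox == 1:
                    fp_unfiltered += n_fp
                else:
                    fp_filtered += n_fp
        assert fp_unfiltered > 0
        assert fp_filtered <= 0.5 * fp_unfiltered


# ---------------------------------------------------------------- assignment


class TestAssignment:
    def _maps(self):
        nucleus = np.zeros((20, 20), dtype=np.int32)
        nucleus[2:6, 2:6] = 1
        nucleus[12:16, 12:16] = 7
        cells = sq.tessellate_cells(nucleus)
        cyto = sq.derive_cytoplasm(cells, nucleus)
        return nucleus, cells, cyto

    def test_centroid_in_nucleus_is_nuclear(self):
        nucleus, cells, cyto = self._maps()
        rec = SpeckleRecord("c", 1, 5, 1.0, (0.0, 3.0, 3.0))
        sq.assign_compartments([rec], cells, cyto, nucleus)
        assert (rec.cell_id, rec.compartment) == (1, "nuclear")

    def test_centroid_in_cytoplasm_of_cell_7(self):
        nucleus, cells, cyto = self._maps()
        rec = SpeckleRecord("c", 1, 5, 1.0, (0.0, 17.0, 17.0))
        sq.assign_compartments([rec], cells, cyto, nucleus)
        assert (rec.cell_id, rec.compartment) == (7, "cytoplasmic")

    def test_excluded_cell_leaves_speckle_unassigned(self):
        nucleus, cells, cyto = self._maps()
        rec = SpeckleRecord("c", 1, 5, 1.0, (0.0, 3.0, 3.0))
        sq.assign_compartments([rec], cells, cyto, nucleus, excluded_cells={1})
        assert (rec.cell_id, rec.compartment) == (0, "unassigned")

    def test_shape_mismatch_rejected(self):
        nucleus, cells, cyto = self._maps()
        with pytest.raises(ValueError):
            sq.assign_compartments([], cells[:10], cyto, nucleus)

    def test_compartment_agreement_with_truth(self, batch):
        from speckquant.evaluate import score_speckles

        agreement = [
            score_speckles(res.speckle_records, truth, "malat1").compartment_agreement
            for res, truth in batch
        ]
        assert np.mean(agreement) >= 0.95


# ---------------------------------------------------------------- properties


def test_count_conservation_is_exact(batch):
    """Per cell and channel: nuclear + cytoplasmic = total assigned."""
    for res, _ in batch:
        s = res.cell_summary
        assert (s.n_nuclear + s.n_cytoplasmic == s.n_total).all()
        assigned = [r for r in res.speckle_records if r.compartment != "unassigned"]
        assert s.n_total.sum() == len(assigned)


def test_recall_monotone_in_amplitude():
    """Raising speckle amplitude never decreases recall (fixed seeds)."""
    from speckquant.evaluate import score_speckles

    amplitudes = (50.0, 90.0, 150.0, 250.0)
    recalls = []
    for amp in amplitudes:
        params = dataclasses.replace(
            sq.FieldParams(image_shape=(21, 128, 128), n_cells=4),
            speckle_amplitude={"malat1": amp},
        )
        per_seed = []
        for seed in (1, 2, 3):
            stack, truth = sq.generate_field(params, seed)
            res = sq.process_field(stack)
            per_seed.append(score_speckles(res.speckle_records, truth, "malat1").recall)
        recalls.append(np.mean(per_seed))
    assert all(b >= a - 0.02 for a, b in zip(recalls, recalls[1:]))
    assert recalls[-1] >= 0.9


def test_detection_recall_on_default_field(result_17):
    from speckquant.evaluate import score_speckles

    res, truth = result_17
    assert score_speckles(res.speckle_records, truth, "malat1").recall >= 0.95
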