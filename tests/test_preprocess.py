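"""Preprocessing: ingestion, VOI windowing, islands, annotation stripping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from oracles import flood_fill_labels, otsu_partition
from pectseg import (
    ImageGrid,
    VOIWindow,
    apply_voi_lut,
    binarize,
    connected_components,
    preprocess_mammogram,
    read_mammogram,
    select_breast_region,
    strip_annotations,
)
from pectseg.phantom import write_synthetic_dicom
from pectseg.preprocess import ANNOTATION_CSV_HEADER, write_annotation_records


# -- ingestion --------------------------------------------------------------

def test_dicom_round_trip_preserves_values(tmp_path):
    payload = np.arange(16, dtype=np.uint16).reshape(4, 4) * 100
    path = write_synthetic_dicom(tmp_path / "t.dcm", payload,
                                 spacing=(0.1, 0.1), window=(800, 400))
    grid = read_mammogram(path)
    assert grid.shape == (4, 4)
    assert np.array_equal(grid.pixels, payload)
    assert grid.spacing == (0.1, 0.1)
    assert grid.voi == VOIWindow(800, 400)


def test_pgm_full_resolution_read(tmp_path):
    arr = np.random.default_rng(0).integers(0, 255, (1024, 1024), dtype=np.uint8)
    p = tmp_path / "scan.pgm"
    Image.fromarray(arr, mode="L").save(p)
    grid = read_mammogram(p)
    assert grid.shape == (1024, 1024)
    assert np.array_equal(grid.pixels, arr)


def test_truncated_file_raises(tmp_path):
    p = tmp_path / "broken.dcm"
    p.write_bytes(b"\x00" * 64)
    with pytest.raises(Exception):
        read_mammogram(p)
    missing = tmp_path / "nope.png"
    with pytest.raises(FileNotFoundError):
        read_mammogram(missing)


# -- VOI LUT ----------------------------------------------------------------

def test_identity_lut_is_noop():
    img = ImageGrid(np.arange(12).reshape(3, 4), bit_depth=8)
    out = apply_voi_lut(img, "identity")
    assert np.array_equal(out.pixels, img.pixels)


def test_linear_window_matches_pointwise_oracle():
    ramp = ImageGrid(np.arange(256).reshape(16, 16), bit_depth=8)
    c, w, top = 128.0, 64.0, 255.0
    out = apply_voi_lut(ramp, VOIWindow(c, w)).pixels
    x = ramp.pixels.astype(float)
    expected = np.clip((x - (c - 0.5)) / (w - 1) + 0.5, 0, 1) * top
    assert np.allclose(out, expected)
    # clipped at the range ends
    assert out.min() == 0.0 and out.max() == top


def test_constant_image_stays_constant():
    img = ImageGrid(np.full((8, 8), 42), bit_depth=8)
    out = apply_voi_lut(img, None)
    assert np.all(out.pixels == 42)


def test_degenerate_window_rejected():
    with pytest.raises(ValueError):
        VOIWindow(100, 0)


@settings(max_examples=50, derandomize=True)
@given(st.integers(1, 250), st.integers(2, 300), st.integers(0, 9999))
def test_windowing_is_order_preserving(center, width, seed):
    x = np.sort(np.random.default_rng(seed).integers(0, 255, 64)).reshape(8, 8)
    out = apply_voi_lut(ImageGrid(x, bit_depth=8), VOIWindow(center, width)).pixels
    assert np.all(np.diff(out.ravel()) >= 0)


# -- binarize / islands -----------------------------------------------------

def test_fixed_threshold_zero_marks_positive_pixels():
    img = np.array([[0, 1], [5, 0]])
    mask = binarize(img, policy="fixed", threshold=0)
    assert np.array_equal(mask.pixels, [[0, 1], [1, 0]])


def test_otsu_separates_two_level_image():
    rng = np.random.default_rng(2)
    img = np.where(rng.random((32, 32)) < 0.7, 200, 10)
    mask = binarize(img, policy="otsu")
    assert np.array_equal(mask.pixels, otsu_partition(img))
    assert np.array_equal(mask.pixels, (img == 200).astype(np.uint8))


def test_constant_image_otsu_warns_all_zero():
    with pytest.warns(UserWarning):
        mask = binarize(np.zeros((4, 4)), policy="otsu")
    assert not mask.pixels.any()


def test_diagonal_pixels_are_separate_islands():
    m = np.zeros((3, 3), dtype=np.uint8)
    m[0, 0] = m[1, 1] = 1
    islands = connected_components(m)
    assert islands.n_islands == 2


def test_plus_sign_is_one_island_of_area_five():
    m = np.zeros((3, 3), dtype=np.uint8)
    m[1, :] = 1
    m[:, 1] = 1
    islands = connected_components(m)
    assert islands.n_islands == 1
    assert islands.areas.tolist() == [5]


@pytest.mark.parametrize("seed", range(5))
def test_labeling_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    m = (rng.random((64, 64)) < 0.4).astype(np.uint8)
    ours = connected_components(m)
    ref = flood_fill_labels(m)
    assert ours.n_islands == ref.max()
    # same partition: labels agree up to renaming (both raster-scan ordered)
    assert np.array_equal(ours.labels, ref)
    assert ours.areas.sum() == m.sum()


# -- breast selection / stripping ------------------------------------------

def test_largest_island_selected_and_others_recorded():
    m = np.zeros((32, 32), dtype=np.uint8)
    m[2:12, 2:12] = 1       # area 100
    m[20:26, 20:25] = 1     # area 30
    m[0, 30:32] = 1         # area 2... make it 5
    m[0, 27:32] = 1
    islands = connected_components(m)
    breast, records = select_breast_region(islands)
    assert breast.pixels.sum() == 100
    assert len(records) == 2
    assert sorted(r.area_px for r in records) == [5, 30]


def test_single_island_yields_no_records():
    m = np.zeros((8, 8), dtype=np.uint8)
    m[2:5, 2:5] = 1
    breast, records = select_breast_region(connected_components(m))
    assert np.array_equal(breast.pixels, m)
    assert records == []


def test_equal_area_tie_breaks_to_first_raster_island():
    m = np.zeros((8, 8), dtype=np.uint8)
    m[0, 0:3] = 1  # island 1 (first in raster order)
    m[4, 0:3] = 1  # island 2, same area
    breast, records = select_breast_region(connected_components(m))
    assert breast.pixels[0, :3].all() and not breast.pixels[4, :3].any()
    assert len(records) == 1


def test_empty_island_set_raises():
    with pytest.raises(ValueError, match="no foreground"):
        select_breast_region(connected_components(np.zeros((4, 4), dtype=np.uint8)))


def test_strip_zeroes_marker_and_records_one_row(tmp_path):
    img = np.full((16, 16), 10.0)
    img[4:10, 4:10] = 200.0           # breast
    img[1, 13:16] = 250.0             # 3-pixel marker
    grid = ImageGrid(img, bit_depth=8)
    breast = binarize(img, policy="fixed", threshold=100)
    breast.pixels[1, 13:16] = 0       # breast mask excludes the marker
    cleaned, records = strip_annotations(grid, breast)
    assert len(records) == 1
    assert records[0].area_px == 3
    assert (records[0].xmin, records[0].ymin, records[0].xmax, records[0].ymax) == (13, 1, 15, 1)
    assert not cleaned.pixels[1, 13:16].any()
    # breast pixels bit-identical
    assert np.array_equal(cleaned.pixels[4:10, 4:10], img[4:10, 4:10])
    out = tmp_path / "ann.csv"
    write_annotation_records(records, out)
    assert out.read_text().splitlines()[0] == ",".join(ANNOTATION_CSV_HEADER)


def test_full_frame_breast_mask_changes_nothing():
    img = ImageGrid(np.random.default_rng(0).integers(1, 200, (16, 16)), bit_depth=8)
    from pectseg.core import BinaryMask

    full = BinaryMask(np.ones((16, 16), dtype=np.uint8))
    cleaned, records = strip_annotations(img, full)
    assert np.array_equal(cleaned.pixels, img.pixels)
    assert records == []


def test_shape_mismatch_raises():
    from pectseg.core import BinaryMask

    with pytest.raises(ValueError, match="shape"):
        strip_annotations(ImageGrid(np.zeros((4, 4))),
                          BinaryMask(np.zeros((5, 5), dtype=np.uint8)))


def test_pipeline_reduces_phantom_to_three_classes(phantom_trio):
    image, mask, annotations = phantom_trio
    cleaned, breast, records = preprocess_mammogram(image)
    # every planted artifact island was removed and recorded
    assert len(records) == len(annotations)
    outside = cleaned.pixels[breast.pixels == 0]
    assert np.all(outside == 0)
    # the breast island covers the breast+muscle ground truth almost exactly
    truth_fg = (mask.pixels > 0)
    agreement = (breast.pixels.astype(bool) == truth_fg).mean()
    assert agreement > 0.99
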