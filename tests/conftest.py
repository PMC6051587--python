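"""Shared fixtures and the independent brute-force radial-binning oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from axoquant import SyntheticFieldSpec


def brute_force_profile(mask: np.ndarray, pixel_scale_um: float, bin_width_um: float):
    """Per-pixel loop reference for radial density binning.

    Deliberately naive: visits every pixel, computes its centre distance from
    the origin corner, and tallies per-bin totals with pure-Python floats.
    Returns (density list with NaN for empty bins, pixel-count list).
    """
    rows, cols = mask.shape
    total: dict[int, int] = {}
    occupied: dict[int, int] = {}
    for r in range(rows):
        for c in range(cols):
            d = pixel_scale_um * math.sqrt((c + 0.5) ** 2 + (r + 0.5) ** 2)
            b = int(math.floor(d / bin_width_um))
            total[b] = total.get(b, 0) + 1
            if mask[r, c]:
                occupied[b] = occupied.get(b, 0) + 1
    n_bins = max(total) + 1
    density = [
        occupied.get(b, 0) / total[b] if b in total else float("nan")
        for b in range(n_bins)
    ]
    counts = [total.get(b, 0) for b in range(n_bins)]
    return density, counts


def small_field_spec(seed: int = 0, **overrides) -> SyntheticFieldSpec:
    """A fast-to-render quarter-field used throughout the suite.

    96 px at 20 um/px spans ~1.9 mm of substrate — the same radial extent
    class as a real quarter-field, at coarse resolution for speed.
    """
    params = dict(
        image_size_px=(96, 96),
        pixel_scale_um=20.0,
        n_axons=40,
        decay_length_um=700.0,
        axon_width_px=1,
        ganglion_radius_um=250.0,
        foreground_intensity=3000.0,
        background_mean=400.0,
        background_sd=80.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticFieldSpec(**params)


@pytest.fixture
def hand_image_0_100() -> np.ndarray:
    """2x4 image with four 0-valued and four 100-valued pixels.

    mean = 50, population SD = 50, so the k=1.5 threshold is 125 (empty mask)
    and the k=0.5 threshold is 75 (exactly the four bright pixels).
    """
    return np.array([[0, 100, 0, 100], [100, 0, 100, 0]], dtype=np.uint8)


@pytest.fixture
def fixture_tree(tmp_path):
    """A small on-disk experiment: 3 embryos x 3 treatments x 1 rep, 2 explants each."""
    from axoquant import write_fixture_experiment

    specs = {}
    seed = 0
    for e in ("e01", "e02", "e03"):
        for t in ("NGF", "antiNGF", "antiNGFEGTA"):
            frag = {"NGF": 0.0, "antiNGF": 0.6, "antiNGFEGTA": 0.2}[t]
            specs[(e, t, "1")] = [
                small_field_spec(seed=seed + i, fragmentation_fraction=frag)
                for i in range(2)
            ]
            seed += 2
    root = write_fixture_experiment(tmp_path / "exp", specs)
    return root, specs
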