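import numpy as np
import pytest

from recombikit import synthgen


@pytest.fixture(scope="session")
def quiet_kymo_params():
    """Small, fast kymograph generator settings shared across tests."""
    return dict(length_um=20.0, duration_s=100.0, frame_interval_s=5.0,
                k_nuc=0.01, v_grow=20.0)


@pytest.fixture(scope="session")
def noise_free_kymo():
    """A deterministic noise-free assembly kymograph with ground truth."""
    params = synthgen.SimKymoParams(
        length_um=40.0, duration_s=100.0, frame_interval_s=5.0,
        k_nuc=0.005, v_grow=20.0, shot_noise=False, read_noise_sd=0.0,
        seed=2)
    return synthgen.simulate_kymograph(params)


def background_region(kymo, gt, pad_px=8, width_px=20):
    """A pixel interval guaranteed never covered by any filament."""
    n_px = kymo.n_pixels
    covered = np.zeros(n_px, dtype=bool)
    px_nm = kymo.pixel_size_nm
    for traj in gt.boundary_trajectories.values():
        for _, lo, hi in traj:
            covered[max(int(lo / px_nm) - pad_px, 0):
                    min(int(hi / px_nm) + pad_px, n_px)] = True
    free = np.nonzero(~covered)[0]
    runs = np.split(free, np.nonzero(np.diff(free) > 1)[0] + 1)
    best = max(runs, key=len)
    return int(best[0]), int(best[0]) + min(width_px, len(best))
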