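import numpy as np
import pytest

from flowradiomics import (
    PhantomSpec,
    ScannerProfile,
    generate_velocity_field,
    lumen_mask_on_plane,
    make_centerline,
    place_planes,
    resample_mpr,
)
from flowradiomics.features import DiscretizedMap


def random_discretized_maps(n_maps=20, max_size=12, max_levels=6, seed=7):
    """Random small gray-level maps with random connected-ish masks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_maps):
        h = int(rng.integers(4, max_size + 1))
        w = int(rng.integers(4, max_size + 1))
        nlev = int(rng.integers(2, max_levels + 1))
        levels = rng.integers(1, nlev + 1, size=(h, w))
        mask = rng.random((h, w)) < 0.85
        # ensure enough pixels and that the max level is present
        mask[h // 2, w // 2] = True
        if mask.sum() < 4:
            mask[:2, :2] = True
        levels = np.where(mask, levels, 0)
        lv_max = levels[mask].max()
        d = DiscretizedMap(levels=levels, mask=mask, n_levels=int(lv_max),
                           bin_width=25.0)
        out.append(d)
    return out


@pytest.fixture(scope="session")
def small_maps():
    return random_discretized_maps()


@pytest.fixture(scope="session")
def poiseuille_spec():
    return PhantomSpec(profile_kind="poiseuille", n_timeframes=6)


@pytest.fixture(scope="session")
def poiseuille_field(poiseuille_spec):
    return generate_velocity_field(
        poiseuille_spec,
        ScannerProfile(n_timeframes=6, voxel_size=1.5, seed=1),
    )


@pytest.fixture(scope="session")
def midtube_sample(poiseuille_spec, poiseuille_field):
    cl = make_centerline(poiseuille_spec)
    plane = place_planes(cl, 0, 0)[1]  # B1, mid-tube
    t = int(np.argmax(poiseuille_spec.waveform))
    sample = resample_mpr(poiseuille_field, plane, t)
    mask = lumen_mask_on_plane(poiseuille_spec, plane) & sample.valid
    sample.mask = mask
    return sample
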