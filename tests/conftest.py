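import numpy as np
import pytest

from lesionfd import CohortTruth, GridSpec


@pytest.fixture
def grid16():
    return GridSpec(shape=(16, 16, 16))


@pytest.fixture
def grid8():
    return GridSpec(shape=(8, 8, 8))


@pytest.fixture
def zero_noise_truth():
    return CohortTruth(seed=7, noise_sd=0.0)


def segment_box_oracle(streamlines, grid):
    """Independent oracle: per-streamline visited voxels by brute-force
    segment/box clipping over every voxel of the grid (slab method)."""
    shape = grid.shape
    lower = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    lower = lower.reshape(-1, 3).astype(float)
    upper = lower + 1.0
    out = []
    for line in streamlines:
        pts = grid.world_to_voxel(line)
        visited = np.zeros(len(lower), dtype=bool)
        for p0, p1 in zip(pts[:-1], pts[1:]):
            d = p1 - p0
            tmin = np.zeros(len(lower))
            tmax = np.ones(len(lower))
            ok = np.ones(len(lower), dtype=bool)
            for ax in range(3):
                if d[ax] == 0.0:
                    ok &= (lower[:, ax] <= p0[ax]) & (p0[ax] < upper[:, ax])
                else:
                    t1 = (lower[:, ax] - p0[ax]) / d[ax]
                    t2 = (upper[:, ax] - p0[ax]) / d[ax]
                    tmin = np.maximum(tmin, np.minimum(t1, t2))
                    tmax = np.minimum(tmax, np.maximum(t1, t2))
            visited |= ok & (tmin <= tmax)
        out.append({tuple(int(v) for v in lower[i]) for i in np.flatnonzero(visited)})
    return out


def point_sampling_oracle(streamlines, grid, step_mm=0.01):
    """Dense point-sampling oracle: voxels visited by samples every step_mm
    along each segment (both endpoints included). One-sided: may miss voxels
    whose chord is shorter than the step."""
    out = []
    for line in streamlines:
        visited = set()
        for p0, p1 in zip(np.asarray(line)[:-1], np.asarray(line)[1:]):
            length = float(np.linalg.norm(p1 - p0))
            n = max(int(np.ceil(length / step_mm)), 1) + 1
            t = np.linspace(0.0, 1.0, n)
            samples = p0 + t[:, None] * (p1 - p0)
            vox = np.floor(grid.world_to_voxel(samples)).astype(int)
            inb = np.all((vox >= 0) & (vox < np.asarray(grid.shape)), axis=1)
            visited.update(map(tuple, vox[inb].tolist()))
        out.append(visited)
    return out
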