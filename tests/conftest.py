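"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library paths they check: connected
components by BFS over an explicit adjacency test, scores by plain Python
loops over voxel lists.
"""

import numpy as np
import pandas as pd
import pytest

from calciomics.phantoms import LesionSpec, PhantomSpec, make_phantom
from calciomics.volumes import CTVolume, TerritoryMask


# ---------------------------------------------------------------------------
# Brute-force connected components (BFS)
# ---------------------------------------------------------------------------

def bfs_components(candidate: np.ndarray, connectivity: int) -> list:
    """Flood-fill labeling of a binary 3D map; returns sorted voxel lists."""
    assert connectivity in (6, 26)
    visited = np.zeros_like(candidate, dtype=bool)
    comps = []
    shape = candidate.shape
    coords = np.argwhere(candidate)
    for start in map(tuple, coords):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        if connectivity == 6 and abs(di) + abs(dj) + abs(dk) != 1:
                            continue
                        w = (v[0] + di, v[1] + dj, v[2] + dk)
                        if any(c < 0 or c >= s for c, s in zip(w, shape)):
                            continue
                        if candidate[w] and not visited[w]:
                            visited[w] = True
                            stack.append(w)
        comps.append(sorted(comp))
    return sorted(comps)


def brute_force_agatston(voxels, hu, spacing) -> float:
    """Per-slice area x weight, written as an explicit loop."""
    dx, dy, dz = spacing
    total = 0.0
    for sl in sorted({i for i, _, _ in voxels}):
        in_slice = [n for n, (i, _, _) in enumerate(voxels) if i == sl]
        area = len(in_slice) * dx * dy
        mx = max(hu[n] for n in in_slice)
        if mx < 200:
            w = 1
        elif mx < 300:
            w = 2
        elif mx < 400:
            w = 3
        else:
            w = 4
        total += area * w
    return total


def random_phantom_pair(seed: int, max_shape: int = 20):
    """Random small HU volume + territory mask for oracle-equivalence runs."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(6, max_shape + 1, size=3))
    data = rng.uniform(0.0, 500.0, size=shape)
    labels = rng.integers(0, 5, size=shape).astype(np.int32)
    spacing = (0.5, 0.5, 2.5)
    return CTVolume(data=data, spacing=spacing), TerritoryMask(labels=labels)


# ---------------------------------------------------------------------------
# Phantom fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def multi_lesion_phantom():
    spec = PhantomSpec(shape=(20, 64, 64), lesions=(
        LesionSpec("LAD", (10.0, 10.0, 6.0), (2.0, 2.0, 3.0), 450.0),
        LesionSpec("LAD", (10.0, 10.0, 20.0), (1.5, 1.5, 2.8), 250.0),
        LesionSpec("LCX", (22.0, 20.0, 12.0), (2.5, 2.0, 3.0), 800.0),
        LesionSpec("RCA", (8.0, 24.0, 30.0), (1.5, 1.5, 2.8), 1100.0),
    ))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def zero_calcium_phantom():
    return make_phantom(PhantomSpec(shape=(10, 32, 32)))


@pytest.fixture(scope="session")
def small_cohort():
    from calciomics.cohorts import CohortSpec, simulate_cohort
    spec = CohortSpec(n=800, beta={"f1": 0.5, "f2": -0.4, "f3": 0.3},
                      n_noise_features=5, seed=3)
    X, surv, truth = simulate_cohort(spec)
    return X.merge(surv, on="patient_id"), truth


@pytest.fixture(scope="session")
def registry_cohort():
    from calciomics.cohorts import synthetic_feature_cohort
    X, surv, truth = synthetic_feature_cohort(n=500, seed=7)
    return X.merge(surv, on="patient_id"), truth
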