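import numpy as np
import pytest

import meshsharp as ms


@pytest.fixture(scope="session")
def small_box():
    """Coarse filleted box (1200 faces) for fast structural tests."""
    return ms.make_filleted_box((1.0, 1.0, 1.0), fillet_radius=0.15, resolution=0.1)


@pytest.fixture(scope="session")
def study_box():
    """The study-scale fixture: ~5k-face unit filleted box (radius 0.1) with
    scanner-level vertex noise (sigma 1e-3, i.e. 60 um on a 60 mm part)."""
    bundle = ms.make_filleted_box((1.0, 1.0, 1.0), fillet_radius=0.1, resolution=0.05)
    noisy = ms.add_vertex_noise(bundle.blurred, 0.001, seed=1)
    return bundle, noisy


@pytest.fixture(scope="session")
def study_runs(study_box):
    """Pipeline outputs on the study box at alpha in {0.2, 0.5, 0.8} plus the
    hard-propagation (oversharpening) limit; shared across acceptance tests."""
    bundle, noisy = study_box
    runs = {}
    for alpha in (0.2, 0.5, 0.8):
        out, diag = ms.sharpen_pipeline(noisy, ms.SharpenConfig(alpha=alpha))
        runs[alpha] = (out, diag)
    out, diag = ms.sharpen_pipeline(
        noisy, ms.SharpenConfig(alpha=0.5, hard_propagation=True)
    )
    runs["hard"] = (out, diag)
    return runs


def random_one_ring(rng, n_faces=None):
    """Random star-shaped one-ring fan around the origin (valid mesh)."""
    if n_faces is None:
        n_faces = int(rng.integers(3, 9))
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_faces))
    radii = rng.uniform(0.5, 1.5, n_faces)
    heights = rng.uniform(-0.3, 0.3, n_faces)
    ring = np.column_stack(
        [radii * np.cos(angles), radii * np.sin(angles), heights]
    )
    verts = np.vstack([[0.0, 0.0, 0.0], ring])
    faces = [(0, 1 + t, 1 + (t + 1) % n_faces) for t in range(n_faces)]
    return ms.TriangleMesh(verts, np.asarray(faces)).validate()
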