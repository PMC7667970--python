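import numpy as np
import pytest

import mucolab as m


@pytest.fixture(scope="session")
def rendered_phantom():
    """Noise-free rendered stack with known surface and bead ground truth.

    Beads are placed with generous pairwise separation so the rendered
    blobs cannot merge and detection counts are well-defined.
    """
    surface = m.generate_tissue_surface(
        m.SurfaceConfig(
            grid_nx=64, grid_ny=64, pixel_size_um=2.0, mean_z_um=50.0,
            amplitude_um=5.0, correlation_length_um=20.0, seed=3,
        )
    )
    model = m.MucusModel(thickness_um=80.0, penetration_fraction=0.5)
    beads = m.generate_bead_population(
        surface, model, 50, seed=4, min_separation_um=12.0
    )
    rendered = m.render_zstack(surface, beads, m.RenderConfig(z_step_um=2.0, seed=5))
    return surface, beads, rendered


@pytest.fixture()
def flat_stack():
    """Flat tissue filling z <= 50 µm, no beads, no noise."""
    surface = m.generate_tissue_surface(
        m.SurfaceConfig(grid_nx=16, grid_ny=16, pixel_size_um=2.0,
                        mean_z_um=50.0, amplitude_um=0.0, seed=0)
    )
    data = np.zeros((2, 40, 16, 16), dtype=np.float32)
    zc = (np.arange(40) + 0.5) * 2.0
    data[0, zc <= 50.0] = 100.0
    return surface, m.VoxelStack(data, (2.0, 2.0, 2.0))
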