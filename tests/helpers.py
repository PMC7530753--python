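"""Small construction helpers shared across test modules."""

import numpy as np

from perisim.core import ParticleSystem, Phase


def make_system(positions, **kwargs):
    """Fluid-by-default particle system with sensible array defaults."""
    n = len(positions)
    defaults = dict(
        velocities=np.zeros((n, 3)), forces=np.zeros((n, 3)),
        masses=np.ones(n), densities=np.full(n, 1000.0),
        phase=np.full(n, Phase.FLUID, dtype=np.int8),
        slice_index=np.full(n, -1, dtype=np.int32))
    defaults.update(kwargs)
    return ParticleSystem(positions=np.asarray(positions, dtype=float), **defaults)
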