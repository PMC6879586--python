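import numpy as np
import pytest

from poreflux import synthgen
from poreflux.trajio import SF_ROLES, ChannelAnnotation


@pytest.fixture(scope="session")
def small_system():
    """A modest synthetic ensemble shared by read-only tests."""
    spec = synthgen.SynthSpec(n_frames=400, n_replicas=2, seed=101)
    return synthgen.generate_ensemble(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_filter_frame(
    plane_z=(0.0, 0.3, 0.6, 0.9, 1.2, 1.5),
    ring_radius=0.2,
    ion_positions=(),
    water_positions=(),
):
    """Hand-built 4-subunit filter frame: 24 oxygen atoms + ions + waters.

    Returns (frame (N,3), annotation).  Role atom k of subunit s sits at
    angle 45° + 90°·s on a ring of ``ring_radius``.
    """
    angles = np.pi / 4 + np.pi / 2 * np.arange(4)
    coords = []
    sf = {}
    idx = 0
    for r, role in enumerate(SF_ROLES):
        ids = []
        for a in angles:
            coords.append([ring_radius * np.cos(a), ring_radius * np.sin(a), plane_z[r]])
            ids.append(idx)
            idx += 1
        sf[role] = tuple(ids)
    ion_ids = []
    for p in ion_positions:
        coords.append(list(p))
        ion_ids.append(idx)
        idx += 1
    water_ids = []
    for p in water_positions:
        coords.append(list(p))
        water_ids.append(idx)
        idx += 1
    ann = ChannelAnnotation(
        n_subunits=4,
        sf=sf,
        ion_indices=np.array(ion_ids, dtype=int),
        water_oxygen_indices=np.array(water_ids, dtype=int),
    )
    return np.asarray(coords, dtype=float), ann
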