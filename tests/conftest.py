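import numpy as np
import pytest
from hypothesis import settings

from synastro import synthio
from synastro.trace import Trace

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

FS = 10_000.0


@pytest.fixture(scope="session")
def kinetics():
    return synthio.EventKinetics()


@pytest.fixture(scope="session")
def kernel(kinetics):
    return kinetics.kernel(FS)


def insert_events(duration_s, onsets_s, amplitudes, kernel, holding=-100.0, fs=FS):
    """Noiseless trace with kernel-shaped events at sample-aligned onsets."""
    y = np.full(int(duration_s * fs), holding, dtype=float)
    for t0, a in zip(onsets_s, np.broadcast_to(amplitudes, (len(onsets_s),))):
        i = int(round(t0 * fs))
        seg = kernel[: y.size - i]
        y[i : i + seg.size] += a * seg
    return Trace(y, fs, "pA")


@pytest.fixture(scope="session")
def straight_phantom():
    """One radial 50-um process; roomy enough that no border is touched."""
    voxel = (0.5, 0.5, 0.5)
    center = (15.0, 55.0, 55.0)
    cell = synthio.CellSpec(center, [np.array([center, (15.0, 55.0, 105.0)])])
    stack, truth = synthio.gen_astro_stack(
        (61, 221, 221), [cell], voxel_um_zyx=voxel, noise_sd=0.0, seed=0
    )
    return stack, truth, center, voxel


@pytest.fixture(scope="session")
def y_branch_phantom():
    """Trunk to 20 um from the centroid, then two branches out to ~50 um."""
    voxel = (0.5, 0.5, 0.5)
    center = (15.0, 55.0, 55.0)
    bp = (15.0, 55.0, 75.0)
    cell = synthio.CellSpec(
        center,
        [
            np.array([center, bp, (15.0, 75.0, 105.0)]),
            np.array([center, bp, (15.0, 35.0, 105.0)]),
        ],
    )
    stack, truth = synthio.gen_astro_stack(
        (61, 221, 221), [cell], voxel_um_zyx=voxel, noise_sd=0.0, seed=0
    )
    return stack, truth, center, voxel
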