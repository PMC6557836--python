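import numpy as np
import pytest

from foldstab.spectra import AxisKind, ProbeKind, SpectrumSeries, UnfoldingCurve
from foldstab.structure import Structure, Trajectory


@pytest.fixture
def small_series():
    """3 conditions x 5 wavelengths with absorbances."""
    return SpectrumSeries(
        probe_kind=ProbeKind.TRP_FLUORESCENCE,
        axis_kind=AxisKind.TEMPERATURE_C,
        condition_values=[20.0, 25.0, 30.0],
        wavelengths_nm=[310.0, 330.0, 340.0, 350.0, 400.0],
        intensities=np.arange(15, dtype=float).reshape(3, 5) + 1.0,
        excitation_nm=295.0,
        absorbances=np.array([[0.05, 0.02], [0.04, 0.02], [0.03, 0.01]]),
    )


def gaussian_series(centers, amplitudes=None, conditions=None,
                    wavelengths=None, width=10.0, axis=AxisKind.TEMPERATURE_C):
    """Series whose row i is a Gaussian band centered at centers[i]."""
    centers = np.asarray(centers, dtype=float)
    n = centers.size
    conditions = np.arange(n, dtype=float) if conditions is None else np.asarray(conditions, float)
    wavelengths = np.arange(310.0, 401.0) if wavelengths is None else np.asarray(wavelengths, float)
    amplitudes = np.ones(n) if amplitudes is None else np.asarray(amplitudes, float)
    grid = amplitudes[:, None] * np.exp(
        -0.5 * ((wavelengths[None, :] - centers[:, None]) / width) ** 2
    )
    return SpectrumSeries(
        probe_kind=ProbeKind.TRP_FLUORESCENCE,
        axis_kind=axis,
        condition_values=conditions,
        wavelengths_nm=wavelengths,
        intensities=grid,
    )


def sigmoid_curve(midpoint, steepness, bn, bd, x, axis=AxisKind.TEMPERATURE_C,
                  noise_sd=0.0, rng=None):
    x = np.asarray(x, dtype=float)
    direction = 1.0 if x[-1] >= x[0] else -1.0
    y = bn + (bd - bn) / (1 + np.exp(-direction * (x - midpoint) / steepness))
    if noise_sd > 0:
        y = y + (rng or np.random.default_rng(0)).normal(scale=noise_sd, size=y.shape)
    return UnfoldingCurve(axis_kind=axis, x=x, y=y, observable_label="test")


def toy_structure(coords, atom_names=None, residue_numbers=None, elements=None,
                  chain="A"):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    atom_names = atom_names or ["CA"] * n
    residue_numbers = residue_numbers if residue_numbers is not None else list(range(1, n + 1))
    elements = elements or ["C"] * n
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.array(atom_names, dtype=object),
        residue_name=np.array(["ALA"] * n, dtype=object),
        chain_id=np.array([chain] * n, dtype=object),
        residue_number=np.array(residue_numbers, dtype=int),
        element=np.array(elements, dtype=object),
        coords=coords,
        masses=np.full(n, 12.011),
    )


def toy_trajectory(frames, **kwargs):
    frames = np.asarray(frames, dtype=float)
    topo = toy_structure(frames[0], **kwargs)
    return Trajectory(topology=topo, frames=frames)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
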