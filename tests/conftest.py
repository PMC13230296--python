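import numpy as np
import pytest

from ctca_audit.io import CTVolume, Mask


def make_volume(values, spacing=(1.0, 1.0, 1.0), case_id="t") -> CTVolume:
    values = np.asarray(values, dtype=np.float32)
    aff = np.diag([*spacing, 1.0])
    return CTVolume(values, spacing, aff, case_id)


def make_mask(labels, spacing=(1.0, 1.0, 1.0), kind="binary", case_id="t") -> Mask:
    aff = np.diag([*spacing, 1.0])
    return Mask(np.asarray(labels), spacing, aff, kind, case_id)


def cylinder_mask(radius_mm, spacing, length_mm=24.0, pad_mm=4.0, axis=2) -> Mask:
    """Rasterised straight cylinder along `axis` (world-mm geometry)."""
    sp = np.asarray(spacing, float)
    r_vox = int(np.ceil(radius_mm / min(sp[:2] if axis == 2 else sp))) + 6
    n_ax = int(np.ceil((length_mm + 2 * pad_mm) / sp[axis])) + 1
    shape = [2 * r_vox + 1] * 3
    shape[axis] = n_ax
    idx = np.indices(shape).astype(float)
    world = [idx[i] * sp[i] for i in range(3)]
    centre = [(shape[i] // 2) * sp[i] for i in range(3)]
    radial = [world[i] - centre[i] for i in range(3) if i != axis]
    d = np.sqrt(radial[0] ** 2 + radial[1] ** 2)
    ax_lo, ax_hi = pad_mm, pad_mm + length_mm
    fg = (d <= radius_mm) & (world[axis] >= ax_lo) & (world[axis] <= ax_hi)
    return make_mask(fg.astype(np.uint8), tuple(sp))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Blur-free, noise-free phantom: lumen 400 HU over tissue 50 HU."""
    from ctca_audit.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(shape=(64, 64, 64), spacing=(0.75, 0.75, 0.75),
                       lumen_hu=400.0, tissue_hu=50.0, blur_sigma=0.0, noise_sd=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry with independent HU noise of SD 10."""
    from ctca_audit.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(shape=(64, 64, 64), spacing=(0.75, 0.75, 0.75),
                       lumen_hu=400.0, tissue_hu=50.0, blur_sigma=0.0, noise_sd=10.0, seed=11)
    return generate_phantom(spec)
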