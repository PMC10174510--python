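import numpy as np
import pytest

from compunet import ArtifactParams, Misalignment, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """A clean 64^3 head/jaw phantom shared across tests (read-only)."""
    return generate_phantom(default_spec, seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom for training smoke tests."""
    return PhantomSpec(grid_shape=(32, 48, 48))


@pytest.fixture
def zero_artifacts():
    return ArtifactParams(streak_amplitude=0.0, ring_amplitude=0.0,
                          noise_sigma=0.0, cupping_strength=0.0,
                          intensity_gain=1.0, intensity_offset=0.0,
                          misalignment=Misalignment())


def gradcheck(fn, arrs, eps=1e-6, tol=1e-5):
    """Finite-difference check of ``fn(*tensors) -> scalar Tensor``."""
    from compunet.ndl import Tensor

    ts = [Tensor(a, requires_grad=True) for a in arrs]
    fn(*ts).backward()
    for k, base in enumerate(arrs):
        num = np.zeros_like(base)
        it = np.nditer(base, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            hi = [a.copy() for a in arrs]
            lo = [a.copy() for a in arrs]
            hi[k][i] += eps
            lo[k][i] -= eps
            num[i] = (fn(*[Tensor(a) for a in hi]).item()
                      - fn(*[Tensor(a) for a in lo]).item()) / (2 * eps)
        err = np.abs(num - ts[k].grad).max()
        assert err < tol, f"analytic/numeric gradient mismatch on arg {k}: {err}"
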