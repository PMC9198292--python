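import itertools

import numpy as np
import pytest

from npvreg import Image, gray_to_bin
from npvreg.kernels import KernelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_pair_2d(rng):
    """16x16 random integer gray pair."""
    ref = Image(data=rng.integers(0, 256, size=(16, 16)).astype(float))
    flt = Image(data=rng.integers(0, 256, size=(16, 16)).astype(float))
    return ref, flt


@pytest.fixture
def random_pair_3d(rng):
    ref = Image(data=rng.integers(0, 256, size=(8, 8, 8)).astype(float))
    flt = Image(data=rng.integers(0, 256, size=(8, 8, 8)).astype(float))
    return ref, flt


def oracle_accumulate(ref, flt, transform, samples, spec: KernelSpec, bins: int):
    """Per-sample brute-force reference for the PV/NPV accumulators.

    Iterates samples one at a time, distributing unit mass over the kernel's
    neighbor offsets; summation order is sample-major, combo-minor.
    Returns (counts, n_in, n_skipped).
    """
    counts = np.zeros((bins, bins))
    offs = spec.offsets
    shape = ref.data.shape
    ndim = len(shape)
    n_in = n_skip = 0
    for p in samples.points:
        q = np.asarray(transform(np.asarray(p, float)[None]))[0]
        base = np.floor(q).astype(int)
        frac = q - base
        if not all(
            base[a] + offs[0] >= 0 and base[a] + offs[-1] <= shape[a] - 1
            for a in range(ndim)
        ):
            n_skip += 1
            continue
        n_in += 1
        fb = gray_to_bin(np.array([flt.data[tuple(p)]]), bins, flt.levels)[0]
        axis_w = [spec.offset_weights(np.array([frac[a]]))[0] for a in range(ndim)]
        for combo in itertools.product(range(len(offs)), repeat=ndim):
            w = axis_w[0][combo[0]]
            for a in range(1, ndim):
                w = w * axis_w[a][combo[a]]
            coord = tuple(base[a] + offs[combo[a]] for a in range(ndim))
            rb = gray_to_bin(np.array([ref.data[coord]]), bins, ref.levels)[0]
            counts[rb, fb] += w
    return counts, n_in, n_skip
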