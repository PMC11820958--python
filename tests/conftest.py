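import logging

import numpy as np
import pytest

import somatrack as st

# per-slice fallback warnings are expected on small fixtures and would
# otherwise drown the test output
logging.getLogger("somatrack").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def mixture_sample(rng, n=10000, p0=0.5, comp0=(2.0, 8.0), comp1=(8.0, 2.0)):
    """Draw from p0*Beta(comp0) + (1-p0)*Beta(comp1)."""
    z = rng.random(n) < p0
    return np.where(z, rng.beta(*comp0, n), rng.beta(*comp1, n))


@pytest.fixture(scope="session")
def headline():
    """The 64x64x24x6 recovery scene, rendered once with its ground truth."""
    script = st.headline_scene(seed=11)
    stack, gt = st.generate_scene(script)
    return script, stack, gt


@pytest.fixture(scope="session")
def headline_run(headline, tmp_path_factory):
    """Full default-parameter pipeline run on the headline scene."""
    _, stack, gt = headline
    out = tmp_path_factory.mktemp("headline_out")
    cfg = st.RunConfig(output_dir=str(out), seed=11)
    result = st.run_pipeline(cfg, stack=stack)
    return stack, gt, result


def brute_force_median(binary, window):
    """Independent per-voxel strict-majority oracle with zero padding."""
    wx, wy, wz = window
    hx, hy, hz = wx // 2, wy // 2, wz // 2
    out = np.zeros_like(binary)
    I, J, K, T = binary.shape
    padded = np.pad(binary, ((hx, hx), (hy, hy), (hz, hz), (0, 0)))
    for t in range(T):
        for i in range(I):
            for j in range(J):
                for k in range(K):
                    block = padded[i : i + wx, j : j + wy, k : k + wz, t]
                    out[i, j, k, t] = int(2 * int(block.sum()) > wx * wy * wz)
    return out


def bfs_components(binary, halfwidths=(1, 1, 1, 1)):
    """Flood-fill oracle: list of frozensets of connected foreground voxels."""
    from collections import deque
    from itertools import product

    offsets = [
        off
        for off in product(*[range(-h, h + 1) for h in halfwidths])
        if any(off)
    ]
    fg = set(map(tuple, np.argwhere(np.asarray(binary) > 0)))
    seen = set()
    comps = []
    for start in sorted(fg):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if w in fg and w not in seen:
                    seen.add(w)
                    comp.add(w)
                    queue.append(w)
        comps.append(frozenset(comp))
    return comps
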