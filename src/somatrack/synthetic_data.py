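"""Seeded synthetic 4D scenes with known ground truth.

The generator emulates longitudinal two-photon stacks of fluorescent
somas: a dim beta-distributed background, bright quasi-spherical somas
(solid balls with a soft one-voxel edge), dimmer thin filaments (myelin
sheaths), multiplicative fluorescence attenuation with depth
``exp(-attenuation * z)``, scripted per-cell appearance/disappearance
times, and optional low-SNR timepoints where the fluorescence signal (but
not the background noise) is scaled down — per-slice percentile
thresholding is scale-invariant, so only sinking the signal beneath the
noise floor reproduces the split-component failure mode of a bad session.

Scenes are scripted (:class:`SceneScript`), rendered deterministically
under a seed, and come with ground-truth per-cell masks and the fate table
implied by the script.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.draw import line_nd

from somatrack.io import ImageStack4D
from somatrack.tracking import FateTable, fate_table_from_spans


@dataclass
class CellSpec:
    """One scripted soma: center (x, y, z) in voxels, radius, 1-based
    inclusive presence span [first_t, last_t], and peak intensity (0-255)."""

    center: tuple[float, float, float]
    radius: float = 5.0
    first_t: int = 1
    last_t: int = 1
    peak_intensity: float = 230.0


@dataclass
class FilamentSpec:
    """A thin bright line segment (myelin-sheath-like noise), present at all t."""

    start: tuple[int, int, int]
    end: tuple[int, int, int]
    thickness: int = 1
    intensity: float = 80.0


@dataclass
class SceneScript:
    """Full description of a synthetic scene."""

    shape: tuple[int, int, int, int]  # (I, J, K, T)
    cells: list = field(default_factory=list)
    filaments: list = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_beta: tuple[float, float] = (2.0, 20.0)
    soma_beta: tuple[float, float] = (20.0, 3.0)
    attenuation: float = 0.015  # per z-voxel, multiplicative exp(-a*z)
    low_snr_timepoints: tuple = ()
    low_snr_scale: float = 0.1
    seed: int = 0
    allow_collisions: bool = False
    quantize: bool = True  # render to uint8 (8-bit acquisition)

    def validate(self, merge_halfwidth: int = 2) -> None:
        I, J, K, T = self.shape
        if min(I, J, K, T) < 1:
            raise ValueError(f"invalid shape {self.shape}")
        for c in self.cells:
            if not (1 <= c.first_t <= c.last_t <= T):
                raise ValueError(f"cell span [{c.first_t}, {c.last_t}] outside 1..{T}")
            if c.radius < 2:
                raise ValueError(f"cell radius must be >= 2 voxels, got {c.radius}")
        if not self.allow_collisions:
            for i, a in enumerate(self.cells):
                for b in self.cells[i + 1 :]:
                    d = float(np.linalg.norm(np.subtract(a.center, b.center)))
                    lim = 2.0 * (max(a.radius, b.radius) + merge_halfwidth)
                    if d <= lim:
                        raise ValueError(
                            f"cells at {a.center} and {b.center} are {d:.1f} voxels apart "
                            f"(<= {lim:.1f}); script a collision explicitly via allow_collisions"
                        )
        if not set(self.low_snr_timepoints) <= set(range(1, T + 1)):
            raise ValueError("low_snr_timepoints outside 1..T")


@dataclass
class GroundTruth:
    """What the generator knows: per-cell 3D masks, spans, and the fate table."""

    cell_masks: dict  # cell_id (1-based script order) -> 3D bool mask
    spans: dict  # cell_id -> (first_t, last_t), 1-based inclusive
    fate_table: FateTable


def _ball_weights(shape3, center, radius):
    """Soft-edged ball: weight 1 inside, linear falloff over the last voxel."""
    I, J, K = shape3
    r_out = radius + 0.5
    lo = [max(0, int(np.floor(c - r_out - 1))) for c in center]
    hi = [min(s, int(np.ceil(c + r_out + 2))) for s, c in zip(shape3, center)]
    x, y, z = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d = np.sqrt(
        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    )
    w = np.clip(radius + 0.5 - d, 0.0, 1.0)
    weights = np.zeros(shape3, dtype=np.float64)
    weights[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = w
    return weights


def _filament_mask(shape3, fil: FilamentSpec):
    mask = np.zeros(shape3, dtype=bool)
    coords = line_nd(fil.start, fil.end, endpoint=True)
    valid = np.all(
        [(c >= 0) & (c < s) for c, s in zip(coords, shape3)], axis=0
    )
    mask[tuple(c[valid] for c in coords)] = True
    if fil.thickness > 1:
        from scipy.ndimage import binary_dilation

        mask = binary_dilation(mask, iterations=fil.thickness - 1)
    return mask


def generate_scene(script: SceneScript) -> tuple[ImageStack4D, GroundTruth]:
    """Render a scripted scene; deterministic under ``script.seed``."""
    script.validate()
    I, J, K, T = script.shape
    rng = np.random.default_rng(script.seed)
    zs = np.arange(K, dtype=np.float64)
    atten = np.exp(-script.attenuation * zs)[np.newaxis, np.newaxis, :]

    a0, b0 = script.background_beta
    background = rng.beta(a0, b0, size=(I, J, K, T)) * 255.0

    a1, b1 = script.soma_beta
    signal = np.zeros((I, J, K, T), dtype=np.float64)
    cell_masks = {}
    spans = {}
    for cid, cell in enumerate(script.cells, start=1):
        w = _ball_weights((I, J, K), cell.center, cell.radius)
        idx = w > 0
        nvox = int(idx.sum())
        cell_masks[cid] = w >= 0.5  # the ball proper, excluding the soft skirt
        spans[cid] = (cell.first_t, cell.last_t)
        for t in range(cell.first_t - 1, cell.last_t):
            draws = rng.beta(a1, b1, size=nvox)
            vox = cell.peak_intensity * draws * w[idx] * np.broadcast_to(atten, (I, J, K))[idx]
            np.maximum.at(signal[..., t], np.nonzero(idx), vox)

    for fil in script.filaments:
        fmask = _filament_mask((I, J, K), fil)
        nvox = int(fmask.sum())
        for t in range(T):
            draws = rng.beta(a1, b1, size=nvox)
            vox = fil.intensity * draws * np.broadcast_to(atten, (I, J, K))[fmask]
            np.maximum.at(signal[..., t], np.nonzero(fmask), vox)

    for t in script.low_snr_timepoints:
        signal[..., t - 1] *= script.low_snr_scale

    img = np.maximum(background, signal)
    img = np.clip(img, 0.0, 255.0)
    if script.quantize:
        img = np.rint(img).astype(np.uint8)
    else:
        img = img.astype(np.float32)

    firsts = [f - 1 for f, _ in spans.values()]
    lasts = [l - 1 for _, l in spans.values()]
    gt = GroundTruth(
        cell_masks=cell_masks,
        spans=spans,
        fate_table=fate_table_from_spans(firsts, lasts, T),
    )
    return ImageStack4D(data=img, voxel_size=script.voxel_size), gt


# ---------------------------------------------------------------------------
# canonical fixtures


def headline_scene(seed: int = 0) -> SceneScript:
    """The canonical 64 x 64 x 24 x 6 recovery fixture.

    15 radius-5 somas on a grid: 10 present throughout, 3 appearing at
    timepoint 4 (new at index 3) and 2 last seen at timepoint 2 (lost at
    index 2), plus two dim filaments. Radius 5 is the smallest sphere whose
    core survives the default 11 x 11 x 3 strict-majority median filter
    with comfortably more than the 30-voxel component minimum.
    """
    xs = [8, 24, 40, 56]
    positions = [(x, y) for y in xs for x in xs][:15]
    cells = []
    for i, (x, y) in enumerate(positions):
        z = 7 if (i % 2 == 0) else 16
        if i < 10:
            first_t, last_t = 1, 6
        elif i < 13:
            first_t, last_t = 4, 6
        else:
            first_t, last_t = 1, 2
        cells.append(CellSpec(center=(x, y, z), radius=5.0, first_t=first_t, last_t=last_t))
    filaments = [
        FilamentSpec(start=(2, 2, 3), end=(60, 14, 3), thickness=1, intensity=80.0),
        FilamentSpec(start=(4, 60, 20), end=(58, 48, 20), thickness=2, intensity=70.0),
    ]
    return SceneScript(shape=(64, 64, 24, 6), cells=cells, filaments=filaments, seed=seed)


def gap_scene(seed: int = 0) -> SceneScript:
    """One soma imaged at t = 1..3 with a low-SNR acquisition at t = 2.

    The signal at t = 2 is scaled far below the background noise floor, so
    the tracker sees the cell only at t = 1 and t = 3: two components
    without a merge window, one with the default spatio-temporal merge.
    """
    return SceneScript(
        shape=(48, 48, 16, 3),
        cells=[CellSpec(center=(24, 24, 8), radius=5.0, first_t=1, last_t=3)],
        low_snr_timepoints=(2,),
        low_snr_scale=0.05,
        seed=seed,
    )


def random_scene(rng: np.random.Generator, shape=(32, 32, 16, 5)) -> SceneScript:
    """A small random scene with 1-4 non-colliding cells and random spans."""
    I, J, K, T = shape
    n_cells = int(rng.integers(1, 5))
    cells = []
    tries = 0
    while len(cells) < n_cells and tries < 200:
        tries += 1
        r = 5.0
        c = (
            float(rng.integers(8, I - 8)),
            float(rng.integers(8, J - 8)),
            float(rng.integers(6, K - 6)),
        )
        if any(np.linalg.norm(np.subtract(c, o.center)) <= 2 * (r + 2) for o in cells):
            continue
        f = int(rng.integers(1, T + 1))
        l = int(rng.integers(f, T + 1))
        cells.append(CellSpec(center=c, radius=r, first_t=f, last_t=l))
    return SceneScript(shape=shape, cells=cells, seed=int(rng.integers(0, 2**31)))
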