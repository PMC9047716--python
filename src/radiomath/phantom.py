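"""Synthetic 3D brain phantoms: labelled ellipsoidal ROIs with
spatially correlated texture and optionally planted score signal.

The phantom stands in for a parcellated structural MR volume: K
disjoint axis-aligned ellipsoids on a regular grid, each filled with a
base intensity plus spatially correlated Gaussian noise (white noise
smoothed with a Gaussian kernel, then rescaled), over a noisy
background.  Anatomy is deliberately absent — downstream stages consume
statistical structure, not brains.

A signal plan links an ROI property to a subject's normalized test
score s in [0, 1], multiplicatively with effect size beta:

* ``texture-contrast`` — noise SD becomes ``sd * (1 + beta * s)``;
* ``volume``           — ellipsoid volume scales by ``1 + beta * s``;
* ``mean-intensity``   — base intensity becomes ``base * (1 + beta * s)``.

ROIs without planted signal are statistically identical across
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

SIGNAL_PROPERTIES = ("texture-contrast", "volume", "mean-intensity")


@dataclass
class RoiGeometry:
    """One ellipsoidal ROI: centre and semi-axes in voxel units.

    Texture parameters default to the spec-wide values when None.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    base_intensity: float | None = None
    noise_sd: float | None = None
    smooth_sigma: float | None = None


@dataclass
class SignalEffect:
    roi_label: int
    property: str
    beta: float
    test: str = "mf"

    def __post_init__(self) -> None:
        if self.property not in SIGNAL_PROPERTIES:
            raise ValueError(f"unknown signal property {self.property!r}")
        if not np.isfinite(self.beta):
            raise ValueError("effect size must be finite")


@dataclass
class PhantomSpec:
    """Geometry and texture description of the phantom volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rois: list[RoiGeometry] = field(default_factory=list)
    base_intensity: float = 300.0
    noise_sd: float = 50.0
    smooth_sigma: float = 1.0
    background_intensity: float = 100.0
    background_noise_sd: float = 20.0
    signal_plan: list[SignalEffect] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def validate(self) -> None:
        labels = {e.roi_label for e in self.signal_plan}
        if any(lab < 1 or lab > self.n_rois for lab in labels):
            raise ValueError("signal plan references ROI labels outside 1..K")
        # geometric disjointness at rest (score 0); volume effects re-check
        masks = _label_volume(self, scale=np.ones(self.n_rois))
        del masks  # raises on overlap


def default_phantom_spec(
    n_rois: int = 12,
    shape: tuple[int, int, int] = (64, 64, 64),
    radius: float | None = None,
    signal_plan: list[SignalEffect] | None = None,
    **kwargs,
) -> PhantomSpec:
    """Ellipsoids on a 3 x 2 x 2-ish grid filling ``shape``.

    ``radius`` defaults to a third of the grid pitch, which keeps ROIs
    disjoint with a comfortable margin even when volume effects inflate
    them by tens of percent.
    """
    grid = _grid_dims(n_rois)
    pitch = np.array(shape) / np.array(grid)
    if radius is None:
        radius = float(pitch.min()) / 3.0
    centers = []
    for a in range(grid[0]):
        for b in range(grid[1]):
            for c in range(grid[2]):
                centers.append(
                    (
                        pitch[0] * (a + 0.5),
                        pitch[1] * (b + 0.5),
                        pitch[2] * (c + 0.5),
                    )
                )
    rois = [
        RoiGeometry(center=ctr, radii=(radius, radius, radius))
        for ctr in centers[:n_rois]
    ]
    return PhantomSpec(
        shape=shape, rois=rois, signal_plan=list(signal_plan or []), **kwargs
    )


def _grid_dims(n: int) -> tuple[int, int, int]:
    dims = [1, 1, 1]
    i = 0
    while dims[0] * dims[1] * dims[2] < n:
        dims[i % 3] += 1
        i += 1
    return tuple(sorted(dims, reverse=True))


def _label_volume(spec: PhantomSpec, scale: np.ndarray) -> np.ndarray:
    """Rasterize ellipsoids; ``scale[k]`` multiplies ROI k+1's volume."""
    grid = np.indices(spec.shape).astype(np.float64)
    labels = np.zeros(spec.shape, dtype=np.int16)
    for k, roi in enumerate(spec.rois):
        r = np.array(roi.radii) * scale[k] ** (1.0 / 3.0)
        d2 = sum(
            ((grid[a] - roi.center[a]) / r[a]) ** 2 for a in range(3)
        )
        mask = d2 <= 1.0
        if np.any(labels[mask] != 0):
            raise ValueError(f"ROI {k + 1} overlaps another ROI")
        labels[mask] = k + 1
    return labels


def _standardized_field(shape, sigma, rng) -> np.ndarray:
    """Smoothed white noise, standardized to zero mean / unit SD volume-wide."""
    field_ = rng.standard_normal(shape)
    if sigma > 0:
        field_ = gaussian_filter(field_, sigma=sigma, mode="reflect")
    return (field_ - field_.mean()) / field_.std()


def generate_phantom(
    subject: "pd.Series | dict",
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity and label volumes for one subject.

    ``subject`` must expose ``<test>_norm`` entries for every test named
    in the signal plan.  Returns (float32 intensity, int16 labels).
    """
    effects: dict[int, dict[str, float]] = {}
    for e in spec.signal_plan:
        s = float(subject[f"{e.test}_norm"])
        if not 0.0 <= s <= 1.0:
            raise ValueError("normalized score outside [0, 1]")
        effects.setdefault(e.roi_label, {})[e.property] = 1.0 + e.beta * s

    scale = np.array(
        [effects.get(k + 1, {}).get("volume", 1.0) for k in range(spec.n_rois)]
    )
    labels = _label_volume(spec, scale)

    fields: dict[float, np.ndarray] = {}

    def field_for(sigma: float) -> np.ndarray:
        if sigma not in fields:
            fields[sigma] = _standardized_field(spec.shape, sigma, rng)
        return fields[sigma]

    intensity = (
        spec.background_intensity
        + spec.background_noise_sd * field_for(spec.smooth_sigma)
    ).astype(np.float64)

    for k, roi in enumerate(spec.rois):
        label = k + 1
        base = roi.base_intensity if roi.base_intensity is not None else spec.base_intensity
        sd = roi.noise_sd if roi.noise_sd is not None else spec.noise_sd
        sigma = roi.smooth_sigma if roi.smooth_sigma is not None else spec.smooth_sigma
        base = base * effects.get(label, {}).get("mean-intensity", 1.0)
        sd = sd * effects.get(label, {}).get("texture-contrast", 1.0)
        mask = labels == label
        intensity[mask] = base + sd * field_for(sigma)[mask]

    return intensity.astype(np.float32), labels


def null_spec(spec: PhantomSpec) -> PhantomSpec:
    """Copy of ``spec`` with the signal plan removed (pure-noise phantom)."""
    return replace(spec, signal_plan=[])
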