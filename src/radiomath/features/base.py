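"""ROI containers and fixed-bin-width gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 13 unique 3D unit-offset directions (one per opposite pair),
#: ordered so the first nonzero component is positive.
DIRECTIONS_3D = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

DEFAULT_BIN_WIDTH = 25.0


@dataclass
class RoiSample:
    """Voxel data for one ROI of one subject.

    ``intensities`` are raw image values (arbitrary MR units) and
    ``coords`` the matching 0-based integer voxel indices.  ``spacing``
    is mm per axis of the native image grid.
    """

    intensities: np.ndarray
    coords: np.ndarray
    spacing: np.ndarray
    roi_label: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64).ravel()
        self.coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).ravel()
        if self.intensities.size == 0:
            raise ValueError("ROI must contain at least one voxel")
        if self.intensities.size != self.coords.shape[0]:
            raise ValueError("intensities and coords disagree in length")
        if self.spacing.size != 3 or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive values")
        if len(np.unique(self.coords, axis=0)) != self.coords.shape[0]:
            raise ValueError("duplicate voxel coordinates in ROI")

    @property
    def n_voxels(self) -> int:
        return int(self.intensities.size)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DiscretizedRoi:
    """Gray-level bins for one ROI under fixed-bin-width discretization.

    Bin assignment uses the ROI minimum as offset:
    ``bin = floor((x - min) / width) + 1`` with ``N_g = max(bin)``.
    Levels are 1-based; intermediate levels may be unoccupied.
    """

    bins: np.ndarray
    n_levels: int
    bin_width: float
    sample: RoiSample = field(repr=False, default=None)


def discretize(sample: RoiSample, bin_width: float = DEFAULT_BIN_WIDTH) -> DiscretizedRoi:
    """Discretize ROI intensities with a fixed bin width (default 25)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = sample.intensities
    bins = np.floor((x - x.min()) / float(bin_width)).astype(np.int64) + 1
    return DiscretizedRoi(
        bins=bins,
        n_levels=int(bins.max()),
        bin_width=float(bin_width),
        sample=sample,
    )


def level_array(disc: DiscretizedRoi) -> np.ndarray:
    """Bounding-box array of gray levels, 0 outside the ROI, padded by 1.

    The one-voxel zero pad makes neighbour lookups at the box border
    safe without bounds checks; texture code indexes the interior via
    ``arr[1:-1, 1:-1, 1:-1]``.
    """
    coords = disc.sample.coords
    lo = coords.min(axis=0)
    shape = coords.max(axis=0) - lo + 3
    arr = np.zeros(shape, dtype=np.int32)
    c = coords - lo + 1
    arr[c[:, 0], c[:, 1], c[:, 2]] = disc.bins
    return arr


def shifted_view(padded: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """View of ``padded`` giving, for each interior voxel p, the value at p+d."""
    sl = tuple(slice(1 + o, s - 1 + o) for o, s in zip(d, padded.shape))
    return padded[sl]
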