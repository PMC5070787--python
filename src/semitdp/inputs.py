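"""Image preprocessing, population-coded spike encoding and feature selection.

Images are binarized, rarely-active pixels are dropped (occupancy filter),
and the binary image is supersampled 2x per side so that partial-feature
ensemble members and a full-feature gating network can receive the same
number of input neurons.  Each surviving pixel is represented by an ON/OFF
pair of input neurons (population code); during a presentation exactly one
neuron of each pair is eligible and fires as a constant-rate Poisson
process, and nothing fires during the rest period.

Three feature-selection schemes assign each ensemble member a quarter of
the active pixels: uniform random, 2-D normal Gaussians with jittered means
spread over the active region, and stretched (bar-shaped) Gaussians of
rotating orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryImageSet",
    "FeatureAssignment",
    "PresentationSchedule",
    "binarize",
    "occupancy_filter",
    "supersample",
    "population_encode_eligible",
    "select_random",
    "select_normal_gaussian",
    "select_stretched_gaussian",
    "JITTER_TABLE",
]

#: (epsilon, delta) of the jitter-accept loop per supported ensemble size:
#: jitter amplitude and minimum pairwise distance between Gaussian means.
JITTER_TABLE = {
    5: (9.0, 14.0),
    7: (7.0, 10.0),
    9: (5.0, 9.0),
    11: (5.0, 7.5),
    13: (5.0, 7.0),
    16: (5.0, 5.5),
    20: (5.0, 4.5),
    25: (3.0, 4.2),
}


def binarize(image: np.ndarray, threshold: int = 200) -> np.ndarray:
    """Binary image: pixel = 1 iff intensity strictly exceeds the threshold
    (grayscale max 255)."""
    image = np.asarray(image)
    if np.any(image < 0) or np.any(image > 255):
        raise ValueError("intensities must lie in [0, 255]")
    return (image > threshold).astype(np.uint8)


def occupancy_filter(images: np.ndarray, min_fraction: float = 0.03) -> np.ndarray:
    """Boolean mask of pixels that are ON in at least ``min_fraction`` of the
    images (pixels below the threshold are disabled)."""
    images = np.asarray(images)
    occupancy = images.reshape(images.shape[0], -1).mean(axis=0)
    mask = (occupancy >= min_fraction).reshape(images.shape[1:])
    if not mask.any():
        raise ValueError("occupancy filter disabled every pixel")
    return mask


def supersample(image: np.ndarray, factor: int = 2) -> np.ndarray:
    """Replicate each pixel into a factor x factor identical block
    (28x28 -> 56x56 for the default factor)."""
    image = np.asarray(image)
    return np.repeat(np.repeat(image, factor, axis=-2), factor, axis=-1)


@dataclass
class BinaryImageSet:
    """A preprocessed binary dataset on the supersampled grid.

    images : (N, H, W) uint8 in {0, 1} (already supersampled)
    labels : (N,) class ids — hidden from the learner, used only by metrics
        and supervised gating
    active_mask : (H, W) bool, identical across images
    """

    images: np.ndarray
    labels: np.ndarray
    active_mask: np.ndarray

    @classmethod
    def from_raw(
        cls,
        images: np.ndarray,
        labels: np.ndarray,
        threshold: int | None = None,
        min_fraction: float = 0.03,
        factor: int = 2,
    ) -> "BinaryImageSet":
        """Full pipeline: (optional) binarize, occupancy-filter on the
        original grid, then supersample images and mask together."""
        images = np.asarray(images)
        if threshold is not None:
            images = binarize(images, threshold)
        if not np.isin(images, (0, 1)).all():
            raise ValueError("images must be binary (pass threshold= to binarize)")
        mask = occupancy_filter(images, min_fraction)
        return cls(
            images=supersample(images.astype(np.uint8), factor),
            labels=np.asarray(labels, dtype=int),
            active_mask=supersample(mask.astype(np.uint8), factor).astype(bool),
        )

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def active_pixel_ids(self) -> np.ndarray:
        """Flat indices (row-major) of active pixels on the supersampled grid."""
        return np.flatnonzero(self.active_mask.ravel())


@dataclass
class PresentationSchedule:
    """Timing of the input stream: each image is shown for T_present with
    eligible input neurons firing as ``input_rate`` Hz Poisson processes,
    followed by T_rest of silence; classes are presented round-robin."""

    T_present: float = 0.040
    T_rest: float = 0.040
    input_rate: float = 40.0

    def __post_init__(self) -> None:
        if self.T_present <= 0 or self.T_rest < 0:
            raise ValueError("durations must be positive")

    @property
    def cycle(self) -> float:
        return self.T_present + self.T_rest


@dataclass
class FeatureAssignment:
    """Pixel subsets (flat ids on the supersampled grid) per ensemble member,
    plus the gating subset (every active pixel once via even selection, or a
    member-style subset)."""

    member_pixels: list[np.ndarray]
    gating_pixels: np.ndarray

    def __post_init__(self) -> None:
        for sub in self.member_pixels:
            if len(set(sub.tolist())) != sub.size:
                raise ValueError("duplicate pixels within a member subset")

    @property
    def n_members(self) -> int:
        return len(self.member_pixels)

    def to_frame(self, shape: tuple[int, int]):
        import pandas as pd

        rows = []
        for j, sub in enumerate(self.member_pixels):
            r, c = np.unravel_index(sub, shape)
            rows.append(pd.DataFrame({"member": j, "pixel_row": r, "pixel_col": c}))
        return pd.concat(rows, ignore_index=True)


def gating_even_selection(dataset: BinaryImageSet) -> np.ndarray:
    """Quarter of the supersampled pixels selected evenly — the top-left
    pixel of every 2x2 supersampling block — so the gating network sees
    every original active pixel exactly once."""
    h, w = dataset.active_mask.shape
    grid = np.zeros((h, w), dtype=bool)
    grid[0::2, 0::2] = True
    return np.flatnonzero((grid & dataset.active_mask).ravel())


def _quarter(n_active: int) -> int:
    return n_active // 4


def population_encode_eligible(
    image: np.ndarray, pixel_ids: np.ndarray
) -> np.ndarray:
    """Eligible input-neuron indices for one image and one pixel subset.

    Pixel p maps to neuron pair (2p, 2p+1) = (ON, OFF); the ON neuron is
    eligible when the pixel is 1, the OFF neuron otherwise.  Exactly one
    neuron per pair is eligible, and eligible neurons fire as Poisson
    processes during the presentation window only.
    """
    flat = np.asarray(image).ravel()
    return 2 * pixel_ids + (1 - flat[pixel_ids])


def select_random(
    dataset: BinaryImageSet, n_members: int, rng: np.random.Generator
) -> FeatureAssignment:
    """Uniform random feature selection: each member independently draws a
    quarter of the active pixels without replacement."""
    ids = dataset.active_pixel_ids()
    if ids.size < 4:
        raise ValueError("need at least 4 active pixels")
    k = _quarter(ids.size)
    members = [rng.choice(ids, size=k, replace=False) for _ in range(n_members)]
    return FeatureAssignment(members, gating_even_selection(dataset))


def _weighted_subset(
    ids: np.ndarray, weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequential weighted draw without replacement with renormalisation."""
    weights = np.asarray(weights, dtype=float)
    if np.all(weights <= 0):
        weights = np.ones_like(weights)
    p = weights / weights.sum()
    return rng.choice(ids, size=k, replace=False, p=p)


def _inner_region(active_mask: np.ndarray, border: int = 3) -> np.ndarray:
    """Active pixels at least ``border``+1 steps (Chebyshev) inside the outer
    border of the active region: the jittered Gaussian means must land here."""
    from scipy.ndimage import binary_erosion

    structure = np.ones((3, 3), dtype=bool)
    # outer border = boundary pixels of the active region; forbidden band is
    # `border` pixels thick inside it; means may lie on the inner boundary
    return binary_erosion(active_mask, structure, iterations=border + 1)


def _initial_means(inner: np.ndarray, n_members: int) -> np.ndarray:
    """Evenly designed starting points for the Gaussian means: a near-square
    lattice over the bounding box of the admissible region, snapped to the
    nearest admissible pixel."""
    rows, cols = np.nonzero(inner)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    n_side = int(np.ceil(np.sqrt(n_members)))
    rr = np.linspace(r0, r1, n_side + 2)[1:-1]
    cc = np.linspace(c0, c1, n_side + 2)[1:-1]
    grid = [(r, c) for r in rr for c in cc]
    pts = np.asarray(grid[:n_members], dtype=float)
    admissible = np.column_stack([rows, cols]).astype(float)
    out = np.empty_like(pts)
    for i, p in enumerate(pts):
        d = np.linalg.norm(admissible - p, axis=1)
        out[i] = admissible[np.argmin(d)]
    return out


def select_normal_gaussian(
    dataset: BinaryImageSet,
    n_members: int,
    rng: np.random.Generator,
    epsilon: float | None = None,
    delta: float | None = None,
    sigma2: float = 49.0,
    max_iter: int = 100_000,
) -> FeatureAssignment:
    """Normal-Gaussian scheme: member i draws pixels with weights
    0.1 exp(-dist((x,y), mean_i)^2 / (2 sigma^2)), sigma^2 = 49, restricted
    to the active mask.  Means are placed by the jitter-accept loop: each
    designed initial point is jittered by [-eps, eps] per axis, and a draw
    is accepted only when all means lie inside the inner region (3-pixel
    forbidden band inside the outer border) and the minimum pairwise
    distance exceeds delta.
    """
    if epsilon is None or delta is None:
        try:
            epsilon, delta = JITTER_TABLE[n_members]
        except KeyError:
            raise ValueError(
                f"no (epsilon, delta) tabulated for N_E={n_members}; "
                "pass them explicitly"
            ) from None
    inner = _inner_region(dataset.active_mask)
    if not inner.any():
        raise ValueError("no admissible region for Gaussian means")
    init = _initial_means(inner, n_members)
    shape = dataset.active_mask.shape
    for _ in range(max_iter):
        means = init + rng.uniform(-epsilon, epsilon, size=init.shape)
        ok_inside = all(
            0 <= round(r) < shape[0]
            and 0 <= round(c) < shape[1]
            and inner[round(r), round(c)]
            for r, c in means
        )
        if not ok_inside:
            continue
        d = np.linalg.norm(means[:, None, :] - means[None, :, :], axis=-1)
        d_min = d[np.triu_indices(n_members, 1)].min() if n_members > 1 else np.inf
        if d_min > delta:
            break
    else:
        raise RuntimeError(
            "Gaussian mean placement did not converge; increase epsilon or "
            "decrease delta"
        )
    ids = dataset.active_pixel_ids()
    r, c = np.unravel_index(ids, shape)
    k = _quarter(ids.size)
    members = []
    for mu in means:
        dist2 = (r - mu[0]) ** 2 + (c - mu[1]) ** 2
        weights = 0.1 * np.exp(-dist2 / (2.0 * sigma2))
        members.append(_weighted_subset(ids, weights, k, rng))
    return FeatureAssignment(members, gating_even_selection(dataset))


def stretched_precision(
    theta: float, sigma_x2: float = 4.0, sigma_y2: float = 625.0
) -> np.ndarray:
    """Inverse covariance of the stretched (bar-shaped) Gaussian rotated by
    theta: symmetric positive definite for every angle."""
    a = np.cos(theta) ** 2 / (2 * sigma_x2) + np.sin(theta) ** 2 / (2 * sigma_y2)
    b = np.sin(2 * theta) / (4 * sigma_y2) - np.sin(2 * theta) / (4 * sigma_x2)
    c = np.sin(theta) ** 2 / (2 * sigma_x2) + np.cos(theta) ** 2 / (2 * sigma_y2)
    return np.array([[a, b], [b, c]])


def select_stretched_gaussian(
    dataset: BinaryImageSet,
    n_members: int,
    rng: np.random.Generator,
    sigma_x2: float = 4.0,
    sigma_y2: float = 625.0,
) -> FeatureAssignment:
    """Stretched-Gaussian scheme: all members share the image-centre mean but
    the bar orientation rotates by pi/N_E between successive members
    (theta_i = i pi / N_E)."""
    shape = dataset.active_mask.shape
    centre = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    ids = dataset.active_pixel_ids()
    r, c = np.unravel_index(ids, shape)
    x = np.column_stack([r - centre[0], c - centre[1]])
    k = _quarter(ids.size)
    members = []
    for i in range(n_members):
        theta = i * np.pi / n_members
        prec = stretched_precision(theta, sigma_x2, sigma_y2)
        weights = np.exp(-np.einsum("ni,ij,nj->n", x, prec, x))
        members.append(_weighted_subset(ids, weights, k, rng))
    return FeatureAssignment(members, gating_even_selection(dataset))
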