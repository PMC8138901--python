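"""Monte-Carlo cluster-extent thresholding on smooth Gaussian noise fields.

To control the family-wise error of voxel-wise maps thresholded at a lenient
height (e.g. p < 0.005), null fields with the residuals' spatial smoothness
are simulated, thresholded, and their largest suprathreshold cluster sizes
tabulated; the cluster-size threshold ``k_min`` is the smallest extent whose
exceedance probability under the null is at most alpha.

Smoothness is parametrized by the Gaussian autocorrelation convention used
in the cluster-simulation literature: a field with smoothness FWHM ``f`` has

    acf(d) = exp(-4 ln2 * d^2 / f^2).

White noise convolved with a Gaussian kernel of FWHM f_k yields a field of
smoothness sqrt(2) * f_k, so ``simulate_field`` applies a kernel of FWHM
f / sqrt(2) to hit the target. Boundaries are periodic, which keeps the
field stationary on small grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from ._validate import require

_CONNECTIVITY = {"faces": 1, "faces+edges": 2, "faces+edges+corners": 3}


@dataclass
class NoiseModel:
    """Spatial null model: grid geometry, smoothness, and test sidedness."""

    shape: tuple[int, ...] = (32, 32, 32)
    voxel_size: float = 1.5       # mm
    fwhm: float = 6.0             # mm, Gaussian-ACF smoothness of the field
    sidedness: str = "two"        # "one" or "two"
    connectivity: str = "faces"

    def validate(self) -> "NoiseModel":
        require(all(int(d) >= 1 for d in self.shape),
                f"grid dimensions must be >= 1, got {self.shape}")
        require(self.voxel_size > 0, "voxel_size must be positive")
        require(self.fwhm >= 0, f"fwhm must be >= 0, got {self.fwhm}")
        require(self.sidedness in ("one", "two"),
                f"sidedness must be 'one' or 'two', got {self.sidedness!r}")
        require(self.connectivity in _CONNECTIVITY,
                f"connectivity must be one of {sorted(_CONNECTIVITY)}")
        return self


def simulate_field(model: NoiseModel,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """One standardized null field with the model's Gaussian-ACF smoothness.

    White Gaussian noise is smoothed with periodic (wrap-around) boundaries
    and standardized to zero mean / unit variance. ``fwhm = 0`` skips the
    smoothing entirely.
    """
    model.validate()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    field = rng.standard_normal(model.shape)
    if model.fwhm > 0:
        # kernel FWHM = target ACF FWHM / sqrt(2); sigma in voxel units
        kernel_fwhm_vox = model.fwhm / np.sqrt(2.0) / model.voxel_size
        sigma = kernel_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        field = ndimage.gaussian_filter(field, sigma=sigma, mode="wrap")
    field = field - field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def label_clusters(binary: np.ndarray, connectivity: str = "faces",
                   ) -> list[int]:
    """Connected-component sizes of a boolean field, descending."""
    binary = np.asarray(binary, dtype=bool)
    structure = ndimage.generate_binary_structure(binary.ndim,
                                                  _CONNECTIVITY[connectivity])
    labeled, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return []
    sizes = np.bincount(labeled.ravel())[1:]
    return sorted((int(s) for s in sizes), reverse=True)


def _height_threshold(voxel_p: float, sidedness: str) -> float:
    return stats.norm.isf(voxel_p / 2.0 if sidedness == "two" else voxel_p)


def _max_cluster(field: np.ndarray, z: float, model: NoiseModel) -> int:
    binary = (np.abs(field) > z) if model.sidedness == "two" else (field > z)
    sizes = label_clusters(binary, model.connectivity)
    return sizes[0] if sizes else 0


@dataclass
class ClusterThresholdResult:
    k_min: int
    alpha: float
    voxel_p: float
    n_iter: int
    exceedance: dict[int, float]   # k -> P(max cluster >= k)


def cluster_threshold(model: NoiseModel, voxel_p: float = 0.005,
                      alpha: float = 0.05, n_iter: int = 1000,
                      seed: int = 0) -> ClusterThresholdResult:
    """Smallest cluster extent k with null exceedance probability <= alpha."""
    model.validate()
    require(0.0 < voxel_p < 1.0, f"voxel_p must lie in (0, 1), got {voxel_p}")
    require(0.0 < alpha < 1.0, f"alpha must lie in (0, 1), got {alpha}")
    require(n_iter >= 100, f"n_iter must be >= 100, got {n_iter}")

    z = _height_threshold(voxel_p, model.sidedness)
    rng = np.random.default_rng(seed)
    maxima = np.array([_max_cluster(simulate_field(model, rng), z, model)
                       for _ in range(n_iter)])

    kmax = int(maxima.max())
    exceedance = {k: float(np.mean(maxima >= k)) for k in range(1, kmax + 2)}
    if alpha < 1.0 / n_iter:
        warnings.warn(
            f"alpha={alpha} is below the 1/{n_iter} simulation resolution; "
            "returning the simulation-ceiling threshold")
        return ClusterThresholdResult(kmax + 1, alpha, voxel_p, n_iter,
                                      exceedance)
    k_min = next(k for k in range(1, kmax + 2) if exceedance[k] <= alpha)
    return ClusterThresholdResult(k_min, alpha, voxel_p, n_iter, exceedance)


def familywise_error(model: NoiseModel, voxel_p: float, k: int,
                     n_iter: int = 500, seed: int = 1) -> float:
    """Fraction of fresh null fields with any suprathreshold cluster >= k."""
    model.validate()
    z = _height_threshold(voxel_p, model.sidedness)
    rng = np.random.default_rng(seed)
    hits = sum(_max_cluster(simulate_field(model, rng), z, model) >= k
               for _ in range(n_iter))
    return hits / n_iter
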