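"""Per-pixel multi-scale feature bank.

Each pixel is described by Gaussian-smoothed colour, edge and texture responses
at several smoothing scales σ — the conventional feature bank for interactive
random-forest pixel classification of micrographs.  The bank stores raw filter
responses; standardisation happens inside the classifier using training-set
statistics.

Boundary handling is mirror reflection, and the two eigenvalue-valued groups
(structure tensor, Hessian) report eigenvalues sorted descending.  Together
these make the bank equivariant under multiples of 90° rotation up to
floating-point rounding, which is what makes downstream osteoclast counts
independent of image orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import DomainError
from .io import RasterImage

#: Canonical group order; eigenvalue groups contribute two components each.
GROUP_COMPONENTS = {
    "smoothed_colour": 1,
    "gradient_magnitude": 1,
    "laplacian": 1,
    "difference_of_gaussians": 1,
    "structure_tensor_eigenvalues": 2,
    "hessian_eigenvalues": 2,
}

#: Default σ ladder (pixels), from sub-pixel to coarse texture context.
DEFAULT_SCALES = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0)

_BOUNDARY = "reflect"


@dataclass(frozen=True)
class FeatureConfig:
    """Which filter groups to compute, at which scales, on which channels."""

    scales: tuple[float, ...] = DEFAULT_SCALES
    groups: tuple[str, ...] = tuple(GROUP_COMPONENTS)
    channel_policy: str = "per-channel"  # or "luminance"

    def __post_init__(self):
        scales = tuple(float(s) for s in self.scales)
        if not scales or any(s <= 0 for s in scales):
            raise DomainError("scales must be positive")
        if list(scales) != sorted(set(scales)):
            raise DomainError("scales must be strictly increasing")
        if not self.groups:
            raise DomainError("at least one feature group is required")
        unknown = set(self.groups) - set(GROUP_COMPONENTS)
        if unknown:
            raise DomainError(f"unknown feature groups {sorted(unknown)}")
        if self.channel_policy not in ("per-channel", "luminance"):
            raise DomainError(f"unknown channel policy {self.channel_policy!r}")
        object.__setattr__(self, "scales", scales)
        # preserve canonical ordering regardless of how groups were given
        object.__setattr__(
            self, "groups", tuple(g for g in GROUP_COMPONENTS if g in self.groups)
        )

    @property
    def n_channels(self) -> int:
        return 3 if self.channel_policy == "per-channel" else 1

    @property
    def n_features(self) -> int:
        per_scale_channel = sum(GROUP_COMPONENTS[g] for g in self.groups)
        return len(self.scales) * self.n_channels * per_scale_channel

    def feature_names(self) -> list[str]:
        names = []
        for s in self.scales:
            for g in self.groups:
                for c in range(self.n_channels):
                    for e in range(GROUP_COMPONENTS[g]):
                        suffix = f"/e{e}" if GROUP_COMPONENTS[g] > 1 else ""
                        names.append(f"{g}/s{s:g}/c{c}{suffix}")
        return names

    def to_json(self) -> str:
        return json.dumps(
            {
                "scales": list(self.scales),
                "groups": list(self.groups),
                "channel_policy": self.channel_policy,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureConfig":
        d = json.loads(text)
        return cls(tuple(d["scales"]), tuple(d["groups"]), d["channel_policy"])


@dataclass
class FeatureStack:
    values: np.ndarray  # (H, W, F) float64
    names: list[str] = field(default_factory=list)

    def as_matrix(self) -> np.ndarray:
        """Flatten to (H*W, F) for the classifier."""
        h, w, f = self.values.shape
        return self.values.reshape(h * w, f)


def _kernel(sigma: float, order: int) -> np.ndarray:
    """Truncated Gaussian-derivative kernel with exact zero DC response.

    The even (second-order) kernel is re-centred so it sums to zero despite
    truncation; odd kernels sum to zero by symmetry.  σ=0.3 yields a minimal
    3-tap kernel rather than being skipped.
    """
    radius = max(1, int(4.0 * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return -(x / sigma**2) * phi
    k = ((x**2 - sigma**2) / sigma**4) * phi
    return k - k.sum() / k.size


def _filter(ch: np.ndarray, sigma: float, order_y: int, order_x: int) -> np.ndarray:
    out = ndi.correlate1d(ch, _kernel(sigma, order_y), axis=0, mode=_BOUNDARY)
    return ndi.correlate1d(out, _kernel(sigma, order_x), axis=1, mode=_BOUNDARY)


def _sym2x2_eigvals(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Eigenvalues of the symmetric matrix [[a, b], [b, c]], sorted descending."""
    half_tr = 0.5 * (a + c)
    root = np.sqrt((0.5 * (a - c)) ** 2 + b**2)
    return half_tr + root, half_tr - root


def _channel_features(ch: np.ndarray, sigma: float) -> dict[str, tuple[np.ndarray, ...]]:
    smoothed = _filter(ch, sigma, 0, 0)
    gy = _filter(ch, sigma, 1, 0)
    gx = _filter(ch, sigma, 0, 1)
    out = {"smoothed_colour": (smoothed,)}
    out["gradient_magnitude"] = (np.sqrt(gy * gy + gx * gx),)
    hyy = _filter(ch, sigma, 2, 0)
    hxy = _filter(ch, sigma, 1, 1)
    hxx = _filter(ch, sigma, 0, 2)
    out["laplacian"] = (hyy + hxx,)
    out["difference_of_gaussians"] = (_filter(ch, 0.66 * sigma, 0, 0) - smoothed,)
    # structure tensor: gradients at the inner scale σ/2, tensor averaged at σ
    inner = max(0.5 * sigma, 0.3)
    igy = _filter(ch, inner, 1, 0)
    igx = _filter(ch, inner, 0, 1)
    a = _filter(igy * igy, sigma, 0, 0)
    b = _filter(igy * igx, sigma, 0, 0)
    c = _filter(igx * igx, sigma, 0, 0)
    out["structure_tensor_eigenvalues"] = _sym2x2_eigvals(a, b, c)
    out["hessian_eigenvalues"] = _sym2x2_eigvals(hyy, hxy, hxx)
    return out


def compute_features(image: RasterImage | np.ndarray, config: FeatureConfig) -> FeatureStack:
    """Compute the full feature stack for one image.

    Raises :class:`DomainError` if any scale exceeds half the smaller image
    dimension — the filter support would wrap the whole image and the feature
    is undefined at that scale.
    """
    pixels = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    h, w = pixels.shape[:2]
    if max(config.scales) > min(h, w) / 2:
        raise DomainError(
            f"scale {max(config.scales)} exceeds half the smaller image dimension "
            f"({min(h, w)}/2)"
        )
    if config.channel_policy == "per-channel":
        channels = [pixels[:, :, c].astype(np.float64) for c in range(3)]
    else:
        channels = [pixels.astype(np.float64).mean(axis=2)]

    planes: list[np.ndarray] = []
    for s in config.scales:
        per_channel = [_channel_features(ch, s) for ch in channels]
        for g in config.groups:
            for feats in per_channel:
                planes.extend(feats[g])
    values = np.stack(planes, axis=-1)
    if not np.isfinite(values).all():
        raise DomainError("non-finite feature values")  # pragma: no cover
    return FeatureStack(values, config.feature_names())
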