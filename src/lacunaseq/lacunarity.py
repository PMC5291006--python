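"""Gray-scale gliding-box lacunarity.

The gliding-box algorithm slides a b x b box one pixel at a time over an
image and records the mass (sum of pixel values; on a binary image, the
white-pixel count) of every fully contained placement.  Lacunarity at box
size b is the ratio of the second moment to the squared first moment of the
resulting box-mass distribution,

    Lambda(b) = Z2 / Z1**2,      Zq = sum_j Mj**q * n(Mj, b) / N(b),

which is 1 for a translation-invariant (constant) image and grows with the
"gappiness" of the texture.  Before the box analysis the CGR count matrix is
min-max normalized to [0, 1] and passed through a logistic sigmoid

    J = 1 / (1 + exp(-k (I - sigma)))

which smoothly thresholds gray levels at sigma; increasing k approaches a
complete binarization at that level.

Box sums are computed with an integral image (summed-area table), so the
whole curve costs O(H*W) per box size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit


#: Defaults of the sigmoid operating point used throughout the pipeline.
DEFAULT_K = 7.0
DEFAULT_SIGMA = 0.7


@dataclass(frozen=True)
class SigmoidParams:
    """Steepness k and gray-level midpoint sigma of the logistic preprocessor."""

    k: float = DEFAULT_K
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.k <= 0 or self.sigma <= 0:
            raise ValueError(f"k and sigma must be positive, got {self.k}, {self.sigma}")


@dataclass
class BoxMassDistribution:
    """Empirical distribution of box masses at one box size."""

    b: int
    masses: np.ndarray        # distinct mass values M_j
    frequencies: np.ndarray   # n(M_j, b)
    total_boxes: int          # N(b)

    def moment(self, q: int) -> float:
        """Raw moment Zq of the box mass under the empirical distribution."""
        return float((self.masses ** q * self.frequencies).sum() / self.total_boxes)


@dataclass
class LacunarityCurve:
    """Lambda(b) sampled at every integer b in [b_min, b_max]."""

    b: np.ndarray
    lam: np.ndarray
    distributions: list[BoxMassDistribution] = field(default_factory=list)

    @property
    def b_min(self) -> int:
        return int(self.b[0])

    @property
    def b_max(self) -> int:
        return int(self.b[-1])


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError(f"image must be 2-D with both sides >= 2, got shape {img.shape}")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image pixels must lie in [0, 1]")
    return img


def normalize_matrix(values: np.ndarray) -> np.ndarray:
    """Min-max scale a non-negative matrix to [0, 1].

    A constant positive matrix maps to all ones; an all-zero matrix is
    rejected (no texture to analyze).
    """
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax == 0:
        raise ValueError("all-zero matrix has no texture to analyze")
    if vmax == vmin:
        return np.ones_like(values)
    return (values - vmin) / (vmax - vmin)


def sigmoid_preprocess(img: np.ndarray, params: SigmoidParams = SigmoidParams()) -> np.ndarray:
    """Apply the logistic gray-level threshold J = 1/(1+exp(-k(I-sigma)))."""
    img = _check_image(img)
    return expit(params.k * (img - params.sigma))


def _box_sums(img: np.ndarray, b: int) -> np.ndarray:
    """Sums of every fully contained b x b box, via a summed-area table."""
    sat = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=sat[1:, 1:])
    return sat[b:, b:] - sat[:-b, b:] - sat[b:, :-b] + sat[:-b, :-b]


def box_mass_distribution(img: np.ndarray, b: int) -> BoxMassDistribution:
    """Gliding-box mass distribution at box size b (stride 1, no padding)."""
    img = _check_image(img)
    h, w = img.shape
    if not 1 <= b <= min(h, w):
        raise ValueError(f"box size {b} out of range [1, {min(h, w)}]")
    sums = _box_sums(img, b)
    # round to kill cumsum float jitter so identical masses collapse in unique()
    masses, freqs = np.unique(np.round(sums, 9), return_counts=True)
    n = (h - b + 1) * (w - b + 1)
    assert freqs.sum() == n
    return BoxMassDistribution(b=b, masses=masses, frequencies=freqs, total_boxes=n)


def lacunarity_at(dist: BoxMassDistribution) -> float:
    """Lambda(b) = Z2 / Z1**2 of a box-mass distribution."""
    z1 = dist.moment(1)
    if z1 <= 0:
        raise ValueError(f"lacunarity undefined at b={dist.b}: mean box mass is zero")
    if dist.masses.size == 1:
        return 1.0  # zero variance: exact, avoids float jitter in the moments
    return dist.moment(2) / z1 ** 2


def lacunarity_curve(img: np.ndarray, b_min: int, b_max: int | None = None) -> LacunarityCurve:
    """Evaluate Lambda at every integer box size in [b_min, b_max].

    ``b_max=None`` selects floor(min(H, W)/2): beyond half the image side
    too few placements remain for a meaningful variance.
    """
    img = _check_image(img)
    side = min(img.shape)
    if b_max is None:
        b_max = side // 2
    if not 1 <= b_min < b_max <= side:
        raise ValueError(
            f"need 1 <= b_min < b_max <= {side}, got b_min={b_min}, b_max={b_max}"
        )
    bs = np.arange(b_min, b_max + 1)
    dists = [box_mass_distribution(img, int(b)) for b in bs]
    lam = np.array([lacunarity_at(d) for d in dists])
    return LacunarityCurve(b=bs, lam=lam, distributions=dists)


def write_curve_csv(curve: LacunarityCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("b,lambda\n")
        for b, lam in zip(curve.b, curve.lam):
            fh.write(f"{int(b)},{lam:.12g}\n")


def read_curve_csv(path: str | Path) -> LacunarityCurve:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return LacunarityCurve(b=data[:, 0].astype(int), lam=data[:, 1])
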