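"""Synthetic-sample construction for minority and medium classes.

Operators
---------
* ``geometric_colour_transform`` (GCT): a seeded random combination of
  horizontal/vertical flips, right-angle rotation, global brightness
  scaling in 50-150% of the original pixel value, and a random crop padded
  back to the original frame.
* ``matrix_mixup``: per-pixel convex interpolation of two same-class images
  with a coefficient *matrix* whose elements are drawn uniformly from
  [0.35, 0.65], so the synthetic image never collapses onto either parent.
  The label set of the result is the intersection of the parents' label
  sets.
* ``nonlinear_mixup``: matrix mixup followed by a per-pixel 3D rotation of
  the (red, green, yellow) colour triple about the green axis (preserves
  the protein-of-interest channel, varies the background) or the red axis
  (preserves the microtubule reference).  The blue (nucleus) channel takes
  part in the interpolation but is excluded from the colour rotation.  The
  rotation angle alternates between two degree sets, [60, 110] and
  [120, 300], across successive draws so consecutive synthetic images do
  not look alike.

All operators consume and produce 4-channel images with values in [0, 1]
and fixed channel order (red, green, blue, yellow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "MultiChannelImage",
    "MixupCoefficientMatrix",
    "ThetaSampler",
    "AugmentedSample",
    "geometric_colour_transform",
    "sample_mixup_matrix",
    "matrix_mixup",
    "rotation_matrix",
    "rotate_colour_space",
    "nonlinear_mixup",
    "materialize_record",
]

#: Fixed channel order relied on by every module.
CHANNELS = ("red", "green", "blue", "yellow")

RED, GREEN, BLUE, YELLOW = 0, 1, 2, 3

#: Default admissible range for mixup coefficient matrix elements.
LAMBDA_LOW, LAMBDA_HIGH = 0.35, 0.65

#: Brightness scaling range (fractions of the original pixel value).
BRIGHTNESS_RANGE = (0.5, 1.5)

#: Crop-then-pad retains this fraction range of each spatial dimension.
CROP_FRACTION_RANGE = (0.8, 1.0)

Axis = Literal["G", "R"]


@dataclass(frozen=True)
class MultiChannelImage:
    """4-channel raster (red, green, blue, yellow), values in [0, 1]."""

    channels: np.ndarray  # shape (4, height, width)

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[0] != len(CHANNELS):
            raise ValueError(
                f"expected channel stack of shape (4, H, W), got {arr.shape}"
            )
        if arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError("image dimensions must be positive")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "channels", arr)

    @property
    def height(self) -> int:
        return self.channels.shape[1]

    @property
    def width(self) -> int:
        return self.channels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNELS.index(name)]


@dataclass(frozen=True)
class MixupCoefficientMatrix:
    """Per-pixel mixup coefficients, every element within [low, high]."""

    values: np.ndarray  # shape (height, width)
    low: float = LAMBDA_LOW
    high: float = LAMBDA_HIGH

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("coefficient matrix must be 2-D")
        if arr.min() < self.low or arr.max() > self.high:
            raise ValueError(
                f"coefficient elements must lie in [{self.low}, {self.high}]"
            )
        object.__setattr__(self, "values", arr)


class ThetaSampler:
    """Rotation-angle source alternating strictly between two degree sets.

    Successive draws come from ``[60, 110]`` and ``[120, 300]`` in strict
    alternation; a seeded fair coin picks which set starts.
    """

    SET_A = (60.0, 110.0)
    SET_B = (120.0, 300.0)

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)
        self._use_a_next = bool(self._rng.integers(2))

    def draw(self) -> float:
        low, high = self.SET_A if self._use_a_next else self.SET_B
        self._use_a_next = not self._use_a_next
        return float(self._rng.uniform(low, high))


@dataclass(frozen=True)
class AugmentedSample:
    """A (possibly synthetic) image together with labels and provenance.

    ``provenance`` records the operator chain: operator name, parent sample
    ids, the rotation angle and coefficient-matrix seed where applicable.
    """

    image: MultiChannelImage
    label_set: frozenset[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "label_set", frozenset(str(x) for x in self.label_set))
        if not self.label_set:
            raise ValueError("label set must be non-empty")

    @property
    def sample_id(self) -> str:
        return str(self.provenance.get("id", ""))


def _as_sample(x: AugmentedSample | MultiChannelImage, labels=None) -> AugmentedSample:
    if isinstance(x, AugmentedSample):
        return x
    return AugmentedSample(image=x, label_set=frozenset(labels or {"?"}))


def geometric_colour_transform(
    sample: AugmentedSample, seed: int
) -> AugmentedSample:
    """Apply a seeded random combination of geometric/colour transforms.

    Each of the five transforms (horizontal flip, vertical flip, right-angle
    rotation, brightness scaling, crop-then-pad) is independently included
    with probability 1/2; a draw selecting none is rejected and redrawn, so
    the output is never the untouched input.  Output dimensions equal input
    dimensions; for non-square images only the 180-degree rotation is
    admissible.  The label set is unchanged.
    """
    rng = np.random.default_rng(seed)
    img = sample.image.channels
    h, w = img.shape[1], img.shape[2]

    while True:
        flags = rng.random(5) < 0.5
        if flags.any():
            break
    do_hflip, do_vflip, do_rot, do_bright, do_crop = flags

    applied: list[str] = []
    out = img.copy()
    if do_hflip:
        out = out[:, :, ::-1]
        applied.append("hflip")
    if do_vflip:
        out = out[:, ::-1, :]
        applied.append("vflip")
    if do_rot:
        k = int(rng.choice([1, 2, 3]))
        if h != w and k in (1, 3):
            k = 2  # 90/270 would change the frame for non-square images
        out = np.rot90(out, k=k, axes=(1, 2))
        applied.append(f"rot{90 * k}")
    if do_bright:
        factor = float(rng.uniform(*BRIGHTNESS_RANGE))
        out = np.clip(out * factor, 0.0, 1.0)
        applied.append(f"brightness{factor:.3f}")
    if do_crop:
        fh = float(rng.uniform(*CROP_FRACTION_RANGE))
        fw = float(rng.uniform(*CROP_FRACTION_RANGE))
        ch = max(1, int(round(fh * h)))
        cw = max(1, int(round(fw * w)))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = out[:, top : top + ch, left : left + cw]
        canvas = np.zeros_like(out)
        ptop = int(rng.integers(0, h - ch + 1))
        pleft = int(rng.integers(0, w - cw + 1))
        canvas[:, ptop : ptop + ch, pleft : pleft + cw] = crop
        out = canvas
        applied.append(f"crop{ch}x{cw}")

    return AugmentedSample(
        image=MultiChannelImage(np.ascontiguousarray(out)),
        label_set=sample.label_set,
        provenance={
            "operator": "GCT",
            "parents": (sample.sample_id,) if sample.sample_id else (),
            "seed": int(seed),
            "transforms": applied,
        },
    )


def sample_mixup_matrix(
    height: int,
    width: int,
    seed: int,
    low: float = LAMBDA_LOW,
    high: float = LAMBDA_HIGH,
) -> MixupCoefficientMatrix:
    """Draw a per-pixel coefficient matrix, elements iid Uniform(low, high).

    One matrix is shared across all four channels of a mixup pair.
    """
    if height < 1 or width < 1:
        raise ValueError("matrix dimensions must be positive")
    rng = np.random.default_rng(seed)
    return MixupCoefficientMatrix(
        values=rng.uniform(low, high, size=(height, width)), low=low, high=high
    )


def matrix_mixup(
    a: AugmentedSample, b: AugmentedSample, lam: MixupCoefficientMatrix
) -> AugmentedSample:
    """Per-pixel convex interpolation: out = lam * a + (1 - lam) * b.

    The same spatial coefficient matrix applies to all four channels.  The
    output label set is the intersection of the parents' label sets; an
    empty intersection is rejected because the synthetic sample would carry
    no defensible label.
    """
    ia, ib = a.image.channels, b.image.channels
    if ia.shape != ib.shape:
        raise ValueError(f"image shape mismatch: {ia.shape} vs {ib.shape}")
    if lam.values.shape != ia.shape[1:]:
        raise ValueError(
            f"coefficient matrix shape {lam.values.shape} does not match "
            f"image plane {ia.shape[1:]}"
        )
    labels = a.label_set & b.label_set
    if not labels:
        raise ValueError(
            "empty label-set intersection: mixup parents must share a label"
        )
    mixed = lam.values[np.newaxis] * ia + (1.0 - lam.values[np.newaxis]) * ib
    return AugmentedSample(
        image=MultiChannelImage(mixed),
        label_set=labels,
        provenance={
            "operator": "mixup",
            "parents": (a.sample_id, b.sample_id),
            "lambda_range": (lam.low, lam.high),
        },
    )


def rotation_matrix(axis: Axis, theta: float) -> np.ndarray:
    """3x3 rotation matrix about the green (G) or red (R) axis of the
    red-green-yellow colour space; ``theta`` in degrees.

    Pixels are row vectors ``[red, green, yellow]`` right-multiplied by the
    returned matrix.
    """
    t = np.deg2rad(theta)
    c, s = np.cos(t), np.sin(t)
    if axis == "G":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    if axis == "R":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    raise ValueError(f"axis must be 'G' or 'R', got {axis!r}")


def rotate_colour_space(
    image: MultiChannelImage, axis: Axis, theta: float, clip: bool = True
) -> MultiChannelImage | np.ndarray:
    """Rotate each pixel's (red, green, yellow) triple about one colour axis.

    The rotation moves each pixel on a circle centred on the chosen axis, so
    the axis channel itself is returned bit-identical: green for axis G
    (keeping the protein-of-interest pattern intact), red for axis R.  The
    blue (nucleus) channel lies outside the RGY colour space and passes
    through untouched.  Off-axis results are clipped back to [0, 1], which
    matters for angles with negative cosine or sine; ``clip=False`` returns
    the raw rotated stack as a plain array (on which the per-pixel
    (red, green, yellow) norm is exactly preserved) for diagnostics.
    """
    r = image.channels[RED]
    g = image.channels[GREEN]
    y = image.channels[YELLOW]
    t = np.deg2rad(theta)
    c, s = np.cos(t), np.sin(t)
    # row [r, g, y] @ rotation_matrix(axis, theta), written out per channel
    if axis == "G":
        new_r, new_g, new_y = c * r - s * y, g, s * r + c * y
    elif axis == "R":
        new_r, new_g, new_y = r, c * g + s * y, -s * g + c * y
    else:
        raise ValueError(f"axis must be 'G' or 'R', got {axis!r}")
    out = np.stack([new_r, new_g, image.channels[BLUE], new_y])
    if not clip:
        return out
    out[RED] = np.clip(out[RED], 0.0, 1.0)
    out[YELLOW] = np.clip(out[YELLOW], 0.0, 1.0)
    out[GREEN] = np.clip(out[GREEN], 0.0, 1.0)
    if axis == "G":
        out[GREEN] = g  # keep the axis channel bit-identical
    else:
        out[RED] = r
    return MultiChannelImage(out)


def materialize_record(
    record,
    load,
    seed: int,
    theta_sampler: ThetaSampler | None = None,
) -> AugmentedSample:
    """Turn a supplement provenance record into pixels.

    ``record`` needs ``operator`` and ``parent_ids`` attributes (and
    optionally ``theta``); ``load`` maps a sample id to an
    :class:`AugmentedSample`.  A recorded theta takes precedence over the
    sampler so that re-materializing a manifest reproduces the original
    image.
    """
    parents = [load(pid) for pid in record.parent_ids]
    op = record.operator
    if op == "GCT":
        return geometric_colour_transform(parents[0], seed)
    if op in ("NLmixupR", "NLmixupG"):
        axis: Axis = "R" if op.endswith("R") else "G"
        theta = getattr(record, "theta", None)
        if theta is not None:
            lam = sample_mixup_matrix(
                parents[0].image.height, parents[0].image.width, seed
            )
            mix = matrix_mixup(parents[0], parents[1], lam)
            out = rotate_colour_space(mix.image, axis, theta)
            return AugmentedSample(
                image=out,
                label_set=mix.label_set,
                provenance={
                    "operator": op,
                    "parents": tuple(record.parent_ids),
                    "theta": float(theta),
                    "lambda_seed": int(seed),
                },
            )
        if theta_sampler is None:
            raise ValueError("record carries no theta and no sampler was given")
        return nonlinear_mixup(parents[0], parents[1], axis, theta_sampler, seed)
    raise ValueError(f"unknown operator {op!r}")


def nonlinear_mixup(
    a: AugmentedSample,
    b: AugmentedSample,
    axis: Axis,
    theta_sampler: ThetaSampler,
    seed: int,
) -> AugmentedSample:
    """Matrix mixup followed by a 3D colour-space rotation.

    A fresh coefficient matrix is drawn from ``seed``, the two parents are
    interpolated, and every pixel's (red, green, yellow) triple is rotated
    about the requested axis by an angle drawn from ``theta_sampler``.  The
    label set is inherited from the mixup step (parents' intersection).
    Axis G leaves the mixup green channel bit-identical; axis R leaves the
    mixup red channel bit-identical.
    """
    lam = sample_mixup_matrix(a.image.height, a.image.width, seed)
    mix = matrix_mixup(a, b, lam)
    theta = theta_sampler.draw()
    rotated = rotate_colour_space(mix.image, axis, theta)
    return AugmentedSample(
        image=rotated,
        label_set=mix.label_set,
        provenance={
            "operator": f"NLmixup{axis}",
            "parents": (a.sample_id, b.sample_id),
            "theta": theta,
            "lambda_seed": int(seed),
        },
    )
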