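"""Thermal-signature extraction by contour peeling and DCT parameterization.

The thermal signature of a blob is the sequence of mean temperatures over
successively peeled contours. The blob mask is first dilated once with the
4-connected cross to sample one ring just outside the object (iteration
``i = -1``, carrying the edge step relative to the immediate background);
then the 4-connected perimeter is repeatedly recorded and removed until the
mask is exhausted (iterations ``i = 0 ... M``). Warm-blooded animals show a
steep temperature rise over the first interior contours — heat escaping past
the insulating coat at the body outline — whereas sun-heated or artificial
hot objects are flat or rise gradually. The signature is invariant to
translation and right-angle rotation by construction, and after subtracting
the outer-ring mean it is also invariant to the scene's absolute
temperature.

The signature length depends on object size, so for classification it is
parameterized by a fixed number of DCT coefficients. The transform used here
is the orthonormal type-II DCT additionally divided by sqrt(N), so a
constant signal of any length maps to the same coefficient vector — the
length invariance that motivates the cosine parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft, ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .detection import Blob
from .io import ThermalFrame

__all__ = [
    "ThermalSignature",
    "FeatureVector",
    "outer_contour",
    "perimeter_contour",
    "extract_signature",
    "normalize_signature",
    "dct_parameterize",
    "reconstruct_signature",
    "energy_fraction",
    "SignatureDCT",
    "blob_features",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ThermalSignature:
    """Contour-mean sequence ``cm(i)`` for ``i = -1, 0, ..., M``.

    ``samples[0]`` is the outer-ring mean (i = -1); ``samples[1:]`` are the
    interior contour means. ``contour_sizes`` holds the pixel count of each
    contour in the same order. ``border_clipped`` flags blobs touching the
    frame border, where the outer ring is incomplete.
    """

    samples: np.ndarray
    contour_sizes: np.ndarray
    border_clipped: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.contour_sizes = np.asarray(self.contour_sizes, dtype=int)
        if self.samples.size < 2:
            raise ValueError("a signature needs the outer ring and >= 1 contour")
        if self.samples.size != self.contour_sizes.size:
            raise ValueError("samples and contour_sizes lengths differ")

    @property
    def M(self) -> int:
        """Index of the last interior contour."""
        return int(self.samples.size) - 2


@dataclass
class FeatureVector:
    """Truncated DCT coefficients of a normalized signature."""

    coefficients: np.ndarray
    source_length: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    @property
    def n_coeff(self) -> int:
        return int(self.coefficients.size)


def outer_contour(blob_mask: np.ndarray) -> np.ndarray:
    """One ring just outside the mask: cross dilation minus the mask.

    The ring is clipped at the frame border; callers detect that case via
    the mask touching the border.
    """
    if not blob_mask.any():
        raise ValueError("empty mask")
    return ndimage.binary_dilation(blob_mask, structure=_CROSS) & ~blob_mask


def perimeter_contour(blob_mask: np.ndarray) -> np.ndarray:
    """Pixels of the mask with at least one axial neighbor outside it.

    Equals the mask minus its erosion by the 4-connected cross; out-of-frame
    pixels count as outside, so a mask touching the border still has a
    perimeter there.
    """
    if not blob_mask.any():
        raise ValueError("empty mask")
    return blob_mask & ~ndimage.binary_erosion(
        blob_mask, structure=_CROSS, border_value=0
    )


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def extract_signature(frame: ThermalFrame, blob: Blob) -> ThermalSignature:
    """Peel a blob down to nothing, recording each contour's mean temperature.

    Contours are peeled from the blob mask only; temperatures are always
    read from the unmodified frame. A blob on the frame border gets a
    clipped (possibly empty) outer ring; an empty ring falls back to the
    first interior mean and the signature is flagged.
    """
    values = frame.values
    mask = blob.mask(values.shape)
    clipped = _touches_border(mask)

    ring = outer_contour(mask)
    samples: list[float] = []
    sizes: list[int] = []
    if ring.any():
        samples.append(float(values[ring].mean()))
        sizes.append(int(ring.sum()))
    else:
        samples.append(np.nan)  # patched with cm(0) below
        sizes.append(0)
        clipped = True

    work = mask.copy()
    while work.any():
        contour = perimeter_contour(work)
        samples.append(float(values[contour].mean()))
        sizes.append(int(contour.sum()))
        work &= ~contour
    if np.isnan(samples[0]):
        samples[0] = samples[1]
    return ThermalSignature(
        samples=np.array(samples),
        contour_sizes=np.array(sizes),
        border_clipped=clipped,
    )


def normalize_signature(
    sig: ThermalSignature, baseline: str = "outer"
) -> np.ndarray:
    """Subtract the first-contour mean, removing absolute temperature.

    ``baseline='outer'`` (default) subtracts the i = -1 outer-ring mean, so
    features are relative to the immediate background; ``'interior'``
    subtracts the i = 0 perimeter mean instead.
    """
    if baseline == "outer":
        ref = sig.samples[0]
    elif baseline == "interior":
        ref = sig.samples[1]
    else:
        raise ValueError("baseline must be 'outer' or 'interior'")
    return sig.samples - ref


def _dct_matrix_free(x: np.ndarray) -> np.ndarray:
    n = x.size
    return fft.dct(x, type=2, norm="ortho") / np.sqrt(n)


def dct_parameterize(
    normalized: np.ndarray, n_coeff: int = 7, label: str | None = None
) -> FeatureVector:
    """Length-invariant DCT coefficients of a normalized signature.

    Orthonormal type-II DCT divided by sqrt(N): coefficient 0 equals the
    sequence mean for any length. The first ``n_coeff`` coefficients are
    kept, zero-padded when the signature is shorter.
    """
    x = np.asarray(normalized, dtype=float)
    if x.size < 1:
        raise ValueError("empty sequence")
    coeffs = _dct_matrix_free(x)
    out = np.zeros(n_coeff)
    m = min(n_coeff, coeffs.size)
    out[:m] = coeffs[:m]
    return FeatureVector(coefficients=out, source_length=x.size, label=label)


def reconstruct_signature(fv: FeatureVector, length: int) -> np.ndarray:
    """Inverse transform of the truncated coefficients at the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    c = np.zeros(length)
    m = min(fv.n_coeff, length)
    c[:m] = fv.coefficients[:m]
    return fft.idct(c * np.sqrt(length), type=2, norm="ortho")


def energy_fraction(normalized: np.ndarray, n_coeff: int) -> float:
    """Fraction of signature energy carried by the first coefficients.

    Retained squared-coefficient mass over total mass under the orthonormal
    convention; an all-zero sequence has nothing to explain and returns 1.
    """
    x = np.asarray(normalized, dtype=float)
    coeffs = fft.dct(x, type=2, norm="ortho")
    total = float(np.sum(coeffs**2))
    if total == 0.0:
        return 1.0
    return float(np.sum(coeffs[:n_coeff] ** 2)) / total


class SignatureDCT(TransformerMixin, BaseEstimator):
    """Transformer mapping signatures to fixed-length DCT feature rows.

    Accepts a list of :class:`ThermalSignature` or of 1-D normalized sample
    sequences and returns an ``(n_samples, n_coeff)`` array. Stateless;
    ``fit`` only validates parameters.
    """

    def __init__(self, n_coeff: int = 7, baseline: str = "outer"):
        self.n_coeff = n_coeff
        self.baseline = baseline

    def fit(self, X, y=None):
        if self.n_coeff < 1:
            raise ValueError("n_coeff must be >= 1")
        self.n_features_in_ = self.n_coeff
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        rows = []
        for item in X:
            if isinstance(item, ThermalSignature):
                seq = normalize_signature(item, baseline=self.baseline)
            else:
                seq = np.asarray(item, dtype=float)
            rows.append(dct_parameterize(seq, self.n_coeff).coefficients)
        return np.vstack(rows) if rows else np.empty((0, self.n_coeff))


def blob_features(
    frame: ThermalFrame,
    blob: Blob,
    n_coeff: int = 7,
    baseline: str = "outer",
    label: str | None = None,
) -> FeatureVector:
    """Full per-blob feature pipeline: peel, normalize, DCT-parameterize."""
    sig = extract_signature(frame, blob)
    return dct_parameterize(
        normalize_signature(sig, baseline=baseline), n_coeff=n_coeff, label=label
    )
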