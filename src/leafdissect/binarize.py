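"""Color scan → single-component binary foreground mask.

The segmentation works in HSV space: a 2-means clustering of the
(saturation, value) pairs seeds a 2-component full-covariance Gaussian
mixture whose covariances start as identity matrices scaled by the
standard deviation of the whole SV data set.  Pixels are assigned to
their maximum-posterior component; the component with the higher mean
saturation is taken as foreground (scanner backgrounds are near-white,
i.e. unsaturated), and only the largest 8-connected foreground
component survives.  Interior speckle holes below a small area
threshold are filled so they cannot corrupt the distance transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.color import rgb2hsv
from skimage.measure import label
from skimage.morphology import remove_small_holes
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .errors import InputImageError, NoForegroundError

log = logging.getLogger(__name__)

__all__ = ["LeafImage", "load_and_rescale", "binarize", "largest_component"]

#: smallest post-rescale side length we accept
MIN_SIDE = 32


@dataclass
class LeafImage:
    """An RGB scan after load-time rescaling."""

    pixels: np.ndarray  # (H, W, 3) uint8
    dpi: float | None = None
    scale_factor: float = 0.25

    @property
    def effective_dpi(self) -> float | None:
        """Scanner dpi corrected for the load-time rescale."""
        return None if self.dpi is None else self.dpi * self.scale_factor


def load_and_rescale(path, scale_factor: float = 0.25, dpi: float | None = None) -> LeafImage:
    """Load an RGB image and rescale it by ``scale_factor`` (bicubic).

    Scans are rescaled (default to 25%) before any processing; bicubic
    interpolation preserves the outline well at this scale.
    """
    if not (0 < scale_factor <= 1):
        raise InputImageError(f"scale_factor must be in (0, 1], got {scale_factor}")
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            w, h = im.size
            nw, nh = round(w * scale_factor), round(h * scale_factor)
            if scale_factor != 1.0:
                im = im.resize((nw, nh), Image.BICUBIC)
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, ValueError) as exc:
        raise InputImageError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise InputImageError(
            f"image {path!r} is {arr.shape[1]}x{arr.shape[0]} after rescaling; "
            f"need at least {MIN_SIDE}x{MIN_SIDE}"
        )
    return LeafImage(pixels=arr, dpi=dpi, scale_factor=scale_factor)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        raise NoForegroundError("mask has no foreground component")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def binarize(
    image: LeafImage | np.ndarray,
    *,
    random_state: int = 0,
    hole_area: int = 25,
    foreground: str = "saturated",
    max_iter: int = 200,
    tol: float = 1e-4,
) -> np.ndarray:
    """Segment a leaf scan into a single-component boolean mask.

    Parameters
    ----------
    image
        ``LeafImage`` or raw ``(H, W, 3)`` uint8 array.
    random_state
        Seed for the 2-means initialization and the EM fit; fixed by
        default so masks are bit-reproducible.
    hole_area
        Interior background holes smaller than this many pixels are
        filled (scan speckle).
    foreground : {"saturated", "dark"}
        Which mixture component is the leaf: the higher-mean-saturation
        one (default, for light scanner backgrounds) or the
        lower-mean-value one.

    Raises
    ------
    NoForegroundError
        If the two components show no saturation/value contrast (e.g. a
        blank scan) or the foreground comes out empty.
    """
    pixels = image.pixels if isinstance(image, LeafImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise InputImageError("binarize expects an (H, W, 3) RGB array")
    hsv = rgb2hsv(pixels)
    sv = hsv[:, :, 1:3].reshape(-1, 2)

    km = KMeans(n_clusters=2, n_init=4, random_state=random_state)
    km_labels = km.fit_predict(sv)

    scale = float(sv.std())
    if scale <= 1e-12:
        raise NoForegroundError("image has no saturation/value contrast")
    prec = np.stack([np.eye(2) / scale**2] * 2)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=km.cluster_centers_,
        precisions_init=prec,
        max_iter=max_iter,
        tol=tol,
        reg_covar=1e-8,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # EM convergence warning handled below
        gm.fit(sv)
    if gm.converged_:
        labels = gm.predict(sv)
        means = gm.means_
    else:
        log.warning("Gaussian mixture did not converge; falling back to 2-means labels")
        labels = km_labels
        means = km.cluster_centers_

    if foreground == "saturated":
        crit = means[:, 0]  # mean saturation
        if abs(crit[0] - crit[1]) < 1e-2:
            raise NoForegroundError(
                "mixture components have indistinguishable saturation; "
                "no leaf foreground detected"
            )
        fg = int(np.argmax(crit))
    elif foreground == "dark":
        fg = int(np.argmin(means[:, 1]))  # mean value
    else:
        raise ValueError(f"unknown foreground rule {foreground!r}")

    mask = (labels == fg).reshape(pixels.shape[:2])
    if not mask.any():
        raise NoForegroundError("foreground component is empty")
    mask = largest_component(mask)
    if hole_area > 0:
        try:
            mask = remove_small_holes(mask, max_size=hole_area - 1)
        except TypeError:  # older scikit-image
            mask = remove_small_holes(mask, area_threshold=hole_area)
    return mask
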