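"""Raw image stack -> aligned, background-subtracted, binarized marker masks.

Each imaging cycle yields one grayscale image per marker (plus, optionally, a
post-photobleach image of the same field used for background subtraction).
Small stage drifts between cycles are corrected by integer-pixel translation so
that a given pixel addresses the same physical spot in every marker image; the
corrected images are background-subtracted, thresholded into presence/absence
masks, and a fixed margin band around the image border is excluded from all
downstream counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

from .panel import MarkerPanel

DEFAULT_MARGIN = 15
#: physical pixel footprint of the reference optical setup, nm
PIXEL_SIZE_NM = (117, 117)


@dataclass
class BinaryStack:
    """Aligned binary presence masks, one per panel marker.

    Attributes
    ----------
    masks
        Boolean array of shape ``(n_markers, H, W)``; ``masks[i]`` is marker
        ``i``'s presence mask.
    panel
        The marker panel the layers refer to.
    margin
        Width in pixels of the border band that was zeroed and must stay
        excluded from analysis.
    provenance
        Free-form record of how the stack was produced (shifts, thresholds...).
    """

    masks: np.ndarray
    panel: MarkerPanel
    margin: int = DEFAULT_MARGIN
    pixel_size_nm: tuple[float, float] = PIXEL_SIZE_NM
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (n_markers, H, W)")
        if self.masks.shape[0] != len(self.panel):
            raise ValueError(
                f"{self.masks.shape[0]} mask layers for a {len(self.panel)}-marker panel"
            )
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks.shape[1:]

    def interior(self) -> np.ndarray:
        """Boolean (H, W) mask of pixels outside the excluded margin band."""
        h, w = self.shape
        keep = np.zeros((h, w), dtype=bool)
        m = self.margin
        if h > 2 * m and w > 2 * m:
            keep[m : h - m, m : w - m] = True
        return keep


def _sliding_sums(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross-correlation surface S(d) = sum_x a(x) b(x - d) for all d, via FFT."""
    return fftconvolve(a, b[::-1, ::-1], mode="full")


def ncc_surface(moving: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of ``moving`` against ``reference``.

    Entry ``[dy + H - 1, dx + W - 1]`` is the Pearson correlation between the
    overlapping regions of ``reference`` and ``moving`` displaced by
    ``(dy, dx)``.  Displacements with a degenerate (constant) overlap get -inf.
    """
    a = np.asarray(moving, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    ones_a = np.ones_like(a)
    ones_b = np.ones_like(b)
    n = _sliding_sums(ones_a, ones_b)
    s_ab = _sliding_sums(a, b)
    s_a = _sliding_sums(a, ones_b)
    s_b = _sliding_sums(ones_a, b)
    s_aa = _sliding_sums(a * a, ones_b)
    s_bb = _sliding_sums(ones_a, b * b)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ab - s_a * s_b / n
        var_a = s_aa - s_a**2 / n
        var_b = s_bb - s_b**2 / n
        ncc = cov / np.sqrt(var_a * var_b)
    # round-off can push tiny variances negative; those overlaps are degenerate
    bad = ~np.isfinite(ncc)
    ncc[bad] = -np.inf
    return ncc


def register_shift(
    moving: np.ndarray,
    reference: np.ndarray,
    max_shift: int = 15,
) -> tuple[int, int]:
    """Integer translation (dy, dx) that best aligns ``moving`` onto ``reference``.

    The returned offset is the displacement of ``moving``'s content relative to
    ``reference`` — the argmax of normalized cross-correlation over
    ``|dy|, |dx| <= max_shift``.  Applying the *negated* offset to ``moving``
    (see :func:`apply_shift`) brings it into register.

    Raises
    ------
    ValueError
        If either image is flat (zero variance), where correlation is undefined,
        or the images differ in shape, or ``max_shift`` is too large.
    """
    moving = np.asarray(moving)
    reference = np.asarray(reference)
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share dimensions")
    if max_shift >= min(moving.shape) / 4:
        raise ValueError("max_shift must be < min(dims)/4")
    if np.ptp(moving) == 0 or np.ptp(reference) == 0:
        raise ValueError("cannot register a flat (zero-variance) image")
    surf = ncc_surface(moving, reference)
    h, w = moving.shape
    cy, cx = h - 1, w - 1
    window = surf[cy - max_shift : cy + max_shift + 1, cx - max_shift : cx + max_shift + 1]
    flat_idx = int(np.argmax(window))
    dy, dx = np.unravel_index(flat_idx, window.shape)
    return int(dy) - max_shift, int(dx) - max_shift


def apply_shift(image: np.ndarray, shift: tuple[int, int], fill=0) -> np.ndarray:
    """Translate an image by integer ``(dy, dx)``, filling exposed pixels."""
    dy, dx = shift
    out = np.full_like(image, fill)
    h, w = image.shape
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = image[src_y, src_x]
    return out


def subtract_background(image: np.ndarray, bleach_image: np.ndarray) -> np.ndarray:
    """Pixelwise ``image - bleach_image`` clipped at zero.

    The bleach image is the same field re-imaged after photobleaching; whatever
    signal survives bleaching is background and is removed before thresholding.
    """
    image = np.asarray(image)
    bleach_image = np.asarray(bleach_image)
    if image.shape != bleach_image.shape:
        raise ValueError("image and bleach image must share dimensions")
    diff = image.astype(np.int64) - bleach_image.astype(np.int64)
    return np.clip(diff, 0, None).astype(image.dtype)


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Presence mask: pixel >= threshold -> True (inclusive comparison)."""
    return np.asarray(image) >= threshold


def zero_margin(mask: np.ndarray, margin: int) -> np.ndarray:
    """Zero a ``margin``-pixel band around the image border."""
    out = np.array(mask, copy=True)
    if margin > 0:
        out[:margin, :] = 0
        out[-margin:, :] = 0
        out[:, :margin] = 0
        out[:, -margin:] = 0
    return out


def auto_thresholds(stack: np.ndarray) -> list[float]:
    """Otsu threshold per marker image, a stand-in for manual thresholding."""
    return [float(threshold_otsu(np.asarray(img))) for img in stack]


def prepare_stack(
    raw_stack: np.ndarray,
    panel: MarkerPanel,
    thresholds: Sequence[float] | None = None,
    bleach_stack: np.ndarray | None = None,
    margin: int = DEFAULT_MARGIN,
    max_shift: int = 15,
    reference_marker: int = 0,
    register: bool = True,
) -> BinaryStack:
    """Full preprocessing chain: register -> subtract background -> binarize.

    Each marker image is registered to marker ``reference_marker``'s raw image
    (integer pixels only), its bleach image — when given — is shifted by the
    same correction and subtracted, the result is thresholded (manual values, or
    per-marker Otsu when ``thresholds`` is None), and the border margin is
    zeroed.  Applied shifts and thresholds are recorded in provenance.

    Cross-channel registration keys on structure shared between channels (cell
    bodies, autofluorescence texture); pass ``register=False`` for input that
    is already aligned but carries no such shared structure (e.g. re-processing
    binarized masks), where a correlation estimate would be meaningless.
    """
    raw_stack = np.asarray(raw_stack)
    if raw_stack.ndim != 3 or raw_stack.shape[0] != len(panel):
        raise ValueError(f"expected {len(panel)} marker images")
    auto = thresholds is None
    if auto:
        thresholds = auto_thresholds(
            raw_stack
            if bleach_stack is None
            else [subtract_background(raw_stack[i], bleach_stack[i]) for i in range(len(panel))]
        )
    if len(thresholds) != len(panel):
        raise ValueError("one threshold per marker required")

    reference = raw_stack[reference_marker]
    masks = np.empty(raw_stack.shape, dtype=bool)
    shifts: list[tuple[int, int]] = []
    for i in range(len(panel)):
        try:
            if i == reference_marker or not register:
                dy, dx = 0, 0
            else:
                dy, dx = register_shift(raw_stack[i], reference, max_shift=max_shift)
            aligned = apply_shift(raw_stack[i], (-dy, -dx))
            if bleach_stack is not None:
                aligned_bleach = apply_shift(np.asarray(bleach_stack[i]), (-dy, -dx))
                aligned = subtract_background(aligned, aligned_bleach)
            masks[i] = zero_margin(binarize(aligned, thresholds[i]), margin)
            shifts.append((dy, dx))
        except Exception as err:
            raise type(err)(f"marker {i} ({panel.names[i]}): {err}") from err
    return BinaryStack(
        masks=masks,
        panel=panel,
        margin=margin,
        provenance={
            "shifts": shifts,
            "thresholds": [float(t) for t in thresholds],
            "threshold_mode": "otsu-auto" if auto else "manual",
            "margin": margin,
            "max_shift": max_shift,
            "reference_marker": reference_marker,
        },
    )
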