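"""Adaptive-threshold ROI detection for lensless sensor video.

The six-step algorithm: (1) each post-stimulation %dF/F0 frame is locally
binarized against its Gaussian-weighted neighborhood mean (kernel 9, sigma
1.5); (2) each binary frame is cleaned by binary opening (2x2 square) then
area opening (min area 15, 4-connected); (3) the binary frames are averaged
into an occupancy image in [0, 1]; (4) the occupancy image is binarized again
(kernel 9, sigma 2.5); (5) cleaned again (3x3 square, area 15); (6) the
8-connected components ("forms") of the result are the ROIs.  A whole-frame
pseudo-ROI "w" accompanies every ROI set.

The threshold is relative to the local mean, so the detected masks are
invariant to affine rescaling of the input intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from calmdx.errors import DimensionError, ValidationError
from calmdx.preprocess import DffVideo


@dataclass(frozen=True)
class BinarizeParams:
    """Local Gaussian binarization: window side `kernel` (odd), weight scale
    `sigma`, additive `offset` on the threshold."""

    kernel: int = 9
    sigma: float = 1.5
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValidationError(f"kernel must be odd and positive, got {self.kernel}")
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0")


@dataclass(frozen=True)
class CleanParams:
    """Morphological cleaning: opening with a footprint x footprint square,
    then removal of 4-connected components of area < min_area."""

    footprint: int = 2
    min_area: int = 15

    def __post_init__(self) -> None:
        if self.footprint < 1 or self.min_area < 1:
            raise ValidationError("footprint and min_area must be >= 1")


FRAME_BINARIZE = BinarizeParams(kernel=9, sigma=1.5)
FRAME_CLEAN = CleanParams(footprint=2, min_area=15)
AVG_BINARIZE = BinarizeParams(kernel=9, sigma=2.5)
AVG_CLEAN = CleanParams(footprint=3, min_area=15)


@dataclass
class Roi:
    roi_id: int
    pixels: np.ndarray  # (N, 2) row/col indices
    centroid: tuple[float, float]
    area: int


@dataclass
class RoiSet:
    """Labeled ROI masks; label_image uses 0 = background, k = ROI k."""

    label_image: np.ndarray
    rois: list[Roi] = field(default_factory=list)
    includes_whole_frame: bool = True

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.label_image == roi_id

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": [r.roi_id for r in self.rois],
                "area": [r.area for r in self.rois],
                "centroid_row": [r.centroid[0] for r in self.rois],
                "centroid_col": [r.centroid[1] for r in self.rois],
            }
        )


def export_label_image(roiset: "RoiSet", path) -> None:
    """Write the ROI label image as 16-bit TIFF (0 = background)."""
    import tifffile

    tifffile.imwrite(str(path), roiset.label_image.astype(np.uint16),
                     photometric="minisblack")


def local_gaussian_binarize(image: np.ndarray, params: BinarizeParams = FRAME_BINARIZE) -> np.ndarray:
    """Foreground where value strictly exceeds the Gaussian-weighted local mean.

    Weights are a normalized Gaussian truncated to an exact kernel x kernel
    window; borders are reflect-padded (edge pixel duplicated).  A 3-D input
    is binarized frame by frame (no smoothing across time).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim not in (2, 3):
        raise DimensionError(f"expected 2-D image or 3-D stack, got ndim={image.ndim}")
    radius = params.kernel // 2
    if params.kernel > min(image.shape[-2:]):
        raise ValidationError(
            f"kernel {params.kernel} larger than image side {min(image.shape[-2:])}"
        )
    if image.ndim == 2:
        local_mean = ndi.gaussian_filter(
            image, sigma=(params.sigma, params.sigma), mode="reflect",
            radius=(radius, radius))
        return image > local_mean + params.offset
    # frame stacks: chunked so the float64 working set stays cache-friendly
    out = np.empty(image.shape, dtype=bool)
    step = 2000
    for a in range(0, image.shape[0], step):
        b = min(a + step, image.shape[0])
        local_mean = ndi.gaussian_filter(
            image[a:b], sigma=(0.0, params.sigma, params.sigma),
            mode="reflect", radius=(0, radius, radius))
        out[a:b] = image[a:b] > local_mean + params.offset
    return out


def binary_opening_square(mask: np.ndarray, footprint: int) -> np.ndarray:
    """Binary opening with a footprint x footprint square structuring element.

    Computed anchor-free as the union of all square translates fully contained
    in the mask (pixels outside the image are background), which is
    well-defined for even footprints where center conventions differ between
    libraries.  A 3-D stack is opened frame by frame.
    """
    mask = np.asarray(mask, dtype=bool)
    f = int(footprint)
    if f == 1:
        return mask.copy()
    squeeze = mask.ndim == 2
    stack = mask[None] if squeeze else mask
    T, H, W = stack.shape
    # erosion over top-left anchors: ero[t, y, x] = all(stack[t, y:y+f, x:x+f])
    padded = np.zeros((T, H + f - 1, W + f - 1), dtype=bool)
    padded[:, :H, :W] = stack
    ero = np.ones((T, H, W), dtype=bool)
    for dy in range(f):
        for dx in range(f):
            ero &= padded[:, dy:dy + H, dx:dx + W]
    # dilation back: out[t, y+dy, x+dx] |= ero[t, y, x]
    acc = np.zeros((T, H + f - 1, W + f - 1), dtype=bool)
    for dy in range(f):
        for dx in range(f):
            acc[:, dy:dy + H, dx:dx + W] |= ero
    out = acc[:, :H, :W]
    return out[0] if squeeze else out


_CROSS_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def area_open(mask: np.ndarray, min_area: int, connectivity: int = 1) -> np.ndarray:
    """Remove connected foreground components of area < min_area.

    connectivity 1 = 4-connected (default), 2 = 8-connected.  Frames of a 3-D
    stack are treated independently (no temporal connectivity).
    """
    mask = np.asarray(mask, dtype=bool)
    s2d = _CROSS_2D if connectivity == 1 else np.ones((3, 3), bool)
    if mask.ndim == 2:
        labels, _ = ndi.label(mask, structure=s2d)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_area
        keep[0] = False
        return keep[labels]
    # stacks: frame-by-frame 2-D labeling is much cheaper than one 3-D pass
    out = np.zeros_like(mask)
    for i in range(mask.shape[0]):
        labels, n = ndi.label(mask[i], structure=s2d)
        if n:
            counts = np.bincount(labels.ravel())
            keep = counts >= min_area
            keep[0] = False
            out[i] = keep[labels]
    return out


def clean_mask(mask: np.ndarray, params: CleanParams = FRAME_CLEAN) -> np.ndarray:
    """Binary opening (square footprint) then 4-connected area opening."""
    return area_open(binary_opening_square(mask, params.footprint), params.min_area)


def detect_rois(
    dff_video: DffVideo,
    frame_params: BinarizeParams = FRAME_BINARIZE,
    frame_clean: CleanParams = FRAME_CLEAN,
    avg_params: BinarizeParams = AVG_BINARIZE,
    avg_clean: CleanParams = AVG_CLEAN,
    label_connectivity: int = 2,
) -> RoiSet:
    """Run the six-step adaptive-binarization ROI algorithm on the
    post-stimulation %dF/F0 frames and label the resulting forms.

    Accepts either a DffVideo (frames with time >= 0 are selected) or a bare
    T x H x W array already restricted to post-stimulation frames.
    """
    if isinstance(dff_video, DffVideo):
        post = dff_video.frames[dff_video.time_s >= 0]
    else:
        post = np.asarray(dff_video, dtype=np.float64)
    if post.ndim != 3:
        raise DimensionError("expected a T x H x W stack")
    if post.shape[0] == 0:
        raise ValidationError("no post-stimulation frames")

    binarized = local_gaussian_binarize(post, frame_params)
    cleaned = clean_mask(binarized, frame_clean)
    occupancy = cleaned.mean(axis=0)
    avg_bin = local_gaussian_binarize(occupancy, avg_params)
    final = clean_mask(avg_bin, avg_clean)

    label_image = measure.label(final, connectivity=label_connectivity)
    rois = []
    for region in measure.regionprops(label_image):
        rois.append(
            Roi(
                roi_id=int(region.label),
                pixels=np.asarray(region.coords),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                area=int(region.area),
            )
        )
    return RoiSet(label_image=label_image, rois=rois, includes_whole_frame=True)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def evaluate_rois(roiset: RoiSet, truth_masks: list[np.ndarray]) -> pd.DataFrame:
    """Greedy one-to-one matching of detected ROIs to planted blobs by
    descending Jaccard; unmatched blobs appear as misses (jaccard 0, no roi).
    """
    for m in truth_masks:
        if np.asarray(m).shape != roiset.label_image.shape:
            raise DimensionError("truth mask geometry differs from label image")
    pairs = []
    for bi, tm in enumerate(truth_masks):
        for roi in roiset.rois:
            pairs.append((jaccard(roiset.mask(roi.roi_id), tm), bi, roi.roi_id))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    matched_blob: dict[int, tuple[int, float]] = {}
    used_rois: set[int] = set()
    for j, bi, rid in pairs:
        if j <= 0 or bi in matched_blob or rid in used_rois:
            continue
        matched_blob[bi] = (rid, j)
        used_rois.add(rid)
    rows = []
    for bi in range(len(truth_masks)):
        rid, j = matched_blob.get(bi, (None, 0.0))
        rows.append({"blob_id": bi, "roi_id": rid, "jaccard": j, "hit": rid is not None})
    return pd.DataFrame(rows)
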