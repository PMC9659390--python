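"""Cell, DNA-object and nucleolus segmentation from three-channel micrographs.

The chain mirrors a high-content screening workflow for procyclic
trypanosomes:

1. flat-field correction by subtracting the per-pixel median over all
   images of an acquisition session;
2. cell bodies from phase contrast: a cascade of Gaussian unsharp filters
   of increasing radius, a threshold at (mean - 1 s.d.) of the processed
   image, hole filling, and filters on object area (2000-7000 px^2 at
   0.103 um/px), minimum darkness (at least 2 s.d. under the mean) and
   border contact;
3. DNA-containing objects (nuclei and kinetoplasts) from the Hoechst
   channel: 1 px Gaussian blur, rolling-ball background subtraction, local
   maxima of prominence above 1.5x the image s.d., each grown to the
   connected region above 0.4x its peak;
4. kinetoplast/nucleus class assignment from object counts per cell: the
   kinetoplast divides first, so 2, 3 and 4 objects correspond to 1K1N,
   2K1N and 2K2N, with the largest object(s) taken as nuclei;
5. nucleus geometry: r = average of the full major and minor axes of the
   moments-fitted ellipse; the nucleolus is the darkest DNA-channel point
   at least r/8 from the nucleus edge, modelled as a disc of radius r/4.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import gaussian
from skimage.morphology import h_maxima
from skimage.restoration import rolling_ball

from .micrograph import Micrograph


@dataclass
class SegmentationParams:
    """Phase-contrast cell segmentation parameters.

    The unsharp radius ladder runs from 1 px upward in 5 px steps; the
    processed image supplies both the detection threshold (mean minus
    ``cell_threshold_sd`` s.d.) and the minimum-darkness filter (minimum
    object value at least ``cell_min_depth_sd`` s.d. under the mean).
    """

    unsharp_radii_px: Sequence[float] = (1, 6, 11, 16, 21, 26, 31)
    unsharp_weight: float = 0.4
    cell_threshold_sd: float = 1.0
    cell_area_px2: Tuple[float, float] = (2000.0, 7000.0)
    cell_min_depth_sd: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.unsharp_weight < 1.0):
            raise ValueError("unsharp_weight must be in (0, 1)")
        radii = list(self.unsharp_radii_px)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("unsharp radii must be strictly increasing")
        lo, hi = self.cell_area_px2
        if lo > hi:
            raise ValueError("empty cell area range")


@dataclass
class DnaDetectionParams:
    """DNA-channel object detection parameters."""

    blur_radius_px: float = 1.0
    ball_radius_px: float = 15.0
    prominence_sd: float = 1.5
    rel_threshold: float = 0.4

    def __post_init__(self) -> None:
        if min(self.blur_radius_px, self.ball_radius_px,
               self.prominence_sd) <= 0:
            raise ValueError("parameters must be > 0")
        if not (0.0 < self.rel_threshold < 1.0):
            raise ValueError("rel_threshold must be in (0, 1)")


@dataclass
class DnaObject:
    """One detected DNA-containing structure (nucleus or kinetoplast)."""

    label: int
    mask: np.ndarray
    area_px2: int
    centroid: Tuple[float, float]
    total_intensity: float
    peak: Tuple[int, int]
    klass: str = "unassigned"  # set by assign_kn: "K" or "N"
    ellipse_axes_px: Optional[Tuple[float, float]] = None


@dataclass
class NucleusGeometry:
    """Fitted nucleus radius and the derived nucleolus model.

    r is the average of the full major and minor ellipse axes. The
    nucleolar centre must sit at least r/8 from the nucleus edge and the
    nucleolus is modelled as a disc of radius r/4 about it.
    """

    r_px: float
    nucleolus_centre: Optional[Tuple[int, int]] = None

    @property
    def edge_margin_px(self) -> float:
        return self.r_px / 8.0

    @property
    def nucleolus_radius_px(self) -> float:
        return self.r_px / 4.0


def flat_field_correct(images: Sequence[np.ndarray]) -> List[np.ndarray]:
    """Subtract the per-pixel median of a session's images from each image.

    Negative values are preserved (no clipping); downstream thresholds are
    relative to image statistics, so an offset-free zero point is not
    required.
    """
    if len(images) == 0:
        raise ValueError("need at least one image per session")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"session images differ in shape: {shapes}")
    stack = np.stack([np.asarray(im, dtype=float) for im in images])
    med = np.median(stack, axis=0)
    return [im - med for im in stack]


def flat_field_correct_micrographs(session: Sequence[Micrograph]
                                   ) -> List[Micrograph]:
    """Flat-field correct every channel of one session's micrographs."""
    if not session:
        raise ValueError("need at least one micrograph per session")
    names = session[0].channels.keys()
    corrected = {
        name: flat_field_correct([m[name] for m in session]) for name in names
    }
    return [
        Micrograph(channels={name: corrected[name][i] for name in names},
                   pixel_size_um=m.pixel_size_um)
        for i, m in enumerate(session)
    ]


def unsharp_cascade(image: np.ndarray,
                    params: SegmentationParams) -> np.ndarray:
    """Sequential Gaussian unsharp sharpening.

    Each pass applies I <- (I - w G_sigma(I)) / (1 - w) with sigma equal to
    the stated radius, in increasing-radius order.
    """
    img = np.asarray(image, dtype=float)
    w = params.unsharp_weight
    for radius in params.unsharp_radii_px:
        img = (img - w * gaussian(img, sigma=radius,
                                  preserve_range=True)) / (1.0 - w)
    return img


def segment_cells(phase: np.ndarray,
                  params: Optional[SegmentationParams] = None
                  ) -> List[np.ndarray]:
    """Detect cell bodies in a phase-contrast image.

    Returns one boolean mask per retained cell. Objects are dark regions of
    the unsharp-processed image (below mean - 1 s.d.), hole-filled,
    8-connected, within the area range, at least ``cell_min_depth_sd`` s.d.
    under the mean at their darkest processed pixel, and not touching the
    image border. A constant image yields no cells.
    """
    params = params or SegmentationParams()
    proc = unsharp_cascade(phase, params)
    mu = proc.mean()
    sd = proc.std()
    binary = proc < mu - params.cell_threshold_sd * sd
    binary = ndi.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    lo, hi = params.cell_area_px2
    depth_cut = mu - params.cell_min_depth_sd * sd
    masks = []
    border = np.zeros_like(binary)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for region in measure.regionprops(labels):
        if not (lo <= region.area <= hi):
            continue
        mask = labels == region.label
        if proc[mask].min() > depth_cut:
            continue
        if (mask & border).any():
            continue
        masks.append(mask)
    return masks


def preprocess_dna(dna: np.ndarray,
                   params: Optional[DnaDetectionParams] = None) -> np.ndarray:
    """Gaussian blur then rolling-ball background subtraction."""
    params = params or DnaDetectionParams()
    blurred = gaussian(np.asarray(dna, dtype=float),
                       sigma=params.blur_radius_px, preserve_range=True)
    background = rolling_ball(blurred, radius=params.ball_radius_px)
    return blurred - background


def detect_dna_objects(dna: np.ndarray,
                       params: Optional[DnaDetectionParams] = None,
                       preprocessed: Optional[np.ndarray] = None
                       ) -> List[DnaObject]:
    """Detect DNA-containing objects in a Hoechst-channel image.

    Local maxima with prominence above ``prominence_sd`` times the image
    s.d. of the preprocessed channel seed objects; each object is the
    connected region above ``rel_threshold`` times its seed's peak value.
    Pixels claimed by several seeds go to the nearest seed. An image with
    no qualifying maxima (e.g. a constant image) yields an empty list.
    """
    params = params or DnaDetectionParams()
    proc = preprocess_dna(dna, params) if preprocessed is None else preprocessed
    sd = proc.std()
    if sd == 0:
        return []
    peaks = h_maxima(proc, params.prominence_sd * sd)
    seed_labels = measure.label(peaks, connectivity=2)
    n_seeds = seed_labels.max()
    if n_seeds == 0:
        return []

    claims = np.zeros(proc.shape, dtype=np.int32)
    contested = np.zeros(proc.shape, dtype=bool)
    seed_info = []
    for s in range(1, n_seeds + 1):
        seed_mask = seed_labels == s
        peak_val = proc[seed_mask].max()
        rr, cc = np.nonzero(seed_mask)
        seed_pt = (float(rr.mean()), float(cc.mean()))
        above = measure.label(proc >= params.rel_threshold * peak_val,
                              connectivity=2)
        comp = above[rr[0], cc[0]]
        mask = above == comp
        contested |= mask & (claims > 0)
        claims[mask & (claims == 0)] = s
        claims[mask & contested] = 0  # re-resolved below
        seed_info.append((seed_pt, peak_val, mask))

    if contested.any():
        rows, cols = np.nonzero(contested)
        pts = np.stack([rows, cols], axis=1).astype(float)
        best = np.full(len(rows), -1)
        best_d = np.full(len(rows), np.inf)
        for s, (seed_pt, _pv, mask) in enumerate(seed_info, start=1):
            claimed_here = mask[rows, cols]
            d = np.hypot(pts[:, 0] - seed_pt[0], pts[:, 1] - seed_pt[1])
            better = claimed_here & (d < best_d)
            best[better] = s
            best_d[better] = d[better]
        claims[rows, cols] = best

    objects = []
    for s, (seed_pt, _peak_val, mask) in enumerate(seed_info, start=1):
        final = (claims == s) & mask
        if not final.any():
            continue
        rr, cc = np.nonzero(final)
        objects.append(
            DnaObject(
                label=s,
                mask=final,
                area_px2=int(final.sum()),
                centroid=(float(rr.mean()), float(cc.mean())),
                total_intensity=float(proc[final].sum()),
                peak=(int(round(seed_pt[0])), int(round(seed_pt[1]))),
            )
        )
    return objects


def assign_objects_to_cells(objects: Sequence[DnaObject],
                            cell_masks: Sequence[np.ndarray]) -> List[list]:
    """Group DNA objects by the cell whose mask contains their centroid.

    Objects outside every cell are dropped. Returns one list per cell mask.
    """
    grouped: List[list] = [[] for _ in cell_masks]
    for obj in objects:
        r, c = (int(round(obj.centroid[0])), int(round(obj.centroid[1])))
        for i, cell in enumerate(cell_masks):
            if cell[r, c]:
                grouped[i].append(obj)
                break
    return grouped


def assign_kn(objects: Sequence[DnaObject]
              ) -> Tuple[List[DnaObject], bool]:
    """Assign kinetoplast/nucleus classes from the object count in one cell.

    2 objects -> largest is the nucleus (1K1N); 3 -> largest is the nucleus
    (2K1N); 4 -> largest two are nuclei (2K2N); any other count excludes
    the cell from partition analysis (returned flag True). Area ties at the
    deciding rank break by higher total intensity, then lower label.
    """
    n = len(objects)
    if n not in (2, 3, 4):
        return list(objects), True
    order = sorted(
        objects,
        key=lambda o: (-o.area_px2, -o.total_intensity, o.label),
    )
    n_nuclei = 2 if n == 4 else 1
    assigned = []
    for rank, obj in enumerate(order):
        assigned.append(replace(
            obj, klass="N" if rank < n_nuclei else "K"))
    assigned.sort(key=lambda o: o.label)
    return assigned, False


def fit_nucleus_geometry(nucleus_mask: np.ndarray) -> NucleusGeometry:
    """Mean nucleus radius from a moments-fitted ellipse.

    The ellipse shares the mask's second central moments; r is the average
    of its full major and minor axis lengths.
    """
    if nucleus_mask.sum() < 4:
        raise ValueError("degenerate nucleus mask (fewer than 4 pixels)")
    props = measure.regionprops(nucleus_mask.astype(np.uint8))[0]
    if props.axis_minor_length == 0:
        raise ValueError("degenerate nucleus mask (zero minor axis)")
    r = (props.axis_major_length + props.axis_minor_length) / 2.0
    return NucleusGeometry(r_px=r)


class NucleolusNotFound(ValueError):
    """No candidate pixel satisfies the edge-margin constraint."""


def locate_nucleolus(dna_proc: np.ndarray, nucleus_mask: np.ndarray,
                     geometry: NucleusGeometry) -> NucleusGeometry:
    """Find the nucleolar centre: darkest point at least r/8 from the edge.

    Darkness is evaluated on the preprocessed (blurred, background-
    subtracted) DNA channel. Ties break by proximity to the nucleus
    centroid, then by row-major scan order. Raises ``NucleolusNotFound``
    when the margin leaves no candidate pixels (the cell is then excluded).
    """
    edt = ndi.distance_transform_edt(nucleus_mask)
    candidates = edt >= geometry.edge_margin_px
    if not candidates.any():
        raise NucleolusNotFound(
            f"no pixel at least {geometry.edge_margin_px:.2f} px from the "
            "nucleus edge"
        )
    rows, cols = np.nonzero(candidates)
    vals = dna_proc[rows, cols]
    vmin = vals.min()
    tied = vals == vmin
    rr, cc = np.nonzero(nucleus_mask)
    centroid = (rr.mean(), cc.mean())
    d = np.hypot(rows[tied] - centroid[0], cols[tied] - centroid[1])
    # scan order is the natural order of np.nonzero, so argmin's first-hit
    # behaviour provides the final tie-break
    best = np.argmin(d)
    centre = (int(rows[tied][best]), int(cols[tied][best]))
    return NucleusGeometry(r_px=geometry.r_px, nucleolus_centre=centre)


def nucleolus_mask(geometry: NucleusGeometry,
                   nucleus_mask: np.ndarray) -> np.ndarray:
    """Disc of radius r/4 about the nucleolar centre, clipped to the nucleus."""
    if geometry.nucleolus_centre is None:
        raise ValueError("nucleolus centre not set; run locate_nucleolus")
    yy, xx = np.ogrid[: nucleus_mask.shape[0], : nucleus_mask.shape[1]]
    cy, cx = geometry.nucleolus_centre
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= geometry.nucleolus_radius_px ** 2
    return disc & nucleus_mask


@dataclass
class CellSegmentation:
    """Per-cell segmentation result for downstream quantification."""

    cell_mask: np.ndarray
    dna_objects: List[DnaObject]
    nuclei: List[DnaObject]
    geometries: List[NucleusGeometry]
    nucleolus_masks: List[np.ndarray]
    excluded: bool = False
    exclusion_reason: str = ""


def segment_micrograph(m: Micrograph,
                       seg_params: Optional[SegmentationParams] = None,
                       dna_params: Optional[DnaDetectionParams] = None
                       ) -> List[CellSegmentation]:
    """Run the full segmentation chain on one micrograph.

    Returns one ``CellSegmentation`` per detected cell; cells failing the
    K/N count rule or the nucleolus margin constraint are flagged excluded
    with a reason rather than dropped, so exclusion counts are reportable.
    """
    seg_params = seg_params or SegmentationParams()
    dna_params = dna_params or DnaDetectionParams()
    cell_masks = segment_cells(m["phase"], seg_params)
    dna_proc = preprocess_dna(m["dna"], dna_params)
    objects = detect_dna_objects(m["dna"], dna_params, preprocessed=dna_proc)
    grouped = assign_objects_to_cells(objects, cell_masks)

    results = []
    for cell_mask, objs in zip(cell_masks, grouped):
        assigned, excluded = assign_kn(objs)
        if excluded:
            results.append(CellSegmentation(
                cell_mask=cell_mask, dna_objects=assigned, nuclei=[],
                geometries=[], nucleolus_masks=[], excluded=True,
                exclusion_reason=f"{len(objs)} DNA objects",
            ))
            continue
        nuclei = [o for o in assigned if o.klass == "N"]
        geometries = []
        discs = []
        reason = ""
        try:
            for nuc in nuclei:
                geom = fit_nucleus_geometry(nuc.mask)
                geom = locate_nucleolus(dna_proc, nuc.mask, geom)
                geometries.append(geom)
                discs.append(nucleolus_mask(geom, nuc.mask))
        except (NucleolusNotFound, ValueError) as err:
            results.append(CellSegmentation(
                cell_mask=cell_mask, dna_objects=assigned, nuclei=nuclei,
                geometries=[], nucleolus_masks=[], excluded=True,
                exclusion_reason=str(err),
            ))
            continue
        results.append(CellSegmentation(
            cell_mask=cell_mask, dna_objects=assigned, nuclei=nuclei,
            geometries=geometries, nucleolus_masks=discs,
        ))
    return results
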