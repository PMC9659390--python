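"""Ground-truth micrograph phantoms of trypanosome cells.

Each phantom field renders three channels of an idealised widefield
acquisition: phase contrast (dark elongated cells with a bright halo on a
mid-grey background), a DNA-stain channel (bright nuclei containing a dimmer
nucleolar disc, plus one or two small bright kinetoplasts per cell) and a
reporter channel that is piecewise-constant over the cytoplasm, nucleoplasm
and nucleolus compartments. The generator returns the exact label masks and
the analytic compartment partition ratios, so segmentation and quantification
can be tested against known truth.

Cells are drawn as bent capsules (a curved centreline rod of constant
width), which reproduces the elongated, slightly curved trypanosome body
well enough to exercise the size and shape filters of the segmentation
chain. Cell-cycle configurations 1K1N, 2K1N and 2K2N (K = kinetoplast,
N = nucleus) are generated in configurable proportions; the kinetoplast
divides before the nucleus, so these are the configurations a real
asynchronous population presents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .micrograph import Micrograph

KN_CONFIGS = ((1, 1), (2, 1), (2, 2))  # (n_kinetoplasts, n_nuclei)


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom field.

    ``reporter_conc`` is the (cytoplasm, nucleoplasm, nucleolus) reporter
    concentration triple in arbitrary intensity units; ``nucleolus_fraction``
    is the nucleolus radius as a fraction of the nucleus mean-axis radius r
    (the average of the full major and minor ellipse axes, the same r the
    segmentation chain estimates).
    """

    n_cells: int = 5
    cell_area_px2: Tuple[float, float] = (2000.0, 7000.0)
    nucleus_axes_px: Tuple[float, float] = (28.0, 22.0)  # full major, minor
    kinetoplast_radius_px: float = 3.0
    nucleolus_fraction: float = 0.25
    hoechst_nucleolus_dimming: float = 0.6
    reporter_conc: Tuple[float, float, float] = (50.0, 200.0, 400.0)
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    background_level: float = 200.0
    dna_background: float = 2.0
    dna_nucleus_level: float = 150.0
    dna_kinetoplast_level: float = 180.0
    dna_dome: float = 0.3  # parabolic brightening of the nucleus centre
    nucleolus_jitter_px: float = 1.5
    reporter_background: float = 0.0
    phase_cell_depth: float = 0.35  # interior = (1 - depth) * background
    kn_config_probs: Tuple[float, float, float] = (0.7, 0.2, 0.1)
    cell_width_px: float = 30.0
    field_shape: Optional[Tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if any(c < 0 for c in self.reporter_conc):
            raise ValueError("reporter concentrations must be >= 0")
        if not (0.0 < self.nucleolus_fraction < 1.0):
            raise ValueError("nucleolus_fraction must be in (0, 1)")
        if min(self.nucleus_axes_px) <= 0:
            raise ValueError("nucleus axes must be > 0")
        lo, hi = self.cell_area_px2
        if not (0 < lo <= hi):
            raise ValueError("invalid cell area range")
        if abs(sum(self.kn_config_probs) - 1.0) > 1e-9:
            raise ValueError("kn_config_probs must sum to 1")


@dataclass
class GroundTruth:
    """Exact masks and analytic partition ratios of a phantom field.

    Label images share the field shape; nucleolus labels match their
    nucleus labels. ``true_partition`` maps cell label to the pair
    (nucleoplasm/cytoplasm, nucleolus/nucleoplasm) concentration ratios.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    kinetoplast_labels: np.ndarray
    nucleolus_labels: np.ndarray
    nucleus_cell: Dict[int, int]
    kinetoplast_cell: Dict[int, int]
    nucleus_centres: Dict[int, Tuple[float, float]]
    kinetoplast_centres: Dict[int, Tuple[float, float]]
    nucleolus_centres: Dict[int, Tuple[float, float]]
    kn_config: Dict[int, Tuple[int, int]]
    true_partition: Dict[int, Tuple[float, float]]
    nucleus_params: Dict[int, tuple] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.max())

    def cell_mask(self, label: int) -> np.ndarray:
        return self.cell_labels == label

    def nuclei_masks(self, cell_label: int) -> list:
        return [self.nucleus_labels == k
                for k, c in self.nucleus_cell.items() if c == cell_label]

    def nucleolus_masks(self, cell_label: int) -> list:
        return [self.nucleolus_labels == k
                for k, c in self.nucleus_cell.items() if c == cell_label]


def _true_partition(conc: Tuple[float, float, float]) -> Tuple[float, float]:
    c_cyto, c_np, c_no = conc
    rnc = c_np / c_cyto if c_cyto > 0 else math.inf
    rnn = c_no / c_np if c_np > 0 else math.inf
    return (rnc, rnn)


def _arc_points(length: float, bend: float, origin, heading,
                step: float = 1.0) -> np.ndarray:
    """Points every ~step px along a circular arc of given total length.

    ``bend`` is the total heading change over the arc (radians); 0 gives a
    straight rod.
    """
    n = max(int(round(length / step)), 2)
    s = np.linspace(0.0, length, n)
    h = heading + bend * (s / length - 0.5)
    if abs(bend) < 1e-9:
        y = origin[0] + s * np.sin(heading)
        x = origin[1] + s * np.cos(heading)
    else:
        radius = length / bend
        y = origin[0] + radius * (-np.cos(h) + np.cos(h[0]))
        x = origin[1] + radius * (np.sin(h) - np.sin(h[0]))
    return np.stack([y, x], axis=1), h


def _capsule_mask(shape, points, width) -> np.ndarray:
    """Pixels within width/2 of the rasterised centreline."""
    marks = np.ones(shape, dtype=bool)
    idx = np.round(points).astype(int)
    idx[:, 0] = np.clip(idx[:, 0], 0, shape[0] - 1)
    idx[:, 1] = np.clip(idx[:, 1], 0, shape[1] - 1)
    marks[idx[:, 0], idx[:, 1]] = False
    dist = ndi.distance_transform_edt(marks)
    return dist <= width / 2.0


def _ellipse_mask(shape, centre, semi_major, semi_minor, angle) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    dy = yy - centre[0]
    dx = xx - centre[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa   # along major axis
    v = -dx * sa + dy * ca
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def _disc_mask(shape, centre, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius ** 2


def _required_half_length(n_k: int, n_n: int, spec: PhantomSpec) -> float:
    """Arc half-length needed to hold the organelle layout plus end margins."""
    major = spec.nucleus_axes_px[0]
    d_nk = major / 2.0 + spec.kinetoplast_radius_px + 6.0
    if (n_k, n_n) == (2, 2):
        sep = major + 10.0
        return sep / 2.0 + d_nk + spec.kinetoplast_radius_px + 5.0
    return d_nk + spec.kinetoplast_radius_px + 5.0


def make_phantom_field(spec: PhantomSpec) -> Tuple[Micrograph, GroundTruth]:
    """Render one phantom field and its ground truth; deterministic per seed.

    Cells are placed one per tile of a regular grid (with random position
    jitter, heading and bend inside the tile), which guarantees separation
    between cells and from the field border. A ``PlacementError`` naming the
    number of cells placed is raised when the requested count does not fit
    the field.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_phase, rng_dna, rng_rep = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    w = spec.cell_width_px
    lo_a, hi_a = spec.cell_area_px2
    cap_area = math.pi * (w / 2.0) ** 2
    max_len = (hi_a - cap_area) / w
    tile = int(math.ceil(max_len + w + 16))
    if spec.field_shape is None:
        side = max(int(math.ceil(math.sqrt(max(spec.n_cells, 1)))), 1)
        shape = (side * tile, side * tile)
    else:
        shape = tuple(int(v) for v in spec.field_shape)
    rows, cols = shape[0] // tile, shape[1] // tile
    if rows * cols < spec.n_cells:
        raise PlacementError(
            f"placed only {rows * cols} of {spec.n_cells} cells: field "
            f"{shape} holds {rows * cols} tiles of {tile} px"
        )

    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    kinetoplast_labels = np.zeros(shape, dtype=np.int32)
    nucleolus_labels = np.zeros(shape, dtype=np.int32)
    nucleus_cell: Dict[int, int] = {}
    kinetoplast_cell: Dict[int, int] = {}
    nucleus_centres: Dict[int, Tuple[float, float]] = {}
    kinetoplast_centres: Dict[int, Tuple[float, float]] = {}
    nucleolus_centres: Dict[int, Tuple[float, float]] = {}
    kn_config: Dict[int, Tuple[int, int]] = {}
    nucleus_params: Dict[int, tuple] = {}  # label -> (centre, angle)

    major, minor = spec.nucleus_axes_px
    r_mean_axes = (major + minor) / 2.0  # the r the pipeline estimates
    nucleolus_radius = spec.nucleolus_fraction * r_mean_axes
    k_r = spec.kinetoplast_radius_px
    d_nk = major / 2.0 + k_r + 6.0

    tiles = [(i, j) for i in range(rows) for j in range(cols)]
    rng_geom.shuffle(tiles)
    next_nuc = 1
    next_kin = 1
    for cell_idx in range(spec.n_cells):
        cell_label = cell_idx + 1
        n_k, n_n = KN_CONFIGS[
            rng_geom.choice(3, p=np.asarray(spec.kn_config_probs))
        ]
        # minimum arc length that holds the K/N layout; target areas keep a
        # 3% margin inside the detection window so rasterisation noise
        # cannot push a cell across the area filter
        min_len = 2.0 * _required_half_length(n_k, n_n, spec)
        lo_len = max((1.03 * lo_a - cap_area) / w, min_len)
        max_len_s = (0.97 * hi_a - cap_area) / w
        if lo_len > max_len_s:
            raise PlacementError(
                f"placed only {cell_idx} of {spec.n_cells} cells: "
                f"{n_k}K{n_n}N layout needs length {lo_len:.0f} px but the "
                f"area range caps length at {max_len_s:.0f} px"
            )
        length = rng_geom.uniform(lo_len, max_len_s)

        ti, tj = tiles[cell_idx]
        centre = np.array([(ti + 0.5) * tile, (tj + 0.5) * tile])
        placed = False
        for _ in range(200):
            heading = rng_geom.uniform(0, 2 * math.pi)
            bend = rng_geom.uniform(0.2, 0.7) * rng_geom.choice([-1, 1])
            jitter = rng_geom.uniform(-6, 6, size=2)
            pts, tangents = _arc_points(length, bend, centre + jitter, heading)
            pts -= pts.mean(axis=0) - (centre + jitter)  # recentre arc
            pad = w / 2.0 + 6.0
            if (
                pts[:, 0].min() - pad < ti * tile
                or pts[:, 0].max() + pad > (ti + 1) * tile
                or pts[:, 1].min() - pad < tj * tile
                or pts[:, 1].max() + pad > (tj + 1) * tile
            ):
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"placed only {cell_idx} of {spec.n_cells} cells: tile "
                f"{tile} px cannot hold a {length:.0f} px cell"
            )

        body = _capsule_mask(shape, pts, w)
        cell_labels[body] = cell_label
        kn_config[cell_label] = (n_k, n_n)

        # organelle anchor arclength indices (points are ~1 px apart)
        n_pts = len(pts)
        mid = n_pts // 2
        def at(s_px: float) -> int:
            return int(np.clip(mid + round(s_px), 0, n_pts - 1))

        if n_n == 1:
            nuc_anchor = [at(0)]
        else:
            half_sep = (major + 10.0) / 2.0
            nuc_anchor = [at(-half_sep), at(half_sep)]
        if n_k == 1:
            kin_anchor = [at(-d_nk)]
        elif n_n == 1:  # 2K1N: kinetoplasts flank the single nucleus
            kin_anchor = [at(-d_nk), at(d_nk)]
        else:  # 2K2N: outside the two nuclei
            half_sep = (major + 10.0) / 2.0
            kin_anchor = [at(-(half_sep + d_nk)), at(half_sep + d_nk)]

        for idx in nuc_anchor:
            c = pts[idx]
            ang = float(tangents[idx])
            nuc = _ellipse_mask(shape, c, major / 2.0, minor / 2.0, ang)
            nucleus_labels[nuc] = next_nuc
            nucleus_cell[next_nuc] = cell_label
            nucleus_centres[next_nuc] = (float(c[0]), float(c[1]))
            nucleus_params[next_nuc] = (tuple(c), ang)
            # nucleolus centres sit on the pixel grid, like the label masks
            j = spec.nucleolus_jitter_px
            off = rng_geom.uniform(-j, j, size=2)
            no_c = (float(round(c[0] + off[0])), float(round(c[1] + off[1])))
            disc = _disc_mask(shape, no_c, nucleolus_radius) & nuc
            nucleolus_labels[disc] = next_nuc
            nucleolus_centres[next_nuc] = no_c
            next_nuc += 1
        for idx in kin_anchor:
            c = pts[idx]
            kin = _disc_mask(shape, c, k_r)
            kinetoplast_labels[kin] = next_kin
            kinetoplast_cell[next_kin] = cell_label
            kinetoplast_centres[next_kin] = (float(c[0]), float(c[1]))
            next_kin += 1

    # --- render channels -------------------------------------------------
    bg = spec.background_level
    in_cell = cell_labels > 0
    halo = ndi.binary_dilation(in_cell, ndi.generate_binary_structure(2, 2),
                               iterations=2) & ~in_cell
    phase = np.full(shape, bg, dtype=float)
    phase[in_cell] = bg * (1.0 - spec.phase_cell_depth)
    phase[halo] = bg * (1.0 + spec.phase_cell_depth)

    # Hoechst nuclei are rendered as smooth parabolic domes (brightest at
    # the nucleus centre, dimmer at the rim) as in real widefield images;
    # the nucleolar disc multiplicatively dims the local dome value.
    in_nucleolus = nucleolus_labels > 0
    in_kin = kinetoplast_labels > 0
    dna = np.full(shape, spec.dna_background, dtype=float)
    yy, xx = np.indices(shape)
    for lab, (centre, ang) in nucleus_params.items():
        nuc = nucleus_labels == lab
        dy = yy[nuc] - centre[0]
        dx = xx[nuc] - centre[1]
        ca, sa = math.cos(ang), math.sin(ang)
        u = (dx * ca + dy * sa) / (major / 2.0)
        v = (-dx * sa + dy * ca) / (minor / 2.0)
        rho2 = u ** 2 + v ** 2
        dna[nuc] = spec.dna_nucleus_level * (1.0 + spec.dna_dome * (0.5 - rho2))
    # nucleolar dip: parabolic dimming, deepest at the disc centre
    for lab, centre in nucleolus_centres.items():
        disc = nucleolus_labels == lab
        if not disc.any():
            continue
        d2 = ((yy[disc] - centre[0]) ** 2 + (xx[disc] - centre[1]) ** 2)
        frac = np.minimum(d2 / nucleolus_radius ** 2, 1.0)
        dim = spec.hoechst_nucleolus_dimming
        dna[disc] *= dim + (1.0 - dim) * frac
    dna[in_kin] = spec.dna_kinetoplast_level

    c_cyto, c_np, c_no = spec.reporter_conc
    reporter = np.full(shape, spec.reporter_background, dtype=float)
    reporter[in_cell] = c_cyto
    reporter[nucleus_labels > 0] = c_np
    reporter[in_nucleolus] = c_no

    channels = {"phase": phase, "dna": dna, "reporter": reporter}
    for name, rng_ch in (("phase", rng_phase), ("dna", rng_dna),
                         ("reporter", rng_rep)):
        img = channels[name]
        if spec.shot_noise:
            img = rng_ch.poisson(np.clip(img, 0, None)).astype(float)
        if spec.read_noise_sd > 0:
            img = img + rng_ch.normal(0.0, spec.read_noise_sd, size=shape)
        channels[name] = img

    truth = GroundTruth(
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        kinetoplast_labels=kinetoplast_labels,
        nucleolus_labels=nucleolus_labels,
        nucleus_cell=nucleus_cell,
        kinetoplast_cell=kinetoplast_cell,
        nucleus_centres=nucleus_centres,
        kinetoplast_centres=kinetoplast_centres,
        nucleolus_centres=nucleolus_centres,
        kn_config=kn_config,
        nucleus_params=nucleus_params,
        true_partition={
            lab: _true_partition(spec.reporter_conc) for lab in kn_config
        },
    )
    return Micrograph(channels=channels), truth
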