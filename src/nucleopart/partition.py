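"""Per-cell reporter partition and per-line aggregation.

Compartments partition the cell mask exactly: cytoplasm = cell minus
nuclei, nucleoplasm = nuclei minus nucleolus discs, nucleolus = the discs.
The two partition ratios are ratios of compartment *means*. By default the
nucleus/cytoplasm ratio uses the nucleoplasmic mean, so that with uniform
per-compartment concentrations each ratio recovers the corresponding
concentration ratio exactly; the nuclear mean pooled over nucleoplasm and
nucleolus is always reported alongside, and ``nuclear_includes_nucleolus``
switches the ratio onto it (the modelled nucleolus disc is a quarter of
the nucleus area, so the two conventions differ appreciably for
nucleolus-enriched proteins). For 2-nucleus (2K2N) cells, pixels are
pooled across both nuclei/discs before the means are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set

import numpy as np

EPS = np.finfo(float).eps


class EmptyCompartment(ValueError):
    """A compartment has no pixels; the cell is excluded."""


@dataclass
class CellMeasurement:
    """Compartment signal sums/means and partition ratios for one cell."""

    cell_id: int
    sum_cyto: float
    sum_nucleoplasm: float
    sum_nucleolus: float
    area_cyto: int
    area_nucleoplasm: int
    area_nucleolus: int
    mean_cyto: float
    mean_nucleoplasm: float
    mean_nucleolus: float
    mean_nuclear: float
    total_sum: float
    total_area: int
    ratio_nc: float
    ratio_nn: float
    n_nuclei: int
    floored: bool = False  # a compartment mean was floored at machine eps


@dataclass
class LineSummary:
    """Per-cell-line aggregate (one tagged protein, one terminus)."""

    line_id: str
    terminus: str  # "N" or "C"
    n_cells: int
    mean_total_signal: float
    mean_ratio_nc: float
    mean_ratio_nn: float
    low_confidence: bool  # fewer than 20 cells


@dataclass
class ClassificationThresholds:
    """Partition-ratio cutoffs separating localisation classes."""

    t_nc: float = 2.0
    t_nn: float = 2.0

    def __post_init__(self) -> None:
        if self.t_nc <= 0 or self.t_nn <= 0:
            raise ValueError("thresholds must be > 0")


def measure_cell(cell_mask: np.ndarray,
                 nuclei_masks: Sequence[np.ndarray],
                 nucleolus_masks: Sequence[np.ndarray],
                 reporter: np.ndarray,
                 cell_id: int = 0,
                 nuclear_includes_nucleolus: bool = False) -> CellMeasurement:
    """Compartment sums, means and partition ratios for one cell.

    Raises ``EmptyCompartment`` when the cytoplasm or nucleoplasm region is
    empty. Compartment means are floored at machine epsilon before ratio
    division (flagged via ``floored``) so that flat-field-corrected images
    with near-zero or negative compartment means yield finite ratios.
    """
    if not nuclei_masks:
        raise EmptyCompartment("cell has no nucleus mask")
    nuclear = np.zeros_like(cell_mask)
    for m in nuclei_masks:
        nuclear |= m
    nuclear &= cell_mask
    discs = np.zeros_like(cell_mask)
    for m in nucleolus_masks:
        discs |= m
    discs &= nuclear

    cyto = cell_mask & ~nuclear
    nucleoplasm = nuclear & ~discs
    if not cyto.any():
        raise EmptyCompartment("empty cytoplasm region")
    if not nucleoplasm.any():
        raise EmptyCompartment("empty nucleoplasm region")

    rep = np.asarray(reporter, dtype=float)
    sums = {c: float(rep[m].sum()) for c, m in
            (("cyto", cyto), ("np", nucleoplasm), ("no", discs))}
    areas = {c: int(m.sum()) for c, m in
             (("cyto", cyto), ("np", nucleoplasm), ("no", discs))}
    mean_cyto = sums["cyto"] / areas["cyto"]
    mean_np = sums["np"] / areas["np"]
    mean_no = sums["no"] / areas["no"] if areas["no"] else 0.0
    mean_nuclear = (sums["np"] + sums["no"]) / (areas["np"] + areas["no"])

    floored = False
    denom_c, denom_np = mean_cyto, mean_np
    if denom_c < EPS:
        denom_c, floored = EPS, True
    if denom_np < EPS:
        denom_np, floored = EPS, True
    numer_n = mean_nuclear if nuclear_includes_nucleolus else mean_np

    return CellMeasurement(
        cell_id=cell_id,
        sum_cyto=sums["cyto"], sum_nucleoplasm=sums["np"],
        sum_nucleolus=sums["no"],
        area_cyto=areas["cyto"], area_nucleoplasm=areas["np"],
        area_nucleolus=areas["no"],
        mean_cyto=mean_cyto, mean_nucleoplasm=mean_np,
        mean_nucleolus=mean_no, mean_nuclear=mean_nuclear,
        total_sum=sums["cyto"] + sums["np"] + sums["no"],
        total_area=areas["cyto"] + areas["np"] + areas["no"],
        ratio_nc=numer_n / denom_c,
        ratio_nn=mean_no / denom_np,
        n_nuclei=len(nuclei_masks),
        floored=floored,
    )


def filter_expressing(cells: Sequence[CellMeasurement],
                      parental_mean: Optional[float] = None,
                      parental_sd: Optional[float] = None,
                      k: float = 3.0) -> List[CellMeasurement]:
    """Retain cells whose mean whole-cell signal exceeds parental background.

    The cutoff is ``parental_mean + k * parental_sd`` on the per-cell mean
    reporter signal; parental statistics come from an untagged control
    population and are mandatory.
    """
    if parental_mean is None or parental_sd is None:
        raise ValueError(
            "parental background statistics required: supply parental_mean "
            "and parental_sd from an untagged control"
        )
    cut = parental_mean + k * parental_sd
    return [c for c in cells if c.total_sum / c.total_area > cut]


def aggregate_line(cells: Sequence[CellMeasurement], line_id: str = "",
                   terminus: str = "N") -> Optional[LineSummary]:
    """Unweighted mean of per-cell ratios and totals for one cell line.

    Lines with fewer than 20 cells are flagged low-confidence; zero cells
    yields no summary.
    """
    if len(cells) == 0:
        return None
    return LineSummary(
        line_id=line_id,
        terminus=terminus,
        n_cells=len(cells),
        mean_total_signal=float(np.mean([c.total_sum for c in cells])),
        mean_ratio_nc=float(np.mean([c.ratio_nc for c in cells])),
        mean_ratio_nn=float(np.mean([c.ratio_nn for c in cells])),
        low_confidence=len(cells) < 20,
    )


def classify_localisation(summary: LineSummary,
                          thr: Optional[ClassificationThresholds] = None
                          ) -> Set[str]:
    """Localisation class set from the two mean partition ratios.

    A line is nuclear iff its nucleus/cytoplasm ratio reaches ``t_nc``;
    nuclear lines are further nucleolar or nucleoplasmic by whether the
    nucleolus/nucleoplasm ratio reaches ``t_nn``; non-nuclear lines are
    cytoplasmic.
    """
    thr = thr or ClassificationThresholds()
    if summary.mean_ratio_nc >= thr.t_nc:
        classes = {"nuclear"}
        if summary.mean_ratio_nn >= thr.t_nn:
            classes.add("nucleolar")
        else:
            classes.add("nucleoplasmic")
        return classes
    return {"cytoplasmic"}
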