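"""Protein primary-sequence features for nuclear/nucleolar targeting analysis.

Quantities computed here are the sequence-level correlates of subnuclear
partition: residue-class composition (charged / hydrophobic / polar),
isoelectric point, occurrences of the monopartite KRXR nuclear localisation
signal (NLS) and their proximity to the protein termini, intrinsically
disordered regions (IDRs) from externally supplied per-residue disorder
scores, and the Das--Pappu diagram-of-states classification of polyampholyte
charge patterning.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Residue classes. "Charged" is the union of the basic and acidic classes;
# histidine counts as basic (positively charged) throughout.
CHARGED = set("RHKDE")
HYDROPHOBIC = set("AILMFWYV")
POLAR = set("STNQ")
POSITIVE = set("KRH")
NEGATIVE = set("DE")

#: Side-chain and terminal pKa tables. ``bjellqvist`` (the ExPASy/ProtParam
#: convention) is the default; ``emboss`` is provided as an alternative.
PKA_TABLES = {
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98,
        "K": 10.0, "R": 12.0, "Y": 10.0,
    },
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    },
}

_KRXR = re.compile(r"(?=(KR.R))")


class SequenceError(ValueError):
    """Raised for sequences containing non-standard residues."""


@dataclass
class ProteinRecord:
    """A protein sequence with optional group label and disorder scores.

    Disorder scores, when present, are one per residue in ``[0, 1]`` as
    produced by an external disorder predictor.
    """

    id: str
    sequence: str
    group: Optional[str] = None
    disorder: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SequenceError(f"{self.id}: empty sequence")
        if self.disorder is not None:
            self.disorder = np.asarray(self.disorder, dtype=float)
            if self.disorder.shape != (len(self.sequence),):
                raise SequenceError(
                    f"{self.id}: {self.disorder.size} disorder scores for "
                    f"{len(self.sequence)} residues"
                )


@dataclass
class CompositionProfile:
    """Residue-class composition, mass and isoelectric point of one protein."""

    id: str
    length: int
    molecular_mass_Da: float
    frac_charged: float
    frac_hydrophobic: float
    frac_polar: float
    frac_positive: float
    frac_negative: float
    pI: float


@dataclass
class MotifHit:
    """One KRXR match; positions are 1-based inclusive.

    ``terminal_flag`` holds the subset of {"N-proximal", "C-proximal"} for
    which the whole motif lies within the first/last 15 residues. Short
    sequences can carry both flags.
    """

    start: int
    end: int
    match: str
    terminal_flag: frozenset = field(default_factory=frozenset)


@dataclass
class DisorderProfile:
    """Maximal disordered segments (score strictly above threshold)."""

    threshold: float
    segments: list  # list of (start, end), 1-based inclusive
    disordered_fraction: float


@dataclass
class ChargeProfile:
    """Charge-patterning coordinates and diagram-of-states region.

    FCR = f+ + f- is the fraction of charged residues; NCPR = f+ - f- the
    net charge per residue.
    """

    f_plus: float
    f_minus: float
    FCR: float
    NCPR: float
    state: str


def _validate_sequence(seq: str, pid: str = "?") -> None:
    for i, aa in enumerate(seq):
        if aa not in STANDARD_AA:
            raise SequenceError(
                f"{pid}: non-standard residue {aa!r} at position {i + 1}"
            )


def composition_profile(
    p: ProteinRecord, pka_table: str = "bjellqvist"
) -> CompositionProfile:
    """Residue-class fractions, average molecular mass and pI of a protein.

    Fractions are class counts divided by sequence length. The charged
    class RHKDE is the disjoint union of the basic (KRH) and acidic (DE)
    classes, so ``frac_charged == frac_positive + frac_negative`` holds
    exactly, by counting.
    """
    seq = p.sequence
    _validate_sequence(seq, p.id)
    n = len(seq)
    counts = {aa: seq.count(aa) for aa in STANDARD_AA}
    n_pos = sum(counts[a] for a in POSITIVE)
    n_neg = sum(counts[a] for a in NEGATIVE)
    frac_positive = n_pos / n
    frac_negative = n_neg / n
    return CompositionProfile(
        id=p.id,
        length=n,
        molecular_mass_Da=molecular_weight(seq, seq_type="protein"),
        frac_charged=frac_positive + frac_negative,
        frac_hydrophobic=sum(counts[a] for a in HYDROPHOBIC) / n,
        frac_polar=sum(counts[a] for a in POLAR) / n,
        frac_positive=frac_positive,
        frac_negative=frac_negative,
        pI=isoelectric_point(p, pka_table=pka_table),
    )


def net_charge(seq: str, pH: float, pka: dict) -> float:
    """Henderson–Hasselbalch net charge of a sequence at a given pH.

    Termini plus D, E, C, Y (acidic) and H, K, R (basic) side chains are
    treated as independent ionisable groups.
    """
    pos = 1.0 / (1.0 + 10.0 ** (pH - pka["Nterm"]))
    for aa in ("K", "R", "H"):
        pos += seq.count(aa) / (1.0 + 10.0 ** (pH - pka[aa]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - pH))
    for aa in ("D", "E", "C", "Y"):
        neg += seq.count(aa) / (1.0 + 10.0 ** (pka[aa] - pH))
    return pos - neg


def isoelectric_point(p: ProteinRecord, pka_table: str = "bjellqvist") -> float:
    """pH at which the net charge crosses zero, found by bisection.

    The net charge is strictly decreasing in pH, so the root is unique.
    Bisection runs to an interval width of 1e-6 pH units, far inside the
    0.01-pH reporting precision, so the residual charge at the returned pH
    is negligible.
    """
    _validate_sequence(p.sequence, p.id)
    pka = PKA_TABLES[pka_table] if isinstance(pka_table, str) else dict(pka_table)
    lo, hi = -2.0, 16.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if net_charge(p.sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    return 0.5 * (lo + hi)


def scan_kr_x_r(p: ProteinRecord, terminal_window: int = 15) -> list:
    """All (possibly overlapping) K-R-X-R matches, in sequence order.

    A hit is flagged N-proximal (C-proximal) when the whole four-residue
    motif lies within the first (last) ``terminal_window`` residues.
    """
    seq = p.sequence
    n = len(seq)
    hits = []
    for m in _KRXR.finditer(seq):
        start = m.start() + 1  # 1-based
        end = start + 3
        flags = set()
        if end <= terminal_window:
            flags.add("N-proximal")
        if start > n - terminal_window:
            flags.add("C-proximal")
        hits.append(
            MotifHit(start=start, end=end, match=m.group(1),
                     terminal_flag=frozenset(flags))
        )
    return hits


def idr_segments(p: ProteinRecord, threshold: float = 0.5) -> DisorderProfile:
    """Maximal runs of residues with disorder score strictly above threshold."""
    if p.disorder is None:
        raise ValueError(f"{p.id}: no disorder scores supplied")
    above = p.disorder > threshold
    segments = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append((start + 1, i))
            start = None
    if start is not None:
        segments.append((start + 1, len(above)))
    covered = int(above.sum())
    return DisorderProfile(
        threshold=threshold,
        segments=segments,
        disordered_fraction=covered / len(above),
    )


def diagram_of_states(f_plus: float, f_minus: float) -> ChargeProfile:
    """Classify a charge composition on the Das–Pappu diagram of states.

    Regions (standard five-region convention): FCR < 0.25 weak polyampholyte
    (globules/tadpoles); 0.25 ≤ FCR ≤ 0.35 boundary (Janus); FCR > 0.35 with
    |NCPR| ≤ 0.35 strong polyampholyte (coils/hairpins); one charge fraction
    above 0.35 with the other at or below it, positive or negative
    polyelectrolyte.
    """
    if not (0.0 <= f_plus <= 1.0 and 0.0 <= f_minus <= 1.0):
        raise ValueError("charge fractions must lie in [0, 1]")
    if f_plus + f_minus > 1.0 + 1e-12:
        raise ValueError("charge fractions sum above 1")
    fcr = f_plus + f_minus
    ncpr = f_plus - f_minus
    if f_plus > 0.35 and f_minus <= 0.35:
        state = "positive polyelectrolyte"
    elif f_minus > 0.35 and f_plus <= 0.35:
        state = "negative polyelectrolyte"
    elif fcr > 0.35:
        state = "strong polyampholyte"
    elif fcr >= 0.25:
        state = "boundary"
    else:
        state = "weak polyampholyte"
    return ChargeProfile(f_plus=f_plus, f_minus=f_minus, FCR=fcr, NCPR=ncpr,
                         state=state)


def charge_profile(p: ProteinRecord) -> ChargeProfile:
    """Diagram-of-states classification from a full sequence."""
    _validate_sequence(p.sequence, p.id)
    n = len(p.sequence)
    f_plus = sum(p.sequence.count(a) for a in POSITIVE) / n
    f_minus = sum(p.sequence.count(a) for a in NEGATIVE) / n
    return diagram_of_states(f_plus, f_minus)


def composition_matrix(
    ps: Sequence[ProteinRecord], trim_n: Optional[int] = None
) -> pd.DataFrame:
    """Per-protein 20-residue composition fractions (rows sum to 1).

    With ``trim_n`` set, the first ``trim_n`` residues are removed before
    counting — used to discount N-terminal targeting presequences (e.g.
    mitochondrial targeting signals) when comparing ribosome groups.
    Records shorter than or equal to the trim are skipped with a warning.
    """
    rows = {}
    for p in ps:
        seq = p.sequence
        if trim_n is not None:
            if trim_n >= len(seq):
                warnings.warn(
                    f"{p.id}: length {len(seq)} <= trim {trim_n}; skipped"
                )
                continue
            seq = seq[trim_n:]
        _validate_sequence(seq, p.id)
        if p.id in rows:
            raise ValueError(f"duplicate protein id {p.id!r}")
        n = len(seq)
        rows[p.id] = [seq.count(aa) / n for aa in STANDARD_AA]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(STANDARD_AA))
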