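"""Synthetic proteome generation.

Sequences are drawn i.i.d. from a configurable background residue
distribution, optionally with a homopolymer tract inserted (emulating basic
or acidic fusion tracts) and/or a fixed motif spiked at a controlled
position (emulating KRXR-type NLS placement near a terminus). Used to test
the motif scanner, composition statistics and group comparisons without any
external sequence download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .seqfeat import STANDARD_AA, ProteinRecord, SequenceError


@dataclass
class ProteomeSpec:
    """Parameters of a synthetic proteome.

    ``residue_freqs`` is a 20-vector over the alphabet ACDEFGHIKLMNPQRSTVWY
    summing to 1 (uniform when omitted). ``spike`` is a list of
    ``(motif, position)`` pairs where position is a 1-based start, or one of
    "N" (start), "C" (end) or "random". ``tract`` is an optional
    ``(residue, length)`` homopolymer inserted at a random interior point.
    """

    n_proteins: int = 100
    length_range: tuple = (200, 400)
    residue_freqs: Optional[Sequence[float]] = None
    spike: Optional[list] = None
    tract: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")
        if self.residue_freqs is not None:
            f = np.asarray(self.residue_freqs, dtype=float)
            if f.shape != (20,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("residue_freqs must be a 20-simplex vector")
        for motif, _pos in self.spike or []:
            for aa in motif:
                if aa not in STANDARD_AA and aa != "X":
                    raise SequenceError(f"motif residue {aa!r} not standard")
            if len(motif) > lo:
                raise ValueError("minimum length shorter than spiked motif")
        if self.tract is not None:
            res, n = self.tract
            if res not in STANDARD_AA:
                raise SequenceError(f"tract residue {res!r} not standard")
            if n < 1:
                raise ValueError("tract length must be >= 1")


def biased_freqs(scale: dict) -> np.ndarray:
    """Uniform background composition with per-residue multipliers, renormalised.

    ``biased_freqs({"K": 1.5, "R": 1.5})`` yields a basic-enriched proteome.
    """
    f = np.ones(20)
    for aa, s in scale.items():
        f[STANDARD_AA.index(aa)] *= s
    return f / f.sum()


def _realise_motif(motif: str, rng: np.random.Generator) -> str:
    """Replace wildcard X positions with random standard residues."""
    return "".join(
        rng.choice(list(STANDARD_AA)) if aa == "X" else aa for aa in motif
    )


def synth_proteome(spec: ProteomeSpec) -> list:
    """Generate ``spec.n_proteins`` ProteinRecords, deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    freqs = (
        np.full(20, 0.05)
        if spec.residue_freqs is None
        else np.asarray(spec.residue_freqs, dtype=float)
    )
    alphabet = np.array(list(STANDARD_AA))
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(alphabet, size=n, p=freqs))
        if spec.tract is not None:
            res, tlen = spec.tract
            at = int(rng.integers(0, n + 1))
            seq[at:at] = [res] * tlen
        for motif, pos in spec.spike or []:
            realised = _realise_motif(motif, rng)
            m = len(realised)
            if pos == "N":
                start = 0
            elif pos == "C":
                start = len(seq) - m
            elif pos == "random":
                start = int(rng.integers(0, len(seq) - m + 1))
            else:
                start = int(pos) - 1  # 1-based start
            if start < 0 or start + m > len(seq):
                raise ValueError(
                    f"motif {motif!r} does not fit at position {pos}"
                )
            seq[start:start + m] = list(realised)
        records.append(ProteinRecord(id=f"syn{i:05d}", sequence="".join(seq)))
    return records
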