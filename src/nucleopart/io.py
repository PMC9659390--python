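"""File I/O: TIFF phantom fields, FASTA proteomes, TSV tables, YAML configs.

Phantom fields are written as multi-page TIFF (page order: phase, DNA,
reporter) with a JSON sidecar carrying the ground-truth label masks as
run-length encodings plus the true partition ratios, so a phantom data set
round-trips through plain files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .micrograph import CHANNEL_ORDER, Micrograph
from .phantom import GroundTruth
from .seqfeat import ProteinRecord


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major, starting with zeros)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    boundaries = np.concatenate([[0], changes + 1, [flat.size]])
    runs = np.diff(boundaries)
    if flat.size and flat[0]:
        runs = np.concatenate([[0], runs])
    return {"shape": list(mask.shape), "runs": [int(r) for r in runs]}


def rle_decode(enc: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(enc["shape"])), dtype=bool)
    pos = 0
    value = False
    for run in enc["runs"]:
        if value:
            flat[pos:pos + run] = True
        pos += run
        value = not value
    return flat.reshape(enc["shape"])


def _labels_to_rle(labels: np.ndarray) -> Dict[str, dict]:
    return {
        str(lab): rle_encode(labels == lab)
        for lab in np.unique(labels) if lab != 0
    }


def _rle_to_labels(encs: Dict[str, dict], shape) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for lab, enc in encs.items():
        labels[rle_decode(enc)] = int(lab)
    return labels


def write_phantom(path: Path, m: Micrograph, truth: GroundTruth) -> None:
    """Write a phantom field as TIFF plus a JSON ground-truth sidecar."""
    path = Path(path)
    stack = np.stack([m[ch] for ch in CHANNEL_ORDER]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "pixel_size_um": m.pixel_size_um,
        "channel_order": list(CHANNEL_ORDER),
        "shape": list(m.shape),
        "masks": {
            name: _labels_to_rle(getattr(truth, name))
            for name in ("cell_labels", "nucleus_labels",
                         "kinetoplast_labels", "nucleolus_labels")
        },
        "nucleus_cell": truth.nucleus_cell,
        "kinetoplast_cell": truth.kinetoplast_cell,
        "nucleus_centres": truth.nucleus_centres,
        "kinetoplast_centres": truth.kinetoplast_centres,
        "nucleolus_centres": truth.nucleolus_centres,
        "kn_config": truth.kn_config,
        "true_partition": truth.true_partition,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_phantom(path: Path):
    """Read back a phantom TIFF and its JSON sidecar."""
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    channels = {ch: stack[i].astype(float)
                for i, ch in enumerate(sidecar["channel_order"])}
    m = Micrograph(channels=channels,
                   pixel_size_um=sidecar["pixel_size_um"])
    shape = tuple(sidecar["shape"])
    truth = GroundTruth(
        cell_labels=_rle_to_labels(sidecar["masks"]["cell_labels"], shape),
        nucleus_labels=_rle_to_labels(sidecar["masks"]["nucleus_labels"],
                                      shape),
        kinetoplast_labels=_rle_to_labels(
            sidecar["masks"]["kinetoplast_labels"], shape),
        nucleolus_labels=_rle_to_labels(
            sidecar["masks"]["nucleolus_labels"], shape),
        nucleus_cell={int(k): v for k, v in sidecar["nucleus_cell"].items()},
        kinetoplast_cell={int(k): v
                          for k, v in sidecar["kinetoplast_cell"].items()},
        nucleus_centres={int(k): tuple(v)
                         for k, v in sidecar["nucleus_centres"].items()},
        kinetoplast_centres={int(k): tuple(v)
                             for k, v in sidecar["kinetoplast_centres"].items()},
        nucleolus_centres={int(k): tuple(v)
                           for k, v in sidecar["nucleolus_centres"].items()},
        kn_config={int(k): tuple(v) for k, v in sidecar["kn_config"].items()},
        true_partition={int(k): tuple(v)
                        for k, v in sidecar["true_partition"].items()},
    )
    return m, truth


def read_micrograph(path: Path, pixel_size_um: float = 0.103) -> Micrograph:
    """Read a 3-page TIFF stack in (phase, dna, reporter) page order."""
    stack = tifffile.imread(Path(path))
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-page TIFF stack")
    return Micrograph(
        channels={ch: stack[i].astype(float)
                  for i, ch in enumerate(CHANNEL_ORDER)},
        pixel_size_um=pixel_size_um,
    )


def write_fasta(path: Path, records: List[ProteinRecord]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description=r.group or "")
         for r in records],
        str(path), "fasta",
    )


def read_fasta(path: Path) -> List[ProteinRecord]:
    return [ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def read_disorder_tsv(path: Path) -> Dict[str, np.ndarray]:
    """Per-residue disorder scores from a TSV of (id, position, score)."""
    df = pd.read_csv(path, sep="\t")
    scores = {}
    for pid, grp in df.groupby("id"):
        grp = grp.sort_values("position")
        if not (grp["position"].values == np.arange(1, len(grp) + 1)).all():
            raise ValueError(f"{pid}: positions must be 1..length contiguous")
        scores[pid] = grp["score"].to_numpy(dtype=float)
    return scores


def read_groups_tsv(path: Path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["id"], df["group"]))


def attach_metadata(records: List[ProteinRecord],
                    disorder: Optional[Dict[str, np.ndarray]] = None,
                    groups: Optional[Dict[str, str]] = None
                    ) -> List[ProteinRecord]:
    out = []
    for r in records:
        out.append(dataclasses.replace(
            r,
            disorder=(disorder or {}).get(r.id, r.disorder),
            group=(groups or {}).get(r.id, r.group),
        ))
    return out


def load_config(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
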