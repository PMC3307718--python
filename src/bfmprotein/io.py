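"""Snapshot and series export: XYZ, CA-only PDB, CSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3

from .sequence import ProteinSequence


def write_xyz(path, positions: np.ndarray, seq: ProteinSequence | None = None,
              comment: str = "") -> None:
    """Write one frame (N, 3) or many (S, N, 3) in plain XYZ.

    Element labels are one-letter residue codes when a sequence is given,
    otherwise ``C``.
    """
    r = np.asarray(positions)
    if r.ndim == 2:
        r = r[None, :, :]
    n = r.shape[1]
    labels = list(seq) if seq is not None else ["C"] * n
    with open(path, "w") as fh:
        for k, frame in enumerate(r):
            fh.write(f"{n}\n{comment} frame={k}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.3f} {y:.3f} {z:.3f}\n")


def write_pdb_ca(path, seq: ProteinSequence, positions: np.ndarray) -> None:
    """Write a coarse-grained CA-only PDB snapshot (one bead per residue)."""
    r = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        for i, (aa, (x, y, z)) in enumerate(zip(seq, r), start=1):
            res = seq3(aa).upper()
            fh.write(
                f"ATOM  {i:5d}  CA  {res:<3s} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_series_csv(path, times: np.ndarray, **columns: np.ndarray) -> None:
    """Write scalar time series keyed by an MCS column."""
    df = pd.DataFrame({"mcs": np.asarray(times), **columns})
    df.to_csv(path, index=False)


def read_xyz(path) -> np.ndarray:
    """Read frames back from :func:`write_xyz`; returns (S, N, 3)."""
    frames = []
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        n = int(lines[k])
        block = [ln.split()[1:4] for ln in lines[k + 2:k + 2 + n]]
        frames.append(np.array(block, dtype=float))
        k += 2 + n
    return np.stack(frames)
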