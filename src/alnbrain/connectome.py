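"""Structural-connectome post-processing and I/O.

Tractography-derived fiber-count matrices are directionless and noisy, so the
model substrate is built by (1) symmetrizing by averaging the two directed
entries, (2) removing self-connections, (3) dividing by the maximum entry so
coupling strengths are relative, and (4) converting fiber lengths to axonal
delays with a global signal speed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Connectome

__all__ = [
    "symmetrize",
    "max_normalize",
    "delays_from_lengths",
    "build_connectome",
    "average_connectomes",
    "load_matrix",
    "save_matrix",
    "load_connectome_dir",
    "save_connectome_dir",
]


def symmetrize(M: np.ndarray) -> np.ndarray:
    """Average the (i, j) and (j, i) entries; zero the diagonal."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    if np.any(M < 0):
        raise ValueError("matrix entries must be non-negative")
    S = 0.5 * (M + M.T)
    np.fill_diagonal(S, 0.0)
    return S


def max_normalize(M: np.ndarray) -> np.ndarray:
    """Divide by the maximum matrix entry (all-zero input passes through)."""
    M = np.asarray(M, dtype=float)
    mx = M.max() if M.size else 0.0
    if mx == 0.0:
        warnings.warn("all-zero matrix: max-normalization is a no-op")
        return M.copy()
    return M / mx


def delays_from_lengths(L_mm: np.ndarray, v_gl_m_per_s: float) -> np.ndarray:
    """Delays in ms from fiber lengths in mm at signal speed in m/s.

    1 mm / (1 m/s) = 1 ms, so D_ij = L_ij / v_gl numerically.
    """
    if v_gl_m_per_s <= 0:
        raise ValueError("signal speed must be positive")
    return np.asarray(L_mm, dtype=float) / v_gl_m_per_s


def build_connectome(counts: np.ndarray, lengths_mm: np.ndarray,
                     v_gl_m_per_s: float = 20.0,
                     labels=None) -> Connectome:
    """Full pipeline: symmetrize and max-normalize counts, delays from lengths."""
    C = max_normalize(symmetrize(counts))
    D = delays_from_lengths(symmetrize(lengths_mm), v_gl_m_per_s)
    con = Connectome(C=C, D=D, labels=list(labels) if labels is not None else [])
    con.validate()
    return con


def average_connectomes(matrices) -> np.ndarray:
    """Group-average substrate: mean of normalized individual matrices,
    re-normalized to unit maximum."""
    mats = [max_normalize(symmetrize(m)) for m in matrices]
    return max_normalize(np.mean(mats, axis=0))


def load_matrix(path) -> np.ndarray:
    """Read a square delimited (whitespace or comma) matrix."""
    M = pd.read_csv(path, sep=None, engine="python", header=None).to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {M.shape}")
    return M


def save_matrix(M: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(M), fmt="%.10g", delimiter="\t")


def load_connectome_dir(directory) -> Connectome:
    """Load ``weights.tsv``, ``lengths.tsv`` and optional ``labels.txt``."""
    d = Path(directory)
    counts = load_matrix(d / "weights.tsv")
    lengths = load_matrix(d / "lengths.tsv")
    if counts.shape != lengths.shape:
        raise ValueError("weights and lengths shapes differ")
    labels = None
    if (d / "labels.txt").exists():
        labels = (d / "labels.txt").read_text().split()
        if len(labels) != counts.shape[0]:
            raise ValueError("labels count does not match matrix size")
    return build_connectome(counts, lengths, labels=labels)


def save_connectome_dir(con: Connectome, lengths_mm: np.ndarray, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_matrix(con.C, d / "weights.tsv")
    save_matrix(lengths_mm, d / "lengths.tsv")
    (d / "labels.txt").write_text("\n".join(con.labels) + "\n")
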