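"""Small shared helpers (correlation-matrix repair, seeding, hashing)."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np


def nearest_correlation(corr: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix onto the correlation matrices.

    Eigenvalues below ``min_eig`` are clipped and the diagonal renormalized
    to 1.  A single clip pass is enough for matrices that are only mildly
    indefinite (e.g. rounded printed tables).
    """
    c = np.asarray(corr, dtype=float)
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= min_eig:
        return c
    vals = np.clip(vals, min_eig, None)
    c = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def is_psd(mat: np.ndarray, tol: float = 1e-8) -> bool:
    vals = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    return bool(vals.min() >= -tol)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
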