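"""Population structure: IBS distance and classical (metric) MDS.

The pairwise dissimilarity is the allele-sharing distance
d(i, j) = 1 - (IBS2 + 0.5 IBS1) / n_joint over jointly non-missing
variants; classical MDS double-centres the squared distances and embeds
samples along the top eigenvectors scaled by the square roots of their
(non-negative) eigenvalues.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rohscan.matrix import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - proportion of alleles identical by state, per sample pair."""
    calls = matrix.calls
    obs = calls != MISSING
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        joint = obs[i] & obs[j]
        n_joint = int(joint.sum())
        if n_joint == 0:
            raise ValueError(
                f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
                "share no observed variants"
            )
        diff = np.abs(calls[i, joint].astype(np.int16) - calls[j, joint].astype(np.int16))
        ibs2 = int((diff == 0).sum())
        ibs1 = int((diff == 1).sum())
        d[i, j] = d[j, i] = 1.0 - (ibs2 + 0.5 * ibs1) / n_joint
    return DistanceMatrix(list(matrix.sample_ids), d)


def classical_mds(dist: DistanceMatrix, k_dims: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared distance matrix, eigendecomposes it, and
    returns coordinates on the top ``k_dims`` axes (ordered by
    descending eigenvalue, each scaled by the square root of its
    eigenvalue).  Negative eigenvalues are reported but never used for
    scaling; if fewer than ``k_dims`` positive eigenvalues exist the
    embedding is truncated with a warning.  Sign convention: the first
    nonzero loading of each axis is positive.

    Returns
    -------
    coords : DataFrame indexed by sample with columns C1..Ck.
    eigenvalues : all eigenvalues, descending.
    """
    if k_dims < 1:
        raise ValueError("k_dims must be >= 1")
    d2 = dist.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int((eigvals > 1e-12).sum())
    k = min(k_dims, n_pos)
    if k < k_dims:
        logger.warning(
            "only %d positive eigenvalues; truncating embedding from %d to %d dims",
            n_pos, k_dims, k,
        )
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for axis in range(k):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    frame = pd.DataFrame(
        coords, index=dist.sample_ids, columns=[f"C{a + 1}" for a in range(k)]
    )
    return frame, eigvals
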