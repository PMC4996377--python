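"""Cyclic sliding-window embedding of copy-number sections into point clouds.

A section of ``m`` consecutive log2 ratios ``(y_0, ..., y_{m-1})`` is mapped to
``m`` points in ``R^D`` by the sliding-window (delay) map

    point_j = (y_j, y_{j+1 mod m}, ..., y_{j+D-1 mod m})

The window wraps around: the last ``D - 1`` points borrow their trailing
coordinates from the start of the section, so every section value appears
exactly once in every coordinate slot.  Two consequences drive the method:

* consecutive gains land far from the origin in the all-positive orthant,
  losses in the all-negative one, while noise stays near the origin; and
* the coordinate-wise mean of the cloud (its center of mass) equals the
  section mean in every coordinate, which makes the center of mass a
  whole-arm dosage statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmbeddingConfig",
    "CenterOfMass",
    "embed_section",
    "embed_cohort",
    "center_of_mass",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding parameters.

    Parameters
    ----------
    D
        Window size, i.e. the dimension of the ambient Euclidean space.
        Must satisfy ``1 < D < m`` for every analyzed section.  The default
        of 2 is sufficient in practice: section p-values are highly
        correlated across window sizes (see the window-size experiment in
        :mod:`taacgh.simulate`).
    """

    D: int = 2

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError(f"embedding dimension must be >= 2, got {self.D}")


@dataclass(frozen=True)
class CenterOfMass:
    """Coordinate-wise mean of a point cloud and its Euclidean norm."""

    coords: np.ndarray
    norm: float


def embed_section(values: np.ndarray, cfg: EmbeddingConfig | int = 2) -> np.ndarray:
    """Embed a section of ``m`` values as ``m`` points in ``R^D``.

    Parameters
    ----------
    values
        1-d array of ``m`` log2 ratios in genomic order.
    cfg
        :class:`EmbeddingConfig` or a bare integer window size.

    Returns
    -------
    ndarray of shape ``(m, D)``; row ``j`` is the cyclic window starting at
    ``values[j]``.
    """
    D = cfg.D if isinstance(cfg, EmbeddingConfig) else int(cfg)
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    m = values.shape[0]
    if m <= D:
        raise ValueError(f"section length m={m} must exceed window size D={D}")
    j = np.arange(m)[:, None]
    k = np.arange(D)[None, :]
    return values[(j + k) % m]


def embed_cohort(values: np.ndarray, D: int = 2) -> np.ndarray:
    """Embed one section for every patient at once.

    Parameters
    ----------
    values
        2-d array ``(m, n_patients)`` of section values, one column per
        patient.

    Returns
    -------
    ndarray ``(n_patients, m, D)`` of point clouds.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if m <= D:
        raise ValueError(f"section length m={m} must exceed window size D={D}")
    j = np.arange(m)[:, None]
    k = np.arange(D)[None, :]
    # (m, D, P) -> (P, m, D)
    return values[(j + k) % m].transpose(2, 0, 1)


def center_of_mass(cloud: np.ndarray) -> CenterOfMass:
    """Center of mass of a point cloud.

    For a cloud produced by :func:`embed_section` each coordinate of the
    center equals the arithmetic mean of the section values, so the norm is
    ``|mean| * sqrt(D)``.
    """
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[0] == 0:
        raise ValueError("cloud must be a non-empty (m, D) array")
    coords = cloud.mean(axis=0)
    return CenterOfMass(coords=coords, norm=float(np.linalg.norm(coords)))
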