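"""Shared containers and pair-index helpers.

Region-level signals are stored as plain (n_regions, n_samples) float arrays.
Undirected region pairs are indexed upper-triangle, ``a < b``, 0-based
internally; report writers shift to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionTimeSeries:
    """One subject's region-by-sample matrix.

    Parameters
    ----------
    data : ndarray, shape (n_regions, n_samples)
        Source-level signals, one row per region (mean series of the region).
    fs : float
        Sampling rate in samples/second.
    region_ids : list of str
        Region identifiers, one per row.
    group : str, optional
        Cohort label, e.g. ``"patient"`` or ``"control"``.
    subject_id : str, optional
    """

    data: np.ndarray
    fs: float
    region_ids: list[str] = field(default_factory=list)
    group: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_regions, n_samples) array")
        if not self.region_ids:
            self.region_ids = [f"R{i + 1}" for i in range(self.data.shape[0])]
        if len(self.region_ids) != self.data.shape[0]:
            raise ValueError("region_ids length must match the number of rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def pair_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, in condensed order."""
    return np.triu_indices(n_regions, k=1)


def n_pairs(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def pair_to_condensed(a: int, b: int, n_regions: int) -> int:
    """Condensed position of the unordered pair (a, b), 0-based."""
    if a == b:
        raise ValueError("diagonal entries are not pairs")
    if a > b:
        a, b = b, a
    if not (0 <= a < b < n_regions):
        raise ValueError("pair indices out of range")
    # offset of row a in the condensed upper triangle
    return a * n_regions - a * (a + 1) // 2 + (b - a - 1)


@dataclass
class ConnectivityTensor:
    """Per-subject edge values for every metric configuration.

    ``values`` maps a metric-configuration id to an
    (n_subjects, n_pairs) array in condensed pair order.
    """

    values: dict[str, np.ndarray]
    subjects: list[str]
    groups: list[str]
    region_ids: list[str]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.groups])
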