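"""Radial binning for kernel RDF estimators.

The radial axis is divided into ``B`` contiguous bins of uniform width
``delta`` starting at ``r_lo``.  Every histogram, target RDF and Lagrange
multiplier vector in this package lives on such a grid.  Bins are half-open
``[lo, hi)``; in documentation bins are numbered 1..B, while all array code
uses 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RDFGrid", "RDFHistogram", "bin_volume", "kernel_split"]


@dataclass(frozen=True)
class RDFGrid:
    """Uniform radial binning.

    Parameters
    ----------
    n_bins : int
        Number of bins ``B`` (at least 2).
    delta : float
        Bin width in length units, strictly positive.
    r_lo : float, optional
        Lower edge of the first bin (default 0).
    """

    n_bins: int
    delta: float
    r_lo: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"need at least 2 bins, got {self.n_bins}")
        if not self.delta > 0:
            raise ValueError(f"bin width must be positive, got {self.delta}")
        if self.r_lo < 0:
            raise ValueError(f"r_lo must be non-negative, got {self.r_lo}")

    @property
    def r_hi(self) -> float:
        """Upper edge of the last bin."""
        return self.r_lo + self.n_bins * self.delta

    @property
    def centers(self) -> np.ndarray:
        """Bin centers ``r_b = r_lo + (b - 1/2) * delta``."""
        return self.r_lo + (np.arange(self.n_bins) + 0.5) * self.delta

    @property
    def edges(self) -> np.ndarray:
        """The ``B + 1`` bin edges."""
        return self.r_lo + np.arange(self.n_bins + 1) * self.delta

    @property
    def bin_volumes(self) -> np.ndarray:
        """Spherical-shell volume of every bin."""
        e = self.edges
        return (4.0 * np.pi / 3.0) * (e[1:] ** 3 - e[:-1] ** 3)

    def locate(self, r: np.ndarray) -> np.ndarray:
        """0-based containing-bin index of each distance (no range check)."""
        return np.floor((np.asarray(r) - self.r_lo) / self.delta).astype(np.intp)

    def check_box(self, box: np.ndarray) -> None:
        """Reject grids wider than half the smallest box length.

        Minimum-image distances are only unique below L/2; a grid reaching
        past that would silently miss periodic images.
        """
        half = 0.5 * float(np.min(box))
        if self.r_hi > half * (1 + 1e-12):
            raise ValueError(
                f"grid range {self.r_hi:g} exceeds half the smallest box "
                f"length {half:g}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RDFGrid):
            return NotImplemented
        return (
            self.n_bins == other.n_bins
            and np.isclose(self.delta, other.delta, rtol=1e-12, atol=0.0)
            and np.isclose(self.r_lo, other.r_lo, rtol=0.0, atol=1e-12 * self.delta)
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((self.n_bins, round(self.delta, 15), round(self.r_lo, 15)))


def bin_volume(grid: RDFGrid, b: int) -> float:
    """Volume of the spherical shell spanned by bin ``b`` (1-based).

    ``(4π/3) [(r_b + Δ/2)³ − (r_b − Δ/2)³]``, strictly positive and
    increasing in ``b``.
    """
    if not 1 <= b <= grid.n_bins:
        raise IndexError(f"bin index {b} outside 1..{grid.n_bins}")
    return float(grid.bin_volumes[b - 1])


def kernel_split(r: float, grid: RDFGrid) -> list[tuple[int, float]]:
    """Split one pair distance over bins with the rectangular kernel.

    The kernel is a rectangle of width Δ (the bin width) centred at ``r``
    with unit area.  Unless ``r`` sits exactly at a bin center, the rectangle
    overlaps two adjacent bins; the contribution to each bin is the kernel
    area inside it.  Returns ``[(bin, fraction), ...]`` with 1-based bin
    indices; fractions sum to 1 unless the rectangle is truncated at a grid
    end (the out-of-grid fraction is dropped).

    A distance exactly on an interior bin edge splits 0.5/0.5 between the
    two bins sharing the edge.
    """
    if not grid.r_lo <= r < grid.r_hi:
        raise ValueError(f"distance {r} outside grid range [{grid.r_lo}, {grid.r_hi})")
    b0 = int((r - grid.r_lo) // grid.delta)
    b0 = min(b0, grid.n_bins - 1)
    u = r - (grid.r_lo + (b0 + 0.5) * grid.delta)
    frac_adj = abs(u) / grid.delta
    out: list[tuple[int, float]] = [(b0 + 1, 1.0 - frac_adj)]
    if frac_adj > 0.0:
        adj = b0 + 1 if u > 0 else b0 - 1
        if 0 <= adj < grid.n_bins:
            out.append((adj + 1, frac_adj))
    return out


@dataclass
class RDFHistogram:
    """RDF intensities on a grid.

    ``values[b]`` is the (dimensionless) pair density relative to an ideal
    gas; the expectation for uncorrelated uniform particles is 1 in every
    bin.  Used for instantaneous, time-averaged and target RDFs alike.
    """

    grid: RDFGrid
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values is None:
            self.values = np.zeros(self.grid.n_bins)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.grid.n_bins} bins"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("histogram values must be finite")

    @property
    def r(self) -> np.ndarray:
        return self.grid.centers

    def copy(self) -> "RDFHistogram":
        return RDFHistogram(self.grid, self.values.copy())
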