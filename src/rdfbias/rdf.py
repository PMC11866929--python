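"""Kernel RDF estimation.

The instantaneous RDF of a frame is a histogram over pair distances where
every distance is spread with a rectangular kernel of one bin width — the
estimator stays differentiable in the pair distances, which is what lets
the same histogram serve as a bias potential with exact forces.

Normalisation: a pair of species (α, β) contributes

    w^{αβ} · 2V / (N_α N'_β V_b)

to bin ``b`` per unit kernel fraction, where ``N'_β = N_β`` for unlike
species and ``N_α − 1`` for like species (ordered pairs without
self-pairs).  With the pair weights summing to 1, the expectation of
every bin is exactly 1 for uncorrelated uniform particles — including at
small N, where the macroscopic N² normalisation would bias the estimator
by a factor N/(N−1).
"""

from __future__ import annotations

import logging

import numpy as np

from .frames import Frame, pair_table
from .grid import RDFGrid, RDFHistogram
from .weighting import SpeciesWeighting

__all__ = ["instantaneous_rdf", "pair_norm_weights", "kernel_accumulate",
           "RunningAverage"]

log = logging.getLogger(__name__)
_truncation_logged = False


def pair_norm_weights(
    species: np.ndarray,
    weighting: SpeciesWeighting,
    i: np.ndarray,
    j: np.ndarray,
) -> np.ndarray:
    """Per-pair normalisation weight, excluding the volume factor.

    Returns ``w^{αβ} · 2 / (N_α N'_β)`` for every listed pair; multiply by
    the instantaneous volume to obtain the full weight.  Species content is
    fixed along a trajectory, so this is computed once and reused.
    """
    labels = np.asarray(species, dtype=str)
    uniq, counts = np.unique(labels, return_counts=True)
    n_of = dict(zip(uniq.tolist(), counts.tolist()))
    if weighting.mode == "identical":
        n = labels.shape[0]
        return np.full(i.shape[0], 2.0 / (n * (n - 1)))
    known = {s for pair in weighting.pair_weights for s in pair}
    unknown = [s for s in uniq.tolist() if s not in known]
    if unknown:
        raise KeyError(f"species {unknown} have no pair weights in this weighting")
    base = {}
    for a in uniq:
        for b in uniq:
            na = n_of[a]
            nb = n_of[b] if a != b else n_of[a] - 1
            if nb == 0:
                continue
            base[(a, b)] = weighting.weight(a, b) * 2.0 / (na * nb)
    si, sj = labels[i], labels[j]
    out = np.empty(i.shape[0])
    for (a, b), w in base.items():
        if a <= b:
            mask = ((si == a) & (sj == b)) | ((si == b) & (sj == a))
            out[mask] = w
    return out


def kernel_accumulate(
    r: np.ndarray,
    weights: np.ndarray,
    grid: RDFGrid,
) -> np.ndarray:
    """Spread weighted distances over bins with the rectangular kernel.

    Every pair whose kernel rectangle overlaps the grid contributes its
    in-grid overlap — including pairs up to half a bin beyond either grid
    end, whose partial overlap is what keeps the expectation of the edge
    bins at the ideal-gas value.  Kernel mass falling outside the grid is
    dropped, not renormalised (logged once per process).  Returns the
    per-bin weighted kernel mass (not yet divided by bin volumes).

    Equivalent to cloud-in-cell (linear) binning: with
    ``t = (r − r_lo)/Δ − 1/2``, the pair splits between bins ``⌊t⌋`` and
    ``⌊t⌋ + 1`` (0-based) with weights ``1 − frac(t)`` and ``frac(t)``.
    """
    global _truncation_logged
    t = (r - grid.r_lo) / grid.delta - 0.5
    keep = (t > -1.0) & (t < grid.n_bins)
    t = t[keep]
    w = weights[keep]
    k0 = np.floor(t)
    f1 = t - k0
    k0 = k0.astype(np.intp)
    # accumulate on a padded axis: slot 0 and slot B+1 catch off-grid spill
    padded = np.bincount(k0 + 1, weights=w * (1.0 - f1),
                         minlength=grid.n_bins + 2)
    padded += np.bincount(k0 + 2, weights=w * f1,
                          minlength=grid.n_bins + 2)
    if not _truncation_logged and (padded[0] > 0 or padded[grid.n_bins + 1] > 0):
        log.info("kernel mass truncated at grid ends (reported once)")
        _truncation_logged = True
    return padded[1 : grid.n_bins + 1]


def instantaneous_rdf(
    frame: Frame,
    grid: RDFGrid,
    weighting: SpeciesWeighting | None = None,
    pairs: pair_table | None = None,
    norm_weights: np.ndarray | None = None,
) -> RDFHistogram:
    """Kernel RDF of a single frame.

    ``pairs`` and ``norm_weights`` let callers reuse precomputed pair
    geometry and species weights along a trajectory.
    """
    weighting = weighting or SpeciesWeighting.identical()
    grid.check_box(frame.box)
    if pairs is None:
        pairs = pair_table(frame)
    if norm_weights is None:
        norm_weights = pair_norm_weights(frame.species, weighting, pairs.i, pairs.j)
    w = norm_weights * frame.volume
    mass = kernel_accumulate(pairs.r, w, grid)
    return RDFHistogram(grid, mass / grid.bin_volumes)


class RunningAverage:
    """Unweighted mean of a stream of histograms on a shared grid.

    The bias controller samples the instantaneous RDF every few steps and
    averages a window of samples per multiplier update; the average resets
    after each update.
    """

    def __init__(self, grid: RDFGrid):
        self.grid = grid
        self._sum = np.zeros(grid.n_bins)
        self.count = 0

    def add(self, hist: RDFHistogram) -> None:
        if hist.grid != self.grid:
            raise ValueError("histogram grid does not match running average grid")
        self._sum += hist.values
        self.count += 1

    def add_values(self, values: np.ndarray) -> None:
        self._sum += values
        self.count += 1

    def mean(self) -> RDFHistogram:
        if self.count == 0:
            raise RuntimeError("running average is empty")
        return RDFHistogram(self.grid, self._sum / self.count)

    def reset(self) -> None:
        self._sum[:] = 0.0
        self.count = 0
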