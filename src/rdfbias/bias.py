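"""Linear maximum-relative-entropy bias: energy, forces, virial.

The maximum relative entropy principle selects, among all ensembles whose
mean RDF matches a target, the one closest (in Kullback–Leibler
divergence) to the unbiased ensemble.  The result is a bias that is
*linear* in the constrained observables,

    E_bias = Σ_b λ̂_b g_b ,

where ``g_b`` is the instantaneous kernel RDF (with species weighting)
and λ̂_b are Lagrange multipliers in energy units.  Because the
rectangular kernel makes each ``g_b`` piecewise linear in every pair
distance, the exact forces are pairwise and central, with each pair
feeling only the multipliers of the (at most) two bins its kernel
touches: for a pair in bin b̂ with offset ``u = r_ij − r_b̂`` the force
magnitude is ``−(W_ij/Δ)(λ̂_b′/V_b′ − λ̂_b̂/V_b̂)`` toward/away along
r̂_ij, b′ being the neighbour bin on the side of ``u``.

The bias also contributes a virial ``T_ME = (1/d) Σ_pairs r_ij·F_ij``
that adds to the physical virial when a barostat is active; its per-bin
decomposition ``T_ME^b`` (the terms generated by each λ̂_b) is what the
controller's optional κ damping inspects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import Frame, _HAVE_NUMBA, _njit, pair_table
from .grid import RDFGrid
from .rdf import kernel_accumulate, pair_norm_weights
from .weighting import SpeciesWeighting

__all__ = ["BiasState", "VirialReport", "bias_energy", "bias_forces",
           "bias_virial", "bias_terms", "MaxEntBiasProvider"]

#: Pairs closer than this fraction of a bin width are excluded from the
#: force (r̂_ij is ill-defined at r → 0; such overlaps never occur in a
#: healthy LJ run).
MIN_DISTANCE_FACTOR = 1e-6


@dataclass
class BiasState:
    """Lagrange multipliers λ̂ (energy units) on an RDF grid."""

    grid: RDFGrid
    lambda_hat: np.ndarray = field(default=None)  # type: ignore[assignment]
    weighting: SpeciesWeighting = field(default_factory=SpeciesWeighting.identical)
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.lambda_hat is None:
            self.lambda_hat = np.zeros(self.grid.n_bins)
        self.lambda_hat = np.asarray(self.lambda_hat, dtype=float)
        if self.lambda_hat.shape != (self.grid.n_bins,):
            raise ValueError("lambda_hat must have one entry per bin")
        if not np.all(np.isfinite(self.lambda_hat)):
            raise ValueError("lambda_hat must be finite")


@dataclass
class VirialReport:
    """Total bias virial and its per-bin decomposition (energy units)."""

    total: float
    per_bin: np.ndarray

    @classmethod
    def zero(cls, n_bins: int) -> "VirialReport":
        return cls(0.0, np.zeros(n_bins))


@_njit(cache=True)
def _fused_pair_terms(r, w, lam_v, n_bins, delta, r_lo, min_r):
    """One pass over pairs: kernel mass, pair forces, per-bin virial.

    Cloud-in-cell split: the pair's kernel overlaps bins k0 and k0+1
    (0-based, either possibly off-grid with the spilled mass dropped);
    dE/dr = (W/Δ)(λ̂_{k0+1}/V_{k0+1} − λ̂_{k0}/V_{k0}) with off-grid
    multipliers treated as zero.
    """
    mass = np.zeros(n_bins)
    per_bin = np.zeros(n_bins)
    pair_force = np.zeros(r.shape[0])
    total = 0.0
    third = 1.0 / 3.0
    for k in range(r.shape[0]):
        rk = r[k]
        t = (rk - r_lo) / delta - 0.5
        if t <= -1.0 or t >= n_bins:
            continue
        k0 = int(np.floor(t))
        f1 = t - k0
        k1 = k0 + 1
        wk = w[k]
        lam0 = 0.0
        lam1 = 0.0
        if k0 >= 0:
            mass[k0] += wk * (1.0 - f1)
            lam0 = lam_v[k0]
        if k1 < n_bins:
            mass[k1] += wk * f1
            lam1 = lam_v[k1]
        if rk <= min_r:
            continue
        dedr = wk / delta * (lam1 - lam0)
        pair_force[k] = -dedr
        if k0 >= 0:
            per_bin[k0] += third * rk * wk / delta * lam0
        if k1 < n_bins:
            per_bin[k1] -= third * rk * wk / delta * lam1
        total -= third * rk * dedr
    return mass, pair_force, per_bin, total


def bias_terms(
    frame: Frame,
    state: BiasState,
    pairs: pair_table | None = None,
    norm_weights: np.ndarray | None = None,
    norm_volume: float | None = None,
) -> tuple[float, np.ndarray, VirialReport]:
    """Energy, forces and virial of the linear bias in one pass.

    ``norm_volume`` overrides the volume used in the RDF normalisation
    (default: the frame's volume).  The kernel RDF references the ensemble
    volume through its ideal-gas normalisation; the virial differentiates
    only through the pair distances, so consistency checks that scale
    positions and box must hold the normalisation volume fixed.
    """
    grid = state.grid
    grid.check_box(frame.box)
    if pairs is None:
        pairs = pair_table(frame)
    if norm_weights is None:
        norm_weights = pair_norm_weights(
            frame.species, state.weighting, pairs.i, pairs.j
        )
    volume = frame.volume if norm_volume is None else norm_volume
    w_full = norm_weights * volume
    lam_v = state.lambda_hat / grid.bin_volumes  # λ̂_b / V_b
    min_r = MIN_DISTANCE_FACTOR * grid.delta

    if _HAVE_NUMBA:
        mass, pair_force, per_bin, total = _fused_pair_terms(
            pairs.r, w_full, lam_v, grid.n_bins, grid.delta, grid.r_lo, min_r
        )
        energy = float(np.dot(state.lambda_hat, mass / grid.bin_volumes))
        idx = np.nonzero(pair_force)[0]
        forces = pairs.scatter_forces(pair_force[idx], idx)
        return energy, forces, VirialReport(total=float(total), per_bin=per_bin)

    # numpy reference path
    # energy: E = Σ_b λ̂_b g_b with g_b from the kernel histogram
    mass = kernel_accumulate(pairs.r, w_full, grid)
    g = mass / grid.bin_volumes
    energy = float(np.dot(state.lambda_hat, g))

    # forces: every pair whose kernel overlaps the grid contributes
    r = pairs.r
    t_all = (r - grid.r_lo) / grid.delta - 0.5
    in_range = (t_all > -1.0) & (t_all < grid.n_bins) & (r > min_r)
    idx = np.nonzero(in_range)[0]
    rr = r[idx]
    ww = w_full[idx]
    k0 = np.floor(t_all[idx]).astype(np.intp)
    k1 = k0 + 1
    lam0 = np.where(k0 >= 0, lam_v[np.clip(k0, 0, grid.n_bins - 1)], 0.0)
    lam1 = np.where(k1 < grid.n_bins, lam_v[np.clip(k1, 0, grid.n_bins - 1)], 0.0)
    # dE/dr_ij = (W/Δ) · (λ̂_{k1}/V_{k1} − λ̂_{k0}/V_{k0})
    dEdr = ww / grid.delta * (lam1 - lam0)
    forces = pairs.scatter_forces(-dEdr, idx)  # force on atom i along +r̂_ij

    # virial: T = (1/3) Σ r_ij · F_ij = −(1/3) Σ r dE/dr, split by the bin
    # whose λ̂ generated each of the two boundary terms
    base = (1.0 / 3.0) * rr * ww / grid.delta
    padded = np.bincount(k0 + 1, weights=base * lam0,
                         minlength=grid.n_bins + 2)
    padded -= np.bincount(k1 + 1, weights=base * lam1,
                          minlength=grid.n_bins + 2)
    per_bin = padded[1 : grid.n_bins + 1]
    total = float(-np.sum((1.0 / 3.0) * rr * dEdr))
    return energy, forces, VirialReport(total=total, per_bin=per_bin)


def bias_energy(frame: Frame, state: BiasState, **kw) -> float:
    """``Σ_b λ̂_b g_b(frame)`` — linear in λ̂."""
    return bias_terms(frame, state, **kw)[0]


def bias_forces(frame: Frame, state: BiasState, **kw) -> np.ndarray:
    """Exact forces ``F_i = −∂E_bias/∂r_i`` (pairwise, central)."""
    return bias_terms(frame, state, **kw)[1]


def bias_virial(frame: Frame, state: BiasState, **kw) -> VirialReport:
    """Total bias virial and its per-bin decomposition."""
    return bias_terms(frame, state, **kw)[2]


class MaxEntBiasProvider:
    """Force-provider adapter: ``(frame, pairs) -> (energy, forces, virial)``.

    Satisfies the same contract as the physical force providers so any
    engine can compose the bias with its interaction model.  Species
    normalisation weights are cached on first use (species content must
    not change along a run).
    """

    def __init__(self, state: BiasState):
        self.state = state
        self._norm_weights: np.ndarray | None = None

    def __call__(self, frame: Frame, pairs: pair_table | None = None):
        if not self.state.enabled or not np.any(self.state.lambda_hat):
            n = frame.n_atoms
            if pairs is None:
                pairs = pair_table(frame)
            return 0.0, np.zeros((n, 3)), VirialReport.zero(self.state.grid.n_bins)
        if pairs is None:
            pairs = pair_table(frame)
        if self._norm_weights is None or self._norm_weights.shape[0] != pairs.r.shape[0]:
            self._norm_weights = pair_norm_weights(
                frame.species, self.state.weighting, pairs.i, pairs.j
            )
        energy, forces, virial = bias_terms(
            frame, self.state, pairs=pairs, norm_weights=self._norm_weights
        )
        return energy, forces, virial
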