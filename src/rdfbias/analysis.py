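"""Trajectory diagnostics: MAE, ADF, diffusion, bond order, phase labels.

Everything here is a pure function of saved trajectories — re-running on
the same frames is bit-stable — and none of it feeds back into the bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y
from scipy.stats import linregress

from .frames import Frame, minimum_image
from .grid import RDFHistogram

__all__ = ["ADFHistogram", "BoopResult", "mae", "adf",
           "mean_squared_displacement", "diffusion_coefficient",
           "qlbar", "classify_phase"]


@dataclass
class ADFHistogram:
    """Angular distribution: normalised density over (0°, 180°]."""

    theta: np.ndarray  # bin centers, degrees
    density: np.ndarray  # integrates to 1 over degrees
    cutoff: float

    @property
    def bin_width(self) -> float:
        return float(self.theta[1] - self.theta[0])


@dataclass
class BoopResult:
    """Per-atom averaged local bond-order parameters q̄_l."""

    q: np.ndarray  # value per included atom
    atoms: np.ndarray  # indices of included atoms
    l: int
    neighbor_rule: dict
    excluded: np.ndarray  # isolated atoms, reported not silently dropped


def mae(a, b) -> float:
    """Mean absolute error between two histograms on one grid.

    Symmetric, zero iff identical, and obeys the triangle inequality —
    the convergence measure for RDF matching and the RDF/ADF agreement
    score."""
    if isinstance(a, RDFHistogram) and isinstance(b, RDFHistogram):
        if a.grid != b.grid:
            raise ValueError("histograms live on different grids")
        return float(np.mean(np.abs(a.values - b.values)))
    if isinstance(a, ADFHistogram) and isinstance(b, ADFHistogram):
        if a.theta.shape != b.theta.shape or not np.allclose(a.theta, b.theta):
            raise ValueError("ADF histograms live on different angle grids")
        return float(np.mean(np.abs(a.density - b.density)))
    raise TypeError("mae expects two RDFHistogram or two ADFHistogram objects")


def _neighbor_pairs_within(frame: Frame, indices: np.ndarray, cutoff: float):
    """KD-tree neighbour lists in a periodic box."""
    pos = frame.positions[indices]
    tree = cKDTree(pos, boxsize=frame.box)
    return tree.query_pairs(cutoff, output_type="ndarray")


def adf(
    frames: list[Frame] | Frame,
    species: str | None = None,
    cutoff: float = 1.5,
    bin_width_deg: float = 2.0,
) -> ADFHistogram:
    """Angular distribution of neighbour–central–neighbour angles.

    For every central atom, every unordered pair of neighbours within
    ``cutoff`` contributes the angle it subtends at the center.  The
    histogram is normalised to unit integral over θ in degrees.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    n_bins = int(round(180.0 / bin_width_deg))
    counts = np.zeros(n_bins)
    total = 0
    for frame in frames:
        if cutoff > 0.5 * float(np.min(frame.box)):
            raise ValueError("cutoff exceeds half the smallest box length")
        if species is None:
            idx = np.arange(frame.n_atoms)
        else:
            idx = np.nonzero(frame.species.astype(str) == species)[0]
        pairs = _neighbor_pairs_within(frame, idx, cutoff)
        if pairs.shape[0] == 0:
            continue
        # gather neighbours per central atom
        nb: dict[int, list[int]] = {}
        for a, b in pairs:
            nb.setdefault(a, []).append(b)
            nb.setdefault(b, []).append(a)
        for center, neigh in nb.items():
            if len(neigh) < 2:
                continue
            vecs = minimum_image(
                frame.positions[idx[neigh]] - frame.positions[idx[center]],
                frame.box,
            )
            vecs /= np.linalg.norm(vecs, axis=1)[:, None]
            m = len(neigh)
            iu, ju = np.triu_indices(m, k=1)
            cosang = np.clip(np.sum(vecs[iu] * vecs[ju], axis=1), -1.0, 1.0)
            ang = np.degrees(np.arccos(cosang))
            b_idx = np.clip((ang / bin_width_deg).astype(int), 0, n_bins - 1)
            counts += np.bincount(b_idx, minlength=n_bins)
            total += ang.shape[0]
    if total == 0:
        raise ValueError("no atom has at least two neighbours within the cutoff")
    density = counts / (total * bin_width_deg)
    theta = (np.arange(n_bins) + 0.5) * bin_width_deg
    return ADFHistogram(theta=theta, density=density, cutoff=cutoff)


def mean_squared_displacement(positions: np.ndarray) -> np.ndarray:
    """FFT-based MSD over all lags, averaged over atoms and time origins.

    ``positions`` must be unwrapped, shape (n_frames, n_atoms, 3).  Uses
    the standard decomposition MSD(m) = S1(m) − 2·ACF(m) with the
    autocorrelation evaluated by FFT, so all time origins contribute at
    O(N log N) cost.
    """
    pos = np.asarray(positions, dtype=float)
    n_t, n_atoms, _ = pos.shape
    nfft = 1 << (2 * n_t - 1).bit_length()
    acf = np.zeros((n_t, n_atoms))
    for c in range(3):
        f = np.fft.fft(pos[:, :, c], n=nfft, axis=0)
        acf += np.fft.ifft(f * np.conj(f), axis=0)[:n_t].real
    sq = np.sum(pos**2, axis=2)  # |r_k|² per frame and atom
    sq_ext = np.vstack([sq, np.zeros((1, n_atoms))])
    q = 2.0 * sq.sum(axis=0)
    s1 = np.empty((n_t, n_atoms))
    for m in range(n_t):
        if m > 0:
            q = q - sq_ext[m - 1] - sq_ext[n_t - m]
        s1[m] = q
    counts = (n_t - np.arange(n_t)).astype(float)[:, None]
    msd = (s1 - 2.0 * acf) / counts
    return msd.mean(axis=1)


@dataclass
class DiffusionResult:
    d: float
    slope: float
    r_squared: float
    loglog_exponent: float  # ~1 in the diffusive regime
    flagged: bool  # sub-linear or super-linear MSD in the fit window

    def __float__(self) -> float:
        return self.d


def diffusion_coefficient(
    positions: np.ndarray,
    dt: float,
    fit_window: tuple[float, float] = (0.5, 1.0),
) -> DiffusionResult:
    """Einstein-relation diffusion coefficient D = slope/(2d), d = 3.

    ``positions``: unwrapped (n_frames, n_atoms, 3) at uniform spacing
    ``dt``.  The least-squares line is fitted over the fractional lag
    range ``fit_window`` (default: the second half of the lag range,
    where the diffusive regime should hold).  The result is flagged
    instead of failing when the fit is poor (R² < 0.9) or when the
    log–log exponent of MSD(t) in the window strays from the diffusive
    value 1 by more than 0.3 (ballistic or caged motion).
    """
    msd = mean_squared_displacement(positions)
    if np.allclose(msd, 0.0):
        return DiffusionResult(0.0, 0.0, 1.0, 1.0, False)
    lags = np.arange(msd.shape[0]) * dt
    lo = max(int(fit_window[0] * msd.shape[0]), 1)
    hi = max(int(fit_window[1] * msd.shape[0]), lo + 2)
    fit = linregress(lags[lo:hi], msd[lo:hi])
    r2 = fit.rvalue**2
    positive = msd[lo:hi] > 0
    exponent = float(
        linregress(np.log(lags[lo:hi][positive]),
                   np.log(msd[lo:hi][positive])).slope
    )
    return DiffusionResult(
        d=float(fit.slope) / 6.0,
        slope=float(fit.slope),
        r_squared=float(r2),
        loglog_exponent=exponent,
        flagged=bool(r2 < 0.9 or abs(exponent - 1.0) > 0.3),
    )


def _neighbors(frame: Frame, neighbor_rule: dict) -> list[np.ndarray]:
    """Neighbour index lists per atom, by cutoff or k-nearest."""
    tree = cKDTree(frame.positions, boxsize=frame.box)
    n = frame.n_atoms
    if "cutoff" in neighbor_rule:
        pairs = tree.query_pairs(float(neighbor_rule["cutoff"]),
                                 output_type="ndarray")
        lists: list[list[int]] = [[] for _ in range(n)]
        for a, b in pairs:
            lists[a].append(b)
            lists[b].append(a)
        return [np.asarray(l, dtype=int) for l in lists]
    if "knn" in neighbor_rule:
        k = int(neighbor_rule["knn"])
        _, idx = tree.query(frame.positions, k=k + 1)
        return [row[1:] for row in idx]  # drop self
    raise ValueError("neighbor_rule needs a 'cutoff' or 'knn' key")


def qlbar(frame: Frame, l: int = 6, neighbor_rule: dict | None = None) -> BoopResult:
    """Averaged local Steinhardt bond-order parameter q̄_l per atom.

    Steinhardt's complex bond-order vector
    ``q_lm(i) = ⟨Y_lm(r̂_ij)⟩_{j∈nb(i)}`` is averaged over the atom and
    its neighbours (the Lechner–Dellago construction), then contracted:

        q̄_l(i) = sqrt( 4π/(2l+1) Σ_m |⟨q_lm⟩_{{i}∪nb(i)}|² )

    The averaging step smears out thermal noise and separates liquid from
    crystalline environments far more cleanly than bare q_l.
    Rotation-invariant; atoms without neighbours are excluded and
    reported.  ``neighbor_rule``: ``{"cutoff": r}`` or ``{"knn": k}``
    (default 12 nearest neighbours).
    """
    if l % 2 != 0 or l < 2:
        raise ValueError("l must be a positive even integer")
    neighbor_rule = neighbor_rule or {"knn": 12}
    neigh = _neighbors(frame, neighbor_rule)
    n = frame.n_atoms
    counts = np.array([len(x) for x in neigh])
    # flat bond list i -> j
    src = np.repeat(np.arange(n), counts)
    dst = np.concatenate([x for x in neigh if len(x)]) if counts.sum() else np.empty(0, int)
    vec = minimum_image(frame.positions[dst] - frame.positions[src], frame.box)
    r = np.linalg.norm(vec, axis=1)
    theta = np.arccos(np.clip(vec[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(vec[:, 1], vec[:, 0])
    ms = np.arange(-l, l + 1)
    qlm = np.zeros((n, ms.shape[0]), dtype=complex)
    for k, m in enumerate(ms):
        y = sph_harm_y(l, m, theta, phi)
        qlm[:, k] = (
            np.bincount(src, weights=y.real, minlength=n)
            + 1j * np.bincount(src, weights=y.imag, minlength=n)
        )
    has = counts > 0
    qlm[has] /= counts[has, None]
    # Lechner–Dellago averaging over {i} ∪ nb(i)
    qbar_lm = qlm.copy()
    for k in range(ms.shape[0]):
        qbar_lm[:, k] += (
            np.bincount(src, weights=qlm[dst, k].real, minlength=n)
            + 1j * np.bincount(src, weights=qlm[dst, k].imag, minlength=n)
        )
    qbar_lm[has] /= (counts[has] + 1)[:, None]
    qbar = np.sqrt(4.0 * np.pi / (2 * l + 1) * np.sum(np.abs(qbar_lm) ** 2, axis=1))
    return BoopResult(
        q=qbar[has],
        atoms=np.nonzero(has)[0],
        l=l,
        neighbor_rule=dict(neighbor_rule),
        excluded=np.nonzero(~has)[0],
    )


#: classification thresholds in common use: q̄6 > 0.07 (water/ice,
#: cutoff 3.5 Å), q̄8 > 0.073 (rutile, 12 NN), q̄10 > 0.085 (anatase, 12 NN)
PHASE_THRESHOLD_PRESETS = {"q6_ice": 0.07, "q8_rutile": 0.073, "q10_anatase": 0.085}


def classify_phase(boop: BoopResult, threshold: float) -> dict:
    """Label atoms solid (q̄_l > threshold) or liquid; report solid fraction."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    solid = boop.q > threshold
    labels = np.where(solid, "solid", "liquid")
    return {
        "labels": labels,
        "atoms": boop.atoms,
        "solid_fraction": float(np.mean(solid)) if solid.size else 0.0,
    }
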