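"""Target RDF generation: reference simulations and broadened lattices.

Two desk-scale sources of targets, both self-contained:

* :func:`reference_run_target` — time-averaged kernel RDF of an unbiased
  reference simulation (e.g. a Lennard-Jones liquid with the interaction
  parameters one wants another system to mimic);
* :func:`lattice_target` — analytic crystalline target built from the
  coordination shells of an ideal lattice, each shell broadened by a
  Gaussian.  Mathematically the same object as the RDF of a cold crystal
  (a sharply peaked g̃^target), without needing a low-temperature run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .engine import EngineConfig, Frame, MDEngine, lattice_positions
from .grid import RDFGrid, RDFHistogram
from .rdf import RunningAverage, instantaneous_rdf
from .weighting import SpeciesWeighting

__all__ = ["LatticeSpec", "lattice_shells", "lattice_target",
           "reference_run_target", "equilibrated_lj_frame"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LatticeSpec:
    """Broadened-lattice target: which lattice, how spaced, how sharp.

    ``spacing`` is the nearest-neighbour distance, ``sigma`` the Gaussian
    broadening width (same length units) and ``n_shells`` how many
    coordination shells to include.
    """

    lattice: str = "fcc"
    spacing: float = 1.1
    sigma: float = 0.08
    n_shells: int = 8

    def __post_init__(self) -> None:
        if self.lattice not in ("fcc", "bcc", "sc", "hcp"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.spacing <= 0 or self.sigma <= 0:
            raise ValueError("spacing and sigma must be positive")
        if self.n_shells < 1:
            raise ValueError("need at least one shell")


def _unit_cell(lattice: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Cell vectors, fractional basis, and NN distance in cell units."""
    if lattice == "sc":
        cell = np.eye(3)
        basis = np.zeros((1, 3))
        nn = 1.0
    elif lattice == "bcc":
        cell = np.eye(3)
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0.5]])
        nn = np.sqrt(3.0) / 2.0
    elif lattice == "fcc":
        cell = np.eye(3)
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
        nn = np.sqrt(2.0) / 2.0
    elif lattice == "hcp":
        # ideal c/a = sqrt(8/3), a = NN distance
        c_over_a = np.sqrt(8.0 / 3.0)
        cell = np.array(
            [[1.0, 0.0, 0.0],
             [0.5, np.sqrt(3.0) / 2.0, 0.0],
             [0.0, 0.0, c_over_a]]
        )
        basis = np.array([[0, 0, 0], [1.0 / 3.0, 1.0 / 3.0, 0.5]])
        nn = 1.0
    else:  # pragma: no cover - guarded by LatticeSpec
        raise ValueError(lattice)
    return cell, basis, nn


def lattice_shells(
    lattice: str, spacing: float, n_shells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Radii and coordination numbers of the first ``n_shells`` shells.

    Computed by tiling the ideal lattice around an atom at the origin and
    counting neighbour distances — no tabulated shell data.
    """
    cell, basis, nn = _unit_cell(lattice)
    scale = spacing / nn
    reach = int(np.ceil(n_shells ** (1.0 / 3.0))) + 3
    shifts = np.arange(-reach, reach + 1)
    gx, gy, gz = np.meshgrid(shifts, shifts, shifts, indexing="ij")
    cells = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
    frac = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    pts = scale * frac @ cell
    d = np.linalg.norm(pts, axis=1)
    d = d[d > 1e-9 * spacing]
    d = np.sort(d)
    radii, counts = np.unique(np.round(d / spacing, 6), return_counts=True)
    radii = radii[:n_shells] * spacing
    counts = counts[:n_shells]
    if radii.shape[0] < n_shells:
        raise ValueError("tiling reach too small for requested shell count")
    return radii, counts.astype(float)


def lattice_density(spec: LatticeSpec) -> float:
    """Number density of the ideal lattice described by ``spec``."""
    cell, basis, nn = _unit_cell(spec.lattice)
    scale = spec.spacing / nn
    vol = abs(np.linalg.det(scale * cell))
    return basis.shape[0] / vol


def lattice_target(
    spec: LatticeSpec, density: float, grid: RDFGrid
) -> RDFHistogram:
    """Gaussian-broadened lattice-shell RDF on a grid.

    Each shell k at radius r_k with coordination z_k contributes

        g(r) += z_k / (4π r² ρ) · N(r; r_k, σ)

    binned by exact Gaussian mass per bin, so integrating
    ``g(r)·4πr²ρ`` over a peak recovers z_k independent of σ.  Shells
    beyond the grid range are dropped; a σ much thinner than the bin
    width triggers a warning (peaks thinner than bins give noisy,
    unstable multiplier updates when used as a bias target).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if spec.sigma < grid.delta / 3.0:
        warnings.warn(
            f"broadening sigma {spec.sigma:g} is thinner than a third of the "
            f"bin width {grid.delta:g}; the binned target under-resolves its "
            "peaks", stacklevel=2,
        )
    radii, counts = lattice_shells(spec.lattice, spec.spacing, spec.n_shells)
    edges = grid.edges
    centers = grid.centers
    values = np.zeros(grid.n_bins)
    for r_k, z_k in zip(radii, counts):
        if r_k >= grid.r_hi:
            continue
        # exact Gaussian mass per bin
        cdf = 0.5 * (1.0 + erf((edges - r_k) / (np.sqrt(2.0) * spec.sigma)))
        mass = np.diff(cdf)
        values += z_k * mass / (4.0 * np.pi * centers**2 * density * grid.delta)
    return RDFHistogram(grid, values)


def equilibrated_lj_frame(
    n: int,
    density: float,
    config: EngineConfig,
    equilibration_steps: int = 2000,
    species: str = "X",
) -> MDEngine:
    """Engine holding an equilibrated LJ liquid at the given density."""
    box = np.full(3, (n / density) ** (1.0 / 3.0))
    frame = Frame(lattice_positions(n, box), box, np.full(n, species, dtype=object))
    engine = MDEngine(frame, config)
    engine.step(equilibration_steps)
    return engine


def reference_run_target(
    config: EngineConfig,
    grid: RDFGrid,
    weighting: SpeciesWeighting | None = None,
    n_frames: int = 100,
    n: int = 500,
    density: float = 0.8,
    sample_every: int = 10,
    equilibration_steps: int = 2000,
) -> RDFHistogram:
    """Time-averaged kernel RDF of an unbiased reference simulation.

    Runs its own equilibration; drifting block averages of the potential
    energy (a sign the input was not equilibrated long enough) trigger a
    warning rather than an error.
    """
    weighting = weighting or SpeciesWeighting.identical()
    engine = equilibrated_lj_frame(n, density, config, equilibration_steps)
    avg = RunningAverage(grid)
    energies = []

    def cb(eng: MDEngine) -> None:
        if eng.state.step % sample_every == 0:
            avg.add(instantaneous_rdf(eng.state.frame, grid, weighting,
                                      pairs=eng.pairs))
            energies.append(eng.state.potential_energy)

    engine.step(n_frames * sample_every, callback=cb)
    blocks = np.array_split(np.asarray(energies), 4)
    means = np.array([b.mean() for b in blocks])
    spread = np.std(means)
    scale = np.std(energies) / np.sqrt(max(len(energies) // 4, 1)) + 1e-12
    if spread > 5 * scale:
        log.warning(
            "block averages of the potential energy drift (spread %.3g); "
            "the reference run may not be equilibrated", spread,
        )
    return avg.mean()
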