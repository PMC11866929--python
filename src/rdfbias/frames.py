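"""Particle configurations in periodic orthorhombic boxes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Frame", "minimum_image", "pair_table"]


@dataclass
class Frame:
    """One configuration: positions, species labels, periodic box.

    Positions are wrapped into ``[0, L)`` per axis on construction; species
    is an array of string labels (a single implicit species if omitted).
    """

    positions: np.ndarray
    box: np.ndarray
    species: np.ndarray = field(default=None)  # type: ignore[assignment]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be N x 3")
        if self.positions.shape[0] < 2:
            raise ValueError("need at least two particles")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        if self.species is None:
            self.species = np.full(self.n_atoms, "X", dtype=object)
        else:
            self.species = np.asarray(self.species, dtype=object)
            if self.species.shape != (self.n_atoms,):
                raise ValueError("species must have one label per atom")
        self.positions = self.positions - self.box * np.floor(self.positions / self.box)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def species_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.species.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.box.copy(), self.species.copy(), self.time)


def minimum_image(dx: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors to the nearest periodic image."""
    return dx - box * np.round(dx / box)


try:  # optional acceleration; the numpy path below is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(fn):
            return fn

        return wrap


@_njit(cache=True)
def _pair_geometry(pos, pi, pj, box):
    m = pi.shape[0]
    dx = np.empty((m, 3))
    r = np.empty(m)
    for k in range(m):
        s = 0.0
        for c in range(3):
            d = pos[pi[k], c] - pos[pj[k], c]
            half = 0.5 * box[c]
            if d > half:
                d -= box[c]
            elif d < -half:
                d += box[c]
            dx[k, c] = d
            s += d * d
        r[k] = np.sqrt(s)
    return dx, r


@_njit(cache=True)
def _scatter(unit, pair_force, pi, pj, n):
    forces = np.zeros((n, 3))
    for k in range(pair_force.shape[0]):
        f = pair_force[k]
        a = pi[k]
        b = pj[k]
        for c in range(3):
            fc = f * unit[k, c]
            forces[a, c] += fc
            forces[b, c] -= fc
    return forces


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


class pair_table:
    """Cached unordered-pair geometry for one frame.

    Computes minimum-image separation vectors and distances for all i<j
    pairs in one vectorised pass; shared between the physical and bias
    force providers so the O(N²) work is done once per step.
    """

    def __init__(self, frame: Frame):
        n = frame.n_atoms
        if n not in _TRIU_CACHE:
            _TRIU_CACHE[n] = np.triu_indices(n, k=1)
        self.i, self.j = _TRIU_CACHE[n]
        if _HAVE_NUMBA:
            # positions are wrapped to [0, L), so one image fold suffices
            self.dx, self.r = _pair_geometry(
                frame.positions, self.i, self.j, frame.box
            )
        else:
            dx = frame.positions[self.i]
            dx -= frame.positions[self.j]
            dx -= frame.box * np.round(dx / frame.box)
            self.dx = dx
            self.r = np.sqrt(np.einsum("kc,kc->k", dx, dx))
        self.n_atoms = n
        self._unit: np.ndarray | None = None

    @property
    def unit(self) -> np.ndarray:
        """Unit separation vectors dx/r (computed once, shared)."""
        if self._unit is None:
            with np.errstate(invalid="ignore", divide="ignore"):
                self._unit = self.dx / self.r[:, None]
        return self._unit

    def scatter_forces(
        self, pair_force: np.ndarray, idx: np.ndarray | None = None
    ) -> np.ndarray:
        """Accumulate per-pair central forces into per-atom vectors.

        ``pair_force[k]`` is the signed magnitude along ``dx[k]/r[k]`` acting
        on atom ``i`` of pair ``k`` (atom ``j`` gets the opposite).  With
        ``idx``, ``pair_force`` refers only to the listed pair subset.
        """
        if idx is None:
            pi, pj, unit = self.i, self.j, self.unit
        else:
            pi, pj, unit = self.i[idx], self.j[idx], self.unit[idx]
        if _HAVE_NUMBA:
            return _scatter(unit, np.ascontiguousarray(pair_force, dtype=float),
                            pi, pj, self.n_atoms)
        fvec = pair_force[:, None] * unit
        forces = np.empty((self.n_atoms, 3))
        for c in range(3):  # bincount beats add.at by ~10x at this size
            forces[:, c] = np.bincount(
                pi, weights=fvec[:, c], minlength=self.n_atoms
            ) - np.bincount(pj, weights=fvec[:, c], minlength=self.n_atoms)
        return forces
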