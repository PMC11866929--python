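"""Minimal periodic MD engine in reduced Lennard-Jones units.

Velocity-Verlet integration with an optional Langevin thermostat (BAOAB
splitting) and an optional isotropic Berendsen barostat.  Forces come
from a list of *providers* sharing one contract:

    provider(frame, pairs) -> (energy, N×3 forces, virial)

where ``pairs`` is the cached minimum-image pair geometry of the step and
``virial`` is either a scalar ``(1/3) Σ r·F`` or a :class:`VirialReport`.
The bundled Lennard-Jones provider and the maximum-entropy bias provider
(:class:`rdfbias.bias.MaxEntBiasProvider`) both use it, so the bias
composes with the physical interactions exactly as any extra pair
potential would, and the total virial driving the barostat is
``T_total = T_0 + T_ME``.

Units: lengths in σ, energies in ε, masses 1, k_B = 1; the time unit is
σ√(m/ε).  Users with physical units convert on the way in and out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .bias import VirialReport
from .frames import Frame, pair_table

__all__ = ["LJParams", "EngineConfig", "EngineState", "LJProvider",
           "lj_forces", "MDEngine", "lattice_positions"]


@dataclass(frozen=True)
class LJParams:
    """12-6 Lennard-Jones parameters for one species pair."""

    epsilon: float = 1.0
    sigma: float = 1.0
    cutoff: float = 2.5
    shift: bool = True  # shift the potential to zero at the cutoff


@dataclass
class EngineConfig:
    """Everything needed to integrate: interactions, ensemble, schedule.

    ``lj_params`` maps sorted species pairs to :class:`LJParams`; a single
    entry under ``("X", "X")`` covers the default one-species system.
    ``temperature`` with ``thermostat_damping`` enables the Langevin
    thermostat; ``pressure`` with ``barostat_tau`` enables the Berendsen
    barostat (NpT).  A fixed ``seed`` makes runs bit-reproducible.
    """

    lj_params: dict[tuple[str, str], LJParams] = field(
        default_factory=lambda: {("X", "X"): LJParams()}
    )
    dt: float = 0.002
    temperature: float | None = None
    thermostat_damping: float = 0.5  # Langevin relaxation time τ
    pressure: float | None = None
    barostat_tau: float = 2.0
    seed: int = 0
    n_steps: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.thermostat_damping <= 0:
            raise ValueError("thermostat damping must be positive")


@dataclass
class EngineState:
    """Frame plus velocities and the most recent force evaluation."""

    frame: Frame
    velocities: np.ndarray
    forces: np.ndarray = field(default=None)  # type: ignore[assignment]
    potential_energy: float = 0.0
    virial_physical: float = 0.0  # T_0
    virial_bias: VirialReport | None = None  # T_ME
    step: int = 0

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.velocities**2))

    @property
    def temperature(self) -> float:
        """Kinetic temperature 2K/(3N) with k_B = 1."""
        return 2.0 * self.kinetic_energy / (3.0 * self.frame.n_atoms)

    @property
    def virial_total(self) -> float:
        """T_total = T_0 + T_ME (bias contribution included when present)."""
        t = self.virial_physical
        if self.virial_bias is not None:
            t += self.virial_bias.total
        return t

    @property
    def pressure(self) -> float:
        """Instantaneous virial pressure P = (2K/3 + T_total)/V."""
        return (2.0 * self.kinetic_energy / 3.0 + self.virial_total) / self.frame.volume


class LJProvider:
    """Truncated (optionally shifted) 12-6 Lennard-Jones forces."""

    #: per-pair force-magnitude cap flagging unphysical overlaps
    FORCE_CAP = 1e8

    def __init__(self, lj_params: dict[tuple[str, str], LJParams]):
        self.lj_params = {tuple(sorted(k)): v for k, v in lj_params.items()}
        self._pair_cache: tuple[int, list] | None = None

    def _pair_param_masks(self, frame: Frame, pairs: pair_table):
        key = pairs.r.shape[0]
        if self._pair_cache is not None and self._pair_cache[0] == key:
            return self._pair_cache[1]
        labels = frame.species.astype(str)
        si, sj = labels[pairs.i], labels[pairs.j]
        groups = []
        if len(self.lj_params) == 1:
            p = next(iter(self.lj_params.values()))
            groups.append((slice(None), p))
        else:
            for (a, b), p in self.lj_params.items():
                mask = ((si == a) & (sj == b)) | ((si == b) & (sj == a))
                if np.any(mask):
                    groups.append((mask, p))
        self._pair_cache = (key, groups)
        return groups

    def __call__(self, frame: Frame, pairs: pair_table | None = None):
        if pairs is None:
            pairs = pair_table(frame)
        r = pairs.r
        energy = 0.0
        virial = 0.0
        idx_parts: list[np.ndarray] = []
        f_parts: list[np.ndarray] = []
        for mask, p in self._pair_param_masks(frame, pairs):
            if isinstance(mask, slice):
                idx = np.nonzero(r < p.cutoff)[0]
            else:
                idx = np.nonzero(mask & (r < p.cutoff))[0]
            rw = r[idx]
            inv6 = (p.sigma / rw) ** 6
            e = 4.0 * p.epsilon * (inv6 * inv6 - inv6)
            if p.shift:
                s6 = (p.sigma / p.cutoff) ** 6
                e -= 4.0 * p.epsilon * (s6 * s6 - s6)
            # f(r) = 24 ε (2 (σ/r)^12 − (σ/r)^6)/r, repulsive positive
            f = 24.0 * p.epsilon * (2.0 * inv6 * inv6 - inv6) / rw
            if f.size and np.max(np.abs(f)) > self.FORCE_CAP:
                raise FloatingPointError(
                    "LJ force exceeds cap: overlapping particles "
                    f"(min r = {rw.min():.3g})"
                )
            energy += float(np.sum(e))
            virial += float(np.sum(f * rw) / 3.0)
            idx_parts.append(idx)
            f_parts.append(f)
        forces = pairs.scatter_forces(
            np.concatenate(f_parts), np.concatenate(idx_parts)
        )
        return energy, forces, virial


def lj_forces(frame: Frame, lj_params: dict[tuple[str, str], LJParams]):
    """One-shot LJ evaluation: ``(energy, forces, virial)``."""
    return LJProvider(lj_params)(frame)


def lattice_positions(n: int, box: np.ndarray) -> np.ndarray:
    """n particles on a simple-cubic lattice filling the box (start config)."""
    box = np.asarray(box, dtype=float)
    per_side = int(np.ceil(n ** (1.0 / 3.0)))
    axes = [np.arange(per_side) / per_side * box[k] for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])[:n]
    return pos + 0.5 * box / per_side


class MDEngine:
    """Velocity-Verlet / BAOAB integrator over a list of force providers."""

    def __init__(
        self,
        state: EngineState | Frame,
        config: EngineConfig,
        providers: Sequence[Callable] | None = None,
    ):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.providers = list(providers) if providers is not None else [
            LJProvider(config.lj_params)
        ]
        if isinstance(state, Frame):
            state = self.initialize_state(state)
        self.state = state
        self._evaluate_forces()

    # -- setup -------------------------------------------------------------
    def initialize_state(self, frame: Frame) -> EngineState:
        """Maxwell–Boltzmann velocities at the target temperature, zero COM."""
        t = self.config.temperature or 1.0
        v = self.rng.normal(0.0, np.sqrt(t), size=(frame.n_atoms, 3))
        v -= v.mean(axis=0)
        return EngineState(frame=frame, velocities=v)

    # -- force composition ---------------------------------------------------
    def _evaluate_forces(self) -> None:
        st = self.state
        pairs = pair_table(st.frame)
        self._pairs = pairs
        energy = 0.0
        forces = np.zeros_like(st.frame.positions)
        t0 = 0.0
        t_bias: VirialReport | None = None
        for provider in self.providers:
            e, f, v = provider(st.frame, pairs)
            energy += e
            forces += f
            if isinstance(v, VirialReport):
                t_bias = v if t_bias is None else VirialReport(
                    t_bias.total + v.total, t_bias.per_bin + v.per_bin
                )
            else:
                t0 += v
        st.potential_energy = energy
        st.forces = forces
        st.virial_physical = t0
        st.virial_bias = t_bias

    @property
    def pairs(self) -> pair_table:
        """Pair geometry of the most recent force evaluation."""
        return self._pairs

    # -- integration ---------------------------------------------------------
    def step(self, n: int = 1, callback: Callable[["MDEngine"], None] | None = None) -> None:
        """Advance ``n`` steps; ``callback(engine)`` runs after each step."""
        cfg = self.config
        st = self.state
        dt = cfg.dt
        langevin = cfg.temperature is not None
        if langevin:
            c1 = np.exp(-dt / cfg.thermostat_damping)
            c2 = np.sqrt((1.0 - c1 * c1) * cfg.temperature)
        for _ in range(n):
            st.velocities += 0.5 * dt * st.forces
            if langevin:  # BAOAB: half drift, OU kick, half drift
                st.frame.positions += 0.5 * dt * st.velocities
                st.velocities = c1 * st.velocities + c2 * self.rng.normal(
                    size=st.velocities.shape
                )
                st.frame.positions += 0.5 * dt * st.velocities
            else:
                st.frame.positions += dt * st.velocities
            box = st.frame.box
            st.frame.positions -= box * np.floor(st.frame.positions / box)
            self._evaluate_forces()
            st.velocities += 0.5 * dt * st.forces
            if not np.all(np.isfinite(st.frame.positions)):
                raise FloatingPointError(
                    f"non-finite coordinates at step {st.step}; "
                    "reduce dt or the bias step size"
                )
            if cfg.pressure is not None:
                self._berendsen_scale()
            st.step += 1
            st.frame.time = st.step * dt
            if callback is not None:
                callback(self)

    def _berendsen_scale(self) -> None:
        """Isotropic Berendsen volume rescaling toward the set pressure."""
        cfg = self.config
        st = self.state
        mu3 = 1.0 - (cfg.dt / cfg.barostat_tau) * (cfg.pressure - st.pressure)
        mu = np.clip(mu3, 0.9, 1.1) ** (1.0 / 3.0)
        st.frame.box *= mu
        st.frame.positions *= mu

    def run(
        self,
        n_steps: int,
        sample_every: int = 0,
        callback: Callable[["MDEngine"], None] | None = None,
    ) -> list[Frame]:
        """Integrate and collect frame snapshots every ``sample_every`` steps."""
        frames: list[Frame] = []

        def cb(engine: "MDEngine") -> None:
            if sample_every and engine.state.step % sample_every == 0:
                frames.append(engine.state.frame.copy())
            if callback is not None:
                callback(engine)

        self.step(n_steps, callback=cb)
        return frames
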