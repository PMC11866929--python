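"""Model/Results interface for RDF biasing runs.

:class:`RDFBiasModel` couples a target RDF, an interaction model and an
update schedule; :meth:`RDFBiasModel.fit` runs the biased simulation
with on-the-fly gradient descent of the Lagrange multipliers and
returns an :class:`RDFBiasResults` carrying the fitted multipliers,
their trace, the convergence history and diagnostics.

    >>> model = RDFBiasModel(target, n_particles=500, density=0.8,
    ...                      engine_config=cfg, schedule=BiasSchedule(gamma=5))
    >>> res = model.fit(n_updates=300, seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .bias import BiasState, MaxEntBiasProvider
from .controller import BiasSchedule, Controller, ControllerState
from .engine import EngineConfig, Frame, LJProvider, MDEngine, lattice_positions
from .grid import RDFGrid, RDFHistogram
from .rdf import RunningAverage, instantaneous_rdf
from .weighting import SpeciesWeighting

__all__ = ["RDFBiasModel", "RDFBiasResults"]

log = logging.getLogger(__name__)


class RDFBiasModel:
    """Maximum-relative-entropy RDF bias fitted by on-the-fly gradient descent.

    Parameters
    ----------
    target : RDFHistogram
        Target RDF; its grid defines the Lagrange-multiplier vector.
    engine_config : EngineConfig
        Interaction model, ensemble and integrator settings.
    schedule : BiasSchedule
        Sampling cadence, step size γ and optional κ damping.
    n_particles, density : int, float
        System size; the initial configuration is a melted lattice at
        this density (ignored when ``initial_frame`` is given).
    weighting : SpeciesWeighting, optional
        Species-pair weighting of the biased total RDF.
    initial_frame : Frame, optional
        Start from an explicit configuration instead.
    """

    def __init__(
        self,
        target: RDFHistogram,
        engine_config: EngineConfig,
        schedule: BiasSchedule,
        n_particles: int = 500,
        density: float = 0.8,
        weighting: SpeciesWeighting | None = None,
        initial_frame: Frame | None = None,
        species: str = "X",
    ):
        self.target = target
        self.grid: RDFGrid = target.grid
        self.engine_config = engine_config
        self.schedule = schedule
        self.weighting = weighting or SpeciesWeighting.identical()
        self.n_particles = n_particles
        self.density = density
        self.species = species
        self.initial_frame = initial_frame

    @classmethod
    def from_target_file(cls, path, engine_config, schedule, **kw) -> "RDFBiasModel":
        from .io import read_rdf_file

        return cls(read_rdf_file(path), engine_config, schedule, **kw)

    def _build_engine(self, seed: int | None) -> MDEngine:
        cfg = self.engine_config
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
        if self.initial_frame is not None:
            frame = self.initial_frame.copy()
        else:
            box = np.full(3, (self.n_particles / self.density) ** (1.0 / 3.0))
            frame = Frame(
                lattice_positions(self.n_particles, box), box,
                np.full(self.n_particles, self.species, dtype=object),
            )
        self.grid.check_box(frame.box)
        bias = BiasState(self.grid, weighting=self.weighting)
        providers = [LJProvider(cfg.lj_params), MaxEntBiasProvider(bias)]
        engine = MDEngine(frame, cfg, providers)
        return engine

    def fit(
        self,
        n_updates: int = 300,
        seed: int | None = None,
        equilibration_steps: int = 2000,
        mae_stop: float | None = None,
        sample_trajectory_every: int = 0,
        post_average_windows: int = 5,
    ) -> "RDFBiasResults":
        """Run the biased simulation and fit the multipliers.

        ``equilibration_steps`` of unbiased dynamics precede the
        controller; after the final update the biased (but no longer
        updated) run continues for ``post_average_windows`` windows to
        measure the converged RDF.  ``mae_stop`` stops the update loop
        early once the windowed MAE drops below it.
        """
        engine = self._build_engine(seed)
        bias_provider = next(
            p for p in engine.providers if isinstance(p, MaxEntBiasProvider)
        )
        engine.step(equilibration_steps)
        state = ControllerState(bias=bias_provider.state, target=self.target)
        controller = Controller(engine, state, self.schedule)
        trajectory: list[Frame] = []
        if sample_trajectory_every:
            orig_cycle = controller.run_cycle

            def cycle_with_snapshots():
                m = orig_cycle()
                if state.update_count % sample_trajectory_every == 0:
                    trajectory.append(engine.state.frame.copy())
                return m

            controller.run_cycle = cycle_with_snapshots  # type: ignore[method-assign]
        controller.run(n_updates, mae_stop=mae_stop)
        # frozen-bias averaging of the achieved RDF
        avg = RunningAverage(self.grid)
        sched = self.schedule
        for _ in range(post_average_windows * sched.samples_per_window):
            engine.step(sched.sample_every)
            avg.add(instantaneous_rdf(
                engine.state.frame, self.grid, self.weighting, pairs=engine.pairs
            ))
        return RDFBiasResults(
            model=self,
            lambda_hat=state.bias.lambda_hat.copy(),
            lambda_trace=np.array(state.lambda_trace),
            mae_history=np.asarray(state.mae_history),
            fitted_rdf=avg.mean(),
            final_frame=engine.state.frame.copy(),
            engine=engine,
            n_updates=state.update_count,
            trajectory=trajectory,
        )


@dataclass
class RDFBiasResults:
    """Fitted multipliers, convergence history and diagnostics."""

    model: RDFBiasModel
    lambda_hat: np.ndarray
    lambda_trace: np.ndarray
    mae_history: np.ndarray
    fitted_rdf: RDFHistogram
    final_frame: Frame
    engine: MDEngine
    n_updates: int
    trajectory: list[Frame] = field(default_factory=list)

    @property
    def grid(self) -> RDFGrid:
        return self.model.grid

    @property
    def mae(self) -> float:
        """MAE between the frozen-bias averaged RDF and the target."""
        return float(np.mean(np.abs(self.fitted_rdf.values - self.model.target.values)))

    def effective_pair_potential(self, smooth_bins: int = 0) -> np.ndarray:
        """The bias expressed as a per-pair potential u_bias(r_b).

        The linear bias Σ_b λ̂_b g_b is, for a one-species system, a sum
        of pairwise terms; collecting the normalisation gives

            u_bias(r_b) = λ̂_b · 2V / (N(N−1) V_b)

        When the target came from the same system with a different
        interaction potential, maximum-entropy theory predicts u_bias
        approximates the pair-potential difference between target and
        simulated models (the classic Lennard-Jones recovery result).
        ``smooth_bins`` applies a centred moving average.
        """
        frame = self.final_frame
        n = frame.n_atoms
        u = self.lambda_hat * 2.0 * frame.volume / (
            n * (n - 1) * self.grid.bin_volumes
        )
        if smooth_bins > 1:
            kernel = np.ones(smooth_bins) / smooth_bins
            u = np.convolve(u, kernel, mode="same")
        return u

    def summary(self) -> str:
        sched = self.model.schedule
        cfg = self.model.engine_config
        lines = [
            "        Maximum-entropy RDF bias fit",
            "=" * 48,
            f"bins                 {self.grid.n_bins} x {self.grid.delta:g} "
            f"(range {self.grid.r_lo:g}..{self.grid.r_hi:g})",
            f"particles            {self.final_frame.n_atoms}",
            f"temperature          {cfg.temperature}",
            f"step size gamma      {sched.gamma:g}",
            f"kappa mode           {sched.kappa_mode} (factor {sched.kappa_factor:g})",
            f"cadence              sample {sched.sample_every} / window "
            f"{sched.window} / equil {sched.equilibrate}",
            f"updates applied      {self.n_updates}",
            f"windowed MAE         {self.mae_history[0]:.4f} -> "
            f"{self.mae_history[-1]:.4f}",
            f"frozen-bias MAE      {self.mae:.4f}",
            f"lambda l1 norm       {np.sum(np.abs(self.lambda_hat)):.4f}",
            f"lambda range         [{self.lambda_hat.min():.4f}, "
            f"{self.lambda_hat.max():.4f}]",
        ]
        if self.engine.state.virial_bias is not None:
            lines.append(
                f"bias virial T_ME     {self.engine.state.virial_bias.total:.4f}"
            )
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_convergence(self, ax=None):
        """MAE history per update cycle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, self.mae_history.shape[0] + 1), self.mae_history)
        ax.set_xlabel("update cycle")
        ax.set_ylabel("windowed MAE")
        ax.set_yscale("log")
        return ax

    def plot_rdf(self, ax=None):
        """Fitted (frozen-bias) RDF against the target."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid.centers, self.model.target.values, "k-", label="target")
        ax.plot(self.grid.centers, self.fitted_rdf.values, "r--", label="biased")
        ax.set_xlabel("r")
        ax.set_ylabel("g(r)")
        ax.legend()
        return ax

    def save(self, prefix) -> None:
        """Write λ̂ trace, MAE trace, fitted RDF and final frame."""
        from pathlib import Path

        from .io import write_rdf_file, write_trace_csv, write_xyz

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_trace_csv(
            f"{prefix}_lambda_trace.csv",
            [f"bin_{b + 1}" for b in range(self.grid.n_bins)],
            self.lambda_trace,
        )
        write_trace_csv(f"{prefix}_mae_trace.csv", ["mae"],
                        self.mae_history[:, None])
        write_rdf_file(self.fitted_rdf, f"{prefix}_fitted.rdf",
                       weighting_mode=self.model.weighting.mode)
        write_xyz(self.final_frame, f"{prefix}_final.xyz")
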