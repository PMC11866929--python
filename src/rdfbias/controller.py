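"""On-the-fly gradient descent for the bias Lagrange multipliers.

The multipliers minimise the Legendre-transform objective Γ(λ) whose
gradient with respect to λ_b is simply the difference between the target
RDF and the ensemble-average RDF measured in the biased run — the
partition-function term of Γ itself is intractable and never evaluated.
The controller therefore alternates between

1. sampling the instantaneous kernel RDF every ``sample_every`` steps and
   averaging a window of samples, and
2. a normalised gradient-descent update

   λ̂_b ← λ̂_b − γ k_BT κ_b (g̃_b^target − ⟨g_b⟩) / Σ_b' |g̃_b'^target − ⟨g_b'⟩|

The ℓ1 normalisation keeps every update the same total size (γ·k_BT when
κ≡1) no matter how close the measured RDF already is, so a single step
size γ works throughout a run.  Sign convention: bins where the target
exceeds the measured average get *lower* λ̂, rewarding configurations
with more pairs there.

κ_b optionally damps updates in bins whose average bias-virial
contribution would contract (``anti_contraction``) or expand
(``anti_expansion``) the box — useful under a barostat, where an
unchecked bias virial can drive large volume drifts that stall phase
transitions.

Because the per-bin RDF intensities are correlated observables, Γ is not
convex; the controller records the windowed mean-absolute-error history
so stalls at local minima are visible, and applies no restart heuristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bias import BiasState, MaxEntBiasProvider
from .grid import RDFHistogram
from .rdf import RunningAverage, instantaneous_rdf, pair_norm_weights

__all__ = ["BiasSchedule", "ControllerState", "gradient", "kappa_vector",
           "update_multipliers", "controller_step", "Controller"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasSchedule:
    """Cadence and step-size parameters of the multiplier updates.

    ``sample_every`` steps between RDF samples; ``window`` steps of
    sampling per update; ``equilibrate`` steps after each update before
    sampling resumes; ``gamma`` the dimensionless step size (applied as
    γ·k_BT in energy units); ``kappa_mode``/``kappa_factor`` the optional
    virial-sign damping.
    """

    sample_every: int = 10
    window: int = 100
    equilibrate: int = 0
    gamma: float = 5.0
    kappa_mode: str = "none"
    kappa_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sample_every < 1:
            raise ValueError("sample_every must be at least 1")
        if self.window < self.sample_every:
            raise ValueError("window must cover at least one sample interval")
        if self.window % self.sample_every != 0:
            raise ValueError("window must be a multiple of sample_every")
        if self.equilibrate < 0:
            raise ValueError("equilibrate must be non-negative")
        if not self.gamma >= 0:
            raise ValueError("gamma must be non-negative")
        if self.kappa_mode not in ("none", "anti_contraction", "anti_expansion"):
            raise ValueError(f"unknown kappa mode {self.kappa_mode!r}")
        if not 0 < self.kappa_factor <= 1:
            raise ValueError("kappa_factor must lie in (0, 1]")

    @property
    def samples_per_window(self) -> int:
        return self.window // self.sample_every


@dataclass
class ControllerState:
    """Mutable controller bookkeeping between updates."""

    bias: BiasState
    target: RDFHistogram
    avg_g: RunningAverage = field(default=None)  # type: ignore[assignment]
    avg_virial_per_bin: np.ndarray = field(default=None)  # type: ignore[assignment]
    virial_samples: int = 0
    update_count: int = 0
    mae_history: list[float] = field(default_factory=list)
    lambda_trace: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bias.grid != self.target.grid:
            raise ValueError("bias and target must share one grid")
        if self.avg_g is None:
            self.avg_g = RunningAverage(self.bias.grid)
        if self.avg_virial_per_bin is None:
            self.avg_virial_per_bin = np.zeros(self.bias.grid.n_bins)


def gradient(target: RDFHistogram, avg: RDFHistogram) -> np.ndarray:
    """Per-bin gradient of Γ: ``g̃_b^target − ⟨g_b⟩``."""
    if target.grid != avg.grid:
        raise ValueError("target and average histograms must share one grid")
    return target.values - avg.values


def kappa_vector(avg_virial_per_bin: np.ndarray, schedule: BiasSchedule) -> np.ndarray:
    """Per-bin update damping from the sign of the average bias virial.

    ``anti_contraction`` damps bins whose virial contribution is negative
    (pulling the box inward); ``anti_expansion`` damps positive ones.
    """
    v = np.asarray(avg_virial_per_bin, dtype=float)
    kappa = np.ones_like(v)
    if schedule.kappa_mode == "anti_contraction":
        kappa[v < 0] = schedule.kappa_factor
    elif schedule.kappa_mode == "anti_expansion":
        kappa[v > 0] = schedule.kappa_factor
    return kappa


def update_multipliers(
    state: ControllerState,
    schedule: BiasSchedule,
    k_t: float = 1.0,
) -> ControllerState:
    """Apply one normalised gradient-descent update to λ̂ in place.

    The ℓ1 norm of the applied change is exactly ``γ·k_BT`` when κ≡1.  A
    perfect target match (zero denominator) is a logged no-op.  Running
    averages reset afterwards; the windowed MAE is appended to history.
    """
    avg = state.avg_g.mean()
    grad = gradient(state.target, avg)
    state.mae_history.append(float(np.mean(np.abs(grad))))
    denom = float(np.sum(np.abs(grad)))
    if denom == 0.0:
        log.info("update %d: measured RDF matches target exactly; no-op",
                 state.update_count)
    else:
        kappa = kappa_vector(state.avg_virial_per_bin, schedule)
        state.bias.lambda_hat -= schedule.gamma * k_t * kappa * grad / denom
        if not np.all(np.isfinite(state.bias.lambda_hat)):
            raise FloatingPointError("non-finite Lagrange multipliers")
    state.update_count += 1
    state.lambda_trace.append(state.bias.lambda_hat.copy())
    state.avg_g.reset()
    state.avg_virial_per_bin[:] = 0.0
    state.virial_samples = 0
    return state


class Controller:
    """Drives an engine through sample/update/equilibrate cycles."""

    def __init__(self, engine, state: ControllerState, schedule: BiasSchedule):
        from .engine import MDEngine  # deferred to avoid a cycle

        self.engine: MDEngine = engine
        self.state = state
        self.schedule = schedule
        self.provider = self._find_provider()
        self._norm_weights = None
        self._warn_statistics()

    def _find_provider(self) -> MaxEntBiasProvider | None:
        for p in self.engine.providers:
            if isinstance(p, MaxEntBiasProvider):
                return p
        return None

    def _warn_statistics(self) -> None:
        """Warn when bins collect too few pairs per window for stable updates."""
        frame = self.engine.state.frame
        grid = self.state.bias.grid
        n = frame.n_atoms
        rho_pairs = n * (n - 1) / (2.0 * frame.volume)
        expected = rho_pairs * grid.bin_volumes * self.schedule.samples_per_window
        thin = int(np.sum(expected < 10))
        if thin:
            log.warning(
                "%d of %d bins expect fewer than 10 pair counts per update "
                "window; multiplier updates may be noisy (enlarge delta or "
                "the window)", thin, grid.n_bins,
            )

    def _sample(self) -> None:
        eng = self.engine
        st = self.state
        pairs = eng.pairs
        if self._norm_weights is None or self._norm_weights.shape[0] != pairs.r.shape[0]:
            self._norm_weights = pair_norm_weights(
                eng.state.frame.species, st.bias.weighting, pairs.i, pairs.j
            )
        hist = instantaneous_rdf(
            eng.state.frame, st.bias.grid, st.bias.weighting,
            pairs=pairs, norm_weights=self._norm_weights,
        )
        st.avg_g.add(hist)
        if eng.state.virial_bias is not None:
            k = st.virial_samples
            st.avg_virial_per_bin *= k / (k + 1)
            st.avg_virial_per_bin += eng.state.virial_bias.per_bin / (k + 1)
            st.virial_samples = k + 1

    def run_cycle(self) -> float:
        """One window of sampling, one update, one equilibration stretch.

        Returns the windowed MAE recorded by the update.
        """
        sched = self.schedule
        for _ in range(sched.samples_per_window):
            self.engine.step(sched.sample_every)
            self._sample()
        k_t = self.engine.config.temperature or 1.0
        update_multipliers(self.state, sched, k_t=k_t)
        if sched.equilibrate:
            self.engine.step(sched.equilibrate)
        return self.state.mae_history[-1]

    def run(self, n_updates: int, mae_stop: float | None = None) -> list[float]:
        """Run up to ``n_updates`` cycles, stopping early below ``mae_stop``."""
        maes = []
        for _ in range(n_updates):
            mae = self.run_cycle()
            maes.append(mae)
            if mae_stop is not None and mae < mae_stop:
                break
        return maes


def controller_step(engine, state: ControllerState, schedule: BiasSchedule):
    """Functional single-cycle entry point: advance engine and controller."""
    ctrl = Controller(engine, state, schedule)
    ctrl.run_cycle()
    return engine, state
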