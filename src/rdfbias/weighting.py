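"""Species-pair weights for total RDFs.

A multi-species total RDF is a weighted sum of partial RDFs
``g = Σ_{α≤β} w^{αβ} g^{αβ}``.  Three weighting modes are supported:

``identical``
    all atoms are treated as one species (single partial, weight 1);
``frequency``
    ``w^{αβ} = m c_α c_β`` with concentrations ``c`` and multiplicity
    ``m = 2`` for unlike pairs — the relative frequency of α-β pairs;
``xray``
    the Warren–Krutter–Morningstar approximation for X-ray weighted total
    RDFs, ``w^{αβ} = m c_α c_β f_α f_β / (Σ_γ c_γ f_γ)²`` with constant
    effective scattering factors ``f``.

In every mode the weights sum to 1, so a system of uncorrelated uniform
particles still has expectation 1 in every bin.

The q-dependent analytic form-factor parametrisations used for real
X-ray data are deliberately replaced by constant per-species effective
factors (defaults: atomic numbers for H, O, Ti), in keeping with the
q-independence the Warren–Krutter–Morningstar approximation is after;
arbitrary per-species values can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpeciesWeighting", "frequency_pair_weights", "xray_pair_weights",
           "DEFAULT_SCATTERING_FACTORS"]

#: Effective (q-independent) scattering factors: atomic numbers.
DEFAULT_SCATTERING_FACTORS: dict[str, float] = {"H": 1.0, "O": 8.0, "Ti": 22.0}


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SpeciesWeighting:
    """Resolved pair weights for one composition.

    ``pair_weights`` maps the sorted species pair ``(α, β)`` to its weight
    ``w^{αβ}``; weights are symmetric by construction and sum to 1 (except
    in ``identical`` mode, where the single implicit pair has weight 1).
    """

    mode: str
    pair_weights: dict[tuple[str, str], float] | None = None
    scattering_factors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("identical", "frequency", "xray"):
            raise ValueError(f"unknown weighting mode {self.mode!r}")
        if self.mode != "identical":
            if not self.pair_weights:
                raise ValueError(f"mode {self.mode!r} requires pair weights")
            total = sum(self.pair_weights.values())
            if not np.isclose(total, 1.0, rtol=1e-9, atol=1e-12):
                raise ValueError(f"pair weights must sum to 1, got {total}")

    def weight(self, a: str, b: str) -> float:
        if self.mode == "identical":
            return 1.0
        try:
            return self.pair_weights[_key(a, b)]
        except KeyError:
            raise KeyError(f"no weight for species pair ({a}, {b})") from None

    @classmethod
    def identical(cls) -> "SpeciesWeighting":
        return cls(mode="identical")


def frequency_pair_weights(concentrations: dict[str, float]) -> SpeciesWeighting:
    """Weights equal to the relative frequency of each unordered pair."""
    _check_concentrations(concentrations)
    species = sorted(concentrations)
    w = {}
    for ia, a in enumerate(species):
        for b in species[ia:]:
            m = 1.0 if a == b else 2.0
            w[(a, b)] = m * concentrations[a] * concentrations[b]
    return SpeciesWeighting(mode="frequency", pair_weights=w)


def xray_pair_weights(
    concentrations: dict[str, float],
    scattering_factors: dict[str, float] | None = None,
) -> SpeciesWeighting:
    """Warren–Krutter–Morningstar pair weights from effective form factors.

    ``w^{αβ} = m c_α c_β f_α f_β / ⟨f⟩²`` with ``⟨f⟩ = Σ_γ c_γ f_γ`` and
    ``m = 2`` for α≠β.  Unspecified factors fall back to the packaged
    atomic-number defaults.
    """
    _check_concentrations(concentrations)
    f = dict(DEFAULT_SCATTERING_FACTORS)
    if scattering_factors:
        f.update(scattering_factors)
    for s in concentrations:
        if s not in f:
            raise ValueError(f"no scattering factor for species {s!r}")
        if not f[s] > 0:
            raise ValueError(f"scattering factor for {s!r} must be positive")
    mean_f = sum(concentrations[s] * f[s] for s in concentrations)
    species = sorted(concentrations)
    w = {}
    for ia, a in enumerate(species):
        for b in species[ia:]:
            m = 1.0 if a == b else 2.0
            w[(a, b)] = m * concentrations[a] * concentrations[b] * f[a] * f[b] / mean_f**2
    return SpeciesWeighting(
        mode="xray", pair_weights=w,
        scattering_factors={s: f[s] for s in concentrations},
    )


def _check_concentrations(concentrations: dict[str, float]) -> None:
    if not concentrations:
        raise ValueError("empty composition")
    total = sum(concentrations.values())
    if not np.isclose(total, 1.0, rtol=1e-9, atol=1e-12):
        raise ValueError(f"concentrations must sum to 1, got {total}")
    if any(c < 0 for c in concentrations.values()):
        raise ValueError("concentrations must be non-negative")
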