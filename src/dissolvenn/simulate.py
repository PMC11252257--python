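"""Synthetic in-vitro dissolution study generator.

Wet-lab dissolution profiles for the 17-batch study are emulated with a
Weibull cumulative-release law,

    F(t) = f_max * (1 - exp(-(t / tau) ** beta)),

whose parameters respond log-linearly (tau) and linearly (f_max, beta)
to the deviation of each excipient mass from the center composition.
The enteric Eudragit polymers and the lipid matrix former glyceryl
behenate retard release (raise tau); the soluble and insoluble fillers
lactose and DCP accelerate it; sodium citrate, a pH modifier, mainly
lifts the release plateau.  Gaussian assay noise is added per time
point, after which profiles are clipped to [0, 105]% and made
non-decreasing with a cumulative maximum, mirroring how cumulative
dissolution data behave.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .design import Formulation, VARIABLE_EXCIPIENTS
from .profiles import DissolutionProfile, STANDARD_TIMES

__all__ = [
    "KineticParams",
    "GeneratorConfig",
    "kinetics_from_formulation",
    "weibull_release",
    "simulate_profile",
    "generate_study",
]

F_MAX_RANGE = (60.0, 100.0)
BETA_RANGE = (0.5, 3.0)


@dataclass(frozen=True)
class KineticParams:
    """Weibull release parameters of one batch."""

    f_max: float  #: asymptotic % released, in [60, 100]
    tau: float  #: characteristic time (h) at which 63.2% of f_max is reached
    beta: float  #: shape exponent; >1 sigmoidal, =1 first-order

    def __post_init__(self) -> None:
        if not (self.f_max > 0 and self.tau > 0 and self.beta > 0):
            raise ValueError("all kinetic parameters must be positive")
        if self.f_max > 100.0:
            raise ValueError("f_max cannot exceed 100% of label claim")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level configuration of the synthetic generator.

    ``coefficients`` maps each excipient to per-mg slopes
    (d log tau / d mg, d f_max / d mg, d beta / d mg) applied to the
    deviation of its mass from ``center``.  Defaults are set so the
    17-run design spans roughly 60-95% release at 24 h with visibly
    different curve shapes, the qualitative behaviour of the study's
    dissolution panels.
    """

    baseline: KineticParams = KineticParams(f_max=90.0, tau=12.0, beta=1.3)
    center: tuple[float, ...] = (50.0, 10.0, 15.0, 33.5, 15.73, 40.0)
    coefficients: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "sodium_citrate": (0.0, 0.08, 0.0),
            "eudragit_l100_55": (0.010, -0.05, 0.004),
            "eudragit_l30_d55": (0.008, -0.03, 0.003),
            "lactose_monohydrate": (-0.004, 0.05, 0.0),
            "dcp": (-0.003, 0.02, 0.0),
            "glyceryl_behenate": (0.005, -0.02, 0.002),
        }
    )
    noise_sd: float = 1.5  #: % release, typical dissolution assay scatter
    time_points: tuple[float, ...] = STANDARD_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        t = np.asarray(self.time_points, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time_points must be strictly increasing")
        if len(self.center) != len(VARIABLE_EXCIPIENTS):
            raise ValueError("center must give one mass per excipient")

    # YAML round-trip -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "baseline": asdict(self.baseline),
            "center": list(self.center),
            "coefficients": {k: list(v) for k, v in self.coefficients.items()},
            "noise_sd": self.noise_sd,
            "time_points": list(self.time_points),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            baseline=KineticParams(**doc["baseline"]),
            center=tuple(doc["center"]),
            coefficients={
                k: tuple(v) for k, v in doc["coefficients"].items()
            },
            noise_sd=float(doc["noise_sd"]),
            time_points=tuple(doc["time_points"]),
            seed=int(doc["seed"]),
        )


def kinetics_from_formulation(
    f: Formulation, cfg: GeneratorConfig
) -> KineticParams:
    """Map an excipient composition to Weibull parameters.

    log(tau), f_max and beta shift linearly with each excipient's
    deviation from the center composition; f_max and beta are clipped
    into their admissible ranges.  Deterministic.
    """
    dev = f.as_array() - np.asarray(cfg.center)
    log_tau = np.log(cfg.baseline.tau)
    f_max = cfg.baseline.f_max
    beta = cfg.baseline.beta
    for i, name in enumerate(VARIABLE_EXCIPIENTS):
        s_tau, s_fmax, s_beta = cfg.coefficients.get(name, (0.0, 0.0, 0.0))
        if not all(np.isfinite((s_tau, s_fmax, s_beta))):
            raise ValueError(f"non-finite coefficient for {name}")
        log_tau += s_tau * dev[i]
        f_max += s_fmax * dev[i]
        beta += s_beta * dev[i]
    return KineticParams(
        f_max=float(np.clip(f_max, *F_MAX_RANGE)),
        tau=float(np.exp(log_tau)),
        beta=float(np.clip(beta, *BETA_RANGE)),
    )


def weibull_release(
    params: KineticParams, times: Sequence[float]
) -> np.ndarray:
    """Noiseless Weibull cumulative release (%) at the given times."""
    t = np.asarray(times, dtype=float)
    return params.f_max * (1.0 - np.exp(-((t / params.tau) ** params.beta)))


def simulate_profile(
    params: KineticParams,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DissolutionProfile:
    """One noisy dissolution curve at the given sampling times.

    Gaussian noise (sd = ``noise_sd`` % release) is added independently
    per time point; the result is clipped to [0, 105] and forced
    non-decreasing with a running maximum, as cumulative release data
    are.  A fixed seed makes the draw bit-reproducible.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    release = weibull_release(params, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        release = release + rng.normal(0.0, noise_sd, size=t.size)
    release = np.maximum.accumulate(np.clip(release, 0.0, 105.0))
    return DissolutionProfile(times=t, release=release)


def generate_study(
    design: Sequence[Formulation], cfg: GeneratorConfig
) -> list[tuple[Formulation, DissolutionProfile]]:
    """One simulated dissolution profile per formulation in the design.

    Per-batch seeds are spawned deterministically from ``cfg.seed`` and
    the batch index, so the whole study is reproducible while batches
    stay mutually independent.
    """
    if not len(design):
        raise ValueError("design is empty")
    out = []
    for i, form in enumerate(design):
        params = kinetics_from_formulation(form, cfg)
        batch_seed = int(
            np.random.SeedSequence(entropy=(cfg.seed, i)).generate_state(1)[0]
        )
        out.append(
            (
                form,
                simulate_profile(
                    params, cfg.time_points, cfg.noise_sd, batch_seed
                ),
            )
        )
    return out
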