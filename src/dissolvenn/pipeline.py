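"""End-to-end synthetic benchmark: generate → train → optimize.

One call runs the whole workflow under a single seed: simulate the
17-batch dissolution study, train the 6-10-10 surrogate, and grid-search
the excipient domain against a reference profile produced by the
noiseless generator at the optimized (center) composition.  Besides the
search's own best f2 it reports the "generator-truth" f2 of the winning
formulation — the f2 its noiseless generator profile scores against the
reference — which measures how close the pipeline got to the true
optimum independent of surrogate error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import Formulation, study_table
from .optimize import (
    OptimizationResult,
    SearchDomain,
    default_search_domain,
    enumerate_candidates,
    optimize,
)
from .profiles import DissolutionProfile, similarity_f2
from .simulate import GeneratorConfig, generate_study, kinetics_from_formulation, simulate_profile
from .surrogate import TrainConfig, train_lm

__all__ = ["PipelineOutcome", "run_synthetic_pipeline", "grid_truth_optimum"]

#: Composition of the optimized formulation (also the design center).
OPTIMIZED_COMPOSITION = Formulation(50.0, 10.0, 15.0, 33.5, 15.73, 40.0)


@dataclass(frozen=True)
class PipelineOutcome:
    seed: int
    best_f2: float  #: best surrogate-predicted f2 found by the search
    truth_f2: float  #: noiseless-generator f2 of the winning formulation
    result: OptimizationResult


def _noiseless_profile(
    form: Formulation, cfg: GeneratorConfig
) -> DissolutionProfile:
    return simulate_profile(
        kinetics_from_formulation(form, cfg), cfg.time_points
    )


def run_synthetic_pipeline(
    seed: int,
    domain: SearchDomain | None = None,
    generator: GeneratorConfig | None = None,
) -> PipelineOutcome:
    """Run the full workflow under one seed and score the outcome."""
    cfg = generator or GeneratorConfig(seed=seed)
    domain = domain or default_search_domain()
    study = generate_study([f for _, f in study_table()], cfg)
    model, _ = train_lm(study, TrainConfig(seed=seed))
    reference = _noiseless_profile(OPTIMIZED_COMPOSITION, cfg)
    result = optimize(model, domain, reference)
    truth = similarity_f2(
        reference, _noiseless_profile(result.best, cfg)
    ).f2
    return PipelineOutcome(
        seed=seed, best_f2=result.best_f2, truth_f2=truth, result=result
    )


def grid_truth_optimum(
    domain: SearchDomain | None = None,
    generator: GeneratorConfig | None = None,
) -> float:
    """Best achievable generator-truth f2 on the grid (noiseless)."""
    cfg = generator or GeneratorConfig()
    domain = domain or default_search_domain()
    reference = _noiseless_profile(OPTIMIZED_COMPOSITION, cfg)
    return max(
        similarity_f2(reference, _noiseless_profile(c, cfg)).f2
        for c in enumerate_candidates(domain)
    )
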