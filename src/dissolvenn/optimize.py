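"""Grid search over the excipient domain for the best-matching profile.

The trained surrogate makes what-if evaluation of candidate
formulations cheap: every grid point in the excipient domain is pushed
through the network and its predicted release profile scored with the
f2 similarity factor against the reference profile.  Tablet mass is
held at the 400 mg nominal by letting one designated slack excipient
(by default lactose monohydrate, the conventional filler) absorb the
residual mass; candidates whose slack value leaves its own bounds are
discarded.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .design import (
    CSV_COLUMNS,
    FIXED_COMPONENTS,
    Formulation,
    NOMINAL_TABLET_MASS,
    VARIABLE_EXCIPIENTS,
)
from .profiles import DissolutionProfile, similarity_f2
from .surrogate import SurrogateModel, forward

__all__ = [
    "SearchDomain",
    "OptimizationResult",
    "enumerate_candidates",
    "optimize",
    "report",
    "write_bundle",
    "default_search_domain",
]


@dataclass(frozen=True)
class SearchDomain:
    """Per-excipient (min, max, step) grid in mg/tab.

    ``slack`` names the excipient that absorbs the mass residual so
    totals hit ``total_mass``; set it to ``None`` for an unconstrained
    grid where candidates are only checked against ``mass_tolerance``.
    """

    bounds: dict[str, tuple[float, float, float]]
    slack: str | None = "lactose_monohydrate"
    total_mass: float = NOMINAL_TABLET_MASS
    mass_tolerance: float = 0.75
    max_candidates: int = 10**6

    def __post_init__(self) -> None:
        unknown = set(self.bounds) - set(VARIABLE_EXCIPIENTS)
        if unknown:
            raise ValueError(f"unknown excipient(s) {sorted(unknown)}")
        missing = set(VARIABLE_EXCIPIENTS) - set(self.bounds)
        if missing:
            raise ValueError(f"bounds missing for {sorted(missing)}")
        for name, (lo, hi, step) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
            if name != self.slack and step <= 0:
                raise ValueError(f"{name}: step must be positive")
        if self.slack is not None and self.slack not in VARIABLE_EXCIPIENTS:
            raise ValueError(f"slack excipient {self.slack!r} unknown")

    def levels(self, name: str) -> np.ndarray:
        lo, hi, step = self.bounds[name]
        n = int(math.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    def center(self) -> np.ndarray:
        return np.array(
            [(lo + hi) / 2 for lo, hi, _ in
             (self.bounds[n] for n in VARIABLE_EXCIPIENTS)]
        )

    def grid_size(self) -> int:
        free = [n for n in VARIABLE_EXCIPIENTS if n != self.slack]
        return math.prod(int(self.levels(n).size) for n in free)


@dataclass(frozen=True)
class OptimizationResult:
    """Winner of the grid search plus the full ranked trace."""

    best: Formulation
    predicted: DissolutionProfile
    best_f2: float
    trace: pd.DataFrame  #: one row per evaluated candidate, f2-descending
    reference: DissolutionProfile
    reference_id: str = "reference"


def enumerate_candidates(domain: SearchDomain) -> Iterator[Formulation]:
    """Deterministic Cartesian grid over the free excipients.

    With a slack excipient set, its mass is whatever brings the tablet
    to ``domain.total_mass`` given the fixed components; candidates
    whose slack mass falls outside the slack's own (min, max) are
    dropped.  Without one, candidates failing the mass-balance
    tolerance are dropped.
    """
    size = domain.grid_size()
    if size > domain.max_candidates:
        raise ValueError(
            f"grid has {size} candidates, above the cap of "
            f"{domain.max_candidates}; coarsen the steps or use random "
            "sampling"
        )
    free = [n for n in VARIABLE_EXCIPIENTS if n != domain.slack]
    fixed_total = sum(FIXED_COMPONENTS.values())
    produced = False
    for combo in itertools.product(*(domain.levels(n) for n in free)):
        masses = dict(zip(free, (float(v) for v in combo)))
        if domain.slack is not None:
            residual = domain.total_mass - fixed_total - sum(masses.values())
            lo, hi, _ = domain.bounds[domain.slack]
            if residual < lo - 1e-9 or residual > hi + 1e-9:
                continue
            masses[domain.slack] = float(residual)
        else:
            total = fixed_total + sum(masses.values())
            if abs(total - domain.total_mass) > domain.mass_tolerance:
                continue
        produced = True
        yield Formulation(**{n: masses[n] for n in VARIABLE_EXCIPIENTS})
    if not produced:
        raise ValueError(
            "search domain is empty after mass-balance constraints"
        )


def optimize(
    model: SurrogateModel,
    domain: SearchDomain,
    reference: DissolutionProfile,
) -> OptimizationResult:
    """Exhaustive f2 maximisation of the surrogate over the domain.

    Ties on f2 are broken by smaller Euclidean distance to the domain
    center, then by lexicographic order of the excipient masses.
    """
    if model.times is not None and not np.array_equal(
        model.times, reference.times
    ):
        raise ValueError(
            "model output time points differ from the reference profile's"
        )
    center = domain.center()
    rows = []
    candidates = list(enumerate_candidates(domain))
    for cand in candidates:
        pred = DissolutionProfile(
            times=reference.times, release=forward(model, cand.as_array())
        )
        res = similarity_f2(reference, pred)
        rows.append((cand, res.f2))
    order = sorted(
        range(len(rows)),
        key=lambda i: (
            -rows[i][1],
            float(np.linalg.norm(rows[i][0].as_array() - center)),
            tuple(rows[i][0].as_array()),
        ),
    )
    best, best_f2 = rows[order[0]]
    trace = pd.DataFrame(
        [
            {
                **dict(zip(VARIABLE_EXCIPIENTS, rows[i][0].as_array())),
                "f2": rows[i][1],
            }
            for i in order
        ]
    )
    predicted = DissolutionProfile(
        times=reference.times, release=forward(model, best.as_array())
    )
    return OptimizationResult(
        best=best,
        predicted=predicted,
        best_f2=best_f2,
        trace=trace,
        reference=reference,
    )


def default_search_domain(step_divisor: int = 4) -> SearchDomain:
    """Grid over the study's experimental domain.

    Each free excipient gets ``step_divisor + 1`` evenly spaced levels
    between its lowest and highest studied mass; lactose monohydrate is
    the mass-balance slack.
    """
    ranges = {
        "sodium_citrate": (25.0, 75.0),
        "eudragit_l100_55": (0.0, 30.0),
        "eudragit_l30_d55": (10.0, 40.0),
        "lactose_monohydrate": (3.5, 53.5),
        "dcp": (3.73, 48.73),
        "glyceryl_behenate": (20.0, 60.0),
    }
    bounds = {
        name: (lo, hi, (hi - lo) / step_divisor)
        for name, (lo, hi) in ranges.items()
    }
    return SearchDomain(bounds=bounds)


# ---------------------------------------------------------------------------
# reporting


def report(result: OptimizationResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tables of the optimized formulation and predicted-vs-reference release.

    The profile table carries the f2 (two decimals) in its final row, in
    the layout conventionally used to present an optimized formulation
    next to the marketed reference.
    """
    comp_rows = [
        ("Drug substance", FIXED_COMPONENTS["drug_substance"]),
        ("Sodium citrate", result.best.sodium_citrate),
        ("Eudragit L100 55", result.best.eudragit_l100_55),
        ("Eudragit L30 D55", result.best.eudragit_l30_d55),
        ("Triethyl citrate", FIXED_COMPONENTS["triethyl_citrate"]),
        ("Lactose monohydrate", result.best.lactose_monohydrate),
        ("DCP", result.best.dcp),
        ("Glyceryl behenate", result.best.glyceryl_behenate),
        ("Magnesium stearate", FIXED_COMPONENTS["magnesium_stearate"]),
        ("Total", result.best.total_mass),
    ]
    components = pd.DataFrame(comp_rows, columns=["component", "mg_per_tab"])
    profile = pd.DataFrame(
        {
            "time_h": result.reference.times,
            "predicted_pct": result.predicted.release,
            "reference_pct": result.reference.release,
        }
    )
    f2_row = pd.DataFrame(
        {
            "time_h": ["f2"],
            "predicted_pct": [f"{result.best_f2:.2f}"],
            "reference_pct": [""],
        }
    )
    return components, pd.concat([profile, f2_row], ignore_index=True)


def render_report(result: OptimizationResult) -> str:
    components, profile = report(result)
    return (
        "Optimized formulation (mg/tab)\n"
        + components.to_string(index=False)
        + "\n\nPredicted vs reference % drug release\n"
        + profile.to_string(index=False)
        + "\n"
    )


def write_bundle(result: OptimizationResult, out_dir: str | Path) -> None:
    """Write the result as CSVs plus a JSON summary into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    best = pd.DataFrame(
        [dict(zip(CSV_COLUMNS, result.best.as_array()))]
    )
    best.insert(0, "batch", ["optimized"])
    best.to_csv(out / "optimized_formulation.csv", index=False)
    _, profile = report(result)
    profile.to_csv(out / "predicted_vs_reference.csv", index=False)
    result.trace.to_csv(out / "search_trace.csv", index=False)
    summary = {
        "f2": round(result.best_f2, 2),
        "f2_unrounded": result.best_f2,
        "n_candidates": int(len(result.trace)),
        "reference_id": result.reference_id,
        "best_formulation": dict(
            zip(VARIABLE_EXCIPIENTS, result.best.as_array().tolist())
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
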