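"""Dissolution profiles and the f2 similarity factor.

A dissolution profile is the cumulative percentage of the label claim
released into the test medium at each sampled time point.  Two profiles
are compared with the FDA-adopted similarity factor

    f2 = 50 * log10( 100 * (1 + (1/n) * sum_j (R_j - T_j)**2) ** -0.5 )

where ``R_j`` and ``T_j`` are the reference and test release percentages
at the j-th of ``n`` shared time points.  f2 is 100 for identical curves
and decreases as the curves diverge; the regulatory similarity band is
50-100.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DissolutionProfile",
    "SimilarityResult",
    "Violation",
    "similarity_f2",
    "validate_profile",
    "read_profile_long",
    "write_profile_long",
    "read_profiles_wide",
    "write_profiles_wide",
    "reference_profile",
    "example_predicted_profile",
]

#: Default time grid (hours) of the modified-release dissolution test.
STANDARD_TIMES = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0, 24.0)


@dataclass(frozen=True)
class DissolutionProfile:
    """Paired vectors of sampling times (h) and cumulative % released.

    Construction checks shape and finiteness only; monotonicity and
    release-range rules are data-quality checks reported by
    :func:`validate_profile`, so that defective profiles can be loaded,
    inspected and reported rather than rejected at the door.
    """

    times: np.ndarray
    release: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        release = np.asarray(self.release, dtype=float)
        if times.ndim != 1 or release.ndim != 1:
            raise ValueError("times and release must be one-dimensional")
        if times.shape != release.shape:
            raise ValueError(
                f"times (n={times.size}) and release (n={release.size}) "
                "must have equal length"
            )
        if not (np.isfinite(times).all() and np.isfinite(release).all()):
            raise ValueError("times and release must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "release", release)

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DissolutionProfile):
            return NotImplemented
        return np.array_equal(self.times, other.times) and np.array_equal(
            self.release, other.release
        )


@dataclass(frozen=True)
class SimilarityResult:
    """f2 score plus the pieces needed to audit it."""

    f2: float
    n_points: int
    sum_sq_diff: float

    @property
    def f2_rounded(self) -> float:
        """Two-decimal value for reports; comparisons use ``f2``."""
        return round(self.f2, 2)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"f2 = {self.f2_rounded:.2f} (n = {self.n_points})"


@dataclass(frozen=True)
class Violation:
    """One data-quality offence found in a profile."""

    kind: str
    index: int
    message: str
    severity: str = "error"


def similarity_f2(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    *,
    truncate_after_85: bool = False,
) -> SimilarityResult:
    """Similarity factor f2 between two profiles on one time grid.

    Parameters
    ----------
    reference, test:
        Profiles defined on identical time vectors with at least three
        points.
    truncate_after_85:
        Apply the regulatory convention of keeping only one point after
        the reference exceeds 85% release.  Off by default: the classic
        all-points calculation is the primary behaviour here.
    """
    if reference.n_points != test.n_points:
        raise ValueError(
            "profiles have different numbers of time points: "
            f"{reference.n_points} vs {test.n_points}"
        )
    mismatch = np.nonzero(reference.times != test.times)[0]
    if mismatch.size:
        i = int(mismatch[0])
        raise ValueError(
            "profiles are defined on different time vectors; first "
            f"difference at index {i}: {reference.times[i]} h vs "
            f"{test.times[i]} h"
        )

    r = reference.release
    t = test.release
    if truncate_after_85:
        above = np.nonzero(r >= 85.0)[0]
        if above.size:
            keep = min(int(above[0]) + 1, r.size - 1)
            r = r[: keep + 1]
            t = t[: keep + 1]
    n = r.size
    if n < 3:
        raise ValueError(
            f"f2 needs at least 3 shared time points, got {n}"
        )
    sum_sq = float(np.sum((r - t) ** 2))
    f2 = 50.0 * np.log10(100.0 * (1.0 + sum_sq / n) ** -0.5)
    return SimilarityResult(f2=float(f2), n_points=int(n), sum_sq_diff=sum_sq)


def validate_profile(
    profile: DissolutionProfile, tolerance: float = 2.0
) -> list[Violation]:
    """Check a profile's internal consistency.

    Returns one :class:`Violation` per offence (empty list = clean):

    * times not strictly increasing;
    * cumulative release dropping by more than ``tolerance`` percentage
      points between consecutive samples (small drops are assay noise);
    * release outside [0, 110] (error) or in (100, 110] (warning flag —
      assay variability can exceed the label claim).
    """
    violations: list[Violation] = []
    dt = np.diff(profile.times)
    for i in np.nonzero(dt <= 0)[0]:
        violations.append(
            Violation(
                kind="non-increasing time",
                index=int(i + 1),
                message=(
                    f"time[{i + 1}] = {profile.times[i + 1]} h does not "
                    f"exceed time[{i}] = {profile.times[i]} h"
                ),
            )
        )
    dr = np.diff(profile.release)
    for i in np.nonzero(dr < -tolerance)[0]:
        violations.append(
            Violation(
                kind="release drop > tolerance",
                index=int(i + 1),
                message=(
                    f"release drops {-dr[i]:.3g} points at index {i + 1}, "
                    f"tolerance is {tolerance:g}"
                ),
            )
        )
    for i in np.nonzero(
        (profile.release < 0) | (profile.release > 110.0)
    )[0]:
        violations.append(
            Violation(
                kind="release out of range",
                index=int(i),
                message=f"release[{i}] = {profile.release[i]:.3g}% outside [0, 110]",
            )
        )
    for i in np.nonzero(
        (profile.release > 100.0) & (profile.release <= 110.0)
    )[0]:
        violations.append(
            Violation(
                kind="release above label claim",
                index=int(i),
                message=f"release[{i}] = {profile.release[i]:.3g}% exceeds 100%",
                severity="warning",
            )
        )
    return violations


# ---------------------------------------------------------------------------
# CSV input/output


def read_profile_long(path: str | Path) -> DissolutionProfile:
    """Read a single-batch profile CSV with columns ``time_h,release_pct``."""
    df = pd.read_csv(path)
    for col in ("time_h", "release_pct"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return DissolutionProfile(
        times=df["time_h"].to_numpy(float),
        release=df["release_pct"].to_numpy(float),
    )


def write_profile_long(profile: DissolutionProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"time_h": profile.times, "release_pct": profile.release}
    ).to_csv(path, index=False)


def read_profiles_wide(
    path: str | Path, times: Sequence[float]
) -> dict[str, DissolutionProfile]:
    """Read a wide-form CSV ``batch,t1,t2,...`` against a sidecar time vector.

    The time columns are positional: the i-th value column pairs with
    ``times[i]``.
    """
    df = pd.read_csv(path)
    if "batch" not in df.columns:
        raise ValueError(f"{path}: missing column 'batch'")
    value_cols = [c for c in df.columns if c != "batch"]
    times = np.asarray(times, dtype=float)
    if len(value_cols) != times.size:
        raise ValueError(
            f"{path}: {len(value_cols)} release columns but "
            f"{times.size} time points supplied"
        )
    out: dict[str, DissolutionProfile] = {}
    for _, row in df.iterrows():
        out[str(row["batch"])] = DissolutionProfile(
            times=times.copy(),
            release=row[value_cols].to_numpy(float),
        )
    return out


def write_profiles_wide(
    profiles: dict[str, DissolutionProfile], path: str | Path
) -> None:
    """Write batches as one row each; columns named t<hours>."""
    items = list(profiles.items())
    if not items:
        raise ValueError("no profiles to write")
    times = items[0][1].times
    for name, prof in items:
        if not np.array_equal(prof.times, times):
            raise ValueError(
                f"batch {name!r} has a different time vector; wide form "
                "requires one shared grid"
            )
    cols = {"batch": [name for name, _ in items]}
    for j, t in enumerate(times):
        cols[f"t{t:g}"] = [prof.release[j] for _, prof in items]
    pd.DataFrame(cols).to_csv(path, index=False)


def _fixture(name: str) -> Path:
    return Path(
        importlib.resources.files("dissolvenn").joinpath(f"data/{name}")
    )


def reference_profile() -> DissolutionProfile:
    """The packaged 10-point marketed-product reference profile."""
    return read_profile_long(_fixture("reference_profile.csv"))


def example_predicted_profile() -> DissolutionProfile:
    """Packaged example of a surrogate-predicted optimized profile."""
    return read_profile_long(_fixture("optimized_predicted_profile.csv"))
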