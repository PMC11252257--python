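"""Two-level fractional factorial designs over tablet excipients.

The experimental domain is a 2^(6-2) fractional factorial over six
variable excipients plus one center run: 17 formulations of a 400 mg
modified-release quetiapine fumarate tablet.  Three components are held
constant in every batch (drug substance 230.27 mg, triethyl citrate
1.5 mg, magnesium stearate 4 mg).
"""

from __future__ import annotations

import importlib.resources
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Formulation",
    "DesignSpec",
    "generate_design",
    "coded_design",
    "formulations_from_design",
    "load_study_table",
    "study_table",
    "study_design_spec",
    "write_design",
    "VARIABLE_EXCIPIENTS",
    "FIXED_COMPONENTS",
    "NOMINAL_TABLET_MASS",
]

#: Variable excipients in factor order x1..x6 (masses in mg per tablet).
VARIABLE_EXCIPIENTS = (
    "sodium_citrate",
    "eudragit_l100_55",
    "eudragit_l30_d55",
    "lactose_monohydrate",
    "dcp",
    "glyceryl_behenate",
)

#: Components held constant across every batch (mg per tablet).
FIXED_COMPONENTS = {
    "drug_substance": 230.27,
    "triethyl_citrate": 1.5,
    "magnesium_stearate": 4.0,
}

NOMINAL_TABLET_MASS = 400.0

#: CSV column names, in factor order, for the design/formulation schema.
CSV_COLUMNS = (
    "x1_sodium_citrate_mg",
    "x2_eudragit_L100_55_mg",
    "x3_eudragit_L30_D55_mg",
    "x4_lactose_mg",
    "x5_dcp_mg",
    "x6_glyceryl_behenate_mg",
)


@dataclass(frozen=True)
class Formulation:
    """Masses (mg/tab) of the six variable excipients of one batch."""

    sodium_citrate: float
    eudragit_l100_55: float
    eudragit_l30_d55: float
    lactose_monohydrate: float
    dcp: float
    glyceryl_behenate: float

    def __post_init__(self) -> None:
        for name in VARIABLE_EXCIPIENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative mass for {name}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in VARIABLE_EXCIPIENTS], dtype=float
        )

    @property
    def total_mass(self) -> float:
        """Total tablet mass: six variables plus the three fixed components."""
        return float(self.as_array().sum() + sum(FIXED_COMPONENTS.values()))

    def mass_balance_error(self) -> float:
        return self.total_mass - NOMINAL_TABLET_MASS

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "Formulation":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValueError(f"expected 6 excipient masses, got shape {x.shape}")
        return cls(*x.tolist())


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a two-level fractional factorial with center runs.

    ``factors`` lists (name, low, high) in run order; letters A, B, C...
    are assigned to factors in that order.  Each generator (e.g.
    ``"E=ABC"``) defines an aliased factor as the product, in ±1 coding,
    of base-factor columns; the fraction index p equals the number of
    generators.  ``center_point`` defaults to the per-factor midpoints.
    """

    factors: tuple[tuple[str, float, float], ...]
    generators: tuple[str, ...] = ()
    center_runs: int = 0
    center_point: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        k = len(self.factors)
        p = len(self.generators)
        if not 0 <= p < k:
            raise ValueError(f"need 0 <= p < k, got k={k}, p={p}")
        for name, low, high in self.factors:
            if not low < high:
                raise ValueError(f"factor {name!r}: low must be below high")
        if self.center_point is not None and len(self.center_point) != k:
            raise ValueError("center_point must give one value per factor")
        letters = string.ascii_uppercase[:k]
        base = set(letters[: k - p])
        aliased = letters[k - p : k]
        for gen, expected in zip(self.generators, aliased):
            lhs, _, rhs = gen.replace(" ", "").partition("=")
            if lhs != expected:
                raise ValueError(
                    f"generator {gen!r} must define factor {expected}"
                )
            bad = set(rhs) - base
            if bad:
                raise ValueError(
                    f"generator {gen!r} references non-base factor(s) "
                    f"{sorted(bad)}; generators may use only {sorted(base)}"
                )

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def p(self) -> int:
        return len(self.generators)

    @property
    def n_runs(self) -> int:
        return 2 ** (self.k - self.p) + self.center_runs

    def midpoints(self) -> np.ndarray:
        if self.center_point is not None:
            return np.asarray(self.center_point, dtype=float)
        return np.array([(lo + hi) / 2 for _, lo, hi in self.factors])


def coded_design(spec: DesignSpec) -> pd.DataFrame:
    """The ±1 coded matrix in standard (Yates) run order, center runs as 0."""
    k, p = spec.k, spec.p
    n_base = k - p
    runs = 2**n_base
    letters = string.ascii_uppercase[:k]
    coded = np.empty((runs, k))
    # Yates standard order: factor i alternates sign in blocks of 2**i.
    for i in range(n_base):
        block = np.repeat([-1.0, 1.0], 2**i)
        coded[:, i] = np.tile(block, runs // block.size)
    for j, gen in enumerate(spec.generators):
        _, _, rhs = gen.replace(" ", "").partition("=")
        col = np.ones(runs)
        for letter in rhs:
            col *= coded[:, letters.index(letter)]
        coded[:, n_base + j] = col
    if spec.center_runs:
        coded = np.vstack([coded, np.zeros((spec.center_runs, k))])
    return pd.DataFrame(coded, columns=[name for name, _, _ in spec.factors])


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Factorial runs mapped from ±1 coding to factor units, plus center runs.

    Rows follow Yates standard order with center runs appended; the
    result is fully determined by the spec.
    """
    coded = coded_design(spec).to_numpy()
    lows = np.array([lo for _, lo, _ in spec.factors])
    highs = np.array([hi for _, _, hi in spec.factors])
    mids = (lows + highs) / 2
    half = (highs - lows) / 2
    values = mids + coded * half
    if spec.center_runs:
        values[-spec.center_runs :] = spec.midpoints()
    return pd.DataFrame(values, columns=[name for name, _, _ in spec.factors])


def formulations_from_design(design: pd.DataFrame) -> list[Formulation]:
    """Convert a six-excipient design table to Formulation objects."""
    missing = [c for c in VARIABLE_EXCIPIENTS if c not in design.columns]
    if missing:
        raise ValueError(f"design lacks excipient column(s) {missing}")
    return [
        Formulation(**{c: float(row[c]) for c in VARIABLE_EXCIPIENTS})
        for _, row in design.iterrows()
    ]


def study_design_spec(
    generators: tuple[str, str] = ("E=ABC", "F=BCD"),
    center_runs: int = 1,
) -> DesignSpec:
    """The default 2^(6-2)+1 spec over the six excipients.

    Levels span each excipient's range in the study table; the center
    point is the optimized composition (50, 10, 15, 33.5, 15.73, 40 mg),
    which is also the modal row of the study table.  The resolution-IV
    generators E=ABC, F=BCD are the textbook default for 2^(6-2).
    """
    ranges = {
        "sodium_citrate": (25.0, 75.0),
        "eudragit_l100_55": (0.0, 30.0),
        "eudragit_l30_d55": (10.0, 40.0),
        "lactose_monohydrate": (3.5, 53.5),
        "dcp": (3.73, 48.73),
        "glyceryl_behenate": (20.0, 60.0),
    }
    return DesignSpec(
        factors=tuple(
            (name, *ranges[name]) for name in VARIABLE_EXCIPIENTS
        ),
        generators=generators,
        center_runs=center_runs,
        center_point=(50.0, 10.0, 15.0, 33.5, 15.73, 40.0),
    )


def load_study_table(
    path: str | Path, mass_tolerance: float = 0.75
) -> list[tuple[str, Formulation]]:
    """Load a batch formulation CSV (schema of the packaged study table).

    Mass-balance violations beyond ``mass_tolerance`` mg are reported as
    warnings carrying the per-batch discrepancy, not errors — a few
    printed batches do not sum exactly to the 400 mg nominal mass.
    Missing values are zero-filled with a warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no batches")
    for col in ("batch", *CSV_COLUMNS):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df[list(CSV_COLUMNS)].isna().any().any():
        warnings.warn(
            f"{path}: missing excipient values zero-filled", stacklevel=2
        )
        df = df.fillna({c: 0.0 for c in CSV_COLUMNS})
    out: list[tuple[str, Formulation]] = []
    for _, row in df.iterrows():
        masses = [float(row[c]) for c in CSV_COLUMNS]
        negative = [c for c, m in zip(CSV_COLUMNS, masses) if m < 0]
        if negative:
            raise ValueError(
                f"{path}: batch {row['batch']!r} has negative mass in "
                f"{negative}"
            )
        form = Formulation(*masses)
        err = form.mass_balance_error()
        if abs(err) > mass_tolerance:
            warnings.warn(
                f"batch {row['batch']}: total mass {form.total_mass:.2f} mg "
                f"deviates {err:+.2f} mg from {NOMINAL_TABLET_MASS:g} mg",
                stacklevel=2,
            )
        out.append((str(row["batch"]), form))
    return out


def study_table() -> list[tuple[str, Formulation]]:
    """The packaged 17-batch quetiapine fumarate MR formulation table."""
    path = importlib.resources.files("dissolvenn").joinpath(
        "data/quetiapine_mr_formulations.csv"
    )
    with warnings.catch_warnings():
        # The printed table's known sub-milligram mass imbalances are
        # documented; do not re-warn on every fixture load.
        warnings.simplefilter("ignore")
        return load_study_table(Path(str(path)))


def write_design(
    design: pd.DataFrame,
    path: str | Path,
    coded: pd.DataFrame | None = None,
    coded_path: str | Path | None = None,
) -> None:
    """Export a design in the study CSV schema, optionally with ±1 coding."""
    df = design.rename(columns=dict(zip(VARIABLE_EXCIPIENTS, CSV_COLUMNS)))
    df.insert(0, "batch", [f"F{i + 1}" for i in range(len(df))])
    df.to_csv(path, index=False)
    if coded is not None and coded_path is not None:
        cdf = coded.copy()
        cdf.insert(0, "batch", [f"F{i + 1}" for i in range(len(cdf))])
        cdf.to_csv(coded_path, index=False)
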