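"""Model input registry: loading, validation, moment matching and sampling.

Every model input (transition probabilities, survival regression
coefficients, costs, utilities, discount rates) is described by a
:class:`ParameterSpec` holding its distribution family, mean and standard
error.  The probabilistic sensitivity analysis draws each non-degenerate
parameter independently from a distribution moment-matched to that
(mean, SE) pair:

* ``beta`` for quantities bounded in [0, 1] (utilities, probabilities),
  with ``alpha = m * (m(1-m)/se^2 - 1)`` and ``beta = (1-m) * (...)``;
* ``gamma`` for non-negative, right-skewed quantities (costs), with
  ``shape = (m/se)^2`` and ``scale = se^2/m``;
* ``normal_coefficient`` for survival regression coefficients, sampled
  as a normal on their own (log-hazard) scale, which induces a lognormal
  on the exponentiated hazard-ratio scale;
* ``fixed`` for point values that are never sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ParameterRegistry",
    "MomentMatched",
    "moment_match",
    "load_parameter_table",
    "default_registry",
    "sibling_donor_probability",
]

_FAMILIES = ("beta", "gamma", "normal_coefficient", "fixed")
_GROUPS = ("transition", "survival", "cost", "utility", "discount")


class ParameterError(ValueError):
    """Raised when a parameter table row violates its invariants."""


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input with its sampling distribution family.

    Units follow the source table: THB for costs, utility index for
    utilities, annual probability for transition rows, dimensionless for
    regression coefficients.
    """

    name: str
    family: str
    mean: float
    se: float = 0.0
    group: str = "cost"
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")
        if self.group not in _GROUPS:
            raise ParameterError(f"{self.name}: unknown group {self.group!r}")
        if self.se < 0:
            raise ParameterError(f"{self.name}: negative SE {self.se}")
        if self.family == "beta":
            if not 0.0 <= self.mean <= 1.0:
                raise ParameterError(
                    f"{self.name}: beta mean {self.mean} outside [0, 1]"
                )
            if self.se > 0 and self.se**2 >= self.mean * (1.0 - self.mean):
                raise ParameterError(
                    f"{self.name}: beta variance {self.se**2:.4g} >= "
                    f"mean(1-mean) = {self.mean * (1 - self.mean):.4g}"
                )
        if self.family == "gamma" and self.mean <= 0:
            raise ParameterError(f"{self.name}: gamma mean {self.mean} <= 0")

    @property
    def is_fixed(self) -> bool:
        """Fixed family, or a degenerate SE of zero."""
        return self.family == "fixed" or self.se == 0.0


@dataclass(frozen=True)
class MomentMatched:
    """Moment-matched distribution parameters for one spec."""

    family: str
    args: tuple[float, ...]

    def rvs(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.args[0], self.args[1], size)
        if self.family == "gamma":
            return rng.gamma(self.args[0], self.args[1], size)
        if self.family == "normal_coefficient":
            return rng.normal(self.args[0], self.args[1], size)
        # degenerate point mass
        return np.full(size if size is not None else (), self.args[0])


def moment_match(spec: ParameterSpec) -> MomentMatched:
    """Method-of-moments distribution parameters for ``spec``.

    A zero SE with a non-fixed family degenerates to a point mass with a
    warning; the model then treats the parameter as constant in the PSA.
    """
    if spec.family == "fixed":
        return MomentMatched("fixed", (spec.mean,))
    if spec.se == 0.0:
        warnings.warn(
            f"{spec.name}: SE is 0 for family {spec.family}; "
            "treated as a point mass",
            stacklevel=2,
        )
        return MomentMatched("fixed", (spec.mean,))
    m, s = spec.mean, spec.se
    if spec.family == "beta":
        k = m * (1.0 - m) / s**2 - 1.0
        return MomentMatched("beta", (m * k, (1.0 - m) * k))
    if spec.family == "gamma":
        return MomentMatched("gamma", ((m / s) ** 2, s**2 / m))
    return MomentMatched("normal_coefficient", (m, s))


@dataclass(frozen=True)
class ParameterSet:
    """A complete realization (point estimate or PSA draw) of all inputs."""

    values: Mapping[str, float]
    provenance: str = "point_estimate"
    seed_info: tuple[int, int] | None = None  # (seed, draw index)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def replace(self, **updates: float) -> "ParameterSet":
        vals = dict(self.values)
        for k, v in updates.items():
            if k not in vals:
                raise KeyError(f"unknown parameter {k!r}")
            vals[k] = float(v)
        return ParameterSet(vals, provenance=self.provenance, seed_info=self.seed_info)


class ParameterRegistry:
    """Ordered collection of :class:`ParameterSpec`, the model's input contract."""

    def __init__(self, specs: Iterator[ParameterSpec] | list[ParameterSpec]):
        self._specs: dict[str, ParameterSpec] = {}
        for s in specs:
            if s.name in self._specs:
                raise ParameterError(f"duplicate parameter {s.name!r}")
            self._specs[s.name] = s

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def point_estimate(self) -> ParameterSet:
        return ParameterSet({s.name: s.mean for s in self})

    def sample_arrays(self, seed: int, n_draws: int) -> dict[str, np.ndarray]:
        """Draw ``n_draws`` joint realizations; fixed parameters are constant.

        Sampling is parameter-major in registry order, so the draw
        sequence is bit-reproducible for a given seed and draw count.
        """
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        rng = np.random.default_rng(seed)
        out: dict[str, np.ndarray] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-SE warnings
            for spec in self:
                out[spec.name] = moment_match(spec).rvs(rng, n_draws)
        return out

    def sample(self, seed: int, n_draws: int) -> list[ParameterSet]:
        """Sequence of sampled :class:`ParameterSet`, one per PSA iteration."""
        arrays = self.sample_arrays(seed, n_draws)
        return [
            ParameterSet(
                {name: float(arrays[name][i]) for name in arrays},
                provenance="psa_draw",
                seed_info=(seed, i),
            )
            for i in range(n_draws)
        ]

    def sample_frame(self, seed: int, n_draws: int) -> pd.DataFrame:
        """Draws as a DataFrame, one row per draw, one column per parameter."""
        arrays = self.sample_arrays(seed, n_draws)
        frame = pd.DataFrame(arrays)
        frame.index.name = "draw"
        return frame


_REQUIRED_COLUMNS = ("name", "family", "mean", "se")


def load_parameter_table(path: str | Path) -> ParameterRegistry:
    """Load a parameter registry from a CSV table.

    Required columns: name, family, mean, se (empty SE means 0);
    optional: group, units, source.  Raises :class:`ParameterError`
    naming the offending row on any invariant violation.
    """
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"parameter table missing column(s): {missing}")
    specs = []
    for _, row in table.iterrows():
        se = row["se"]
        specs.append(
            ParameterSpec(
                name=str(row["name"]),
                family=str(row["family"]),
                mean=float(row["mean"]),
                se=0.0 if pd.isna(se) else float(se),
                group=str(row.get("group", "cost")),
                units="" if pd.isna(row.get("units")) else str(row.get("units")),
                source="" if pd.isna(row.get("source")) else str(row.get("source")),
            )
        )
    return ParameterRegistry(specs)


def default_registry() -> ParameterRegistry:
    """The packaged base-case parameter table."""
    with resources.as_file(
        resources.files("thalcea.data").joinpath("parameters.csv")
    ) as p:
        return load_parameter_table(p)


def sibling_donor_probability(
    n_siblings: int, non_thalassemic_fraction: float = 0.75
) -> float:
    """Probability of an HLA-matched, non-thalassemic sibling donor.

    ``(1 - 0.75**n) * non_thalassemic_fraction``: each sibling has a 1/4
    chance of being HLA-identical, and (by default) a 3/4 chance of being
    free of the disease and thus eligible as a donor.
    """
    if n_siblings < 0:
        raise ValueError("n_siblings must be >= 0")
    if not 0.0 <= non_thalassemic_fraction <= 1.0:
        raise ValueError("non_thalassemic_fraction must be in [0, 1]")
    return (1.0 - 0.75**n_siblings) * non_thalassemic_fraction
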