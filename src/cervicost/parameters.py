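"""Parameter registry and probabilistic sampling for the screening cost model.

Every model input — screening volumes, HIV positivity, smear adequacy,
device effects, cytology sensitivity/specificity, flow probabilities and
unit costs (2014 USD) — lives here as a declarative :class:`ParameterSpec`
with a distribution family (``normal``, ``proportion`` or ``point``), a mean
and 95 % interval bounds.  A packaged YAML registry carries the default
values; :func:`sample_parameters` draws one coherent realization of all of
them for a Monte Carlo trial.

Percentages are stored internally as fractions in [0, 1]; all currency is
2014 USD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "ParameterSpec",
    "ParameterRegistry",
    "ParameterSet",
    "MissingParameterError",
    "ParameterValidationError",
    "load_parameters",
    "default_registry",
    "interval_to_sd",
    "sample_parameters",
    "or_apply",
]

#: two-sided z for a central 95 % interval (2.5th/97.5th percentiles)
Z_CENTRAL_95 = 1.959964
#: z for a 5th/95th-percentile interval, the alternative reading of the
#: registry's interval columns
Z_P5_P95 = 1.644854

_DISTRIBUTIONS = ("normal", "proportion", "point")
_DIST_ALIASES = {"binomial": "proportion"}

#: every name the model requires; a registry missing any of these is invalid
REQUIRED_PARAMETERS = (
    "women_tested_annual",
    "or_endocervical_broom_vs_spatula",
    "or_detection_with_endocervical",
    "or_detection_severe_with_endocervical",
    "hiv_positive_fraction",
    "hiv_women_tested_annual",
    "p_abnormal",
    "f_hsil",
    "f_lsil",
    "f_ascus",
    "p_endocervical_spatula",
    "p_endocervical_broom",
    "sensitivity_with_endocervical",
    "sensitivity_no_endocervical",
    "sensitivity_no_endocervical_hsil",
    "p_repeat_done",
    "p_satisfactory",
    "specificity",
    "p_lost_to_followup",
    "usd_per_zar",
    "cost_spatula",
    "cost_broom",
    "cost_clinic_visit",
    "cost_lab_test",
)


class MissingParameterError(KeyError):
    """A required parameter is absent from a registry or configuration."""


class ParameterValidationError(ValueError):
    """A parameter's value, bounds or distribution violate its invariants."""


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input with its sampling distribution.

    ``proportion`` parameters are fractions in [0, 1] (converted from
    percent at load time when the configured units say so); ``point``
    parameters carry no uncertainty and must have no bounds.
    """

    name: str
    distribution: str
    mean: float
    low95: float | None = None
    high95: float | None = None
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.distribution not in _DISTRIBUTIONS:
            raise ParameterValidationError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )
        has_low, has_high = self.low95 is not None, self.high95 is not None
        if has_low != has_high:
            raise ParameterValidationError(f"{self.name}: one-sided interval bounds")
        if self.distribution == "point":
            if has_low:
                raise ParameterValidationError(
                    f"{self.name}: point parameters carry no interval bounds"
                )
        elif not has_low:
            raise ParameterValidationError(
                f"{self.name}: {self.distribution} parameter needs interval bounds"
            )
        if has_low:
            if not self.low95 <= self.mean <= self.high95:
                raise ParameterValidationError(
                    f"{self.name}: bounds ({self.low95}, {self.high95}) do not "
                    f"bracket the mean {self.mean}"
                )
        if self.distribution == "proportion":
            lo = self.mean if self.low95 is None else self.low95
            hi = self.mean if self.high95 is None else self.high95
            if lo < 0.0 or hi > 1.0:
                raise ParameterValidationError(
                    f"{self.name}: proportion support outside [0, 1]"
                )

    @property
    def is_stochastic(self) -> bool:
        return self.distribution != "point"


def interval_to_sd(low95: float, high95: float, *, interval: str = "central95") -> float:
    """Standard deviation implied by a symmetric 95 % interval.

    ``interval="central95"`` treats the bounds as 2.5th/97.5th percentiles
    (divisor 2 x 1.959964); ``interval="p5p95"`` treats them as 5th/95th
    percentiles (divisor 2 x 1.644854).
    """
    if not low95 < high95:
        raise ValueError(f"interval_to_sd: need low95 < high95, got ({low95}, {high95})")
    if interval == "central95":
        z = Z_CENTRAL_95
    elif interval == "p5p95":
        z = Z_P5_P95
    else:
        raise ValueError(f"interval_to_sd: unknown interval mode {interval!r}")
    return (high95 - low95) / (2.0 * z)


def or_apply(p_base: float, odds_ratio: float) -> float:
    """Apply an odds ratio to a baseline probability.

    Returns the probability whose odds are ``odds_ratio`` times the odds of
    ``p_base``.  Provided as a sensitivity-analysis utility: the default
    registry carries the derived rates (e.g. broom endocervical presence)
    as printed, because the published derivation from the odds ratios is
    not reproducible from the stated inputs.
    """
    if not 0.0 < p_base < 1.0:
        raise ValueError(f"or_apply: p_base must lie strictly in (0, 1), got {p_base}")
    if odds_ratio <= 0.0:
        raise ValueError(f"or_apply: odds_ratio must be positive, got {odds_ratio}")
    odds = odds_ratio * p_base / (1.0 - p_base)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class ParameterSet:
    """A realized value for every parameter, with provenance.

    ``provenance`` is ``"means"`` for the deterministic evaluation at the
    registry means, or ``"sampled(seed,trial)"`` for a Monte Carlo draw.
    """

    values: Mapping[str, float]
    provenance: str = "means"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise MissingParameterError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self.provenance == other.provenance and self.values == other.values


class ParameterRegistry:
    """An ordered mapping of :class:`ParameterSpec` by name."""

    def __init__(self, specs: Iterable[ParameterSpec], *, require_complete: bool = True):
        self._specs: dict[str, ParameterSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ParameterValidationError(f"duplicate parameter {spec.name!r}")
            self._specs[spec.name] = spec
        if require_complete:
            for name in REQUIRED_PARAMETERS:
                if name not in self._specs:
                    raise MissingParameterError(name)
            self._check_grade_mix()

    def _check_grade_mix(self) -> None:
        total = sum(self[n].mean for n in ("f_hsil", "f_lsil", "f_ascus"))
        if abs(total - self["p_abnormal"].mean) > 0.005:
            raise ParameterValidationError(
                "grade fractions f_hsil + f_lsil + f_ascus = "
                f"{total:.4f} differ from p_abnormal = {self['p_abnormal'].mean:.4f} "
                "by more than 0.005"
            )

    def __getitem__(self, name: str) -> ParameterSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise MissingParameterError(name) from None

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterRegistry):
            return NotImplemented
        return self._specs == other._specs

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._specs)

    def means(self) -> ParameterSet:
        """The deterministic realization at the registry means."""
        return ParameterSet({s.name: s.mean for s in self}, provenance="means")

    def to_dict(self) -> dict:
        return {
            "parameters": [
                {
                    "name": s.name,
                    "distribution": s.distribution,
                    "mean": s.mean,
                    **({"low95": s.low95, "high95": s.high95} if s.low95 is not None else {}),
                    "units": s.units,
                    "source": s.source,
                }
                for s in self
            ]
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _parse_entry(entry: Mapping) -> ParameterSpec:
    try:
        name = entry["name"]
    except KeyError:
        raise ParameterValidationError(f"parameter entry without a name: {entry!r}")
    missing = [k for k in ("distribution", "mean") if k not in entry]
    if missing:
        raise ParameterValidationError(f"{name}: missing fields {missing}")
    dist = str(entry["distribution"]).lower()
    dist = _DIST_ALIASES.get(dist, dist)
    units = str(entry.get("units", ""))
    mean = float(entry["mean"])
    low = entry.get("low95")
    high = entry.get("high95")
    low = None if low is None else float(low)
    high = None if high is None else float(high)
    # percent-valued proportions are written as printed; store as fractions
    if "%" in units or "percent" in units.lower():
        mean /= 100.0
        low = None if low is None else low / 100.0
        high = None if high is None else high / 100.0
        units = units.replace("%", "fraction").replace("percent", "fraction")
    return ParameterSpec(
        name=name,
        distribution=dist,
        mean=mean,
        low95=low,
        high95=high,
        units=units,
        source=str(entry.get("source", "")),
    )


def load_parameters(config_source=None, *, require_complete: bool = True) -> ParameterRegistry:
    """Load a :class:`ParameterRegistry` from YAML text, a path, or a mapping.

    With no argument the packaged default registry is loaded; it mirrors the
    published input tables value-for-value.
    """
    if config_source is None:
        text = resources.files("cervicost.data").joinpath("parameters.yaml").read_text()
        payload = yaml.safe_load(text)
    elif isinstance(config_source, Mapping):
        payload = config_source
    else:
        text = str(config_source)
        if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
            with open(text) as fh:
                payload = yaml.safe_load(fh)
        else:
            payload = yaml.safe_load(text)
    if not isinstance(payload, Mapping) or "parameters" not in payload:
        raise ParameterValidationError("configuration must contain a 'parameters' list")
    specs = [_parse_entry(e) for e in payload["parameters"]]
    return ParameterRegistry(specs, require_complete=require_complete)


def default_registry() -> ParameterRegistry:
    """The packaged default registry (published input tables)."""
    return load_parameters(None)


# ---------------------------------------------------------------------------
# sampling


def _trial_uniforms(seed: int, trial: int, n: int) -> np.ndarray:
    """The reproducible uniform draws underlying one trial."""
    if trial < 0:
        raise ValueError("trial index must be >= 0")
    rng = np.random.default_rng([int(seed), int(trial)])
    return rng.random(n)


def _spec_ppf(
    spec: ParameterSpec,
    u,
    *,
    interval: str = "central95",
    proportion_dist: str = "truncnorm",
):
    """Inverse-CDF transform of uniforms for one parameter.

    ``normal`` parameters are truncated at zero (all are inherently
    positive: counts and odds ratios); ``proportion`` parameters are either
    a symmetric normal shape matched to mean and bounds truncated to [0, 1]
    (default, matching the symmetric printed intervals) or a
    moment-matched beta.
    """
    if spec.distribution == "point":
        return np.full_like(np.asarray(u, dtype=float), spec.mean)
    sd = interval_to_sd(spec.low95, spec.high95, interval=interval)
    if spec.distribution == "normal":
        a = (0.0 - spec.mean) / sd
        return stats.truncnorm.ppf(u, a, np.inf, loc=spec.mean, scale=sd)
    if proportion_dist == "truncnorm":
        a = (0.0 - spec.mean) / sd
        b = (1.0 - spec.mean) / sd
        return stats.truncnorm.ppf(u, a, b, loc=spec.mean, scale=sd)
    if proportion_dist == "beta":
        m, v = spec.mean, sd * sd
        k = m * (1.0 - m) / v - 1.0
        if k <= 0:
            raise ParameterValidationError(
                f"{spec.name}: variance too large for a beta moment match"
            )
        return stats.beta.ppf(u, m * k, (1.0 - m) * k)
    raise ValueError(f"unknown proportion_dist {proportion_dist!r}")


def sample_parameters(
    registry: ParameterRegistry,
    seed: int,
    trial: int,
    *,
    interval: str = "central95",
    proportion_dist: str = "truncnorm",
) -> ParameterSet:
    """Draw one Monte Carlo realization of every parameter.

    Identical ``(seed, trial)`` pairs reproduce bit-identical sets.  Point
    parameters are returned as-is.
    """
    names = registry.names
    u = _trial_uniforms(seed, trial, len(names))
    values = {
        name: float(
            _spec_ppf(
                registry[name], u[i], interval=interval, proportion_dist=proportion_dist
            )
        )
        for i, name in enumerate(names)
    }
    return ParameterSet(values, provenance=f"sampled({seed},{trial})")


def sample_trial_matrix(
    registry: ParameterRegistry,
    seed: int,
    n_trials: int,
    *,
    interval: str = "central95",
    proportion_dist: str = "truncnorm",
) -> dict[str, np.ndarray]:
    """Vectorized sampling of ``n_trials`` parameter sets.

    Column ``t`` equals ``sample_parameters(registry, seed, t)``: the same
    per-trial uniform stream feeds a vectorized inverse CDF, so the paired
    Monte Carlo engine and single-trial draws agree exactly.
    """
    names = registry.names
    u = np.empty((n_trials, len(names)))
    for t in range(n_trials):
        u[t] = _trial_uniforms(seed, t, len(names))
    return {
        name: np.asarray(
            _spec_ppf(
                registry[name], u[:, i], interval=interval, proportion_dist=proportion_dist
            ),
            dtype=float,
        )
        for i, name in enumerate(names)
    }
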