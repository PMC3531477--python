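"""Deterministic recursion for centromeric mark levels across generations.

Centromeres are slightly overloaded on passage through the male germline
and underloaded on passage through the female germline.  An autosomal
centromere in a parent descends from its grandfather or grandmother with
equal weight, so the expected parental level is the mean of the previous
generation's paternal and maternal levels; the Y passes exclusively
through males and the X through females two thirds of the time.  Both an
additive and a multiplicative loading mode are provided; levels are
floored at zero (protein amounts are nonnegative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import yaml

logger = logging.getLogger(__name__)


class NonConvergentError(RuntimeError):
    """The paternal-maternal difference did not stabilize within the horizon."""


@dataclass(frozen=True)
class GermlineParams:
    """Sex-specific germline loading parameters.

    Additive mode uses ``male_increment`` (a_m) / ``female_increment``
    (a_f); multiplicative mode uses ``male_factor`` / ``female_factor``.
    The symmetric case a_m == a_f encodes equal extents of over- and
    underloading.
    """

    founder_level: float = 100.0
    male_increment: float = 10.0
    female_increment: float = 10.0
    male_factor: float = 1.1
    female_factor: float = 0.9
    mode: str = "additive"
    n_generations: int = 10

    def __post_init__(self) -> None:
        if self.founder_level <= 0:
            raise ValueError("founder_level must be > 0")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError("mode must be 'additive' or 'multiplicative'")
        if self.mode == "multiplicative" and (self.male_factor <= 0 or self.female_factor <= 0):
            raise ValueError("multiplicative factors must be > 0")
        if self.mode == "additive" and (self.male_increment < 0 or self.female_increment < 0):
            raise ValueError("additive increments must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "GermlineParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class LineageState:
    """Level of one centromere lineage at a given generation."""

    level: float
    chromosome_class: str = "autosome"  # autosome | X | Y
    parental_origin: str = "paternal"  # paternal | maternal
    generation: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("level must be >= 0")


def germline_pass(level: float, sex: str, params: GermlineParams) -> float:
    """One passage through the male or female germline."""
    if level < 0:
        raise ValueError("level must be >= 0")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if params.mode == "additive":
        out = level + params.male_increment if sex == "male" else level - params.female_increment
    else:
        out = level * (params.male_factor if sex == "male" else params.female_factor)
    if out < 0:
        logger.warning("germline pass floored a negative level (%.3g) at 0", out)
        out = 0.0
    return out


def advance_autosomes(
    paternal: float, maternal: float, params: GermlineParams
) -> tuple[float, float]:
    """One generation of the autosomal recursion.

    The expected level in either parent is the mean of the previous
    paternal and maternal levels; the next paternal (maternal) level is
    that mean after a male (female) germline pass.
    """
    mean = (paternal + maternal) / 2.0
    return germline_pass(mean, "male", params), germline_pass(mean, "female", params)


def autosome_trajectory(params: GermlineParams, n: int) -> list[tuple[float, float]]:
    """(paternal, maternal) autosomal levels for generations 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = m = params.founder_level
    out = []
    for _ in range(n):
        p, m = advance_autosomes(p, m, params)
        out.append((p, m))
    return out


def y_trajectory(params: GermlineParams, n: int) -> list[float]:
    """Y-centromere levels for generations 1..n (male germline every time)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    level = params.founder_level
    out = []
    for _ in range(n):
        level = germline_pass(level, "male", params)
        out.append(level)
    return out


def x_expected_trajectory(params: GermlineParams, n: int) -> list[float]:
    """Expected X levels for generations 1..n (1/3 male, 2/3 female passes)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    level = params.founder_level
    out = []
    for _ in range(n):
        level = (
            germline_pass(level, "male", params) / 3.0
            + 2.0 * germline_pass(level, "female", params) / 3.0
        )
        out.append(level)
    return out


def stabilization_generation(
    params: GermlineParams, horizon: int = 20, tol: float = 1e-9
) -> int:
    """First generation from which the paternal-maternal autosomal
    difference stays within ``tol`` of its value at the horizon.

    Raises :class:`NonConvergentError` if only the horizon itself
    qualifies (the difference is still moving there).
    """
    if horizon < 3:
        raise ValueError("horizon must be >= 3")
    diffs = [0.0]  # generation 0: founders, no difference
    p = m = params.founder_level
    for _ in range(horizon):
        p, m = advance_autosomes(p, m, params)
        diffs.append(p - m)
    final = diffs[-1]
    for t, d in enumerate(diffs):
        if all(abs(s - final) <= tol for s in diffs[t:]):
            if t == horizon:
                raise NonConvergentError(
                    f"non-convergent parameters: difference still changing at horizon {horizon}"
                )
            return t
    raise NonConvergentError("non-convergent parameters")  # pragma: no cover


def apply_perturbation(state: LineageState, factor: float) -> LineageState:
    """Multiply the level of a lineage state by a positive factor."""
    if factor <= 0:
        raise ValueError("perturbation factor must be > 0")
    return replace(state, level=state.level * factor)


def embryo_mix(paternal_level: float, maternal_level: float) -> float:
    """Per-nucleus total on a scale where the unperturbed embryo is 1.

    Half of the centromeres in the embryo are paternal, half maternal.
    """
    if paternal_level < 0 or maternal_level < 0:
        raise ValueError("levels must be >= 0")
    return (paternal_level + maternal_level) / 2.0


def template_maintenance(level: float, n_cycles: int) -> float:
    """Level after n mitotic cycles under template-governed loading.

    The amount partitioned onto sister chromatids instructs loading of an
    exactly equivalent amount, so the level is maintained unchanged; a
    zero level is never replenished de novo.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if level < 0:
        raise ValueError("level must be >= 0")
    return level


def sample_autosome_lineages(
    params: GermlineParams, n_generations: int, n_lineages: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic cross-check of the deterministic autosomal recursion.

    Each lineage is one autosomal centromere that is transmitted through a
    uniformly random parental sex every generation.  Returns the final
    levels and the sex of the last germline pass ("male"/"female"); the
    conditional means estimate the deterministic paternal and maternal
    levels.
    """
    if n_generations < 1 or n_lineages < 1:
        raise ValueError("n_generations and n_lineages must be >= 1")
    rng = np.random.default_rng(seed)
    levels = np.full(n_lineages, params.founder_level, dtype=float)
    last = np.empty(n_lineages, dtype="U6")
    for _ in range(n_generations):
        male = rng.random(n_lineages) < 0.5
        if params.mode == "additive":
            levels = np.where(male, levels + params.male_increment, levels - params.female_increment)
            levels = np.maximum(levels, 0.0)
        else:
            levels = np.where(male, levels * params.male_factor, levels * params.female_factor)
        last = np.where(male, "male", "female")
    return levels, last
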