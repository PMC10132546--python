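"""Ranked-set sampling designs based on extreme order statistics.

Three designs are implemented, all ranking units on the cheap auxiliary
covariate ``y`` and keeping the *full* record of the selected unit
(concomitant selection):

* **SRS** — simple random sampling, the baseline comparator.
* **ERSS** — from each of ``m`` independent sets of ``m`` units, measure
  the unit with the minimum (or maximum) auxiliary value; one cycle
  yields ``m`` records at a screening cost of ``m**2`` units.
* **DERSS** — two-stage extreme selection: each of ``m`` sets of ``m**2``
  units is reduced by single-stage extreme selection to ``m`` candidates,
  whose extreme is measured.  Each measured auxiliary value is therefore
  distributionally the extreme of ``m**2`` i.i.d. units, at a screening
  cost of ``m**3`` units per cycle.

Each design supports a ``literal`` mode that screens exactly the stated
number of units, and a distributionally equivalent ``fast`` mode (the
default for simulations) that draws only the ``m`` (or ``m**2``)
auxiliary values behind each measured record and completes the selected
record afterwards.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "Scheme",
    "Direction",
    "SamplingDesign",
    "ExtremeLaw",
    "extreme_cdf",
    "extreme_pdf",
    "srs_draw",
    "erss_draw",
    "derss_draw",
    "scheme_draw",
    "finite_population_draw",
    "CapacityError",
]


class Scheme(str, enum.Enum):
    SRS = "srs"
    ERSS = "erss"
    DERSS = "derss"


class Direction(str, enum.Enum):
    MIN = "min"
    MAX = "max"


class CapacityError(ValueError):
    """Finite population too small for the requested design."""


@runtime_checkable
class UnitSource(Protocol):
    """Anything the samplers can draw i.i.d. units from."""

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame: ...

    def draw_y(self, shape, rng: np.random.Generator) -> np.ndarray: ...

    def complete(self, y: np.ndarray, rng: np.random.Generator) -> pd.DataFrame: ...


class DistributionSource:
    """Unit source whose records carry only an auxiliary value drawn from a
    scipy frozen distribution.  Used to validate the selection laws against
    their closed forms."""

    def __init__(self, dist):
        self.dist = dist

    def draw_y(self, shape, rng: np.random.Generator) -> np.ndarray:
        return self.dist.rvs(size=shape, random_state=rng)

    def complete(self, y: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
        y = np.asarray(y, dtype=float).ravel()
        return pd.DataFrame(
            {"time": np.ones_like(y), "status": np.ones(y.size, dtype=int),
             "x": np.zeros_like(y), "y": y}
        )

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return self.complete(self.draw_y(n, rng), rng)


@dataclass(frozen=True)
class SamplingDesign:
    """A sampling design: scheme, set size ``m``, cycle count ``r`` and
    extreme direction.

    The measured sample size is ``n = m * r`` for every scheme; the
    number of units screened per cycle is ``m`` (SRS), ``m**2`` (ERSS)
    or ``m**3`` (DERSS) in literal mode.
    """

    scheme: Scheme
    m: int
    r: int = 1
    direction: Direction = Direction.MIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        object.__setattr__(self, "direction", Direction(self.direction))
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError(f"set size m must be a positive integer, got {self.m}")
        if self.r < 1 or int(self.r) != self.r:
            raise ValueError(f"cycle count r must be a positive integer, got {self.r}")

    @property
    def n(self) -> int:
        """Measured sample size m * r."""
        return self.m * self.r

    @property
    def screened_per_cycle(self) -> int:
        power = {Scheme.SRS: 1, Scheme.ERSS: 2, Scheme.DERSS: 3}[self.scheme]
        return self.m**power

    @property
    def screened_total(self) -> int:
        return self.screened_per_cycle * self.r


@dataclass(frozen=True)
class ExtremeLaw:
    """Law of the extreme of ``k`` i.i.d. draws from a base distribution,
    where ``k = m**2`` when ``squared`` (the double-extreme design) and
    ``k = m`` otherwise.

    For the minimum, ``G(y) = 1 - (1 - F(y))**k``; for the maximum,
    ``G(y) = F(y)**k``; densities follow by differentiation.
    """

    base_cdf: Callable[[np.ndarray], np.ndarray]
    base_pdf: Callable[[np.ndarray], np.ndarray]
    m: int
    squared: bool = False
    direction: Direction = Direction.MIN

    @property
    def k(self) -> int:
        return self.m**2 if self.squared else self.m

    def cdf(self, y):
        return extreme_cdf(self, y)

    def pdf(self, y):
        return extreme_pdf(self, y)


def extreme_cdf(law: ExtremeLaw, y) -> np.ndarray:
    """CDF of the selected extreme under ``law``."""
    F = np.asarray(law.base_cdf(y), dtype=float)
    if Direction(law.direction) is Direction.MIN:
        return 1.0 - (1.0 - F) ** law.k
    return F**law.k


def extreme_pdf(law: ExtremeLaw, y) -> np.ndarray:
    """Density of the selected extreme under ``law``."""
    F = np.asarray(law.base_cdf(y), dtype=float)
    f = np.asarray(law.base_pdf(y), dtype=float)
    k = law.k
    if Direction(law.direction) is Direction.MIN:
        return k * (1.0 - F) ** (k - 1) * f
    return k * F ** (k - 1) * f


def _extreme_index(y: np.ndarray, direction: Direction, axis: int = -1) -> np.ndarray:
    # ties broken toward the lowest index (argmin/argmax convention);
    # probability zero for continuous auxiliaries
    if direction is Direction.MIN:
        return np.argmin(y, axis=axis)
    return np.argmax(y, axis=axis)


def _reduce_extreme(y: np.ndarray, direction: Direction, axis: int = -1) -> np.ndarray:
    if direction is Direction.MIN:
        return np.min(y, axis=axis)
    return np.max(y, axis=axis)


def srs_draw(source: UnitSource, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Simple random sample of ``n`` i.i.d. records; screened count = n."""
    if n < 0 or int(n) != n:
        raise ValueError(f"sample size must be a nonnegative integer, got {n}")
    df = source.draw(int(n), rng).reset_index(drop=True)
    df.attrs["n_screened"] = int(n)
    return df


def erss_draw(
    source: UnitSource,
    design: SamplingDesign,
    rng: np.random.Generator,
    mode: str = "fast",
) -> pd.DataFrame:
    """Extreme ranked-set sample: ``m * r`` records, each the within-set
    extreme (on ``y``) of an independent set of ``m`` units.

    ``mode="literal"`` screens the full ``m**2`` units per cycle and keeps
    the selected rows; ``mode="fast"`` draws only the auxiliary values and
    completes the selected records, which has the same distribution.
    """
    if design.scheme is not Scheme.ERSS:
        raise ValueError(f"design.scheme must be ERSS, got {design.scheme}")
    m, r, direction = design.m, design.r, design.direction
    if mode == "fast":
        y = source.draw_y((m * r, m), rng)
        df = source.complete(_reduce_extreme(y, direction), rng)
    elif mode == "literal":
        units = source.draw(m * m * r, rng)
        y = units["y"].to_numpy().reshape(r, m, m)
        sel = _extreme_index(y, direction)  # (r, m) index within each set
        flat = (np.arange(r)[:, None] * m * m + np.arange(m)[None, :] * m + sel).ravel()
        df = units.iloc[flat].reset_index(drop=True)
    else:
        raise ValueError(f"mode must be 'fast' or 'literal', got {mode!r}")
    df.attrs["n_screened"] = design.screened_total if mode == "literal" else m * design.n
    return df


def derss_draw(
    source: UnitSource,
    design: SamplingDesign,
    rng: np.random.Generator,
    mode: str = "fast",
) -> pd.DataFrame:
    """Double extreme ranked-set sample: ``m * r`` records, each measured
    auxiliary value distributionally the extreme of ``m**2`` i.i.d. units.

    In literal mode each of the ``m`` sets per cycle holds ``m**2`` units
    arranged as ``m`` samples of ``m``: stage one selects the per-sample
    extreme, stage two the extreme of those ``m`` candidates, screening
    ``m**3`` units per cycle.  Fast mode draws ``m**2`` auxiliary values
    per measured record and takes their extreme directly.
    """
    if design.scheme is not Scheme.DERSS:
        raise ValueError(f"design.scheme must be DERSS, got {design.scheme}")
    m, r, direction = design.m, design.r, design.direction
    if mode == "fast":
        y = source.draw_y((m * r, m * m), rng)
        df = source.complete(_reduce_extreme(y, direction), rng)
    elif mode == "literal":
        units = source.draw(m**3 * r, rng)
        y = units["y"].to_numpy().reshape(r, m, m, m)  # cycle, set, sample, unit
        stage1 = _extreme_index(y, direction)  # (r, m, m): unit index per sample
        y1 = np.take_along_axis(y, stage1[..., None], axis=-1)[..., 0]  # (r, m, m)
        stage2 = _extreme_index(y1, direction)  # (r, m): winning sample per set
        unit_in_sample = np.take_along_axis(stage1, stage2[..., None], axis=-1)[..., 0]
        flat = (
            np.arange(r)[:, None] * m**3
            + np.arange(m)[None, :] * m * m
            + stage2 * m
            + unit_in_sample
        ).ravel()
        df = units.iloc[flat].reset_index(drop=True)
    else:
        raise ValueError(f"mode must be 'fast' or 'literal', got {mode!r}")
    df.attrs["n_screened"] = design.screened_total if mode == "literal" else m * m * design.n
    return df


def scheme_draw(
    source: UnitSource,
    design: SamplingDesign,
    rng: np.random.Generator,
    mode: str = "fast",
) -> pd.DataFrame:
    """Dispatch to the sampler matching ``design.scheme``."""
    if design.scheme is Scheme.SRS:
        return srs_draw(source, design.n, rng)
    if design.scheme is Scheme.ERSS:
        return erss_draw(source, design, rng, mode=mode)
    return derss_draw(source, design, rng, mode=mode)


def finite_population_draw(
    population: pd.DataFrame,
    design: SamplingDesign,
    rank_on: str = "y",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Apply a sampling design to a finite population table.

    Sets are formed by sampling the per-cycle screening requirement
    without replacement from the population; the population is restored
    between cycles so cycles are i.i.d.  For SRS the whole sample of
    ``m * r`` is drawn without replacement in one pass (so a sample the
    size of the population is a permutation of it).
    """
    if rng is None:
        rng = np.random.default_rng()
    if rank_on not in population.columns:
        raise ValueError(f"ranking column {rank_on!r} not in population")
    if population[rank_on].isna().any():
        raise ValueError(f"ranking column {rank_on!r} has missing values")
    pop_n = len(population)
    m, r, direction = design.m, design.r, design.direction

    if design.scheme is Scheme.SRS:
        need = design.n
        if pop_n < need:
            raise CapacityError(
                f"SRS of size {need} needs a population of at least {need} units, got {pop_n}"
            )
        idx = rng.choice(pop_n, size=need, replace=False)
        out = population.iloc[idx].reset_index(drop=True)
        out.attrs["n_screened"] = need
        return out

    need = design.screened_per_cycle
    if pop_n < need:
        raise CapacityError(
            f"{design.scheme.value.upper()} with m={m} screens {need} units per "
            f"cycle but the population has only {pop_n}"
        )
    yvals = population[rank_on].to_numpy()
    rows = []
    for _ in range(r):
        idx = rng.choice(pop_n, size=need, replace=False)
        if design.scheme is Scheme.ERSS:
            sets = idx.reshape(m, m)
            sel = _extreme_index(yvals[sets], direction)
            rows.append(sets[np.arange(m), sel])
        else:  # DERSS
            sets = idx.reshape(m, m, m)  # set, sample, unit
            y = yvals[sets]
            stage1 = _extreme_index(y, direction)  # (m, m)
            y1 = np.take_along_axis(y, stage1[..., None], axis=-1)[..., 0]
            stage2 = _extreme_index(y1, direction)  # (m,)
            unit = np.take_along_axis(stage1, stage2[:, None], axis=-1)[:, 0]
            rows.append(sets[np.arange(m), stage2, unit])
    flat = np.concatenate(rows)
    out = population.iloc[flat].reset_index(drop=True)
    out.attrs["n_screened"] = need * r
    return out
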