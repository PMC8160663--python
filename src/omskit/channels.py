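"""Optical sensor channels and their genetic-algorithm optimization.

A channel is a wavelength interval with a weighting function (boxcar,
gaussian, or triangular); reducing a full spectrum to channel responses
emulates what a few-LED / few-filter multisensor measures.  Channel
configurations are searched with a two-loop genetic algorithm: the inner
loop evolves a population minimizing the calibration error (RMSEC), and
the outer loop restarts from fresh random populations and keeps the
solution with the lowest cross-validated error (RMSECV), which guards
against overfitted interval choices.  Preprocessing parameters can be
co-optimized as extra chromosome loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import calibrate
from .preprocess import PreprocSpec, apply_spec
from .simulate import SpectraSet

__all__ = [
    "Channel",
    "Chromosome",
    "GAParams",
    "GAResult",
    "apply_channels",
    "ga_optimize",
    "co_optimize_preprocessing",
]

_SHAPES = ("boxcar", "gaussian", "triangular")


@dataclass(frozen=True)
class Channel:
    """A sensor channel: center and width in axis units.

    Width is the full width for boxcar/triangular weights and the FWHM for
    gaussian weights (the maximum/half-height-width convention of LED
    emission specs).
    """

    center: float
    width: float
    shape: str = "boxcar"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("channel width must be > 0")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown weight shape {self.shape!r}")

    def weights(self, axis: np.ndarray) -> np.ndarray:
        if self.shape == "boxcar":
            half = self.width / 2
            return (
                (axis >= self.center - half) & (axis <= self.center + half)
            ).astype(float)
        if self.shape == "gaussian":
            return np.exp(
                -4.0 * np.log(2.0) * ((axis - self.center) / self.width) ** 2
            )
        # triangular: apex at center, zero at center +- width/2
        return np.maximum(0.0, 1.0 - 2.0 * np.abs(axis - self.center) / self.width)


def apply_channels(sset: SpectraSet, channels: list[Channel]) -> np.ndarray:
    """Reduce spectra to channel responses (normalized weighted means).

    response = sum(w(lambda) x(lambda)) / sum(w(lambda)) over the axis
    grid, so a channel over a spectrum constant at c responds exactly c.
    """
    if not channels:
        raise ValueError("channel list must not be empty")
    axis = sset.axis
    W = np.empty((len(axis), len(channels)))
    for j, ch in enumerate(channels):
        w = ch.weights(axis)
        tot = w.sum()
        if tot <= 0:
            raise ValueError(
                f"channel at {ch.center:g}/{ch.width:g} has no support on the axis"
            )
        W[:, j] = w / tot
    return sset.X @ W


@dataclass(frozen=True)
class Chromosome:
    channels: tuple[Channel, ...]
    preproc_index: int = 0


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm settings and channel constraints."""

    population_size: int = 30
    generations: int = 60
    mutation_rate: float = 0.4
    crossover_rate: float = 0.7
    n_restarts: int = 3
    n_channels: tuple[int, int] = (2, 2)
    width_bounds: tuple[float, float] = (10.0, 100.0)
    min_separation: float = 0.0
    candidate_centers: tuple[float, ...] | None = None
    candidate_widths: tuple[float, ...] | None = None
    shape: str = "boxcar"
    stagnation: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        for r in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        lo, hi = self.n_channels
        if lo < 1 or hi < lo:
            raise ValueError("n_channels bounds must satisfy 1 <= min <= max")


@dataclass
class GAResult:
    chromosome: Chromosome
    model: calibrate.CalibrationModel
    rmsec: float
    rmsecv: float
    history: list[list[float]] = field(default_factory=list)
    validator_name: str = "loocv"


class _Searcher:
    def __init__(self, sset, target, ga, model_type, n_lv, validator, catalogue):
        self.ga = ga
        self.model_type = model_type
        self.n_lv = n_lv
        self.catalogue = catalogue or [PreprocSpec()]
        self.validator = validator or calibrate.make_loocv_validator(model_type, n_lv)
        self.rng = np.random.default_rng(ga.seed)

        train = sset.meta["role"].to_numpy() == "train"
        self.sets = {}  # preproc index -> processed train SpectraSet
        self._raw = sset.subset(train)
        self.y = self._raw.target(target)
        self.axis = sset.axis
        self._check_feasible()

    def _check_feasible(self) -> None:
        ga = self.ga
        span = float(self.axis[-1] - self.axis[0])
        if ga.min_separation * (ga.n_channels[1] - 1) > span:
            raise ValueError(
                "infeasible constraints: minimum separation "
                f"{ga.min_separation} x {ga.n_channels[1] - 1} channels exceeds "
                f"axis span {span}"
            )

    def _processed(self, idx: int) -> SpectraSet:
        if idx not in self.sets:
            self.sets[idx] = apply_spec(self.catalogue[idx], self._raw)
        return self.sets[idx]

    # -- random genes -------------------------------------------------
    def _random_center(self) -> float:
        ga = self.ga
        if ga.candidate_centers is not None:
            return float(self.rng.choice(ga.candidate_centers))
        return float(self.rng.uniform(self.axis[0], self.axis[-1]))

    def _random_width(self) -> float:
        ga = self.ga
        if ga.candidate_widths is not None:
            return float(self.rng.choice(ga.candidate_widths))
        return float(self.rng.uniform(*ga.width_bounds))

    def _feasible(self, channels: tuple[Channel, ...]) -> bool:
        centers = sorted(c.center for c in channels)
        if self.ga.min_separation > 0:
            for a, b in zip(centers, centers[1:]):
                if b - a < self.ga.min_separation:
                    return False
        return True

    def _random_chromosome(self) -> Chromosome:
        lo, hi = self.ga.n_channels
        for _ in range(200):
            n = int(self.rng.integers(lo, hi + 1))
            chans = tuple(
                Channel(self._random_center(), self._random_width(), self.ga.shape)
                for _ in range(n)
            )
            if self._feasible(chans):
                return Chromosome(
                    chans, int(self.rng.integers(0, len(self.catalogue)))
                )
        raise ValueError("could not sample a feasible chromosome; relax constraints")

    # -- genetic operators --------------------------------------------
    def _crossover(self, a: Chromosome, b: Chromosome) -> Chromosome:
        ca = sorted(a.channels, key=lambda c: c.center)
        cb = sorted(b.channels, key=lambda c: c.center)
        n = len(ca) if self.rng.random() < 0.5 else len(cb)
        child = []
        for i in range(n):
            pool = [c[i] for c in (ca, cb) if i < len(c)]
            child.append(pool[int(self.rng.integers(0, len(pool)))])
        pp = a.preproc_index if self.rng.random() < 0.5 else b.preproc_index
        return Chromosome(tuple(child), pp)

    def _mutate(self, chrom: Chromosome) -> Chromosome:
        ga = self.ga
        chans = list(chrom.channels)
        i = int(self.rng.integers(0, len(chans)))
        c = chans[i]
        move = self.rng.random()
        if move < 0.5:  # center
            if ga.candidate_centers is not None:
                c = replace(c, center=self._random_center())
            else:
                span = self.axis[-1] - self.axis[0]
                new = c.center + self.rng.normal(0.0, 0.05 * span)
                c = replace(c, center=float(np.clip(new, self.axis[0], self.axis[-1])))
        elif move < 0.8:  # width
            if ga.candidate_widths is not None:
                c = replace(c, width=self._random_width())
            else:
                lo, hi = ga.width_bounds
                new = c.width + self.rng.normal(0.0, 0.2 * (hi - lo))
                c = replace(c, width=float(np.clip(new, lo, hi)))
        else:  # add/remove a channel, or re-roll preprocessing
            lo_n, hi_n = ga.n_channels
            if len(self.catalogue) > 1 and self.rng.random() < 0.5:
                return Chromosome(
                    chrom.channels, int(self.rng.integers(0, len(self.catalogue)))
                )
            if len(chans) < hi_n and self.rng.random() < 0.5:
                chans.append(
                    Channel(self._random_center(), self._random_width(), ga.shape)
                )
                return Chromosome(tuple(chans), chrom.preproc_index)
            if len(chans) > lo_n:
                chans.pop(i)
                return Chromosome(tuple(chans), chrom.preproc_index)
        chans[i] = c
        return Chromosome(tuple(chans), chrom.preproc_index)

    def _repaired(self, chrom: Chromosome) -> Chromosome:
        for _ in range(50):
            if self._feasible(chrom.channels):
                return chrom
            chrom = self._mutate(chrom)
        return Chromosome(
            self._random_chromosome().channels, chrom.preproc_index
        )

    # -- fitness ------------------------------------------------------
    def _reduced(self, chrom: Chromosome) -> np.ndarray:
        return apply_channels(self._processed(chrom.preproc_index), list(chrom.channels))

    def fitness(self, chrom: Chromosome) -> float:
        """Inner-loop objective: RMSEC of the calibration on the channels."""
        try:
            R = self._reduced(chrom)
            model = calibrate.fit(R, self.y, self.model_type, self.n_lv)
            return calibrate.rmse(self.y, model.predict(R))
        except (ValueError, np.linalg.LinAlgError):
            return np.inf

    def rmsecv(self, chrom: Chromosome) -> float:
        try:
            return float(self.validator(self._reduced(chrom), self.y))
        except (ValueError, np.linalg.LinAlgError):
            return np.inf

    # -- loops ----------------------------------------------------------
    def evolve(self) -> tuple[Chromosome, float, list[float]]:
        ga = self.ga
        pop = [self._random_chromosome() for _ in range(ga.population_size)]
        fits = [self.fitness(c) for c in pop]
        best_i = int(np.argmin(fits))
        best, best_fit = pop[best_i], fits[best_i]
        trace = [best_fit]
        stagnant = 0
        for _ in range(ga.generations):
            new_pop = [best]  # elitism of 1
            while len(new_pop) < ga.population_size:
                pa = self._tournament(pop, fits)
                if self.rng.random() < ga.crossover_rate:
                    pb = self._tournament(pop, fits)
                    child = self._crossover(pa, pb)
                else:
                    child = pa
                if self.rng.random() < ga.mutation_rate:
                    child = self._mutate(child)
                new_pop.append(self._repaired(child))
            pop = new_pop
            fits = [self.fitness(c) for c in pop]
            gen_best = int(np.argmin(fits))
            if fits[gen_best] < best_fit - 1e-15:
                best, best_fit = pop[gen_best], fits[gen_best]
                stagnant = 0
            else:
                stagnant += 1
            trace.append(best_fit)
            if stagnant >= ga.stagnation:
                break
        return best, best_fit, trace

    def _tournament(self, pop, fits) -> Chromosome:
        i, j = self.rng.integers(0, len(pop), size=2)
        return pop[i] if fits[i] <= fits[j] else pop[j]

    def run(self) -> GAResult:
        best_res = None
        history = []
        for _ in range(self.ga.n_restarts):
            chrom, rmsec, trace = self.evolve()
            history.append(trace)
            cv = self.rmsecv(chrom)
            if best_res is None or cv < best_res[2]:
                best_res = (chrom, rmsec, cv)
        chrom, rmsec, cv = best_res
        R = self._reduced(chrom)
        model = calibrate.fit(R, self.y, self.model_type, self.n_lv)
        model.preproc = self.catalogue[chrom.preproc_index]
        return GAResult(
            chromosome=chrom,
            model=model,
            rmsec=rmsec,
            rmsecv=cv,
            history=history,
        )


def ga_optimize(
    sset: SpectraSet,
    target: str,
    ga: GAParams,
    model_type: str = "mlr",
    n_lv: int | None = None,
    validator=None,
) -> GAResult:
    """Two-loop GA channel optimization.

    Inner loop: evolve a population minimizing RMSEC.  Outer loop: repeat
    from ``n_restarts`` random initial populations and keep the converged
    solution with the lowest RMSECV under the injected validator (LOOCV
    by default).  All randomness flows from ``ga.seed``.
    """
    return _Searcher(sset, target, ga, model_type, n_lv, validator, None).run()


def co_optimize_preprocessing(
    sset: SpectraSet,
    target: str,
    ga: GAParams,
    catalogue: list[PreprocSpec],
    model_type: str = "mlr",
    n_lv: int | None = None,
    validator=None,
) -> GAResult:
    """GA over the product space of channel parameters and preprocessing.

    The chromosome carries an extra integer locus indexing the finite
    ``catalogue`` of preprocessing pipelines (derivative order, smoothing
    window, ...), applied to the full spectra before channel reduction.
    With a single-entry catalogue this reduces exactly to
    :func:`ga_optimize`.
    """
    if not catalogue:
        raise ValueError("preprocessing catalogue must not be empty")
    return _Searcher(sset, target, ga, model_type, n_lv, validator, catalogue).run()
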