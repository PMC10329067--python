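"""HLA population coverage and peptidome saturation.

Population coverage assumes Hardy-Weinberg genotype frequencies within each
HLA locus and independence across loci: if the covered alleles at locus ``l``
sum to frequency ``f``, a random individual carries 2 covered allotypes at
that locus with probability ``f**2``, exactly one with ``2 f (1 - f)`` and
none with ``(1 - f)**2``. Convolving these per-locus distributions gives the
probability of carrying ``m`` covered allotypes overall; allele frequencies
need not sum to 1 per locus (the remainder is uncovered mass). Linkage
disequilibrium between loci is ignored.

Saturation of the cumulative number of unique items (antigens or peptides)
with growing sample number is summarised by fitting
``y(x) = y_max * (1 - exp(-rate * x))`` to the mean accumulation curve over
random sample orderings; ``attained_fraction`` is the observed unique count
divided by the fitted asymptote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)


def locus_of(allotype: str) -> str:
    """Locus label of an allotype name such as ``A*02:01`` -> ``A``."""
    if "*" not in allotype:
        raise ValidationError(f"cannot infer locus from allotype name {allotype!r}")
    return allotype.split("*", 1)[0]


@dataclass
class AlleleFrequencyTable:
    """Per-population allele frequencies: population -> locus -> allotype -> f."""

    freqs: dict[str, dict[str, dict[str, float]]]

    def __post_init__(self) -> None:
        for pop, loci in self.freqs.items():
            for locus, table in loci.items():
                total = 0.0
                for allo, f in table.items():
                    if not (0.0 <= f <= 1.0):
                        raise ValidationError(
                            f"frequency of {allo} in {pop} outside [0, 1]: {f}"
                        )
                    total += f
                if total > 1.0 + 1e-9:
                    raise ValidationError(
                        f"frequencies at locus {locus} in {pop} sum to {total} > 1"
                    )

    def populations(self) -> list[str]:
        return sorted(self.freqs)

    def loci(self, population: str) -> list[str]:
        return sorted(self.freqs[population])

    def covered_fraction(self, population: str, locus: str,
                         covered: Iterable[str]) -> float:
        """Summed frequency of the covered allotypes at one locus."""
        table = self.freqs[population].get(locus, {})
        return float(sum(table.get(a, 0.0) for a in covered))


@dataclass
class CoverageResult:
    """Distribution of the number of covered allotypes carried per individual."""

    population: str
    pmf: np.ndarray  # index m = number of matched allotypes, 0 .. 2 * n_loci
    n_loci: int

    def p_at_least(self, k: int) -> float:
        if k <= 0:
            return 1.0
        if k >= len(self.pmf):
            return 0.0
        return float(self.pmf[k:].sum())


@dataclass
class SaturationFit:
    """Exponential-saturation fit of an accumulation curve."""

    y_max: float
    rate: float
    attained_fraction: float
    observed_unique: int
    n_samples: int
    mean_curve: np.ndarray = field(repr=False)


def locus_hit_distribution(f: float) -> np.ndarray:
    """Hardy-Weinberg pmf over {0, 1, 2} covered allotypes at one locus."""
    if not (0.0 <= f <= 1.0):
        raise ValidationError(f"covered allele frequency outside [0, 1]: {f}")
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f * f])


def population_coverage(table: AlleleFrequencyTable, covered_allotypes: Iterable[str],
                        population: str) -> CoverageResult:
    """Distribution of covered-allotype counts for one population.

    Allotypes absent from the table contribute zero frequency (a warning is
    logged); loci without any covered allotype still enter the convolution
    with f = 0 so the support is always 0 .. 2 * n_loci.
    """
    covered = set(covered_allotypes)
    loci_tables = table.freqs[population]
    known = {a for t in loci_tables.values() for a in t}
    unknown = covered - known
    if unknown:
        logger.warning("%d covered allotypes absent from frequency table: %s",
                       len(unknown), sorted(unknown)[:5])
    pmf = np.array([1.0])
    loci = sorted(loci_tables)
    for locus in loci:
        f = table.covered_fraction(population, locus, covered)
        pmf = np.convolve(pmf, locus_hit_distribution(f))
    return CoverageResult(population=population, pmf=pmf, n_loci=len(loci))


def expected_matching_items(items: Sequence[tuple[str, Iterable[str]]],
                            table: AlleleFrequencyTable,
                            population: str) -> float:
    """Expected number of items matched per random individual.

    ``items`` are (item_id, restricting allotypes) pairs; an item matches an
    individual carrying at least one of its restricting allotypes. Items with
    an empty restriction set are excluded (counted in a log message).
    """
    skipped = 0
    total = 0.0
    for item_id, restriction in items:
        allos = set(restriction)
        if not allos:
            skipped += 1
            continue
        p_none = 1.0
        by_locus: dict[str, set[str]] = {}
        for a in allos:
            by_locus.setdefault(locus_of(a), set()).add(a)
        for locus, group in by_locus.items():
            f = table.covered_fraction(population, locus, group)
            p_none *= (1.0 - f) ** 2
        total += 1.0 - p_none
    if skipped:
        logger.warning("%d items without restricting allotypes excluded", skipped)
    return total


def accumulation_curve(item_sets: Mapping[str, set], n_orderings: int,
                       seed: int) -> np.ndarray:
    """Mean cumulative-unique curve over random orderings of the samples."""
    ids = sorted(item_sets)
    n = len(ids)
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for _ in range(n_orderings):
        order = rng.permutation(n)
        seen: set = set()
        for i, j in enumerate(order):
            seen |= item_sets[ids[j]]
            total[i] += len(seen)
    return total / n_orderings


def fit_saturation_curve(x: np.ndarray, y: np.ndarray,
                         y_floor: float | None = None) -> tuple[float, float]:
    """Least-squares fit of ``y = y_max * (1 - exp(-rate * x))``.

    ``y_floor`` constrains the asymptote from below (the observed unique
    count can never exceed the estimated maximum).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = y_floor if y_floor is not None else 0.0
    p0 = [max(float(y[-1]) * 1.2, lo + 1e-6), 0.5]

    def model(xx, y_max, rate):
        return y_max * (1.0 - np.exp(-rate * xx))

    try:
        popt, _ = curve_fit(model, x, y, p0=p0,
                            bounds=([lo, 1e-12], [np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FitError(f"saturation fit did not converge: {exc}; "
                       f"n={len(x)}, y_last={y[-1]}") from exc
    return float(popt[0]), float(popt[1])


def saturation_estimate(item_sets: Mapping[str, set], n_orderings: int = 1000,
                        seed: int = 0) -> SaturationFit:
    """Estimate the maximum attainable unique-item count from a cohort.

    ``item_sets`` maps sample_id to its set of items (source proteins or
    peptides). Requires at least three samples.
    """
    if len(item_sets) < 3:
        raise ValidationError(
            f"saturation estimate requires >= 3 samples, got {len(item_sets)}")
    curve = accumulation_curve(item_sets, n_orderings, seed)
    observed = len(set().union(*item_sets.values()))
    x = np.arange(1, len(curve) + 1, dtype=float)
    y_max, rate = fit_saturation_curve(x, curve, y_floor=float(observed))
    return SaturationFit(y_max=y_max, rate=rate,
                         attained_fraction=observed / y_max,
                         observed_unique=observed,
                         n_samples=len(item_sets), mean_curve=curve)
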