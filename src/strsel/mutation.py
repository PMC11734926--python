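"""Allele-size-dependent stepwise mutation for microsatellites.

Mutation rate rises with allele size.  For dinucleotide repeats of size
``a >= 8`` the per-allele per-generation rate follows the empirical
polynomial ``(0.08 + 0.002*a + 0.0002*a**2) / 1000``; other motif sizes use
the same polynomial scaled by a motif-specific factor, and rate uncertainty
is integrated over by a family of multiplicative curves.  Alleles shorter
than 8 repeats mutate at a very low flat rate (between 1e-8 and 1e-6).

A mutation changes allele size by an integer step: the magnitude is
geometric on {1, 2, ...} (single-repeat steps dominate) and the direction is
+/- with equal probability.  Mutated sizes are clamped to [1, max_allele].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MutationSpec",
    "CURVE_MULTIPLIERS",
    "SMALL_ALLELE_RATE_RANGE",
    "mutation_rate",
    "mutation_rate_table",
    "mutate_allele",
    "mutate_alleles",
    "draw_mutation_spec",
]

#: Five-curve uncertainty family applied multiplicatively to the baseline curve.
CURVE_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)

#: Flat-rate bounds for alleles shorter than 8 repeats.
SMALL_ALLELE_RATE_RANGE = (1e-8, 1e-6)

#: Baseline polynomial scaling per motif size (dinucleotide = 1; trinucleotide
#: curves are less certain and default to half the dinucleotide baseline).
DEFAULT_BASELINE_SCALE = {1: 1.0, 2: 1.0, 3: 0.5, 4: 0.5, 5: 0.5, 6: 0.5}

_POLY_THRESHOLD = 8  # smallest allele size governed by the polynomial


@dataclass(frozen=True)
class MutationSpec:
    """Mutation process parameters for one motif size.

    Parameters
    ----------
    motif_size
        Repeat-unit length in nucleotides (1-6).
    curve_multiplier
        One member of the five-curve uncertainty family
        (:data:`CURVE_MULTIPLIERS`); drawn per simulation when building
        reference tables.
    baseline_scale
        Motif-specific scaling of the dinucleotide polynomial.
    small_allele_rate
        Flat per-allele per-generation rate for alleles of size < 8;
        must lie in [1e-8, 1e-6].
    step_prob
        Success parameter of the geometric step-magnitude distribution;
        1.0 means strictly single-step mutation.
    max_allele
        Hard cap on simulated allele size (mutations are clamped).
    rate_scale
        Extra multiplier applied to every rate; 1.0 except under diffusion
        rescaling (see :mod:`strsel.scaling`).
    """

    motif_size: int = 2
    curve_multiplier: float = 1.0
    baseline_scale: float = 1.0
    small_allele_rate: float = 1e-7
    step_prob: float = 0.85
    max_allele: int = 120
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.motif_size not in range(1, 7):
            raise ValueError(f"motif_size must be in 1..6, got {self.motif_size}")
        if self.curve_multiplier <= 0 or self.baseline_scale <= 0:
            raise ValueError("curve_multiplier and baseline_scale must be positive")
        lo, hi = SMALL_ALLELE_RATE_RANGE
        if not (lo <= self.small_allele_rate <= hi):
            raise ValueError(
                f"small_allele_rate must be in [{lo:g}, {hi:g}], got {self.small_allele_rate:g}"
            )
        if not (0.0 < self.step_prob <= 1.0):
            raise ValueError(f"step_prob must be in (0, 1], got {self.step_prob}")
        if self.max_allele < 1:
            raise ValueError("max_allele must be >= 1")

    @classmethod
    def for_motif(cls, motif_size: int, **kwargs) -> "MutationSpec":
        """Spec with the default baseline scaling for a motif size."""
        kwargs.setdefault("baseline_scale", DEFAULT_BASELINE_SCALE[motif_size])
        return cls(motif_size=motif_size, **kwargs)


def _polynomial_rate(a: float) -> float:
    return (0.08 + 0.002 * a + 0.0002 * a * a) / 1000.0


def mutation_rate(spec: MutationSpec, a: int) -> float:
    """Per-allele per-generation mutation probability for allele size ``a``."""
    if a < 1:
        raise ValueError(f"allele size must be >= 1, got {a}")
    if a < _POLY_THRESHOLD:
        rate = spec.small_allele_rate
    else:
        rate = spec.curve_multiplier * spec.baseline_scale * _polynomial_rate(a)
    return min(max(rate * spec.rate_scale, 0.0), 1.0)


def mutation_rate_table(spec: MutationSpec) -> np.ndarray:
    """Lookup table ``MU[a]`` for a = 0..max_allele (index 0 is NaN)."""
    sizes = np.arange(1, spec.max_allele + 1, dtype=float)
    poly = (0.08 + 0.002 * sizes + 0.0002 * sizes**2) / 1000.0
    rates = np.where(
        sizes < _POLY_THRESHOLD,
        spec.small_allele_rate,
        spec.curve_multiplier * spec.baseline_scale * poly,
    )
    rates = np.clip(rates * spec.rate_scale, 0.0, 1.0)
    table = np.full(spec.max_allele + 1, np.nan)
    table[1:] = rates
    return table


def _step(spec: MutationSpec, rng: np.random.Generator) -> int:
    """One signed mutation step: geometric magnitude, fair sign."""
    magnitude = rng.geometric(spec.step_prob)
    sign = 1 if rng.random() < 0.5 else -1
    return sign * magnitude

def mutate_allele(spec: MutationSpec, a: int, rng: np.random.Generator) -> int:
    """Apply the mutation process to a single transmitted allele."""
    if a < 1:
        raise ValueError(f"allele size must be >= 1, got {a}")
    if rng.random() >= mutation_rate(spec, a):
        return a
    return int(min(max(a + _step(spec, rng), 1), spec.max_allele))


def mutate_alleles(
    alleles: np.ndarray,
    mu_table: np.ndarray,
    spec: MutationSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized mutation of an array of transmitted alleles (in place).

    ``mu_table`` must come from :func:`mutation_rate_table` for ``spec``.
    """
    hit = rng.random(alleles.size) < mu_table[alleles]
    n = int(hit.sum())
    if n:
        steps = rng.geometric(spec.step_prob, size=n).astype(alleles.dtype)
        signs = (rng.integers(0, 2, size=n) * 2 - 1).astype(alleles.dtype)
        mutated = alleles[hit] + signs * steps
        alleles[hit] = np.clip(mutated, 1, spec.max_allele)
    return alleles


def draw_mutation_spec(
    motif_size: int, rng: np.random.Generator, **overrides
) -> MutationSpec:
    """Draw the per-simulation mutation nuisance parameters.

    One of the five uncertainty curves is drawn uniformly, and the
    small-allele rate is drawn log-uniformly on [1e-8, 1e-6].
    """
    lo, hi = SMALL_ALLELE_RATE_RANGE
    spec = MutationSpec.for_motif(
        motif_size,
        curve_multiplier=float(rng.choice(CURVE_MULTIPLIERS)),
        small_allele_rate=float(math.exp(rng.uniform(math.log(lo), math.log(hi)))),
    )
    if overrides:
        spec = replace(spec, **overrides)
    return spec
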