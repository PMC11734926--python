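"""Selection models for microsatellite loci.

A microsatellite allele is an integer repeat count ``a``.  Five evolutionary
models are supported: a neutral model and four two-parameter selection models
built from a key allele size ``alpha`` and a selection strength ``s``:

* **ASO / DSO** (additive / dominant, single optimum): marginal fitness is a
  Gaussian function of the distance from the optimum,
  ``w(a) = exp(-s * (a - alpha)**2)``.
* **APO / DPO** (additive / dominant, periodic optima): every positive
  multiple of ``alpha`` is an optimum, and marginal fitness declines
  exponentially with the (linear) distance to the nearest multiple,
  ``w(a) = exp(-s * min(a - alpha*floor(a/alpha), alpha*ceil(a/alpha) - a))``.

Additive models assign a genotype the mean of its two allelic marginal
fitnesses; dominant models assign the maximum.  Under neutrality every
genotype has relative fitness 1.0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelKind",
    "SelectionModelSpec",
    "FitnessSurface",
    "marginal_fitness",
    "genotype_fitness",
    "genotype_count",
    "fitness_surface",
    "fitness_table",
]

S_PRIOR_LOW = 1e-6
S_PRIOR_HIGH = 0.02
ALPHA_PRIOR_LOW = 2
ALPHA_PRIOR_HIGH = 50


class ModelKind(enum.Enum):
    """The five evolutionary models, in canonical order."""

    NEUTRAL = "NEUTRAL"
    ASO = "ASO"
    DSO = "DSO"
    APO = "APO"
    DPO = "DPO"

    @property
    def is_neutral(self) -> bool:
        return self is ModelKind.NEUTRAL

    @property
    def is_periodic(self) -> bool:
        return self in (ModelKind.APO, ModelKind.DPO)

    @property
    def is_dominant(self) -> bool:
        return self in (ModelKind.DSO, ModelKind.DPO)


#: Canonical model order used for tie-breaking and table layouts.
MODEL_ORDER = [
    ModelKind.NEUTRAL,
    ModelKind.ASO,
    ModelKind.DSO,
    ModelKind.APO,
    ModelKind.DPO,
]


@dataclass(frozen=True)
class SelectionModelSpec:
    """An evolutionary model plus its two selection parameters.

    Parameters
    ----------
    kind
        One of the five model kinds (or its string name).
    s
        Selection strength; must lie in ``(0, 0.02]`` for non-neutral kinds
        (ignored, treated as 0, under neutrality).  Diffusion-rescaled
        specs (see :mod:`strsel.scaling`) may exceed the prior bound and are
        marked with ``rescaled=True``.
    alpha
        Key allele size in repeat units, an integer in ``[2, 50]`` for
        non-neutral kinds.
    """

    kind: ModelKind
    s: float = 0.0
    alpha: int = 0
    rescaled: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            object.__setattr__(self, "kind", ModelKind(self.kind))
        if not self.kind.is_neutral:
            if not (self.s > 0.0):
                raise ValueError(f"s must be positive for {self.kind.value}, got {self.s}")
            if not self.rescaled and self.s > S_PRIOR_HIGH:
                raise ValueError(f"s={self.s} outside prior bound (0, {S_PRIOR_HIGH}]")
            if not (ALPHA_PRIOR_LOW <= int(self.alpha) <= ALPHA_PRIOR_HIGH):
                raise ValueError(
                    f"alpha must be an integer in [{ALPHA_PRIOR_LOW}, {ALPHA_PRIOR_HIGH}], got {self.alpha}"
                )
            object.__setattr__(self, "alpha", int(self.alpha))

    @classmethod
    def neutral(cls) -> "SelectionModelSpec":
        return cls(kind=ModelKind.NEUTRAL)


def marginal_fitness(model: SelectionModelSpec, a: int) -> float:
    """Relative marginal fitness of an allele of size ``a`` under ``model``.

    Returns 1.0 under neutrality, at ``a == alpha`` for any selection model,
    and at every positive multiple of ``alpha`` under the periodic models.
    """
    if a < 1:
        raise ValueError(f"allele size must be >= 1, got {a}")
    kind = model.kind
    if kind.is_neutral:
        return 1.0
    s, alpha = model.s, model.alpha
    if kind.is_periodic:
        below = a - alpha * math.floor(a / alpha)
        above = alpha * math.ceil(a / alpha) - a
        return math.exp(-s * min(below, above))
    return math.exp(-s * (a - alpha) ** 2)


def genotype_fitness(model: SelectionModelSpec, a1: int, a2: int) -> float:
    """Relative fitness of the unordered diploid genotype ``(a1, a2)``.

    Additive kinds average the two marginal fitnesses; dominant kinds take
    their maximum; neutral returns 1.0.  Symmetric in its allele arguments.
    """
    if a1 < 1 or a2 < 1:
        raise ValueError(f"allele sizes must be >= 1, got ({a1}, {a2})")
    if model.kind.is_neutral:
        return 1.0
    w1 = marginal_fitness(model, a1)
    w2 = marginal_fitness(model, a2)
    if model.kind.is_dominant:
        return max(w1, w2)
    return 0.5 * (w1 + w2)


def genotype_count(n: int) -> int:
    """Number of distinct unordered diploid genotypes for ``n`` alleles: n(n+1)/2."""
    if n < 1:
        raise ValueError(f"number of alleles must be >= 1, got {n}")
    return n * (n + 1) // 2


def _marginal_vector(model: SelectionModelSpec, sizes: np.ndarray) -> np.ndarray:
    """Vectorized marginal fitness over an array of allele sizes."""
    if model.kind.is_neutral:
        return np.ones_like(sizes, dtype=float)
    s, alpha = model.s, model.alpha
    a = sizes.astype(float)
    if model.kind.is_periodic:
        below = a - alpha * np.floor(a / alpha)
        above = alpha * np.ceil(a / alpha) - a
        return np.exp(-s * np.minimum(below, above))
    return np.exp(-s * (a - alpha) ** 2)


@dataclass(frozen=True)
class FitnessSurface:
    """Genotypic fitness over all unordered allele pairs in a size range.

    ``grid[i, j]`` is the relative fitness of genotype
    ``(sizes[i], sizes[j])``; the matrix is symmetric, all values lie in
    (0, 1] and at least one genotype attains 1.0 whenever the range covers
    an optimum (always true for neutral models).
    """

    model: SelectionModelSpec
    sizes: np.ndarray
    grid: np.ndarray

    def to_frame(self):
        """Tab-separable matrix labelled by allele size (pandas DataFrame)."""
        import pandas as pd

        return pd.DataFrame(self.grid, index=self.sizes, columns=self.sizes)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="allele_size")


def fitness_surface(model: SelectionModelSpec, a_min: int, a_max: int) -> FitnessSurface:
    """Build the genotypic fitness surface over allele sizes ``[a_min, a_max]``."""
    if not (1 <= a_min <= a_max):
        raise ValueError(f"need 1 <= a_min <= a_max, got ({a_min}, {a_max})")
    sizes = np.arange(a_min, a_max + 1)
    w = _marginal_vector(model, sizes)
    if model.kind.is_dominant:
        grid = np.maximum.outer(w, w)
    elif model.kind.is_neutral:
        grid = np.ones((sizes.size, sizes.size))
    else:
        grid = 0.5 * np.add.outer(w, w)
    return FitnessSurface(model=model, sizes=sizes, grid=grid)


def fitness_table(model: SelectionModelSpec, max_allele: int) -> np.ndarray:
    """Dense lookup table ``W`` with ``W[a1, a2]`` = genotype fitness.

    Index 0 is unused (allele sizes start at 1) and filled with NaN so that
    accidental use is loud.  Used by the forward simulator for O(1) fitness
    lookups.
    """
    surf = fitness_surface(model, 1, max_allele)
    table = np.full((max_allele + 1, max_allele + 1), np.nan)
    table[1:, 1:] = surf.grid
    return table
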