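"""Forward-in-time simulation of microsatellite evolution.

The simulation pipeline mirrors the inference method's generative model:

1. Draw a starting allele-frequency distribution (AFD) from a pool built by
   single-population Kingman coalescent simulation under the stepwise
   mutation model (population mutation rate ``theta = 4*Ne*mu``).
2. Found the universal common ancestor (UCA) population of 10,000 diploids
   at Hardy-Weinberg equilibrium and evolve it neutrally for a 2,000
   generation burn-in.
3. Follow the demographic schedule: populations split at fixed generations,
   descendants are founded as proportions of the parent and grow linearly,
   and every descendant population evolves under the drawn selection model
   (viability selection), sex-free random mating with replacement, and
   allele-size-dependent stepwise mutation at transmission.
4. 4,750 generations after the first split, sample the eight extant
   populations at the study sample sizes (200 diploids total) and summarize
   them as 408 features: per population, the frequencies of allele sizes
   1-50 plus observed heterozygosity.

Reference tables pair these feature vectors with the generating model label
and parameters, and are the training data for the ABC random forests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .demography import LEAF_POPULATIONS, DemographicSchedule
from .mutation import MutationSpec, draw_mutation_spec, mutation_rate_table
from .scaling import rescale_model, rescale_mutation, rescale_schedule
from .selection import (
    MODEL_ORDER,
    ModelKind,
    SelectionModelSpec,
    fitness_table,
)

__all__ = [
    "AFD",
    "AFDPoolConfig",
    "AFDPool",
    "Priors",
    "SimulationResult",
    "ReferenceTable",
    "MinSResult",
    "generate_afd",
    "build_afd_pool",
    "init_population",
    "step_generation",
    "run_simulation",
    "summarize",
    "feature_names",
    "build_reference_table",
    "min_s_for_invariance",
]

_ALLELE_DTYPE = np.int16
_MAX_BINNED_SIZE = 50  # allele-frequency features cover sizes 1..50


# ---------------------------------------------------------------------------
# Allele-frequency distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AFD:
    """Allele-frequency distribution: allele sizes and their frequencies."""

    sizes: np.ndarray
    freqs: np.ndarray
    theta: Optional[float] = None
    ancestral_size: Optional[int] = None

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=int)
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "freqs", freqs)
        if sizes.size == 0:
            raise ValueError("AFD must contain at least one allele")
        if sizes.min() < 1:
            raise ValueError("allele sizes must be >= 1")
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be nonnegative and sum to 1")

    @classmethod
    def from_counts(cls, counts: dict[int, int], **kwargs) -> "AFD":
        sizes = np.array(sorted(counts))
        n = np.array([counts[s] for s in sizes], dtype=float)
        return cls(sizes=sizes, freqs=n / n.sum(), **kwargs)

    @classmethod
    def monomorphic(cls, size: int) -> "AFD":
        return cls(sizes=np.array([size]), freqs=np.array([1.0]))

    def mean_allele_size(self) -> float:
        return float(np.dot(self.sizes, self.freqs))

    def variance_allele_size(self) -> float:
        m = self.mean_allele_size()
        return float(np.dot((self.sizes - m) ** 2, self.freqs))

    def homozygosity(self) -> float:
        """Expected homozygosity sum(p_i^2)."""
        return float(np.dot(self.freqs, self.freqs))


def generate_afd(
    theta: float, ancestral_size: int, n_haplotypes: int, rng: np.random.Generator
) -> AFD:
    """Simulate one AFD with a Kingman coalescent under stepwise mutation.

    ``n_haplotypes`` lineages coalesce at the standard pairwise rate;
    mutations fall on branches as a Poisson process at rate ``theta/2`` per
    lineage per coalescent time unit, each shifting allele size by +/-1
    (clamped at 1).  The returned AFD is the sample's normalized frequency
    spectrum.
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if ancestral_size < 2:
        raise ValueError(f"ancestral_size must be >= 2, got {ancestral_size}")
    if n_haplotypes < 2:
        raise ValueError(f"n_haplotypes must be >= 2, got {n_haplotypes}")

    n = n_haplotypes
    n_nodes = 2 * n - 1
    parent = np.empty(n_nodes - 1, dtype=np.int64)  # root has no parent
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        for idx in sorted((i, j), reverse=True):
            active[idx] = active[-1]
            active.pop()
        active.append(nxt)
        nxt += 1
        k -= 1

    root = n_nodes - 1
    branch_len = node_time[parent] - node_time[: n_nodes - 1]
    n_mut = rng.poisson(theta / 2.0 * branch_len)
    ups = rng.binomial(n_mut, 0.5)
    net = 2 * ups - n_mut
    value = np.empty(n_nodes, dtype=np.int64)
    value[root] = ancestral_size
    for node in range(root - 1, -1, -1):
        value[node] = max(1, value[parent[node]] + net[node])
    leaves = value[:n]
    sizes, counts = np.unique(leaves, return_counts=True)
    return AFD(
        sizes=sizes,
        freqs=counts / counts.sum(),
        theta=float(theta),
        ancestral_size=int(ancestral_size),
    )


@dataclass(frozen=True)
class AFDPoolConfig:
    """Configuration of the starting-AFD pool.

    The full-scale pool holds 20,000 AFDs with ``theta ~ U[0.04, 40]`` and
    an integer ancestral allele size drawn uniformly on
    ``ancestral_size_range``; scaled-down runs use smaller pools.
    """

    pool_size: int = 20_000
    theta_range: tuple[float, float] = (0.04, 40.0)
    ancestral_size_range: tuple[int, int] = (5, 30)
    n_haplotypes: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not (0 < self.theta_range[0] <= self.theta_range[1]):
            raise ValueError("theta_range must lie within (0, inf)")
        if self.ancestral_size_range[0] < 2:
            raise ValueError("ancestral sizes must be >= 2")


@dataclass
class AFDPool:
    """A pool of starting AFDs plus its generating configuration."""

    afds: list[AFD]
    config: AFDPoolConfig

    def __len__(self) -> int:
        return len(self.afds)

    def draw(self, rng: np.random.Generator) -> AFD:
        return self.afds[int(rng.integers(len(self.afds)))]

    def save(self, path) -> None:
        """One AFD per line as tab-separated size:frequency pairs."""
        meta = {
            "pool_size": self.config.pool_size,
            "theta_range": list(self.config.theta_range),
            "ancestral_size_range": list(self.config.ancestral_size_range),
            "n_haplotypes": self.config.n_haplotypes,
            "seed": self.config.seed,
        }
        with open(path, "w") as fh:
            fh.write("# strsel AFD pool " + json.dumps(meta) + "\n")
            for afd in self.afds:
                fh.write(
                    "\t".join(f"{int(s)}:{float(f)!r}" for s, f in zip(afd.sizes, afd.freqs))
                    + "\n"
                )

    @classmethod
    def load(cls, path) -> "AFDPool":
        afds = []
        meta = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    brace = line.find("{")
                    if brace != -1:
                        meta = json.loads(line[brace:])
                    continue
                pairs = [tok.split(":") for tok in line.split("\t")]
                sizes = np.array([int(s) for s, _ in pairs])
                freqs = np.array([float(f) for _, f in pairs])
                afds.append(AFD(sizes=sizes, freqs=freqs))
        config = AFDPoolConfig(
            pool_size=meta.get("pool_size", len(afds)),
            theta_range=tuple(meta.get("theta_range", (0.04, 40.0))),
            ancestral_size_range=tuple(meta.get("ancestral_size_range", (5, 30))),
            n_haplotypes=meta.get("n_haplotypes", 1000),
            seed=meta.get("seed", 0),
        )
        return cls(afds=afds, config=config)


def build_afd_pool(config: AFDPoolConfig) -> AFDPool:
    """Build the pool; deterministic given ``config.seed``."""
    lo_t, hi_t = config.theta_range
    lo_a, hi_a = config.ancestral_size_range
    afds = []
    for i in range(config.pool_size):
        rng = np.random.default_rng([config.seed, 11, i])
        theta = rng.uniform(lo_t, hi_t)
        anc = int(rng.integers(lo_a, hi_a + 1))
        afds.append(generate_afd(theta, anc, config.n_haplotypes, rng))
    return AFDPool(afds=afds, config=config)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


def init_population(afd: AFD, N: int, rng: np.random.Generator) -> np.ndarray:
    """``N`` diploid genotypes at Hardy-Weinberg equilibrium from an AFD."""
    if N < 1:
        raise ValueError(f"population size must be >= 1, got {N}")
    alleles = rng.choice(afd.sizes, size=(N, 2), p=afd.freqs)
    return alleles.astype(_ALLELE_DTYPE)


def _next_generation(
    pop2: np.ndarray,
    W: Optional[np.ndarray],
    MU: np.ndarray,
    next_size: int,
    spec: MutationSpec,
    rng: np.random.Generator,
    allow_selfing: bool = True,
) -> np.ndarray:
    """One generation: viability selection, mating, transmission, mutation.

    ``pop2`` holds the population chromosome-major, shape ``(2, n)``.  When
    selfing is allowed, drawing a uniform parent and then a uniform
    chromosome is equivalent to one uniform draw over all ``2n``
    chromosomes, which halves the random-number traffic in the hot loop.
    """
    n = pop2.shape[1]
    if W is not None:
        fit = W[pop2[0], pop2[1]]
        keep = rng.random(n, dtype=np.float32) <= fit
        if int(keep.sum()) < 2:
            # Degenerate case: viability removed (almost) everyone.  Retain
            # the two highest-fitness individuals as parents.
            pop2 = pop2[:, np.argsort(fit)[-2:]]
        else:
            pop2 = pop2[:, keep]
        n = pop2.shape[1]
    m = 2 * next_size
    if allow_selfing:
        idx = rng.integers(0, 2 * n, size=m)
        alleles = np.ascontiguousarray(pop2).reshape(-1)[idx]
    else:
        parents = rng.integers(0, n, size=m)
        if n > 1:
            clash = parents[:next_size] == parents[next_size:]
            while clash.any():
                parents[next_size:][clash] = rng.integers(0, n, size=int(clash.sum()))
                clash = parents[:next_size] == parents[next_size:]
        chrom = rng.integers(0, 2, size=m)
        alleles = pop2[chrom, parents]
    hit = rng.random(m, dtype=np.float32) < MU[alleles]
    k = int(hit.sum())
    if k:
        steps = rng.geometric(spec.step_prob, size=k).astype(alleles.dtype)
        signs = (rng.integers(0, 2, size=k) * 2 - 1).astype(alleles.dtype)
        alleles[hit] = np.clip(alleles[hit] + signs * steps, 1, spec.max_allele)
    return alleles.reshape(2, next_size)


def step_generation(
    pop: np.ndarray,
    model: SelectionModelSpec,
    mut: MutationSpec,
    next_size: int,
    rng: np.random.Generator,
    allow_selfing: bool = True,
) -> np.ndarray:
    """Public single-generation update (precomputes lookup tables).

    Under a selection model, each individual survives the viability filter
    independently with probability equal to its genotype's relative fitness;
    ``next_size`` offspring are then formed by drawing parent pairs with
    replacement from the survivors, transmitting one uniformly chosen allele
    per parent, and mutating each transmitted allele.  The neutral model
    skips the filter.
    """
    if pop.shape[0] == 0:
        raise RuntimeError("cannot advance an empty population")
    if next_size < 1:
        raise ValueError("next_size must be >= 1")
    W = None if model.kind.is_neutral else _fitness32(model, mut.max_allele)
    MU = _mu32(mut)
    pop2 = np.asarray(pop, dtype=_ALLELE_DTYPE).T
    return _next_generation(pop2, W, MU, next_size, mut, rng, allow_selfing).T


def _fitness32(model: SelectionModelSpec, max_allele: int) -> np.ndarray:
    return fitness_table(model, max_allele).astype(np.float32)


def _mu32(spec: MutationSpec) -> np.ndarray:
    return mutation_rate_table(spec).astype(np.float32)


@dataclass
class SimulationResult:
    """Output of one full simulation: per-population samples + features."""

    model: SelectionModelSpec
    mutation: MutationSpec
    samples: dict[str, np.ndarray]
    features: np.ndarray


def run_simulation(
    schedule: DemographicSchedule,
    model: SelectionModelSpec,
    mut: MutationSpec,
    afd_source: Union[AFDPool, AFD],
    rng: np.random.Generator,
    allow_selfing: bool = True,
) -> SimulationResult:
    """Run one forward simulation over the full demographic schedule.

    The UCA is initialized from a pool AFD and evolves neutrally during
    burn-in; after the first split every extant population is updated each
    generation under the selection model.  Returns per-population genotype
    samples at the configured sample sizes plus the 408-entry feature
    vector.
    """
    afd = afd_source.draw(rng) if isinstance(afd_source, AFDPool) else afd_source
    W = None if model.kind.is_neutral else _fitness32(model, mut.max_allele)
    MU = _mu32(mut)

    uca = init_population(afd, schedule.equilibrium_Ne, rng).T.copy()
    ne = schedule.equilibrium_Ne
    for _ in range(schedule.burn_in_generations):
        uca = _next_generation(uca, None, MU, ne, mut, rng, allow_selfing)

    pops: dict[str, np.ndarray] = {schedule.ROOT: uca}
    for t in range(schedule.post_split_generations):
        for ev in schedule.splits_at(t):
            parent_pop = pops.pop(ev.parent)
            perm = rng.permutation(parent_pop.shape[1])
            offset = 0
            for child in ev.children:
                n_child = min(
                    schedule.founding_sizes[child], parent_pop.shape[1] - offset
                )
                pops[child] = parent_pop[:, perm[offset : offset + n_child]]
                offset += n_child
        for name in list(pops):
            next_size = schedule.population_size_at(name, t + 1)
            pops[name] = _next_generation(
                pops[name], W, MU, next_size, mut, rng, allow_selfing
            )

    samples = {}
    for name in LEAF_POPULATIONS:
        pop = pops[name]
        n_sample = schedule.populations[name].sample_size
        idx = rng.choice(pop.shape[1], size=n_sample, replace=False)
        samples[name] = pop[:, idx].T
    return SimulationResult(
        model=model, mutation=mut, samples=samples, features=summarize(samples)
    )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def feature_names() -> list[str]:
    """Column names for the 408 features, in fixed population order."""
    names = []
    for pop in LEAF_POPULATIONS:
        names.extend(f"f_{pop}_{size}" for size in range(1, _MAX_BINNED_SIZE + 1))
        names.append(f"het_{pop}")
    return names


def summarize(samples: dict[str, np.ndarray]) -> np.ndarray:
    """The 408 summary statistics of the eight population samples.

    Per population (fixed order CEU, CHB, FIN, GIH, LWK, MXL, TSI, YRI):
    frequencies of allele sizes 1-50 over all sampled alleles (alleles
    longer than 50 count in the denominator but have no bin), followed by
    the fraction of heterozygous individuals.
    """
    missing = [p for p in LEAF_POPULATIONS if p not in samples]
    if missing:
        raise ValueError(f"missing populations: {missing}")
    out = np.empty(len(LEAF_POPULATIONS) * (_MAX_BINNED_SIZE + 1))
    pos = 0
    for pop in LEAF_POPULATIONS:
        geno = np.asarray(samples[pop])
        if geno.size == 0:
            raise ValueError(f"population {pop!r} sample is empty")
        alleles = geno.reshape(-1)
        counts = np.bincount(
            alleles, minlength=_MAX_BINNED_SIZE + 1
        )[1 : _MAX_BINNED_SIZE + 1]
        out[pos : pos + _MAX_BINNED_SIZE] = counts / alleles.size
        out[pos + _MAX_BINNED_SIZE] = float(np.mean(geno[:, 0] != geno[:, 1]))
        pos += _MAX_BINNED_SIZE + 1
    return out


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Priors:
    """Prior distributions over the selection parameters.

    ``s ~ Uniform(s_low, s_high]`` (the lower bound is a small positive
    number, excluding exact neutrality) and ``alpha`` uniform over the
    integers ``[alpha_low, alpha_high]``.
    """

    s_low: float = 1e-6
    s_high: float = 0.02
    alpha_low: int = 2
    alpha_high: int = 50

    def draw(self, rng: np.random.Generator) -> tuple[float, int]:
        return (
            float(rng.uniform(self.s_low, self.s_high)),
            int(rng.integers(self.alpha_low, self.alpha_high + 1)),
        )


@dataclass
class ReferenceTable:
    """Rows of (model label, s, alpha, 408 features) plus metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def features(self) -> np.ndarray:
        return self.df[feature_names()].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.df["model"].to_numpy()

    def subset(self, kind: ModelKind) -> "ReferenceTable":
        sub = self.df[self.df["model"] == kind.value].reset_index(drop=True)
        meta = dict(self.metadata, subset=kind.value)
        return ReferenceTable(df=sub, metadata=meta)

    def save(self, path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.metadata, indent=2)
        )

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(df=df, metadata=metadata)


def _reference_columns() -> list[str]:
    return ["model", "s", "alpha"] + feature_names()


def _simulate_row(
    i: int,
    seed: int,
    motif: int,
    priors: Priors,
    schedule_scaled: DemographicSchedule,
    afd_pool: AFDPool,
    scale_factor: int,
    mutation_overrides: dict,
) -> list:
    rng = np.random.default_rng([seed, 17, i])
    kind = MODEL_ORDER[int(rng.integers(len(MODEL_ORDER)))]
    if kind.is_neutral:
        model = SelectionModelSpec.neutral()
        s, alpha = 0.0, 0
    else:
        s, alpha = priors.draw(rng)
        model = SelectionModelSpec(kind=kind, s=s, alpha=alpha)
    mut = draw_mutation_spec(motif, rng, **mutation_overrides)
    res = run_simulation(
        schedule_scaled,
        rescale_model(model, scale_factor),
        rescale_mutation(mut, scale_factor),
        afd_pool,
        rng,
    )
    return [kind.value, s, alpha] + list(res.features)


def build_reference_table(
    n_sims: int,
    motif: int,
    schedule: DemographicSchedule,
    afd_pool: AFDPool,
    seed: int,
    priors: Optional[Priors] = None,
    scale_factor: int = 1,
    out_path=None,
    kinds: Optional[list[ModelKind]] = None,
    mutation_overrides: Optional[dict] = None,
    checkpoint_every: int = 200,
) -> ReferenceTable:
    """Simulate a reference table of ``n_sims`` rows.

    The evolutionary model is drawn uniformly over the five kinds (or over
    ``kinds`` if given, e.g. a single kind for parameter-estimation tables),
    the selection parameters from ``priors``, and the mutation-curve
    multiplier and small-allele rate are redrawn per simulation.  Rows are
    generated on independent substreams of ``seed``, so builds are
    deterministic, resumable from a partially written ``out_path``, and
    identical regardless of chunking.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    priors = priors or Priors()
    schedule_scaled = rescale_schedule(schedule, scale_factor)
    cols = _reference_columns()
    metadata = {
        "motif_size": motif,
        "n_rows": n_sims,
        "priors": vars(priors),
        "schedule_hash": schedule.config_hash(),
        "scale_factor": scale_factor,
        "seed": seed,
        "kinds": [k.value for k in (kinds or MODEL_ORDER)],
    }
    order = kinds or MODEL_ORDER

    def row(i: int) -> list:
        if kinds is None:
            return _simulate_row(
                i, seed, motif, priors, schedule_scaled, afd_pool, scale_factor,
                mutation_overrides or {},
            )
        # restricted-kind tables draw the kind from the provided list
        rng = np.random.default_rng([seed, 17, i])
        kind = order[int(rng.integers(len(order)))]
        if kind.is_neutral:
            model, s, alpha = SelectionModelSpec.neutral(), 0.0, 0
        else:
            s, alpha = priors.draw(rng)
            model = SelectionModelSpec(kind=kind, s=s, alpha=alpha)
        mut = draw_mutation_spec(motif, rng, **(mutation_overrides or {}))
        res = run_simulation(
            schedule_scaled,
            rescale_model(model, scale_factor),
            rescale_mutation(mut, scale_factor),
            afd_pool,
            rng,
        )
        return [kind.value, s, alpha] + list(res.features)

    if out_path is None:
        rows = [row(i) for i in range(n_sims)]
        return ReferenceTable(df=pd.DataFrame(rows, columns=cols), metadata=metadata)

    out_path = Path(out_path)
    start = 0
    if out_path.exists():
        with open(out_path) as fh:
            start = max(0, sum(1 for _ in fh) - 1)  # minus header
    mode = "a" if start > 0 else "w"
    with open(out_path, mode) as fh:
        if start == 0:
            fh.write(",".join(cols) + "\n")
        buffer = []
        for i in range(start, n_sims):
            buffer.append(row(i))
            if len(buffer) >= checkpoint_every or i == n_sims - 1:
                pd.DataFrame(buffer, columns=cols).to_csv(fh, header=False, index=False)
                fh.flush()
                buffer = []
    out_path.with_suffix(out_path.suffix + ".meta.json").write_text(
        json.dumps(metadata, indent=2)
    )
    table = ReferenceTable.load(out_path)
    table.metadata = metadata
    return table


# ---------------------------------------------------------------------------
# Minimum-s search
# ---------------------------------------------------------------------------


@dataclass
class MinSResult:
    """Result of the minimum-s invariance search.

    ``min_s`` is the smallest tested s at which the fraction of replicates
    with zero sampled allele-size variance met the consistency threshold,
    or ``None`` when the search range was exhausted (``above_range=True``);
    ``fractions`` maps each tested s to its (possibly early-stopped)
    zero-variance fraction estimate.
    """

    min_s: Optional[float]
    above_range: bool
    threshold: float
    n_reps: int
    fractions: dict[float, float]

    @property
    def lower_bound(self) -> float:
        """Largest s known to be insufficient, or the found minimum."""
        if self.min_s is not None:
            return self.min_s
        return max(self.fractions) if self.fractions else math.nan


DEFAULT_S_GRID = (0.0005, 0.001, 0.002, 0.003, 0.004, 0.005, 0.0075, 0.01, 0.015, 0.02)


def min_s_for_invariance(
    kind: ModelKind,
    alpha: int,
    mut: MutationSpec,
    schedule: DemographicSchedule,
    n_reps: int,
    seed: int,
    afd_pool: Optional[AFDPool] = None,
    threshold: float = 0.95,
    s_grid=DEFAULT_S_GRID,
    scale_factor: int = 1,
) -> MinSResult:
    """Smallest s that consistently maintains zero sampled variance.

    For each candidate s (ascending), ``n_reps`` full-schedule simulations
    are run starting from a population monomorphic for the key allele
    ``alpha`` (the "maintain zero variance" reading); a candidate passes
    when at least ``threshold`` of replicates yield zero variance across
    all 400 sampled alleles.  Candidates are abandoned early once enough
    failures accumulate to rule the threshold out.
    """
    if kind.is_neutral:
        raise ValueError("min-s search requires a non-neutral model kind")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    schedule_scaled = rescale_schedule(schedule, scale_factor)
    mut_scaled = rescale_mutation(mut, scale_factor)
    start_afd = AFD.monomorphic(alpha)
    max_failures = math.floor((1.0 - threshold) * n_reps)
    fractions: dict[float, float] = {}
    for s in sorted(s_grid):
        model = rescale_model(
            SelectionModelSpec(kind=kind, s=float(s), alpha=alpha), scale_factor
        )
        successes = failures = 0
        for rep in range(n_reps):
            rng = np.random.default_rng([seed, 23, int(round(s * 1e8)), rep])
            afd = afd_pool.draw(rng) if afd_pool is not None else start_afd
            res = run_simulation(schedule_scaled, model, mut_scaled, afd, rng)
            alleles = np.concatenate([g.reshape(-1) for g in res.samples.values()])
            if np.all(alleles == alleles[0]):
                successes += 1
            else:
                failures += 1
                if failures > max_failures:
                    break
        ran = successes + failures
        fractions[float(s)] = successes / ran
        if failures <= max_failures and ran == n_reps:
            return MinSResult(
                min_s=float(s),
                above_range=False,
                threshold=threshold,
                n_reps=n_reps,
                fractions=fractions,
            )
    return MinSResult(
        min_s=None, above_range=True, threshold=threshold, n_reps=n_reps, fractions=fractions
    )
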