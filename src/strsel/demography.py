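"""Eight-population demographic schedule for forward simulation.

The schedule encodes a rooted binary population tree starting from a
universal common ancestor (UCA) at mutation-drift equilibrium
(``Ne = 10,000``), a neutral burn-in epoch, and a 4,750-generation
post-split epoch in which ancestral populations bifurcate into the eight
sampled 1000 Genomes populations (CEU, CHB, FIN, GIH, LWK, MXL, TSI, YRI).
Descendant populations are founded as fixed proportions of their parent and
grow linearly (+100 individuals per generation) until they reach the
equilibrium size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "LEAF_POPULATIONS",
    "LEAF_SAMPLE_SIZES",
    "PopulationRecord",
    "SplitEvent",
    "DemographicSchedule",
    "load_schedule",
    "default_schedule",
    "ScheduleValidationError",
]

#: The eight sampled populations, in the fixed feature-vector order.
LEAF_POPULATIONS = ("CEU", "CHB", "FIN", "GIH", "LWK", "MXL", "TSI", "YRI")

#: Number of diploid individuals sampled per population (total 200).
LEAF_SAMPLE_SIZES = {
    "CEU": 25,
    "CHB": 27,
    "FIN": 30,
    "GIH": 25,
    "LWK": 25,
    "MXL": 18,
    "TSI": 25,
    "YRI": 25,
}

_PROPORTION_SUM_TOL = 1e-9


class ScheduleValidationError(ValueError):
    """Raised with the full list of schedule violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid demographic schedule:\n  - " + "\n  - ".join(violations))


@dataclass(frozen=True)
class PopulationRecord:
    """One population in the tree.

    ``split_generation`` is the offset (from the first split) at which the
    population is founded; the root UCA has ``split_generation = 0`` and
    ``parent = None``.  ``retire_generation`` is when the population itself
    splits (``None`` for leaves, which persist to the end of the epoch).
    """

    name: str
    parent: Optional[str]
    split_generation: int
    founding_proportion: float
    sample_size: int = 0
    retire_generation: Optional[int] = None


@dataclass(frozen=True)
class SplitEvent:
    parent: str
    generation: int
    children: tuple[str, ...]
    proportions: tuple[float, ...]


@dataclass
class DemographicSchedule:
    """Validated population split schedule.

    Use :func:`load_schedule` (or :func:`default_schedule`) to construct one
    from a YAML config; the constructor validates and precomputes founding
    sizes so that :meth:`population_size_at` is O(1).
    """

    equilibrium_Ne: int = 10_000
    burn_in_generations: int = 2_000
    post_split_generations: int = 4_750
    growth_increment: int = 100
    generation_years: float = 20.0  # metadata only
    populations: dict[str, PopulationRecord] = field(default_factory=dict)
    splits: list[SplitEvent] = field(default_factory=list)
    founding_sizes: dict[str, int] = field(default_factory=dict, init=False)

    ROOT = "UCA"

    def __post_init__(self) -> None:
        self._validate()
        self._compute_founding_sizes()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        errs: list[str] = []
        pops = self.populations
        if self.ROOT not in pops:
            errs.append(f"missing root population {self.ROOT!r}")
        for ev in self.splits:
            if ev.parent not in pops:
                errs.append(f"split parent {ev.parent!r} is not a known population")
            if len(ev.children) != 2:
                errs.append(f"split of {ev.parent!r} must have exactly 2 children")
            if not (0 <= ev.generation < self.post_split_generations):
                errs.append(
                    f"split of {ev.parent!r} at generation {ev.generation} outside "
                    f"[0, {self.post_split_generations})"
                )
            for prop in ev.proportions:
                if not (0.0 < prop <= 1.0):
                    errs.append(
                        f"founding proportion {prop} for a child of {ev.parent!r} "
                        "outside (0, 1]"
                    )
            if sum(ev.proportions) > 1.0 + _PROPORTION_SUM_TOL:
                errs.append(f"founding proportions of {ev.parent!r} children exceed 1")
        # parent resolution and acyclicity (walk up from every population)
        for name, rec in pops.items():
            seen = {name}
            cur = rec.parent
            while cur is not None:
                if cur not in pops:
                    errs.append(f"population {name!r} has unknown ancestor {cur!r}")
                    break
                if cur in seen:
                    errs.append(f"cycle detected through population {cur!r}")
                    break
                seen.add(cur)
                cur = pops[cur].parent
        leaves = {n for n, r in pops.items() if r.retire_generation is None}
        if leaves != set(LEAF_POPULATIONS):
            errs.append(
                f"leaf populations must be exactly {sorted(LEAF_POPULATIONS)}, "
                f"got {sorted(leaves)}"
            )
        for ev in self.splits:
            parent_rec = pops.get(ev.parent)
            if parent_rec and ev.parent != self.ROOT and ev.generation < parent_rec.split_generation:
                errs.append(
                    f"{ev.parent!r} splits at {ev.generation}, before it is founded "
                    f"at {parent_rec.split_generation}"
                )
        if errs:
            raise ScheduleValidationError(errs)

    def _compute_founding_sizes(self) -> None:
        sizes = {self.ROOT: self.equilibrium_Ne}
        for ev in sorted(self.splits, key=lambda e: e.generation):
            parent_size = self._size_from_founding(ev.parent, ev.generation, sizes)
            for child, prop in zip(ev.children, ev.proportions):
                sizes[child] = max(1, round(prop * parent_size))
        self.founding_sizes = sizes

    def _size_from_founding(self, name: str, t: int, sizes: dict[str, int]) -> int:
        if name == self.ROOT:
            return self.equilibrium_Ne
        rec = self.populations[name]
        grown = sizes[name] + self.growth_increment * (t - rec.split_generation)
        return min(self.equilibrium_Ne, grown)

    # -- queries ----------------------------------------------------------

    @property
    def leaves(self) -> tuple[str, ...]:
        return LEAF_POPULATIONS

    @property
    def sample_sizes(self) -> dict[str, int]:
        return {n: self.populations[n].sample_size for n in LEAF_POPULATIONS}

    def alive_at(self, name: str, t: int) -> bool:
        """Whether population ``name`` exists at post-split generation ``t``.

        The root is alive for ``t <= 0`` (the burn-in epoch and the instant
        of the first split); other populations from their founding until
        they are retired by their own split.
        """
        rec = self.populations[name]
        if name == self.ROOT:
            return t <= rec.retire_generation if rec.retire_generation is not None else t <= 0
        if t < rec.split_generation:
            return False
        end = rec.retire_generation
        return t <= (self.post_split_generations if end is None else end)

    def population_size_at(self, name: str, t: int) -> int:
        """Population size of ``name`` at post-split generation ``t``.

        ``min(Ne, founding_size + growth_increment * (t - split_generation))``;
        the root UCA is constant at the equilibrium size.
        """
        if name not in self.populations:
            raise KeyError(f"unknown population {name!r}")
        if not self.alive_at(name, t):
            raise ValueError(f"population {name!r} is not alive at generation {t}")
        if name == self.ROOT:
            return self.equilibrium_Ne
        rec = self.populations[name]
        grown = self.founding_sizes[name] + self.growth_increment * (t - rec.split_generation)
        return min(self.equilibrium_Ne, grown)

    def splits_at(self, t: int) -> list[SplitEvent]:
        return [ev for ev in self.splits if ev.generation == t]

    # -- serialization ----------------------------------------------------

    def to_config(self) -> dict:
        return {
            "equilibrium_Ne": self.equilibrium_Ne,
            "burn_in_generations": self.burn_in_generations,
            "post_split_generations": self.post_split_generations,
            "growth_increment": self.growth_increment,
            "generation_years": self.generation_years,
            "splits": [
                {
                    "parent": ev.parent,
                    "generation": ev.generation,
                    "children": [
                        {"name": c, "proportion": p}
                        for c, p in zip(ev.children, ev.proportions)
                    ],
                }
                for ev in self.splits
            ],
            "sample_sizes": {n: self.populations[n].sample_size for n in sorted(LEAF_POPULATIONS)},
        }

    def config_hash(self) -> str:
        """Stable hash of the schedule config, embedded in artifacts."""
        payload = json.dumps(self.to_config(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _schedule_from_config(cfg: dict) -> DemographicSchedule:
    splits = [
        SplitEvent(
            parent=ev["parent"],
            generation=int(ev["generation"]),
            children=tuple(c["name"] for c in ev["children"]),
            proportions=tuple(float(c["proportion"]) for c in ev["children"]),
        )
        for ev in cfg.get("splits", [])
    ]
    sample_sizes = cfg.get("sample_sizes", {})
    retire = {ev.parent: ev.generation for ev in splits}
    pops: dict[str, PopulationRecord] = {}
    pops[DemographicSchedule.ROOT] = PopulationRecord(
        name=DemographicSchedule.ROOT,
        parent=None,
        split_generation=0,
        founding_proportion=1.0,
        retire_generation=retire.get(DemographicSchedule.ROOT),
    )
    for ev in splits:
        for child, prop in zip(ev.children, ev.proportions):
            pops[child] = PopulationRecord(
                name=child,
                parent=ev.parent,
                split_generation=ev.generation,
                founding_proportion=prop,
                sample_size=int(sample_sizes.get(child, 0)),
                retire_generation=retire.get(child),
            )
    return DemographicSchedule(
        equilibrium_Ne=int(cfg.get("equilibrium_Ne", 10_000)),
        burn_in_generations=int(cfg.get("burn_in_generations", 2_000)),
        post_split_generations=int(cfg.get("post_split_generations", 4_750)),
        growth_increment=int(cfg.get("growth_increment", 100)),
        generation_years=float(cfg.get("generation_years", 20.0)),
        populations=pops,
        splits=sorted(splits, key=lambda e: e.generation),
    )


def load_schedule(path_or_config) -> DemographicSchedule:
    """Load and validate a schedule from a YAML file path or config dict."""
    if isinstance(path_or_config, dict):
        return _schedule_from_config(path_or_config)
    text = Path(path_or_config).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ScheduleValidationError(["config did not parse to a mapping"])
    return _schedule_from_config(cfg)


def default_schedule() -> DemographicSchedule:
    """The bundled eight-population schedule."""
    text = resources.files("strsel.data").joinpath("demography.yaml").read_text()
    return _schedule_from_config(yaml.safe_load(text))
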