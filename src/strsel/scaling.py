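"""Diffusion rescaling for desk-scale simulation.

A rescaling factor ``c`` shrinks the effective population size and every
generation count by ``c`` while multiplying the mutation rate and the
selection coefficient by ``c``.  This preserves the diffusion-scale
compound parameters ``N*mu`` and ``N*s`` (and the growth trajectory
``N(t) = N0 + 100 t`` maps onto itself), so scaled runs reproduce the
stochastic behaviour of full-scale runs at a fraction of the cost.  Sample
sizes and the starting allele-frequency distributions are unchanged.
"""

from __future__ import annotations

from dataclasses import replace

from .demography import DemographicSchedule, PopulationRecord, SplitEvent
from .mutation import MutationSpec
from .selection import ModelKind, SelectionModelSpec

__all__ = ["rescale_model", "rescale_mutation", "rescale_schedule"]


def rescale_model(model: SelectionModelSpec, c: int) -> SelectionModelSpec:
    """Multiply the selection coefficient by ``c`` (neutral is unchanged)."""
    if c == 1 or model.kind is ModelKind.NEUTRAL:
        return model
    return SelectionModelSpec(kind=model.kind, s=model.s * c, alpha=model.alpha, rescaled=True)


def rescale_mutation(spec: MutationSpec, c: int) -> MutationSpec:
    """Multiply every mutation rate by ``c`` via the spec's rate_scale."""
    if c == 1:
        return spec
    return replace(spec, rate_scale=spec.rate_scale * c)


def rescale_schedule(schedule: DemographicSchedule, c: int) -> DemographicSchedule:
    """Divide Ne and all generation counts by ``c`` (sample sizes kept)."""
    if c == 1:
        return schedule
    if c < 1:
        raise ValueError(f"scale factor must be >= 1, got {c}")

    def gens(g: int) -> int:
        return max(1, round(g / c))

    splits = [
        SplitEvent(
            parent=ev.parent,
            generation=round(ev.generation / c),
            children=ev.children,
            proportions=ev.proportions,
        )
        for ev in schedule.splits
    ]
    retire = {ev.parent: ev.generation for ev in splits}
    pops = {}
    for name, rec in schedule.populations.items():
        pops[name] = PopulationRecord(
            name=rec.name,
            parent=rec.parent,
            split_generation=0 if rec.parent is None else round(rec.split_generation / c),
            founding_proportion=rec.founding_proportion,
            sample_size=rec.sample_size,
            retire_generation=retire.get(name),
        )
    return DemographicSchedule(
        equilibrium_Ne=max(2, round(schedule.equilibrium_Ne / c)),
        burn_in_generations=gens(schedule.burn_in_generations),
        post_split_generations=gens(schedule.post_split_generations),
        growth_increment=schedule.growth_increment,
        generation_years=schedule.generation_years,
        populations=pops,
        splits=splits,
    )
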