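"""YAML serialization of model and mutation specifications.

The config keys are stable: ``kind``, ``s``, ``alpha`` for selection
models; ``motif_size``, ``curve_multiplier``, ``baseline_scale``,
``small_allele_rate``, ``step_prob``, ``max_allele`` for mutation specs.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .mutation import MutationSpec
from .selection import ModelKind, SelectionModelSpec

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "mutation_to_dict",
    "mutation_from_dict",
    "save_specs",
    "load_specs",
]

_MODEL_KEYS = ("kind", "s", "alpha")
_MUTATION_KEYS = (
    "motif_size",
    "curve_multiplier",
    "baseline_scale",
    "small_allele_rate",
    "step_prob",
    "max_allele",
)


def model_to_dict(model: SelectionModelSpec) -> dict:
    return {"kind": model.kind.value, "s": float(model.s), "alpha": int(model.alpha)}


def model_from_dict(cfg: dict) -> SelectionModelSpec:
    kind = ModelKind(cfg["kind"])
    if kind.is_neutral:
        return SelectionModelSpec.neutral()
    return SelectionModelSpec(kind=kind, s=float(cfg["s"]), alpha=int(cfg["alpha"]))


def mutation_to_dict(spec: MutationSpec) -> dict:
    return {k: getattr(spec, k) for k in _MUTATION_KEYS}


def mutation_from_dict(cfg: dict) -> MutationSpec:
    if "motif_size" in cfg and len(cfg) == 1:
        return MutationSpec.for_motif(int(cfg["motif_size"]))
    return MutationSpec(**{k: cfg[k] for k in _MUTATION_KEYS if k in cfg})


def save_specs(path, model: SelectionModelSpec = None, mutation: MutationSpec = None) -> None:
    payload = {}
    if model is not None:
        payload["model"] = model_to_dict(model)
    if mutation is not None:
        payload["mutation"] = mutation_to_dict(mutation)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_specs(path) -> tuple[SelectionModelSpec | None, MutationSpec | None]:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    model = model_from_dict(cfg["model"]) if "model" in cfg else None
    mutation = mutation_from_dict(cfg["mutation"]) if "mutation" in cfg else None
    return model, mutation
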