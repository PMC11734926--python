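"""Synthetic per-locus genotype datasets with known ground truth.

These datasets stand in for an empirical study design in which 200
individuals from eight human populations are genotyped at microsatellite
loci (alleles recorded as integer repeat counts).  Each synthetic locus is
produced by one full forward simulation under a chosen evolutionary model,
so the generating model, s, and alpha are known exactly — which makes the
datasets suitable for end-to-end validation of the inference pipeline.

The exchange format is tab-separated text with columns
``sample_id  population  locus_id  motif_size  allele1  allele2``; missing
genotypes are encoded as ``.`` and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .demography import LEAF_POPULATIONS, DemographicSchedule
from .mutation import MutationSpec
from .scaling import rescale_model, rescale_mutation, rescale_schedule
from .selection import SelectionModelSpec
from .simulate import AFDPool, run_simulation

__all__ = [
    "GenotypeDataset",
    "LocusSummary",
    "generate_locus_dataset",
    "locus_summary",
    "read_genotypes",
    "write_genotypes",
    "apply_heterozygote_dropout",
]

_COLUMNS = ["sample_id", "population", "locus_id", "motif_size", "allele1", "allele2"]
_MISSING = "."


@dataclass
class GenotypeDataset:
    """Diploid genotypes for one locus across the eight study populations.

    ``records`` holds one row per individual with integer repeat-count
    alleles stored as ``allele1 <= allele2`` (NaN for missing genotypes).
    ``truth`` optionally records the generating model for synthetic loci.
    """

    locus_id: str
    motif_size: int
    records: pd.DataFrame
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        unknown = set(self.records["population"]) - set(LEAF_POPULATIONS)
        if unknown:
            raise ValueError(f"unknown population labels: {sorted(unknown)}")
        a1 = self.records["allele1"].to_numpy(dtype=float)
        a2 = self.records["allele2"].to_numpy(dtype=float)
        swap = a1 > a2
        if swap.any():
            self.records.loc[swap, ["allele1", "allele2"]] = np.column_stack(
                (a2[swap], a1[swap])
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.locus_id == other.locus_id
            and self.motif_size == other.motif_size
            and self.records.reset_index(drop=True).equals(
                other.records.reset_index(drop=True)
            )
        )

    def called(self) -> pd.DataFrame:
        """Records with a non-missing genotype."""
        return self.records.dropna(subset=["allele1", "allele2"])

    def samples(self) -> dict[str, np.ndarray]:
        """Per-population genotype arrays (n, 2), called genotypes only."""
        out = {}
        called = self.called()
        for pop, grp in called.groupby("population"):
            out[pop] = grp[["allele1", "allele2"]].to_numpy(dtype=np.int64)
        return out


@dataclass(frozen=True)
class LocusSummary:
    """Global and per-population allele-size summaries for one locus.

    ``V_AS`` uses the population-variance convention (denominator n) over
    all called alleles pooled across populations with equal weight per
    allele.
    """

    M_AS: float
    V_AS: float
    per_population_M_AS: dict[str, float]
    per_population_heterozygosity: dict[str, float]


def generate_locus_dataset(
    model: SelectionModelSpec,
    mut: MutationSpec,
    schedule: DemographicSchedule,
    afd_pool: AFDPool,
    seed: int,
    locus_id: str = "locus",
    scale_factor: int = 1,
) -> GenotypeDataset:
    """One full simulation emitted in the empirical genotype-table shape."""
    rng = np.random.default_rng([seed, 29])
    res = run_simulation(
        rescale_schedule(schedule, scale_factor),
        rescale_model(model, scale_factor),
        rescale_mutation(mut, scale_factor),
        afd_pool,
        rng,
    )
    rows = []
    for pop in LEAF_POPULATIONS:
        geno = np.sort(res.samples[pop], axis=1)
        for i, (a1, a2) in enumerate(geno):
            rows.append(
                {
                    "sample_id": f"{pop}_{i:03d}",
                    "population": pop,
                    "locus_id": locus_id,
                    "motif_size": mut.motif_size,
                    "allele1": float(a1),
                    "allele2": float(a2),
                }
            )
    records = pd.DataFrame(rows, columns=_COLUMNS)
    truth = {
        "kind": model.kind.value,
        "s": model.s,
        "alpha": model.alpha,
        "seed": seed,
    }
    return GenotypeDataset(
        locus_id=locus_id, motif_size=mut.motif_size, records=records, truth=truth
    )


def locus_summary(ds: GenotypeDataset) -> LocusSummary:
    """Global M_AS/V_AS plus per-population means and heterozygosities."""
    called = ds.called()
    if called.empty:
        raise ValueError("dataset has no called genotypes")
    alleles = called[["allele1", "allele2"]].to_numpy(dtype=float).reshape(-1)
    m_as = float(alleles.mean())
    v_as = float(alleles.var())  # denominator n
    per_m = {}
    per_het = {}
    for pop, grp in called.groupby("population"):
        a = grp[["allele1", "allele2"]].to_numpy(dtype=float)
        per_m[pop] = float(a.mean())
        per_het[pop] = float(np.mean(a[:, 0] != a[:, 1]))
    return LocusSummary(
        M_AS=m_as,
        V_AS=v_as,
        per_population_M_AS=per_m,
        per_population_heterozygosity=per_het,
    )


def apply_heterozygote_dropout(
    ds: GenotypeDataset, dropout: float, rng: np.random.Generator
) -> GenotypeDataset:
    """Corrupt heterozygotes to homozygotes with probability ``dropout``.

    Emulates allelic dropout in short-read-derived genotype calls, for
    robustness experiments; the kept allele is chosen at random.  Default
    pipelines do not apply this operator.
    """
    if not (0.0 <= dropout <= 1.0):
        raise ValueError("dropout must be in [0, 1]")
    records = ds.records.copy()
    het = records["allele1"] != records["allele2"]
    hit = het & (rng.random(len(records)) < dropout)
    keep_first = rng.random(len(records)) < 0.5
    a1 = records["allele1"].to_numpy(dtype=float)
    a2 = records["allele2"].to_numpy(dtype=float)
    kept = np.where(keep_first, a1, a2)
    records.loc[hit, "allele1"] = kept[hit]
    records.loc[hit, "allele2"] = kept[hit]
    return GenotypeDataset(
        locus_id=ds.locus_id, motif_size=ds.motif_size, records=records, truth=ds.truth
    )


def write_genotypes(ds: GenotypeDataset, path) -> None:
    out = ds.records.copy()
    for col in ("allele1", "allele2"):
        out[col] = out[col].map(lambda v: _MISSING if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeDataset:
    """Read the exchange format; malformed lines are reported by number."""
    path = Path(path)
    rows = []
    errors = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise ValueError(
                f"{path}: expected header {_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                errors.append(f"line {lineno}: expected {len(_COLUMNS)} fields, got {len(parts)}")
                continue
            sample_id, population, locus_id, motif_size, a1, a2 = parts
            if population not in LEAF_POPULATIONS:
                errors.append(f"line {lineno}: unknown population {population!r}")
                continue
            try:
                rec = {
                    "sample_id": sample_id,
                    "population": population,
                    "locus_id": locus_id,
                    "motif_size": int(motif_size),
                    "allele1": np.nan if a1 == _MISSING else float(int(a1)),
                    "allele2": np.nan if a2 == _MISSING else float(int(a2)),
                }
            except ValueError:
                errors.append(f"line {lineno}: non-integer allele in {parts[-2:]}")
                continue
            rows.append(rec)
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    if not rows:
        raise ValueError(f"{path}: no genotype records")
    records = pd.DataFrame(rows, columns=_COLUMNS)
    locus_ids = records["locus_id"].unique()
    motifs = records["motif_size"].unique()
    return GenotypeDataset(
        locus_id=str(locus_ids[0]) if len(locus_ids) == 1 else "multiple",
        motif_size=int(motifs[0]) if len(motifs) == 1 else 0,
        records=records,
    )
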