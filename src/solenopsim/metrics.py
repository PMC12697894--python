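"""Biomass and allele-frequency metrics, spatial slicing and file output.

Biomass is measured in monogyne-worker-equivalent units: each colony of
age >= 1 contributes its size times a mass factor (1.0 for monogyne and
native colonies, 0.6 for polygyne, whose workers are smaller).  Allele
frequencies are counted over queen diploid genomes plus each colony's
stored haploid mate genome (males are not persistent agents, so the mate
genomes are the male allele sample); unmated released males are excluded
from the denominator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import genetics
from .colonies import GrowthParams, Species, colony_size
from .genetics import SocialForm

__all__ = [
    "MASS_FACTOR_MONOGYNE",
    "MASS_FACTOR_POLYGYNE",
    "YearRecord",
    "total_biomass",
    "biomass_by_group",
    "drive_frequency",
    "allele_frequencies",
    "slice_biomass",
    "write_timeseries",
    "read_timeseries",
    "write_config_echo",
    "write_snapshot",
]

MASS_FACTOR_MONOGYNE = 1.0
MASS_FACTOR_POLYGYNE = 0.6


@dataclass
class YearRecord:
    """One row of the per-year output time series."""

    year: int
    n_monogyne: int = 0            # established fire colonies (age >= 2)
    n_polygyne: int = 0
    n_native: int = 0
    n_monogyne_all: int = 0        # including age-1 founders
    n_polygyne_all: int = 0
    n_native_all: int = 0
    biomass_monogyne: float = 0.0
    biomass_polygyne: float = 0.0
    biomass_native: float = 0.0
    biomass_fire: float = 0.0
    drive_frequency: float = float("nan")
    resistance_frequency: float = float("nan")
    sb_frequency: float = float("nan")
    nn_index: float = float("nan")
    fire_slices: tuple = ()
    native_slices: tuple = ()

    def to_row(self) -> dict:
        row = dataclasses.asdict(self)
        for key in ("fire_slices", "native_slices"):
            vals = row.pop(key)
            for i in range(10):
                row[f"{key[:-1]}_{i}"] = vals[i] if len(vals) == 10 else 0.0
        return row


def _mass_factors(form: np.ndarray) -> np.ndarray:
    return np.where(form == int(SocialForm.POLYGYNE),
                    MASS_FACTOR_POLYGYNE, MASS_FACTOR_MONOGYNE)


def _sizes(age: np.ndarray, form: np.ndarray, growth: GrowthParams) -> np.ndarray:
    mono = colony_size(np.maximum(age, 0), SocialForm.MONOGYNE, Species.FIRE_ANT, growth)
    poly = colony_size(np.maximum(age, 0), SocialForm.POLYGYNE, Species.FIRE_ANT, growth)
    return np.where(form == int(SocialForm.POLYGYNE), poly, mono)


def _biomass_values(age, form, growth: GrowthParams) -> np.ndarray:
    """Per-colony biomass contributions; colonies below age 1 contribute 0."""
    vals = _sizes(age, form, growth) * _mass_factors(form)
    return np.where(age >= 1, vals, 0.0)


def total_biomass(age, form, growth: GrowthParams = GrowthParams()) -> float:
    return float(_biomass_values(np.asarray(age), np.asarray(form), growth).sum())


def biomass_by_group(age, form, species, growth: GrowthParams = GrowthParams()):
    """(monogyne fire, polygyne fire, native) biomass."""
    vals = _biomass_values(np.asarray(age), np.asarray(form), growth)
    fire = np.asarray(species) == int(Species.FIRE_ANT)
    poly = np.asarray(form) == int(SocialForm.POLYGYNE)
    return (float(vals[fire & ~poly].sum()),
            float(vals[fire & poly].sum()),
            float(vals[~fire].sum()))


def _allele_counts(queen_a, queen_b, mate, mated, target) -> tuple[float, float]:
    hits = (queen_a == target).sum() + (queen_b == target).sum() + (
        (mate == target) & mated).sum()
    total = 2 * queen_a.shape[0] + int(mated.sum())
    return float(hits), float(total)


def drive_frequency(qf1, qf2, mf, mated, qd1=None, qd2=None, md=None) -> float:
    """Drive allele frequency at the drive-bearing locus.

    Counted over queens (two alleles) and stored mates (one allele); raises
    on an empty accounting set.  For two-target variants pass the drive-site
    columns, where the drive construct actually sits.
    """
    if qd1 is not None and np.any(qd1 >= 0):
        hits, total = _allele_counts(qd1, qd2, md, mated, genetics.DS_D)
    else:
        hits, total = _allele_counts(qf1, qf2, mf, mated, genetics.D)
    if total == 0:
        raise ValueError("no alleles to count in an empty population")
    return hits / total


def allele_frequencies(qf1, qf2, qs1, qs2, mf, ms, mated,
                       qd1=None, qd2=None, md=None) -> dict[str, float]:
    """Drive, (nonfunctional + dominant-sterile) resistance and Sb frequencies."""
    n = qf1.shape[0]
    if n == 0:
        return {"drive": float("nan"), "resistance": float("nan"), "sb": float("nan")}
    drive = drive_frequency(qf1, qf2, mf, mated, qd1, qd2, md)
    res_hits = 0.0
    for code in (genetics.R, genetics.R_DOM):
        h, total = _allele_counts(qf1, qf2, mf, mated, code)
        res_hits += h
    if qd1 is not None and np.any(qd1 >= 0):
        h, _ = _allele_counts(qd1, qd2, md, mated, genetics.DS_R)
        res_hits += h
    sb_hits, total = _allele_counts(qs1, qs2, ms, mated, genetics.Sb)
    return {"drive": drive, "resistance": res_hits / total, "sb": sb_hits / total}


def slice_biomass(x, age, form, side: float, n_slices: int = 10,
                  growth: GrowthParams = GrowthParams()) -> np.ndarray:
    """Biomass per vertical slice of the arena (slice i covers
    x in [i, i+1) * side / n_slices); slices sum to the total biomass."""
    vals = _biomass_values(np.asarray(age), np.asarray(form), growth)
    idx = np.clip((np.asarray(x) / side * n_slices).astype(int), 0, n_slices - 1)
    out = np.zeros(n_slices)
    np.add.at(out, idx, vals)
    return out


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[YearRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def write_timeseries(records: Sequence[YearRecord] | pd.DataFrame, path) -> None:
    """One CSV row per year (year 0 = the initialized population)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config_echo(config, path, seed=None) -> None:
    """JSON echo of the fully resolved configuration (replay support)."""
    payload = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    if seed is not None:
        payload["seed"] = int(seed)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def write_snapshot(path, x, y, age, form, species, qf1, qf2, qs1, qs2, mated) -> None:
    """Plain-CSV spatial snapshot (positions, age, form, species, genotype)."""
    df = pd.DataFrame({
        "x": x, "y": y, "age": age, "form": form, "species": species,
        "queen_fert_1": qf1, "queen_fert_2": qf2,
        "queen_social_1": qs1, "queen_social_2": qs2,
        "mated": mated.astype(int),
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
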