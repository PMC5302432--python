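"""Core data model for multi-environment wheat trials.

A trial ("MET", multi-environment trial) evaluates a set of genotypes in
several environments — here, site-year combinations — with replicated plots.
Every downstream analysis (nutritional yield, AMMI, BLUP, selection indexes)
consumes the plot-level records or genotype-by-environment mean tables
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GENOTYPE_GROUPS",
    "PlotRecord",
    "METDataset",
    "AnalysisConfig",
    "TraitMatrix",
    "SchemaError",
    "IntegrityError",
    "IncompleteDataError",
    "ConfigError",
    "read_met_table",
    "write_met_table",
    "cell_means",
    "round_half_away",
]

#: Recognised germplasm groups. "Spelt" and "Primitive" carry hulled grain
#: by default and are subject to the dehulling yield correction.
GENOTYPE_GROUPS = frozenset(
    {"Selection", "Old cultivar", "Primitive", "Spelt", "Landrace", "Cultivar"}
)


class SchemaError(ValueError):
    """Input table is missing a required column."""


class IntegrityError(ValueError):
    """Duplicate plot identity or inconsistent dataset contents."""


class IncompleteDataError(ValueError):
    """A genotype × environment cell required by an analysis is empty."""


class ConfigError(ValueError):
    """Configuration references traits or minerals absent from the data."""


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (reporting convention for printed tables).

    numpy rounds half to even; published trial tables conventionally round
    0.5 up in magnitude, and that is what result tables here use.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if decimals <= 0 and out.ndim == 0:
        return int(out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PlotRecord:
    """One harvested plot: a genotype in an environment, one replicate.

    yield_raw is grain yield in kg·ha⁻¹ at 13% moisture, *before* any
    dehulling correction; concentrations are wholemeal mineral
    concentrations in mg·kg⁻¹.
    """

    genotype_id: str
    genotype_group: str
    environment_id: str
    replicate: int
    yield_raw: float
    concentrations: Mapping[str, float]

    def __post_init__(self):
        if self.genotype_group not in GENOTYPE_GROUPS:
            raise ValueError(
                f"unknown genotype group {self.genotype_group!r} for "
                f"{self.genotype_id}; expected one of {sorted(GENOTYPE_GROUPS)}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")
        if self.yield_raw < 0:
            raise ValueError(
                f"negative yield {self.yield_raw} for genotype {self.genotype_id}, "
                f"environment {self.environment_id}, replicate {self.replicate}"
            )
        for mineral, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(
                    f"negative {mineral} concentration {conc} for genotype "
                    f"{self.genotype_id}, environment {self.environment_id}, "
                    f"replicate {self.replicate}"
                )


@dataclass
class METDataset:
    """Plot-level records plus the ordered genotype/environment/mineral lists."""

    records: list[PlotRecord]
    minerals: list[str]
    genotypes: list[str]
    environments: list[str]

    def __post_init__(self):
        if not self.minerals:
            raise ValueError("mineral list must be non-empty")
        geno = set(self.genotypes)
        envs = set(self.environments)
        seen: set[tuple[str, str, int]] = set()
        for rec in self.records:
            if rec.genotype_id not in geno:
                raise IntegrityError(f"record references unlisted genotype {rec.genotype_id!r}")
            if rec.environment_id not in envs:
                raise IntegrityError(
                    f"record references unlisted environment {rec.environment_id!r}"
                )
            key = (rec.genotype_id, rec.environment_id, rec.replicate)
            if key in seen:
                raise IntegrityError(f"duplicate plot identity {key}")
            seen.add(key)
            missing = [m for m in self.minerals if m not in rec.concentrations]
            if missing:
                raise IntegrityError(
                    f"record {key} lacks concentrations for {missing}"
                )

    @property
    def complete(self) -> bool:
        """True iff every genotype × environment cell holds at least one plot."""
        cells = {(r.genotype_id, r.environment_id) for r in self.records}
        return all(
            (g, e) in cells for g in self.genotypes for e in self.environments
        )

    @property
    def groups(self) -> dict[str, str]:
        """genotype_id → genotype_group (constant per genotype)."""
        out: dict[str, str] = {}
        for rec in self.records:
            prev = out.setdefault(rec.genotype_id, rec.genotype_group)
            if prev != rec.genotype_group:
                raise IntegrityError(
                    f"genotype {rec.genotype_id} listed in groups {prev!r} and "
                    f"{rec.genotype_group!r}"
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format plot table (one row per plot)."""
        rows = []
        for rec in self.records:
            row = {
                "genotype": rec.genotype_id,
                "group": rec.genotype_group,
                "environment": rec.environment_id,
                "replicate": rec.replicate,
                "yield_kg_ha": rec.yield_raw,
            }
            for m in self.minerals:
                row[f"conc_{m}_mg_kg"] = rec.concentrations[m]
            rows.append(row)
        return pd.DataFrame(rows)


_DRI_DEFAULT = {"Fe": 12.0, "Zn": 8.0, "Cu": 0.9, "Mg": 315.0}
_LAL_DEFAULT = {"Fe": 28.0, "Zn": 40.0, "Cu": 50.0, "Mg": 25.0}
_GAINS_DEFAULT = {"Fe": 11.0, "Zn": 4.0, "Cu": 0.0, "Mg": 6.0}


@dataclass
class AnalysisConfig:
    """Constants of the analysis.

    dri
        Daily recommended intake per mineral, mg·day⁻¹ (adult averages):
        defaults Fe 12, Zn 8, Cu 0.9, Mg 315.
    year_days
        Days per year in the nutritional-yield formula (365).
    dehulling_factor
        Fraction of hulled grain mass remaining after dehulling (0.75).
    hulled_groups
        Genotype groups whose yields are hulled and need the correction.
    lal
        Lowest acceptable limit per mineral nutritional yield
        (adults·ha⁻¹·year⁻¹) for Elston's multiplicative index.
    desired_gains
        Desired gain per mineral nutritional yield for the desired-gains
        index (adults·ha⁻¹·year⁻¹).
    """

    dri: dict[str, float] = field(default_factory=lambda: dict(_DRI_DEFAULT))
    year_days: float = 365.0
    dehulling_factor: float = 0.75
    hulled_groups: frozenset[str] = frozenset({"Spelt", "Primitive"})
    lal: dict[str, float] = field(default_factory=lambda: dict(_LAL_DEFAULT))
    desired_gains: dict[str, float] = field(default_factory=lambda: dict(_GAINS_DEFAULT))
    above_average_rule: str = "grand_mean"
    rounding: str = "half_away_from_zero"

    def __post_init__(self):
        self.hulled_groups = frozenset(self.hulled_groups)
        for mineral, v in self.dri.items():
            if v <= 0:
                raise ValueError(f"DRI for {mineral} must be positive, got {v}")
        if not (0 < self.dehulling_factor <= 1):
            raise ValueError(f"dehulling_factor must be in (0, 1], got {self.dehulling_factor}")
        if self.year_days <= 0:
            raise ValueError(f"year_days must be positive, got {self.year_days}")

    def validate_against(self, data: METDataset) -> None:
        """Fail if the config names minerals the dataset does not carry."""
        have = set(data.minerals)
        for name, mapping in (("dri", self.dri), ("lal", self.lal),
                              ("desired_gains", self.desired_gains)):
            unknown = set(mapping) - have
            if unknown:
                raise ConfigError(
                    f"config {name} names minerals absent from the data: {sorted(unknown)}"
                )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class TraitMatrix:
    """Genotype × environment table of trait cell means."""

    values: pd.DataFrame  # index = genotypes, columns = environments
    trait_name: str
    rep_counts: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.rep_counts.index) or not (
            self.values.columns.equals(self.rep_counts.columns)
        ):
            raise ValueError("values and rep_counts must share index/columns")

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def environments(self) -> list[str]:
        return list(self.values.columns)

    def require_complete(self) -> None:
        if self.values.isna().any().any():
            cell = self.values.stack(future_stack=True)
            bad = cell[cell.isna()].index[0]
            raise IncompleteDataError(
                f"trait {self.trait_name!r} has an empty cell at genotype "
                f"{bad[0]!r}, environment {bad[1]!r}"
            )


_REQUIRED_COLUMNS = ["genotype", "group", "environment", "replicate", "yield_kg_ha"]


def read_met_table(path: str | Path, config: AnalysisConfig | None = None) -> METDataset:
    """Read a plot-level CSV into a validated :class:`METDataset`.

    The dialect is fixed: comma-separated, header row, decimal point, UTF-8.
    Mineral names are inferred from ``conc_<mineral>_mg_kg`` columns.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    conc_cols = [c for c in df.columns if c.startswith("conc_") and c.endswith("_mg_kg")]
    if not conc_cols:
        raise SchemaError(f"{path}: no mineral concentration columns (conc_<mineral>_mg_kg)")
    minerals = [c[len("conc_"):-len("_mg_kg")] for c in conc_cols]

    records = []
    for idx, row in df.iterrows():
        if row["yield_kg_ha"] < 0:
            raise ValueError(
                f"{path}: negative yield {row['yield_kg_ha']} in data row {idx + 1} "
                f"(genotype {row['genotype']})"
            )
        conc = {}
        for m, c in zip(minerals, conc_cols):
            if row[c] < 0:
                raise ValueError(
                    f"{path}: negative {m} concentration {row[c]} in data row "
                    f"{idx + 1} (genotype {row['genotype']})"
                )
            conc[m] = float(row[c])
        records.append(
            PlotRecord(
                genotype_id=str(row["genotype"]),
                genotype_group=str(row["group"]),
                environment_id=str(row["environment"]),
                replicate=int(row["replicate"]),
                yield_raw=float(row["yield_kg_ha"]),
                concentrations=conc,
            )
        )
    genotypes = list(dict.fromkeys(r.genotype_id for r in records))
    environments = list(dict.fromkeys(r.environment_id for r in records))
    try:
        data = METDataset(records, minerals, genotypes, environments)
    except IntegrityError as exc:
        raise IntegrityError(f"{path}: {exc}") from exc
    if config is not None:
        config.validate_against(data)
    return data


def write_met_table(data: METDataset, path: str | Path) -> None:
    """Write the plot table as CSV at full numeric precision (round-trip safe)."""
    df = data.to_frame()
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def _trait_series(data: METDataset, trait: str) -> pd.DataFrame:
    df = data.to_frame()
    if trait == "yield":
        col = "yield_kg_ha"
    elif trait in data.minerals:
        col = f"conc_{trait}_mg_kg"
    else:
        raise KeyError(f"unknown trait {trait!r}; expected 'yield' or one of {data.minerals}")
    return df[["genotype", "environment", col]].rename(columns={col: "value"})


def cell_means(data: METDataset, trait: str) -> TraitMatrix:
    """Genotype × environment arithmetic means over replicates for one trait.

    ``trait`` is ``"yield"`` or a mineral name (raw concentration). Derived
    traits (nutritional yield) build their matrices in the nutrition module.
    """
    df = _trait_series(data, trait)
    grouped = df.groupby(["genotype", "environment"])["value"]
    means = grouped.mean().unstack()
    counts = grouped.size().unstack()
    means = means.reindex(index=data.genotypes, columns=data.environments)
    counts = counts.reindex(index=data.genotypes, columns=data.environments).fillna(0).astype(int)
    tm = TraitMatrix(values=means, trait_name=trait, rep_counts=counts)
    tm.require_complete()
    return tm


def frame_to_dataset(df: pd.DataFrame) -> METDataset:
    """Inverse of :meth:`METDataset.to_frame` (long plot table → dataset)."""
    conc_cols = [c for c in df.columns if c.startswith("conc_") and c.endswith("_mg_kg")]
    minerals = [c[len("conc_"):-len("_mg_kg")] for c in conc_cols]
    records = [
        PlotRecord(
            genotype_id=str(row["genotype"]),
            genotype_group=str(row["group"]),
            environment_id=str(row["environment"]),
            replicate=int(row["replicate"]),
            yield_raw=float(row["yield_kg_ha"]),
            concentrations={m: float(row[c]) for m, c in zip(minerals, conc_cols)},
        )
        for _, row in df.iterrows()
    ]
    genotypes = list(dict.fromkeys(r.genotype_id for r in records))
    environments = list(dict.fromkeys(r.environment_id for r in records))
    return METDataset(records, minerals, genotypes, environments)
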