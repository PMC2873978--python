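"""Cohort ingestion, codebook-driven harmonization, case definition, factor filters.

A *codebook* maps raw cohort-specific column names onto harmonized exposure
symbols and carries the metadata the scan needs per factor: environmental
class, measurement scale, units, assay detection limit (LOD), the referent
level of categorical assays, and whether the assay targeted only a population
subset. Harmonization is strictly codebook-driven: no fuzzy name matching.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DESIGN_COLUMNS = ("stratum", "psu", "weight")
STATUS_COLUMN = "status"

#: standard substitution constants for values below the detection limit
LOD_SUBSTITUTIONS = {
    "lod_sqrt2": lambda lod: lod / np.sqrt(2.0),
    "lod_half": lambda lod: lod / 2.0,
    "raw": None,  # keep the machine-read value
}


class HarmonizationError(ValueError):
    """Two raw columns of one cohort map onto the same harmonized symbol."""


@dataclasses.dataclass
class FactorDescriptor:
    """Metadata for one harmonized environmental factor."""

    symbol: str
    display_name: str = ""
    env_class: str = ""
    scale: str = "continuous"
    aliases: tuple[str, ...] = ()
    units: str = ""
    lod: float | None = None
    referent_level: str | None = None
    subset_targeted: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("continuous", "categorical"):
            raise ValueError(f"{self.symbol}: scale must be continuous or "
                             f"categorical, got {self.scale!r}")
        if self.scale == "continuous" and self.referent_level is not None:
            raise ValueError(f"{self.symbol}: continuous factors have no "
                             "referent level")
        if self.lod is not None and not self.lod > 0:
            raise ValueError(f"{self.symbol}: lod must be > 0")
        self.aliases = tuple(self.aliases)
        if not self.display_name:
            self.display_name = self.symbol


class Codebook:
    """Ordered collection of :class:`FactorDescriptor`, unique by symbol."""

    def __init__(self, factors: Iterable[FactorDescriptor]) -> None:
        self._factors: dict[str, FactorDescriptor] = {}
        for f in factors:
            if f.symbol in self._factors:
                raise ValueError(f"duplicate symbol {f.symbol!r} in codebook")
            self._factors[f.symbol] = f

    def __iter__(self):
        return iter(self._factors.values())

    def __len__(self) -> int:
        return len(self._factors)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._factors

    def __getitem__(self, symbol: str) -> FactorDescriptor:
        return self._factors[symbol]

    @property
    def symbols(self) -> list[str]:
        return list(self._factors)

    def alias_map(self) -> dict[str, str]:
        """Raw-column-name -> harmonized symbol (symbols map to themselves)."""
        out: dict[str, str] = {}
        for f in self:
            out[f.symbol] = f.symbol
            for a in f.aliases:
                if a in out and out[a] != f.symbol:
                    raise ValueError(f"alias {a!r} claimed by both "
                                     f"{out[a]!r} and {f.symbol!r}")
                out[a] = f.symbol
        return out

    # -- serialization (lossless YAML/JSON round trip) -----------------
    def to_dict(self) -> dict:
        return {"factors": [dataclasses.asdict(f) | {"aliases": list(f.aliases)}
                            for f in self]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        return cls(FactorDescriptor(**{**f, "aliases": tuple(f.get("aliases", ()))})
                   for f in d["factors"])

    def to_yaml(self, path_or_buf) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_yaml(cls, path_or_buf) -> "Codebook":
        if hasattr(path_or_buf, "read"):
            data = yaml.safe_load(path_or_buf)
        else:
            with open(path_or_buf) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


@dataclasses.dataclass(frozen=True)
class CaseDefinition:
    """Dichotomize a continuous phenotype: case iff value >= threshold.

    The default is the ADA fasting-blood-glucose criterion for diabetes,
    126 mg/dL. Rows with a missing phenotype are excluded, never imputed.
    """

    phenotype_column: str = "fbg"
    threshold: float = 126.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")


@dataclasses.dataclass
class CohortTable:
    """One survey cohort: participant rows plus design and exposure columns."""

    cohort_id: str
    data: pd.DataFrame
    exposure_columns: tuple[str, ...] = ()

    @property
    def n_case(self) -> int:
        return int((self.data[STATUS_COLUMN] == 1).sum())

    @property
    def n_control(self) -> int:
        return int((self.data[STATUS_COLUMN] == 0).sum())


def read_cohort_csv(path, cohort_id: str, **kwargs) -> CohortTable:
    return CohortTable(cohort_id=cohort_id, data=pd.read_csv(path, **kwargs))


def read_cohort_xpt(path, cohort_id: str) -> CohortTable:
    """Read a SAS transport (XPT) cohort file, the format national health
    surveys distribute."""
    return CohortTable(cohort_id=cohort_id,
                       data=pd.read_sas(path, format="xport"))


def harmonize_symbols(tables: Sequence[CohortTable], codebook: Codebook,
                      ) -> tuple[list[CohortTable], dict[str, list[str]]]:
    """Rename cohort-specific exposure columns onto harmonized symbols.

    Returns the harmonized tables and a registry symbol -> cohort ids in
    which the factor is measured. A factor measured under different raw
    names in different cohorts appears under one symbol in all of them.
    Two raw columns of a single cohort mapping to the same symbol is a hard
    error. Idempotent: symbols map to themselves.
    """
    amap = codebook.alias_map()
    out: list[CohortTable] = []
    registry: dict[str, list[str]] = {s: [] for s in codebook.symbols}
    for t in tables:
        rename: dict[str, str] = {}
        claimed: dict[str, str] = {}
        for col in t.data.columns:
            sym = amap.get(col)
            if sym is None:
                continue
            if sym in claimed:
                raise HarmonizationError(
                    f"cohort {t.cohort_id!r}: columns {claimed[sym]!r} and "
                    f"{col!r} both map to symbol {sym!r}")
            claimed[sym] = col
            if col != sym:
                rename[col] = sym
        df = t.data.rename(columns=rename) if rename else t.data
        present = tuple(s for s in codebook.symbols if s in claimed)
        for s in present:
            registry[s].append(t.cohort_id)
        out.append(CohortTable(cohort_id=t.cohort_id, data=df,
                               exposure_columns=present))
    return out, registry


def classify_cases(table: CohortTable,
                   case_def: CaseDefinition = CaseDefinition()) -> CohortTable:
    """Attach binary case status and drop rows with a missing phenotype.

    Raises if the classified cohort has zero cases or zero controls (no
    estimable model).
    """
    pheno = pd.to_numeric(table.data[case_def.phenotype_column],
                          errors="raise")
    keep = pheno.notna()
    df = table.data.loc[keep].copy()
    df[STATUS_COLUMN] = (pheno[keep] >= case_def.threshold).astype(int)
    n_case = int(df[STATUS_COLUMN].sum())
    n_control = len(df) - n_case
    if n_case == 0 or n_control == 0:
        raise ValueError(
            f"cohort {table.cohort_id!r}: {n_case} cases / {n_control} "
            "controls after classification; no estimable model")
    return CohortTable(cohort_id=table.cohort_id, data=df,
                       exposure_columns=table.exposure_columns)


@dataclasses.dataclass(frozen=True)
class FactorExclusion:
    symbol: str
    reason: str
    detail: str = ""


def filter_factors(table: CohortTable, codebook: Codebook,
                   lod_fraction: float = 0.90,
                   ) -> tuple[list[str], list[FactorExclusion]]:
    """Apply the factor-inclusion filters; rows are never removed.

    A factor is excluded when strictly more than ``lod_fraction`` (default
    90%) of its non-missing observations fall below its detection limit, or
    when the assay targeted only a population subset. Factors without a
    recorded LOD skip the LOD rule.
    """
    retained: list[str] = []
    excluded: list[FactorExclusion] = []
    for sym in table.exposure_columns:
        f = codebook[sym]
        if f.subset_targeted:
            excluded.append(FactorExclusion(sym, "subset_targeted",
                                            "assay targeted a population subset"))
            continue
        if f.scale == "continuous" and f.lod is not None:
            x = pd.to_numeric(table.data[sym], errors="coerce")
            x = x[x.notna()]
            if len(x) > 0:
                frac = float((x < f.lod).mean())
                if frac > lod_fraction:
                    excluded.append(FactorExclusion(
                        sym, "below_lod",
                        f"{frac:.1%} of non-missing observations below "
                        f"LOD={f.lod:g}"))
                    continue
        retained.append(sym)
    return retained, excluded


def substitute_below_lod(table: CohortTable, codebook: Codebook,
                         method: str = "lod_sqrt2") -> CohortTable:
    """Replace below-LOD machine values of continuous factors.

    Default is the LOD/sqrt(2) convention standard for national survey
    laboratory data; ``lod_half`` and ``raw`` (no substitution) are also
    available.
    """
    if method not in LOD_SUBSTITUTIONS:
        raise ValueError(f"unknown substitution method {method!r}")
    rule = LOD_SUBSTITUTIONS[method]
    if rule is None:
        return table
    df = table.data.copy()
    for sym in table.exposure_columns:
        f = codebook[sym]
        if f.scale != "continuous" or f.lod is None or sym not in df:
            continue
        x = df[sym]
        df[sym] = x.where(~(x < f.lod), rule(f.lod))
    return CohortTable(cohort_id=table.cohort_id, data=df,
                       exposure_columns=table.exposure_columns)
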