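"""The published three-file data model: read, validate, zero-fill, summarize.

The survey ships as three coupled CSVs:

* ``samples.csv``  — one row per sampled station visit, with planar metadata
  and the reduced sediment measures (median grain size, mud percentage);
* ``species.csv``  — one row per taxon, with identification metadata and the
  codes driving length measurement and missing-biomass imputation;
* ``biota.csv``    — one row per (sample, taxon) with standardized density
  and biomass; absences are *not* stored, so zeros must be reconstructed by
  joining against the sample list ("zero-filling").

This module enforces those contracts, performs the zero-filling join, and
produces the campaign-level and community-level summary tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "SAMPLES_COLUMNS",
    "SPECIES_COLUMNS",
    "BIOTA_COLUMNS",
    "read_table",
    "write_table",
    "Violation",
    "ValidationReport",
    "validate",
    "zero_fill",
    "CampaignSummary",
    "summarize_campaign",
    "per_year_from_samples",
    "reference_campaign_table",
    "summarize_community",
    "round_half_up",
]

SAMPLES_COLUMNS = [
    "sample_id", "sampling_station_id", "sampling_type", "date", "platform",
    "tidal_basin_name", "tidal_flat_name", "x", "y",
    "median_grain_size", "percentage_mud",
]
SPECIES_COLUMNS = [
    "sibes_id", "name", "short_name", "aphia_id", "taxonomic_group",
    "taxonomic_indentification_level", "year_added", "occurance", "occupancy",
    "weight_is_measured", "length_measuring_method_id",
    "min_shell_length_to_separate_flesh", "missing_afdm_method_id", "remarks",
]
BIOTA_COLUMNS = ["sample_id", "sibes_id", "abundance_m2", "afdm_m2"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (numpy/python round are half-even)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def read_table(path, na_token: str = "") -> pd.DataFrame:
    """Read one of the three CSVs; empty fields are missing values."""
    return pd.read_csv(path, na_values=[na_token], keep_default_na=True)


def write_table(df: pd.DataFrame, path, na_token: str = "") -> None:
    """Write a table with the package's missing-value convention."""
    df.to_csv(path, index=False, na_rep=na_token)


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    table: str
    rule: str
    detail: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(v.severity == "error" for v in self.violations)

    @property
    def exit_status(self) -> int:
        return 0 if self.ok else 1

    def to_json_lines(self) -> str:
        return "\n".join(v.to_json() for v in self.violations)

    def __str__(self) -> str:
        if not self.violations:
            return "OK: no violations"
        return "\n".join(
            f"[{v.severity}] {v.table}: {v.rule} — {v.detail}" for v in self.violations
        )


def _dup(report, table, df, keys):
    d = df.duplicated(subset=keys)
    if d.any():
        report.violations.append(
            Violation("error", table, "duplicate key",
                      f"{int(d.sum())} duplicated {keys} rows")
        )


def validate(
    samples: pd.DataFrame, species: pd.DataFrame, biota: pd.DataFrame
) -> ValidationReport:
    """Check the three tables against their published contracts.

    Covers duplicate keys, enum membership (platform, sampling_type), value
    ranges (mud percentage, coordinates, occupancy, non-positive abundance)
    and referential integrity of biota against samples and species.
    """
    r = ValidationReport()
    for col in ("sample_id",):
        if col not in samples.columns:
            r.violations.append(Violation("error", "samples", "missing column", col))
            return r
    _dup(r, "samples", samples, ["sample_id"])
    _dup(r, "species", species, ["sibes_id"])
    if {"sample_id", "sibes_id"}.issubset(biota.columns):
        _dup(r, "biota", biota, ["sample_id", "sibes_id"])

    bad = ~samples["platform"].isin(["boat", "walk"]) & samples["platform"].notna()
    if bad.any():
        r.violations.append(
            Violation("error", "samples", "unknown enum",
                      f"platform not in {{boat, walk}} for {int(bad.sum())} rows")
        )
    bad = ~samples["sampling_type"].isin(["grid", "random"]) & samples["sampling_type"].notna()
    if bad.any():
        r.violations.append(
            Violation("error", "samples", "unknown enum",
                      f"sampling_type not in {{grid, random}} for {int(bad.sum())} rows")
        )
    mud = pd.to_numeric(samples.get("percentage_mud"), errors="coerce")
    bad = ((mud < 0) | (mud > 100)) & mud.notna()
    if bad.any():
        r.violations.append(
            Violation("error", "samples", "out of range",
                      f"percentage_mud outside [0, 100] for {int(bad.sum())} rows")
        )
    for col, lo, hi in (("x", -180, 180), ("y", -90, 90)):
        v = pd.to_numeric(samples.get(col), errors="coerce")
        bad = ((v < lo) | (v > hi)) & v.notna()
        if bad.any():
            r.violations.append(
                Violation("error", "samples", "out of range",
                          f"{col} outside [{lo}, {hi}] for {int(bad.sum())} rows")
            )

    occ = pd.to_numeric(species.get("occupancy"), errors="coerce")
    bad = ((occ < 0) | (occ > 100)) & occ.notna()
    if bad.any():
        r.violations.append(
            Violation("error", "species", "out of range",
                      f"occupancy outside [0, 100] for {int(bad.sum())} rows")
        )
    aphia = pd.to_numeric(species.get("aphia_id"), errors="coerce")
    bad = (aphia <= 0) & aphia.notna()
    if bad.any():
        r.violations.append(
            Violation("error", "species", "out of range",
                      f"aphia_id not a positive integer for {int(bad.sum())} rows")
        )

    ab = pd.to_numeric(biota.get("abundance_m2"), errors="coerce")
    bad = (ab <= 0) | ab.isna()
    if bad.any():
        r.violations.append(
            Violation("error", "biota", "out of range",
                      f"abundance_m2 not > 0 for {int(bad.sum())} rows "
                      "(absences must be absent rows, not zeros)")
        )
    af = pd.to_numeric(biota.get("afdm_m2"), errors="coerce")
    bad = (af < 0) & af.notna()
    if bad.any():
        r.violations.append(
            Violation("error", "biota", "out of range",
                      f"afdm_m2 negative for {int(bad.sum())} rows")
        )

    orphan = ~biota["sample_id"].isin(samples["sample_id"])
    if orphan.any():
        r.violations.append(
            Violation("error", "biota", "referential",
                      f"{int(orphan.sum())} rows reference unknown sample_id")
        )
    orphan = ~biota["sibes_id"].isin(species["sibes_id"])
    if orphan.any():
        r.violations.append(
            Violation("error", "biota", "referential",
                      f"{int(orphan.sum())} rows reference unknown sibes_id")
        )
    return r


def zero_fill(
    samples: pd.DataFrame,
    species: pd.DataFrame,
    biota: pd.DataFrame,
    taxa: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Dense sample x taxon table with explicit zeros for absences.

    Exactly ``len(samples) * len(taxa)`` rows; rows present in biota keep
    their values, everything else gets abundance and biomass 0.
    """
    if taxa is None:
        taxa = species["sibes_id"].tolist()
    else:
        unknown = set(taxa) - set(species["sibes_id"])
        if unknown:
            raise KeyError(f"taxa not in species table: {sorted(unknown)}")
    full = pd.MultiIndex.from_product(
        [samples["sample_id"], list(taxa)], names=["sample_id", "sibes_id"]
    ).to_frame(index=False)
    sub = biota[biota["sibes_id"].isin(list(taxa))]
    dense = full.merge(sub, on=["sample_id", "sibes_id"], how="left")
    dense["abundance_m2"] = dense["abundance_m2"].fillna(0.0)
    dense["afdm_m2"] = dense["afdm_m2"].fillna(0.0)
    return dense


@dataclass
class CampaignSummary:
    """Per-year station bookkeeping plus the averages and min/max rows."""

    per_year: pd.DataFrame
    averages: pd.Series
    min_total: int
    max_total: int
    averages_years: tuple[int, int]


def per_year_from_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Build the per-year campaign table from a samples.csv frame."""
    df = samples.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    rows = []
    for year, g in df.groupby("year"):
        total = len(g)
        random = int((g["sampling_type"] == "random").sum())
        boat = int((g["platform"] == "boat").sum())
        rows.append(
            {
                "year": int(year),
                "total": total,
                "grid": total - random,
                "random": random,
                "pct_random": round_half_up(100.0 * random / total),
                "pct_boating": round_half_up(100.0 * boat / total),
            }
        )
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def summarize_campaign(
    per_year: pd.DataFrame,
    averages_range: Optional[tuple[int, int]] = (2008, 2019),
    exclude_years: Sequence[int] = (),
) -> CampaignSummary:
    """Campaign summary: recomputed percentages, averages row, min/max totals.

    ``averages_range`` bounds the years entering the averages row (inclusive;
    None = all years); ``exclude_years`` removes specific years instead, for
    the "all but the disrupted year" convention. Percentages and averages are
    rounded half-up to integers, matching the printed table.
    """
    if per_year.empty:
        return CampaignSummary(per_year, pd.Series(dtype=float), 0, 0, (0, 0))
    df = per_year.copy().sort_values("year").reset_index(drop=True)
    df["pct_random"] = [
        round_half_up(100.0 * r / t) for r, t in zip(df["random"], df["total"])
    ]
    sel = df
    if averages_range is not None:
        lo, hi = averages_range
        sel = sel[(sel["year"] >= lo) & (sel["year"] <= hi)]
    if exclude_years:
        sel = sel[~sel["year"].isin(list(exclude_years))]
    avg_cols = [
        c for c in ("total", "grid", "random", "pct_random", "pct_boating")
        if c in df.columns
    ]
    averages = pd.Series(
        {c: round_half_up(sel[c].mean()) for c in avg_cols}, dtype=float
    )
    years = (int(sel["year"].min()), int(sel["year"].max())) if len(sel) else (0, 0)
    return CampaignSummary(
        per_year=df,
        averages=averages,
        min_total=int(df["total"].min()),
        max_total=int(df["total"].max()),
        averages_years=years,
    )


def reference_campaign_table() -> pd.DataFrame:
    """The published per-year campaign totals, shipped as package data."""
    with resources.files("mudflat.data").joinpath("campaign_totals.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_community(
    dense: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-station richness/biomass and per-year species means with SE.

    Requires a zero-filled dense table (richness on a sparse table would be
    ill-defined): every sample must carry a row for every taxon. Returns
    (per_sample, yearly_species_means, cross_year) where cross_year has the
    among-year mean and standard error (SD / sqrt(n_years)) per taxon.
    """
    n_taxa = dense["sibes_id"].nunique()
    if set(dense["sample_id"]) != set(samples["sample_id"]) or len(dense) != samples[
        "sample_id"
    ].nunique() * n_taxa:
        raise SchemaError(
            "input is not zero-filled: need every sample x taxon combination"
        )
    per_sample = (
        dense.groupby("sample_id")
        .agg(
            richness=("abundance_m2", lambda a: int((a > 0).sum())),
            total_afdm_m2=("afdm_m2", "sum"),
        )
        .reset_index()
    )
    meta = samples[["sample_id", "date"]].copy()
    meta["year"] = pd.to_datetime(meta["date"]).dt.year
    joined = dense.merge(meta[["sample_id", "year"]], on="sample_id", how="left")
    yearly = (
        joined.groupby(["year", "sibes_id"])
        .agg(
            mean_abundance_m2=("abundance_m2", "mean"),
            mean_afdm_m2=("afdm_m2", "mean"),
        )
        .reset_index()
    )
    cross = (
        yearly.groupby("sibes_id")
        .agg(
            mean_abundance_m2=("mean_abundance_m2", "mean"),
            se_abundance_m2=(
                "mean_abundance_m2",
                lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            ),
            mean_afdm_m2=("mean_afdm_m2", "mean"),
            se_afdm_m2=(
                "mean_afdm_m2",
                lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            ),
            n_years=("year", "nunique"),
        )
        .reset_index()
    )
    return per_sample, yearly, cross
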