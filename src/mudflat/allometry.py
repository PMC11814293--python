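"""Species-specific biomass-length allometry: LOESS fits, outlier QC, imputation.

Ash-free dry mass (AFDM, g) scales with body length roughly as a power law,
but the exponent drifts with condition, so the relationship is modelled
non-parametrically: a locally weighted quadratic regression (LOESS, tricube
weights, span 0.6) of log mass on length. Residual outliers beyond twice the
interquartile range outside the quartiles are flagged, the curve is refitted
once without them, and the fitted curve bank predicts AFDM for individuals
whose mass could not be weighed.

Fits are hierarchical: the record pool for a species is narrowed from the
full multi-year season, to the year, to the region, to the tidal basin, and
the model is fitted at the *finest* scale that still holds enough records
(75; 45 for taxa predominantly under 11 mm). Individuals without a length
fall back to a hierarchical mean with a 30-record minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ScaleError
from .processing import DEFAULT_PROTOCOL, ProtocolConstants

__all__ = [
    "Taxon",
    "ScaleLadder",
    "SCALE_LEVELS",
    "LoessAllometry",
    "AllometryModel",
    "detect_outliers",
    "select_scale",
    "select_scale_bulk",
    "fit_allometry",
    "HierarchicalImputer",
    "impute_afdm",
    "outlier_share",
]

SCALE_LEVELS = ("season", "year", "region", "basin")

#: missing-AFDM method codes used in the species table
METHOD_MEAN = 12                 # hierarchical average
METHOD_LOESS = 24                # allometric LOESS prediction
METHOD_HISTORICAL_MEAN = 25      # average over prior years


@dataclass(frozen=True)
class Taxon:
    """Species metadata mirroring the species.csv columns that drive QC."""

    sibes_id: int
    name: str
    aphia_id: Optional[int] = None
    taxonomic_group: str = ""
    taxonomic_identification_level: str = "species"
    length_measuring_method_id: int = 1
    min_shell_length_to_separate_flesh: Optional[float] = None
    weight_is_measured: bool = True
    missing_afdm_method_id: int = METHOD_LOESS
    small_species: bool = False
    count_whole_only: bool = False

    def __post_init__(self) -> None:
        if self.length_measuring_method_id not in range(1, 7):
            raise ValueError("length_measuring_method_id must be in 1..6")
        if self.missing_afdm_method_id not in (
            METHOD_MEAN, METHOD_LOESS, METHOD_HISTORICAL_MEAN
        ):
            raise ValueError("missing_afdm_method_id must be 12, 24 or 25")


@dataclass(frozen=True)
class ScaleLadder:
    """Record counts at each hierarchical level, coarse to fine."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [lv for lv in SCALE_LEVELS if lv not in self.counts]
        if missing:
            raise ValueError(f"ladder lacks levels: {missing}")
        seq = [int(self.counts[lv]) for lv in SCALE_LEVELS]
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError("counts must be non-increasing from coarse to fine")

    def as_array(self) -> np.ndarray:
        return np.array([int(self.counts[lv]) for lv in SCALE_LEVELS])


def _threshold(taxon: Optional[Taxon], purpose: str, constants: ProtocolConstants) -> int:
    if purpose == "mean":
        return constants.scale_threshold_mean
    if purpose == "loess":
        if taxon is not None and taxon.small_species:
            return constants.scale_threshold_small
        return constants.scale_threshold_standard
    raise ValueError(f"unknown purpose {purpose!r} (expected 'loess' or 'mean')")


def select_scale(
    ladder: ScaleLadder,
    taxon: Optional[Taxon] = None,
    purpose: str = "loess",
    constants: ProtocolConstants = DEFAULT_PROTOCOL,
) -> Optional[str]:
    """Finest hierarchical level with enough records, or None.

    The threshold is 75 records for a LOESS fit (45 for small taxa) and 30
    for a mean fallback; the levels are scanned from tidal basin up to the
    pooled season and the finest qualifying one wins.
    """
    t = _threshold(taxon, purpose, constants)
    for level in reversed(SCALE_LEVELS):
        if int(ladder.counts[level]) >= t:
            return level
    return None


def select_scale_bulk(counts: np.ndarray, threshold: int) -> np.ndarray:
    """Vectorized scale selection on an (n, 4) count array (coarse->fine).

    Returns the selected level index per row (0=season .. 3=basin), or -1
    when no level reaches the threshold.
    """
    c = np.asarray(counts)
    out = np.full(c.shape[0], -1, dtype=np.int8)
    for i, _ in enumerate(SCALE_LEVELS):  # coarse to fine: later wins
        out[c[:, i] >= threshold] = i
    return out


def _tricube(u: np.ndarray) -> np.ndarray:
    a = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return a**3


class LoessAllometry(RegressorMixin, BaseEstimator):
    """Locally weighted quadratic regression of log(AFDM) on length.

    Mirrors the classical LOESS smoother (tricube kernel, local polynomial of
    degree 2, span as the fraction of points in each local window). Mass is
    fitted on the log scale — it spans orders of magnitude and the residual
    spread is far more homogeneous there — and by default length enters on
    the log scale too, so a clean power law ``m = a L^b`` is locally linear
    and recovered without boundary bias. Predictions are returned in grams;
    lengths outside the training range are clamped to the nearest domain
    edge (use :meth:`predict_with_flags` to know which).

    Parameters
    ----------
    span : float, default 0.6
        Fraction of records in each local window.
    degree : int, default 2
        Local polynomial degree.
    log_mass : bool, default True
        Fit on log(mass); predictions are back-transformed.
    log_length : bool, default True
        Smooth against log(length) instead of raw length.
    """

    def __init__(
        self,
        span: float = 0.6,
        degree: int = 2,
        log_mass: bool = True,
        log_length: bool = True,
    ):
        self.span = span
        self.degree = degree
        self.log_mass = log_mass
        self.log_length = log_length

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if x.shape[0] < self.degree + 2:
            raise ScaleError("too few records for a local polynomial fit")
        if np.any(y <= 0) and self.log_mass:
            raise ValueError("masses must be positive to fit on the log scale")
        if np.any(x <= 0) and self.log_length:
            raise ValueError("lengths must be positive to smooth on the log scale")
        order = np.argsort(x, kind="stable")
        if self.log_length:
            x = np.log(x)
        self.x_ = x[order]
        self.z_ = np.log(y[order]) if self.log_mass else y[order]
        self._order_ = order
        lo, hi = float(self.x_[0]), float(self.x_[-1])
        # domain_ is always in mm, whatever the working scale
        self.domain_ = (np.exp(lo), np.exp(hi)) if self.log_length else (lo, hi)
        self.n_records_ = int(x.shape[0])
        resid = self.z_ - self._smooth(self.x_)
        self.residuals_ = np.empty_like(resid)
        self.residuals_[order] = resid  # back in input order
        self.residual_sd_ = float(resid.std(ddof=1)) if resid.size > 1 else 0.0
        return self

    def _window(self, x0: float) -> tuple[np.ndarray, np.ndarray]:
        n = self.x_.shape[0]
        q = int(np.floor(self.span * n)) if self.span <= 1 else n
        q = min(max(q, self.degree + 1), n)
        d = np.abs(self.x_ - x0)
        idx = np.argpartition(d, q - 1)[:q]
        h = d[idx].max()
        if h == 0:
            h = 1.0
        return idx, _tricube(d[idx] / h)

    def _smooth(self, xs: np.ndarray) -> np.ndarray:
        out = np.empty(xs.shape[0])
        for i, x0 in enumerate(xs):
            idx, w = self._window(x0)
            xi = self.x_[idx] - x0
            zi = self.z_[idx]
            # weighted polynomial fit centred on x0: intercept = prediction
            A = np.vander(xi, self.degree + 1, increasing=True)
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(A * sw[:, None], zi * sw, rcond=None)
            out[i] = coef[0]
        return out

    def predict(self, X) -> np.ndarray:
        pred, _ = self.predict_with_flags(X)
        return pred

    def predict_with_flags(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predict AFDM; second return flags lengths clamped to the domain."""
        check_is_fitted(self, "x_")
        xs = np.asarray(X, dtype=float).reshape(-1)
        lo, hi = self.domain_
        extrapolated = (xs < lo) | (xs > hi)
        clamped = np.clip(xs, lo, hi)
        if self.log_length:
            clamped = np.log(clamped)
        z = self._smooth(clamped)
        pred = np.exp(z) if self.log_mass else z
        return pred, extrapolated


def detect_outliers(
    observed: np.ndarray,
    predicted: np.ndarray,
    log_scale: bool = True,
    k: float = 2.0,
) -> np.ndarray:
    """Flag records whose residual falls outside the quartile fences.

    Residuals are observed minus predicted on the fitting scale (log mass by
    default); a record is an outlier when its residual is below
    ``Q1 - k*IQR`` or above ``Q3 + k*IQR`` with k = 2. Fewer than four
    records leave the quartiles undefined: nothing is flagged and a warning
    is emitted.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if log_scale:
        r = np.log(observed) - np.log(predicted)
    else:
        r = observed - predicted
    if r.size < 4:
        warnings.warn("fewer than 4 records: quartiles undefined, no outliers flagged")
        return np.zeros(r.size, dtype=bool)
    q1, q3 = np.percentile(r, [25.0, 75.0])
    iqr = q3 - q1
    return (r < q1 - k * iqr) | (r > q3 + k * iqr)


def outlier_share(n_outliers: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of records flagged, rounded half-up to the printed precision."""
    pct = Decimal(100) * Decimal(n_outliers) / Decimal(n_total)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AllometryModel:
    """A fitted biomass-length curve plus its provenance."""

    taxon_id: int
    level: str
    span: float
    model: LoessAllometry
    n_records: int
    domain: tuple[float, float]
    residual_sd: float
    n_outliers_removed: int = 0

    def predict(self, lengths) -> np.ndarray:
        return self.model.predict(lengths)


def fit_allometry(
    lengths: np.ndarray,
    afdm: np.ndarray,
    taxon: Taxon,
    level: str,
    constants: ProtocolConstants = DEFAULT_PROTOCOL,
) -> AllometryModel:
    """Fit the species curve at one hierarchical level with one QC pass.

    Fits LOESS (span 0.6), flags residual outliers with the 2xIQR fences,
    refits once without them, and records the training-length domain (no
    extrapolation beyond it). Raises :class:`ScaleError` when the record
    count is below the applicable threshold — pick a coarser level with
    :func:`select_scale`.
    """
    lengths = np.asarray(lengths, dtype=float)
    afdm = np.asarray(afdm, dtype=float)
    need = _threshold(taxon, "loess", constants)
    if lengths.shape[0] < need:
        raise ScaleError(
            f"{lengths.shape[0]} records < threshold {need}; use select_scale "
            "to choose a coarser level"
        )
    first = LoessAllometry(span=constants.loess_span).fit(lengths, afdm)
    pred, _ = first.predict_with_flags(lengths)
    flags = detect_outliers(afdm, pred, log_scale=first.log_mass)
    keep = ~flags
    model = LoessAllometry(span=constants.loess_span).fit(lengths[keep], afdm[keep])
    return AllometryModel(
        taxon_id=taxon.sibes_id,
        level=level,
        span=constants.loess_span,
        model=model,
        n_records=int(keep.sum()),
        domain=model.domain_,
        residual_sd=model.residual_sd_,
        n_outliers_removed=int(flags.sum()),
    )


def _ladder_masks(df: pd.DataFrame, rec) -> dict[str, pd.Series]:
    """Nested record pools, coarse to fine, for one target record."""
    season = pd.Series(True, index=df.index)
    year = season & (df["year"] == rec["year"])
    region = year & (df["region"] == rec["region"])
    basin = region & (df["tidal_basin_name"] == rec["tidal_basin_name"])
    return {"season": season, "year": year, "region": region, "basin": basin}


class HierarchicalImputer(TransformerMixin, BaseEstimator):
    """Fill missing AFDM values with the hierarchical LOESS/mean procedure.

    fit() takes the individual-record table (columns: sibes_id, length_mm,
    afdm_g, year, region, tidal_basin_name) and the taxon metadata; the
    complete records (both length and mass present) become the training pool.
    transform() returns a copy of its input with ``afdm_filled_g`` plus audit
    columns ``impute_method_id`` (12/24/25, or <NA>) and ``impute_scale``.

    Dispatch per record follows the taxon's missing-AFDM method: a length
    inside a qualifying LOESS model's domain is predicted from the curve
    (method 24); otherwise the hierarchical mean with a 30-record minimum
    (method 12); method-25 taxa pool prior years of the same taxon instead.
    Records nothing qualifies for stay missing, with the reason in the audit.
    """

    def __init__(self, constants: ProtocolConstants = DEFAULT_PROTOCOL):
        self.constants = constants

    def fit(self, X: pd.DataFrame, taxa: Mapping[int, Taxon]):
        df = X.copy()
        for col in ("sibes_id", "length_mm", "afdm_g", "year"):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        if "region" not in df.columns:
            df["region"] = "all"
        if "tidal_basin_name" not in df.columns:
            df["tidal_basin_name"] = "all"
        self.taxa_ = dict(taxa)
        # curve fits need both measures; the mean fallback only needs mass
        self.train_ = df[df["length_mm"].notna() & df["afdm_g"].notna()].copy()
        self.train_mean_ = df[df["afdm_g"].notna()].copy()
        self._model_bank: dict[tuple, AllometryModel] = {}
        self._mean_bank: dict[tuple, float] = {}
        return self

    # -- internals ----------------------------------------------------------

    def _taxon(self, sibes_id: int) -> Taxon:
        if sibes_id in self.taxa_:
            return self.taxa_[sibes_id]
        return Taxon(sibes_id=int(sibes_id), name=f"taxon_{sibes_id}")

    def _loess_for(self, rec, taxon: Taxon):
        pool = self.train_[self.train_["sibes_id"] == taxon.sibes_id]
        if pool.empty:
            return None
        masks = _ladder_masks(pool, rec)
        ladder = ScaleLadder({lv: int(m.sum()) for lv, m in masks.items()})
        level = select_scale(ladder, taxon, "loess", self.constants)
        if level is None:
            return None
        key_vals = {
            "season": (),
            "year": (rec["year"],),
            "region": (rec["year"], rec["region"]),
            "basin": (rec["year"], rec["region"], rec["tidal_basin_name"]),
        }[level]
        key = (taxon.sibes_id, level) + key_vals
        if key not in self._model_bank:
            sub = pool[masks[level]]
            self._model_bank[key] = fit_allometry(
                sub["length_mm"].to_numpy(),
                sub["afdm_g"].to_numpy(),
                taxon,
                level,
                self.constants,
            )
        return self._model_bank[key]

    def _mean_for(self, rec, taxon: Taxon, historical: bool):
        pool = self.train_mean_[self.train_mean_["sibes_id"] == taxon.sibes_id]
        if historical:
            pool = pool[pool["year"] < rec["year"]]
        if pool.empty:
            return None
        masks = _ladder_masks(pool, rec)
        if historical:  # prior years: the year level no longer filters
            masks["year"] = pd.Series(True, index=pool.index)
            masks["region"] = pool["region"] == rec["region"]
            masks["basin"] = masks["region"] & (
                pool["tidal_basin_name"] == rec["tidal_basin_name"]
            )
        ladder = ScaleLadder({lv: int(m.sum()) for lv, m in masks.items()})
        level = select_scale(ladder, taxon, "mean", self.constants)
        if level is None:
            return None
        return float(pool[masks[level]]["afdm_g"].mean()), level

    # -- public -------------------------------------------------------------

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "train_")
        df = X.copy()
        if "region" not in df.columns:
            df["region"] = "all"
        if "tidal_basin_name" not in df.columns:
            df["tidal_basin_name"] = "all"
        filled = df.get("afdm_g", pd.Series(np.nan, index=df.index)).copy().astype(float)
        method = pd.array([pd.NA] * len(df), dtype="Int64")
        scale = pd.array([pd.NA] * len(df), dtype="string")
        reason = pd.array([pd.NA] * len(df), dtype="string")

        for pos, (_, rec) in enumerate(df.iterrows()):
            if not pd.isna(rec.get("afdm_g", np.nan)):
                continue
            taxon = self._taxon(int(rec["sibes_id"]))
            value = None
            if rec.get("length_mm") is not None and not pd.isna(rec.get("length_mm")):
                m = self._loess_for(rec, taxon)
                if m is not None:
                    value = float(m.predict([rec["length_mm"]])[0])
                    method[pos] = METHOD_LOESS
                    scale[pos] = m.level
            if value is None:
                historical = taxon.missing_afdm_method_id == METHOD_HISTORICAL_MEAN
                got = self._mean_for(rec, taxon, historical)
                if got is not None:
                    value, level = got
                    method[pos] = (
                        METHOD_HISTORICAL_MEAN if historical else METHOD_MEAN
                    )
                    scale[pos] = level
            if value is None:
                reason[pos] = "insufficient records"
            else:
                filled.iloc[pos] = max(value, 0.0)
        out = df.copy()
        out["afdm_filled_g"] = filled
        out["impute_method_id"] = method
        out["impute_scale"] = scale
        out["impute_missing_reason"] = reason
        return out

    def audit(self, transformed: pd.DataFrame) -> pd.DataFrame:
        """The audit columns alone, for writing next to (never into) biota.csv."""
        cols = ["impute_method_id", "impute_scale", "impute_missing_reason"]
        return transformed[[c for c in cols if c in transformed.columns]].copy()


def impute_afdm(
    record: Mapping,
    taxon: Taxon,
    imputer: HierarchicalImputer,
) -> tuple[Optional[float], Optional[int], Optional[str]]:
    """Impute one record through a fitted bank: (afdm_g, method_id, scale).

    The record must lack a measured AFDM; passing a measured one is a misuse
    error, because imputation would silently overwrite data.
    """
    if record.get("afdm_g") is not None and not pd.isna(record.get("afdm_g")):
        raise ValueError("record already has a measured AFDM; refusing to impute")
    row = pd.DataFrame([dict(record)])
    row["sibes_id"] = taxon.sibes_id
    out = imputer.transform(row)
    val = out["afdm_filled_g"].iloc[0]
    meth = out["impute_method_id"].iloc[0]
    lvl = out["impute_scale"].iloc[0]
    return (
        None if pd.isna(val) else float(val),
        None if pd.isna(meth) else int(meth),
        None if pd.isna(lvl) else str(lvl),
    )
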