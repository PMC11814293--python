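"""LOESS allometry, outlier fences, scale selection and hierarchical imputation."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from mudflat.allometry import (
    SCALE_LEVELS,
    AllometryModel,
    HierarchicalImputer,
    LoessAllometry,
    ScaleLadder,
    Taxon,
    detect_outliers,
    fit_allometry,
    impute_afdm,
    outlier_share,
    select_scale,
    select_scale_bulk,
)
from mudflat.errors import ScaleError

STANDARD = Taxon(sibes_id=1, name="Clam")
SMALL = Taxon(sibes_id=2, name="Snail", small_species=True)


def brute_force_scale(counts, threshold):
    """Oracle: walk fine to coarse, return the first level meeting the threshold."""
    for level in ("basin", "region", "year", "season"):
        if counts[level] >= threshold:
            return level
    return None


class TestSelectScale:
    @pytest.mark.parametrize(
        "counts,taxon,purpose,expected",
        [
            ({"season": 1000, "year": 200, "region": 80, "basin": 40}, STANDARD, "loess", "region"),
            ({"season": 1000, "year": 200, "region": 80, "basin": 50}, SMALL, "loess", "basin"),
            ({"season": 20, "year": 10, "region": 5, "basin": 0}, STANDARD, "mean", None),
            ({"season": 74, "year": 74, "region": 74, "basin": 74}, STANDARD, "loess", None),
            ({"season": 75, "year": 74, "region": 0, "basin": 0}, STANDARD, "loess", "season"),
            ({"season": 40, "year": 35, "region": 31, "basin": 30}, STANDARD, "mean", "basin"),
        ],
    )
    def test_rule_examples(self, counts, taxon, purpose, expected):
        assert select_scale(ScaleLadder(counts), taxon, purpose) == expected

    def test_matches_brute_force_on_random_ladders(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            raw = np.sort(rng.integers(0, 121, size=4))[::-1]
            counts = dict(zip(SCALE_LEVELS, raw.tolist()))
            for taxon, purpose in ((STANDARD, "loess"), (SMALL, "loess"), (STANDARD, "mean")):
                assert select_scale(ScaleLadder(counts), taxon, purpose) == brute_force_scale(
                    counts, {("loess", False): 75, ("loess", True): 45, ("mean", False): 30, ("mean", True): 30}[(purpose, taxon.small_species)]
                )

    def test_bulk_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 121, size=(2000, 4))
        got = select_scale_bulk(counts, 75)
        for row, g in zip(counts, got):
            expected = brute_force_scale(dict(zip(SCALE_LEVELS, row.tolist())), 75)
            assert (None if g < 0 else SCALE_LEVELS[g]) == expected

    def test_threshold_monotonicity(self):
        """Raising the threshold never selects a finer scale."""
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 121, size=(500, 4))
        lo = select_scale_bulk(counts, 45)
        hi = select_scale_bulk(counts, 75)
        # level index: -1 none < 0 season < ... < 3 basin (finer = larger)
        assert np.all(hi <= lo)

    def test_invalid_ladder_rejected(self):
        with pytest.raises(ValueError):
            ScaleLadder({"season": 10, "year": 20, "region": 5, "basin": 0})
        with pytest.raises(ValueError):
            ScaleLadder({"season": 10})


class TestDetectOutliers:
    def test_zero_residuals_no_flags(self):
        obs = np.full(20, 2.0)
        assert not detect_outliers(obs, obs).any()

    def test_single_gross_outlier_flagged_exactly(self):
        rng = np.random.default_rng(3)
        resid = rng.choice([-0.1, 0.1], size=98)
        resid = np.concatenate([resid, [10.0]])
        observed = np.exp(resid)  # predicted == 1 -> log residual == resid
        flags = detect_outliers(observed, np.ones_like(observed))
        assert flags.sum() == 1 and flags[-1]

    def test_gaussian_flag_share_below_two_percent(self):
        rng = np.random.default_rng(4)
        resid = rng.standard_normal(10_000)
        flags = detect_outliers(np.exp(resid), np.ones(10_000))
        assert flags.mean() < 0.02

    def test_too_few_records_warns_and_flags_nothing(self):
        with pytest.warns(UserWarning):
            flags = detect_outliers(np.array([1.0, 2.0, 3.0]), np.ones(3))
        assert not flags.any()

    def test_printed_outlier_share(self):
        assert outlier_share(560, 58_989) == 0.9


class TestLoessAllometry:
    def test_noiseless_power_law_recovered_within_one_percent(self):
        a, b = 1e-5, 3.0
        lengths = np.linspace(2.0, 40.0, 500)
        afdm = a * lengths**b
        model = LoessAllometry().fit(lengths, afdm)
        inner = np.linspace(5.0, 35.0, 61)
        rel = np.abs(model.predict(inner) / (a * inner**b) - 1.0)
        assert rel.max() < 0.01

    def test_constant_mass_gives_flat_curve(self):
        lengths = np.linspace(1, 30, 100)
        model = LoessAllometry().fit(lengths, np.full(100, 0.25))
        assert model.predict(np.linspace(2, 28, 10)) == pytest.approx(np.full(10, 0.25))

    def test_out_of_domain_clamped_and_flagged(self):
        model = LoessAllometry().fit(np.linspace(10, 20, 80), np.linspace(1, 2, 80))
        pred, flags = model.predict_with_flags([5.0, 15.0, 25.0])
        assert flags.tolist() == [True, False, True]
        assert pred[0] == pytest.approx(model.predict([10.0])[0])
        assert pred[2] == pytest.approx(model.predict([20.0])[0])

    def test_matches_r_loess_reference(self):
        """Cross-check the smoother against R's loess (surface='direct')."""
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(2, 40, 120))
        y = np.log(1e-5 * x**3) + rng.normal(0, 0.15, x.size)
        mine = LoessAllometry(log_mass=False, log_length=False).fit(x, y).predict(
            np.linspace(3, 39, 25)
        )
        fmt = lambda a: ",".join(f"{float(v):.17g}" for v in a)
        rcode = (
            f"x <- c({fmt(x)}); y <- c({fmt(y)}); xs <- c({fmt(np.linspace(3, 39, 25))})\n"
            'fit <- loess(y ~ x, span=0.6, degree=2, surface="direct")\n'
            'cat(paste(predict(fit, xs), collapse=","))'
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        rvals = np.array([float(v) for v in out.stdout.strip().split(",")])
        assert np.abs(mine - rvals).max() < 1e-8

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            LoessAllometry().fit([1, 2, 3, 4, 5], [1, -1, 1, 1, 1])


class TestFitAllometry:
    def test_outlier_removed_and_refit(self):
        rng = np.random.default_rng(6)
        lengths = np.sort(rng.uniform(5, 30, 100))
        afdm = 1e-5 * lengths**3 * np.exp(rng.normal(0, 0.05, 100))
        afdm[50] *= 1e3  # gross data-entry error
        model = fit_allometry(lengths, afdm, STANDARD, "season")
        assert model.n_outliers_removed >= 1
        assert model.n_records == 100 - model.n_outliers_removed
        pred = model.predict([lengths[50]])[0]
        assert pred == pytest.approx(1e-5 * lengths[50] ** 3, rel=0.15)

    def test_below_threshold_raises_scale_error(self):
        with pytest.raises(ScaleError):
            fit_allometry(np.linspace(1, 10, 50), np.linspace(1, 2, 50), STANDARD, "basin")
        # small species: 45 records suffice
        fit_allometry(
            np.linspace(1, 10, 50), np.linspace(0.1, 2, 50), SMALL, "basin"
        )


def _records(n, taxon_id, year, basin, region, rng, with_len=True, with_afdm=True):
    lengths = rng.uniform(5, 30, n)
    afdm = 1e-5 * lengths**3 * np.exp(rng.normal(0, 0.1, n))
    return pd.DataFrame(
        {
            "sibes_id": np.full(n, taxon_id),
            "length_mm": lengths if with_len else np.full(n, np.nan),
            "afdm_g": afdm if with_afdm else np.full(n, np.nan),
            "year": np.full(n, year),
            "region": [region] * n,
            "tidal_basin_name": [basin] * n,
        }
    )


class TestHierarchicalImputer:
    def test_loess_dispatch_with_provenance(self):
        rng = np.random.default_rng(7)
        train = _records(120, 1, 2015, "b1", "west", rng)
        target = _records(1, 1, 2015, "b1", "west", rng, with_afdm=False)
        imp = HierarchicalImputer().fit(train, {1: STANDARD})
        out = imp.transform(target)
        assert out["impute_method_id"].iloc[0] == 24
        assert out["impute_scale"].iloc[0] == "basin"
        assert out["afdm_filled_g"].iloc[0] > 0

    def test_mean_fallback_without_length(self):
        rng = np.random.default_rng(8)
        # 35 records in the target year, but split so no region/basin reaches 30
        same_basin = _records(20, 1, 2015, "b1", "west", rng)
        other_region = _records(15, 1, 2015, "b9", "east", rng)
        other_year = _records(300, 1, 2014, "b2", "east", rng)
        train = pd.concat([same_basin, other_region, other_year], ignore_index=True)
        target = _records(1, 1, 2015, "b1", "west", rng, with_len=False, with_afdm=False)
        imp = HierarchicalImputer().fit(train, {1: STANDARD})
        out = imp.transform(target)
        # 35 >= 30 records in the target's year -> year-level mean, method 12
        assert out["impute_method_id"].iloc[0] == 12
        assert out["impute_scale"].iloc[0] == "year"
        assert out["afdm_filled_g"].iloc[0] == pytest.approx(
            pd.concat([same_basin, other_region])["afdm_g"].mean(), rel=1e-9
        )

    def test_nothing_qualifies_reports_reason(self):
        rng = np.random.default_rng(9)
        train = _records(20, 1, 2015, "b1", "west", rng)
        target = _records(1, 1, 2015, "b1", "west", rng, with_len=False, with_afdm=False)
        imp = HierarchicalImputer().fit(train, {1: STANDARD})
        out = imp.transform(target)
        assert pd.isna(out["afdm_filled_g"].iloc[0])
        assert out["impute_missing_reason"].iloc[0] == "insufficient records"

    def test_historical_method_pools_prior_years(self):
        taxon = Taxon(sibes_id=1, name="Hist", missing_afdm_method_id=25)
        rng = np.random.default_rng(10)
        prior = _records(40, 1, 2013, "b1", "west", rng, with_len=False)
        later = _records(40, 1, 2016, "b1", "west", rng, with_len=False)
        train = pd.concat([prior, later], ignore_index=True)
        target = _records(1, 1, 2015, "b1", "west", rng, with_len=False, with_afdm=False)
        imp = HierarchicalImputer().fit(train, {1: taxon})
        out = imp.transform(target)
        assert out["impute_method_id"].iloc[0] == 25
        # only 2013 (prior to 2015) may contribute
        assert out["afdm_filled_g"].iloc[0] == pytest.approx(prior["afdm_g"].mean(), rel=1e-9)

    def test_measured_afdm_is_never_overwritten(self):
        rng = np.random.default_rng(11)
        train = _records(120, 1, 2015, "b1", "west", rng)
        imp = HierarchicalImputer().fit(train, {1: STANDARD})
        out = imp.transform(train)
        assert np.allclose(out["afdm_filled_g"], train["afdm_g"])
        assert out["impute_method_id"].isna().all()

    def test_impute_afdm_rejects_measured_record(self):
        rng = np.random.default_rng(12)
        imp = HierarchicalImputer().fit(_records(120, 1, 2015, "b1", "west", rng), {1: STANDARD})
        with pytest.raises(ValueError):
            impute_afdm({"afdm_g": 0.5, "length_mm": 10.0, "year": 2015}, STANDARD, imp)

    def test_imputation_never_negative(self, individuals_frame):
        df = individuals_frame.copy()
        rng = np.random.default_rng(13)
        drop = rng.random(len(df)) < 0.2
        df.loc[drop, "afdm_g"] = np.nan
        imp = HierarchicalImputer().fit(
            df, {1: STANDARD, 2: Taxon(sibes_id=2, name="Snail", small_species=True)}
        )
        out = imp.transform(df)
        filled = out["afdm_filled_g"].dropna()
        assert (filled >= 0).all()

    def test_end_to_end_recovery_error_bounded(self, individuals_frame, small_world):
        """Deleting 20% of masses: LOESS-imputed values err < 2x the noise CV."""
        df = individuals_frame.copy()
        rng = np.random.default_rng(14)
        drop = (rng.random(len(df)) < 0.2) & df["afdm_g"].notna() & df["length_mm"].notna()
        truth = df.loc[drop, "afdm_g"].to_numpy()
        df.loc[drop, "afdm_g"] = np.nan
        taxa = {
            sp.sibes_id: Taxon(sp.sibes_id, sp.name, small_species=sp.small_species)
            for sp in small_world.config.species_params
        }
        imp = HierarchicalImputer().fit(df, taxa)
        out = imp.transform(df)
        loess_mask = (out.loc[drop, "impute_method_id"] == 24).to_numpy()
        imputed = out.loc[drop, "afdm_filled_g"].to_numpy()
        rel_err = np.abs(imputed[loess_mask] - truth[loess_mask]) / truth[loess_mask]
        noise_sd = small_world.config.species_params[0].noise_sd
        cv = np.sqrt(np.exp(noise_sd**2) - 1.0)
        assert loess_mask.sum() > 50
        assert rel_err.mean() < 2.0 * cv
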