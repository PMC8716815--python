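"""Sloan neutral model: prediction, fitting, deviation labels, persistence."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from endopersist import fit_ncm, ncm_predicted_freq, persistence_across_seasons
from endopersist.data_model import TaxonStats
from endopersist.neutral_model import NCMFit


def stats_from(p, freq):
    p = np.asarray(p, dtype=float)
    freq = np.asarray(freq, dtype=float)
    ids = [f"t{i}" for i in range(p.size)]
    return TaxonStats(ids, p, freq, n_samples=30)


class TestPredictedFreq:
    def test_matches_quadrature(self):
        """Closed form equals numerical integration of the beta density."""
        for p, nm, d in [(0.01, 200.0, 1e-4), (0.3, 15.0, 0.01), (0.001, 5000.0, 1e-3)]:
            a, b = nm * p, nm * (1 - p)
            num, _ = quad(lambda x: beta_dist.pdf(x, a, b), d, 1.0, limit=200)
            assert ncm_predicted_freq(p, nm, d) == pytest.approx(num, abs=1e-8)

    def test_large_nm_limit(self):
        assert ncm_predicted_freq(0.01, 1e7, 1e-4) > 0.999
        assert ncm_predicted_freq(5e-5, 1e7, 1e-4) < 1e-3

    def test_symmetric_median(self):
        assert ncm_predicted_freq(0.5, 40.0, 0.5) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_p_and_nm(self):
        ps = np.linspace(1e-4, 3e-3, 50)  # below float saturation at 1.0
        vals = ncm_predicted_freq(ps, 300.0, 1e-3)
        assert (np.diff(vals) > 0).all()
        nms = np.logspace(0.5, 5, 30)
        above_d = [ncm_predicted_freq(0.05, nm, 1e-3) for nm in nms]
        assert (np.diff(above_d) > -1e-12).all()

    def test_degenerate_p_rejected(self):
        with pytest.raises(ValueError):
            ncm_predicted_freq(0.0, 100.0, 0.01)
        with pytest.raises(ValueError):
            ncm_predicted_freq(1.0, 100.0, 0.01)


class TestFitNCM:
    def test_noiseless_recovery(self):
        """Data generated exactly on the model curve recover Nm and r2 ~ 1."""
        rng = np.random.default_rng(0)
        p = np.sort(rng.lognormal(-7, 1.5, 200))
        p = p[(p > 0) & (p < 1)]
        truth = 800.0
        freq = ncm_predicted_freq(p, truth, 1e-4)
        fit = fit_ncm(stats_from(p, freq), depth=10000, n_boot=0)
        assert abs(fit.Nm - truth) / truth < 0.01
        assert fit.r2 > 0.999

    def test_forced_high_occupancy_labeled_above(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.lognormal(-7, 1.2, 150))
        freq = np.clip(ncm_predicted_freq(p, 500.0, 1e-4), 0, 1)
        # plant three rare taxa at full occupancy
        freq[:3] = 1.0
        fit = fit_ncm(stats_from(p, freq), depth=10000, n_boot=0)
        assert (fit.per_taxon.iloc[:3]["label"] == "above").all()

    def test_label_partition_consistent_with_bands(self):
        rng = np.random.default_rng(2)
        p = rng.lognormal(-6, 1.5, 100)
        p = np.clip(p, 1e-6, 0.5)
        freq = rng.integers(0, 31, 100) / 30.0
        freq = np.clip(freq, 1 / 30, 1.0)
        fit = fit_ncm(stats_from(p, freq), depth=5000, n_boot=0)
        pt = fit.per_taxon
        assert ((pt["label"] == "above") == (pt["freq"] > pt["ci_upper"])).all()
        assert ((pt["label"] == "below") == (pt["freq"] < pt["ci_lower"])).all()
        assert set(pt["label"]) <= {"above", "below", "neutral"}
        assert (pt["ci_lower"] <= pt["freq_hat"]).all()
        assert (pt["ci_upper"] >= pt["freq_hat"]).all()

    def test_bootstrap_interval_brackets_estimate(self):
        rng = np.random.default_rng(3)
        p = np.clip(rng.lognormal(-7, 1.5, 120), 1e-8, 0.9)
        freq = np.clip(
            ncm_predicted_freq(p, 400.0, 1e-4) + rng.normal(0, 0.03, p.size), 0.01, 1.0
        )
        fit = fit_ncm(stats_from(p, freq), depth=10000, n_boot=100, seed=1)
        assert fit.Nm_ci[0] <= fit.Nm <= fit.Nm_ci[1]

    def test_interval_shrinks_with_taxon_count(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (60, 480):
            p = np.clip(rng.lognormal(-7, 1.5, n), 1e-8, 0.9)
            freq = np.clip(
                ncm_predicted_freq(p, 400.0, 1e-4) + rng.normal(0, 0.05, n), 0.01, 1.0
            )
            fit = fit_ncm(stats_from(p, freq), depth=10000, n_boot=80, seed=2)
            widths.append(fit.Nm_ci[1] - fit.Nm_ci[0])
        assert widths[1] < widths[0]

    def test_too_few_taxa_is_error(self):
        with pytest.raises(ValueError):
            fit_ncm(stats_from([0.5] * 5, [1.0] * 5), depth=100, n_boot=0)


class TestPersistence:
    def _fit_with_labels(self, labels):
        pt = pd.DataFrame(
            {
                "p": 0.01,
                "freq": 0.5,
                "freq_hat": 0.5,
                "ci_lower": 0.2,
                "ci_upper": 0.8,
                "label": list(labels.values()),
            },
            index=pd.Index(list(labels), name="taxon_id"),
        )
        return NCMFit(100.0, 0.9, 1e-4, 5, pt)

    def test_persistent_in_all_seasons(self):
        fits = {
            s: self._fit_with_labels({"x": "above", "y": "neutral"})
            for s in ("spring", "summer", "autumn", "winter")
        }
        records = persistence_across_seasons(fits, min_count=4)
        (rec,) = [r for r in records if r.taxon_id == "x"]
        assert rec.direction == "above" and rec.count == 4 and rec.persistent

    def test_mixed_direction_bookkeeping(self):
        labels = [
            {"x": "above"}, {"x": "above"}, {"x": "below"}, {"x": "neutral"},
        ]
        fits = {
            s: self._fit_with_labels(lab)
            for s, lab in zip(("spring", "summer", "autumn", "winter"), labels)
        }
        records = persistence_across_seasons(fits, min_count=4)
        by_dir = {r.direction: r for r in records}
        assert by_dir["above"].count == 2
        assert by_dir["below"].count == 1
        assert not any(r.persistent for r in records)
        assert by_dir["above"].seasons_deviating == ("spring", "summer")

    def test_missing_taxon_counts_as_non_deviating(self):
        f1 = self._fit_with_labels({"x": "above", "y": "above"})
        f2 = self._fit_with_labels({"x": "above"})
        records = persistence_across_seasons({"spring": f1, "summer": f2}, min_count=2)
        counts = {r.taxon_id: r.count for r in records}
        assert counts == {"x": 2, "y": 1}

    def test_wrong_season_count_is_error(self):
        f = self._fit_with_labels({"x": "above"})
        with pytest.raises(ValueError):
            persistence_across_seasons({"spring": f}, min_count=1)
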