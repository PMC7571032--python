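"""Generator determinism, truncation bounds, and calibrated-fixture structure."""

import numpy as np
import pandas as pd
import pytest

from aarisk import defaults, synthetic
from aarisk.datatypes import ProductModel

from conftest import truncated_normal_moments


def _model(**over):
    base = dict(name="toy", category="bread", conc_mean=57, conc_sd=18,
                conc_min=31, conc_max=90, n_samples=5,
                moisture_range=(41, 43), sugars_range=(1.0, 1.2),
                salt_range=(1.6, 1.8))
    base.update(over)
    return ProductModel(**base)


class TestProductModel:
    @pytest.mark.parametrize("bad", [
        dict(conc_sd=0.0),
        dict(conc_sd=-1.0),
        dict(conc_min=95.0),              # min above max
        dict(n_samples=0),
        dict(moisture_range=(43, 41)),    # bounds out of order
        dict(conc_mean=31.0),             # mean on the bound
    ])
    def test_invalid_models_rejected(self, bad):
        with pytest.raises(ValueError):
            _model(**bad)

    def test_point_mass_requires_matching_mean(self):
        with pytest.raises(ValueError):
            _model(conc_min=100, conc_max=100, conc_mean=57)


class TestGenerateOccurrence:
    def test_values_respect_truncation_and_recipe_bounds(self, study_occurrence, study_config):
        by_name = {m.name: m for m in study_config.products}
        for name, grp in study_occurrence.groupby("product"):
            m = by_name[name]
            assert grp["concentration_ug_kg"].between(m.conc_min, m.conc_max).all()
            assert grp["moisture_pct"].between(*m.moisture_range).all()
            assert grp["sugars_pct"].between(*m.sugars_range).all()
            assert grp["salt_pct"].between(*m.salt_range).all()
            assert len(grp) == m.n_samples

    def test_seed_determinism(self, study_config, study_occurrence):
        again = synthetic.generate_occurrence(synthetic.default_config(seed=study_config.seed))
        pd.testing.assert_frame_equal(study_occurrence, again)

    def test_different_seeds_differ(self, study_occurrence):
        other = synthetic.generate_occurrence(synthetic.default_config(seed=21))
        assert not study_occurrence["concentration_ug_kg"].equals(other["concentration_ug_kg"])

    def test_appending_product_leaves_earlier_draws_unchanged(self, study_config, study_occurrence):
        extended = synthetic.GeneratorConfig(
            seed=study_config.seed,
            products=study_config.products + [_model(name="extra")],
        )
        out = synthetic.generate_occurrence(extended)
        head = out[out["product"] != "extra"].reset_index(drop=True)
        pd.testing.assert_frame_equal(head, study_occurrence)

    def test_point_mass_model_yields_exact_value(self):
        cfg = synthetic.GeneratorConfig(
            seed=0, products=[_model(conc_min=100, conc_max=100, conc_mean=100, n_samples=1)])
        out = synthetic.generate_occurrence(cfg)
        assert len(out) == 1
        assert out.loc[0, "concentration_ug_kg"] == 100.0

    def test_empty_product_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            synthetic.GeneratorConfig(seed=0, products=[])

    def test_sample_mean_matches_quadrature_oracle(self):
        """Rejection sampler recovers the truncated-normal mean (n=5000)."""
        cfg = synthetic.GeneratorConfig(seed=5, products=[_model(n_samples=5000)])
        out = synthetic.generate_occurrence(cfg)
        mu, _ = truncated_normal_moments(57, 18, 31, 90)
        assert abs(out["concentration_ug_kg"].mean() - mu) < 1.0

    def test_hopeless_truncation_interval_rejected(self, rng):
        with pytest.raises(ValueError, match="mass"):
            synthetic.truncated_normal(rng, mean=0, sd=1, lo=50, hi=51, size=3)


class TestGenerateConsumption:
    def test_calibrated_targets_emitted_exactly(self, study_consumption):
        medians = {r.product: r.median for r in defaults.reference_summaries()}
        for _, row in study_consumption.iterrows():
            bs_med = defaults.PUBLISHED_INTAKE[(row["product"], row["age_group"])]["median"][0]
            bw = defaults.BODY_WEIGHTS[row["age_group"]]
            assert row["q_median_g_day"] == pytest.approx(bs_med * bw / medians[row["product"]])
            assert row["bw_kg"] == bw

    def test_p95_consumer_at_least_median(self, study_consumption):
        assert (study_consumption["q_p95_g_day"] >= study_consumption["q_median_g_day"]).all()

    def test_determinism(self, study_config, study_consumption):
        again = synthetic.generate_consumption(synthetic.default_config(seed=study_config.seed))
        pd.testing.assert_frame_equal(study_consumption, again)

    def test_random_consumption_is_seeded_and_ordered(self):
        cfg = synthetic.GeneratorConfig(seed=3, products=[_model()])
        a = synthetic.generate_consumption(cfg)
        b = synthetic.generate_consumption(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a["q_p95_g_day"] >= a["q_median_g_day"]).all()

    def test_missing_age_group_weight_rejected(self):
        with pytest.raises(ValueError, match="body weight"):
            synthetic.GeneratorConfig(seed=0, products=[_model()],
                                      age_groups=("adolescents", "centenarians"))

    def test_missing_consumption_target_rejected(self):
        cfg = synthetic.GeneratorConfig(seed=0, products=[_model()],
                                        consumption_targets={("toy", "adolescents"): (80, 160)})
        with pytest.raises(ValueError, match="target"):
            synthetic.generate_consumption(cfg)
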