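"""Vital-rate fitting, AICc and the selection rule."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from coverdyn.params import (COLONISATION_TERMS, GROWTH_TERMS,
                             VitalRateParams)
from coverdyn.vitalrates import (CandidateModel, SelectionError, aicc,
                                 enumerate_candidates, fit_colonisation,
                                 fit_expansion, fit_persistence,
                                 params_from_frame, params_from_models,
                                 params_to_frame, select_model)


def frame(**cols):
    return pd.DataFrame(cols)


class TestAicc:
    @pytest.mark.parametrize("ll,k,n", [(-50.0, 3, 40), (-10.5, 1, 10),
                                        (-123.4, 12, 250)])
    def test_matches_hand_formula(self, ll, k, n):
        expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(ll, k, n) == pytest.approx(expected, rel=1e-12)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 5, 6)


class TestEnumerate:
    def test_cardinalities(self):
        assert len(enumerate_candidates("persistence")) == 32
        assert len(enumerate_candidates("expansion")) == 32
        assert len(enumerate_candidates("colonisation")) == 8

    def test_power_set_structure(self):
        subsets = enumerate_candidates("persistence")
        assert len(set(subsets)) == 32
        assert subsets[0] == ()
        assert subsets[-1] == ("x", "x2", "ug", "ul", "uf")

    def test_unknown_role(self):
        with pytest.raises(ValueError):
            enumerate_candidates("germination")


class TestFitPersistence:
    def test_intercept_only_is_logit_of_proportion(self, rng):
        df = frame(persisted=np.r_[np.ones(75), np.zeros(25)],
                   x=np.zeros(100), ug=np.zeros(100), ul=np.zeros(100),
                   uf=np.zeros(100))
        cand = fit_persistence(df, terms=())
        assert cand.params["1"] == pytest.approx(logit(0.75), abs=1e-6)
        assert cand.k == 1

    def test_all_persisted_flags_separation(self):
        df = frame(persisted=np.ones(30), x=np.zeros(30), ug=np.zeros(30),
                   ul=np.zeros(30), uf=np.zeros(30))
        cand = fit_persistence(df, terms=())
        assert cand.flagged
        assert not cand.usable

    def test_recovers_known_slope(self, rng):
        n = 2000
        x = rng.uniform(0, 4, n)
        p = expit(0.5 + 0.6 * x)
        df = frame(persisted=(rng.random(n) < p).astype(float), x=x,
                   ug=np.zeros(n), ul=np.zeros(n), uf=np.zeros(n))
        cand = fit_persistence(df, terms=("x",))
        assert abs(cand.params["x"] - 0.6) <= 3 * cand.se["x"]


class TestFitExpansion:
    def test_intercepts_only_reduce_to_gaussian_mle(self, rng):
        y = rng.normal(1.5, 0.4, 200)
        df = frame(x=np.zeros(200), y=y, ug=np.zeros(200),
                   ul=np.zeros(200), uf=np.zeros(200))
        cand = fit_expansion(df, terms=())
        assert cand.params["1"] == pytest.approx(y.mean(), abs=1e-4)
        assert cand.sd_params["1"] == pytest.approx(y.std(), abs=1e-3)
        assert cand.k == 2

    def test_recovers_known_line(self, rng):
        n = 500
        x = rng.uniform(0, 4, n)
        y = 0.5 + 0.8 * x + rng.normal(0, 0.3, n)
        df = frame(x=x, y=y, ug=np.zeros(n), ul=np.zeros(n), uf=np.zeros(n))
        cand = fit_expansion(df, terms=("x",))
        assert abs(cand.params["1"] - 0.5) <= 3 * cand.se["1"]
        assert abs(cand.params["x"] - 0.8) <= 3 * cand.se["x"]
        assert abs(cand.sd_params["1"] - 0.3) <= 3 * cand.sd_se["1"]

    def test_nested_models_never_beat_full_loglik(self, rng):
        n = 300
        x = rng.uniform(0, 4, n)
        ug = rng.normal(3, 0.5, n)
        y = 0.4 + 0.7 * x - 0.1 * ug + rng.normal(0, 0.35, n)
        df = frame(x=x, y=y, ug=ug, ul=np.zeros(n), uf=np.zeros(n))
        full = fit_expansion(df, terms=("x", "ug"))
        for terms in [(), ("x",), ("ug",)]:
            nested = fit_expansion(df, terms=terms)
            assert nested.loglik <= full.loglik + 1e-6

    def test_too_few_rows_flagged(self, rng):
        df = frame(x=np.arange(5.0), y=np.arange(5.0), ug=np.zeros(5),
                   ul=np.zeros(5), uf=np.zeros(5))
        cand = fit_expansion(df)  # full model k=12 > n
        assert cand.flagged and not cand.usable


class TestFitColonisation:
    def test_intercept_only_sample_stats(self, rng):
        y = rng.normal(0.8, 0.5, 150)
        df = frame(y=y, ug=np.zeros(150), ul=np.zeros(150),
                   uf=np.zeros(150))
        cand = fit_colonisation(df, terms=())
        assert cand.params["1"] == pytest.approx(y.mean(), abs=1e-4)
        assert cand.sd_params["1"] == pytest.approx(y.std(), abs=1e-3)

    def test_no_events_raises(self):
        df = frame(y=np.array([]), ug=np.array([]), ul=np.array([]),
                   uf=np.array([]))
        with pytest.raises(ValueError, match="no colonisation"):
            fit_colonisation(df)

    def test_recovers_abundance_effect(self, rng):
        n = 800
        ug = rng.normal(3.0, 0.8, n)
        y = 1.2 - 0.3 * ug + rng.normal(0, 0.4, n)
        df = frame(y=y, ug=ug, ul=np.zeros(n), uf=np.zeros(n))
        cand = fit_colonisation(df, terms=("ug",))
        assert abs(cand.params["ug"] + 0.3) <= 3 * cand.se["ug"]


def _cand(aicc_val, k=3, plaus=True, terms=("x",), role="persistence"):
    c = CandidateModel(role=role, terms=terms, k=k, n=100, aicc=aicc_val,
                       converged=True)
    c._plaus = plaus
    return c


class TestSelectModel:
    def test_lowest_aicc_wins_when_all_plausible(self):
        cands = [_cand(100.0), _cand(101.5, terms=("x2",)),
                 _cand(103.0, terms=("ug",))]
        sel = select_model(cands, lambda c: True)
        assert sel.aicc == 100.0

    def test_implausible_best_passes_to_runner_up(self):
        cands = [_cand(100.0, plaus=False), _cand(101.5, terms=("x2",))]
        sel = select_model(cands, lambda c: c._plaus)
        assert sel.aicc == 101.5

    def test_aicc_tie_broken_by_fewer_parameters(self):
        cands = [_cand(100.0, k=4, terms=("x", "x2")),
                 _cand(100.0, k=2, terms=("ug",))]
        sel = select_model(cands, lambda c: True)
        assert sel.k == 2

    def test_widening_beyond_window_when_needed(self):
        cands = [_cand(100.0, plaus=False), _cand(104.0, terms=("ug",))]
        sel = select_model(cands, lambda c: c._plaus)
        assert sel.aicc == 104.0

    def test_no_plausible_model_raises(self):
        cands = [_cand(100.0, plaus=False)]
        with pytest.raises(SelectionError):
            select_model(cands, lambda c: c._plaus)

    def test_no_usable_candidate_raises(self):
        c = _cand(100.0)
        c.converged = False
        with pytest.raises(SelectionError):
            select_model([c], lambda _: True)

    def test_without_oracle_returns_window_head(self):
        cands = [_cand(101.0), _cand(100.5, terms=("x2",))]
        assert select_model(cands).aicc == 100.5


class TestParamsAssembly:
    def test_excluded_terms_are_zero_and_predictions_match(self, rng):
        n = 400
        x = rng.uniform(0, 4, n)
        y = 0.5 + 0.7 * x + rng.normal(0, 0.3, n)
        df = frame(x=x, y=y, ug=rng.normal(3, 0.5, n), ul=np.zeros(n),
                   uf=np.zeros(n))
        pers = fit_persistence(frame(
            persisted=(rng.random(n) < 0.7).astype(float), x=x,
            ug=df["ug"], ul=df["ul"], uf=df["uf"]), terms=("x",))
        expa = fit_expansion(df, terms=("x",))
        colo = fit_colonisation(frame(y=y[:50], ug=df["ug"][:50],
                                      ul=np.zeros(50), uf=np.zeros(50)),
                                terms=())
        p = params_from_models(pers, expa, colo, col_rate=0.4)
        # excluded terms carry exact zeros
        assert p.expansion_mean[GROWTH_TERMS.index("ug")] == 0.0
        assert p.colonisation_mean[COLONISATION_TERMS.index("uf")] == 0.0
        # the assembled params reproduce the restricted model's predictions
        u = (3.0, 1.0, 2.0)
        xs = np.array([0.5, 2.0])
        manual = expa.params["1"] + expa.params["x"] * xs
        assert np.allclose(p.growth_mean(xs, u), manual)
        manual_s = expit(pers.params["1"] + pers.params["x"] * xs)
        assert np.allclose(p.survival(xs, u), manual_s)

    def test_frame_round_trip(self, default_params):
        df = params_to_frame(default_params)
        back = params_from_frame(df)
        for key, p in default_params.items():
            q = back[key]
            assert np.allclose(p.persistence, q.persistence)
            assert np.allclose(p.expansion_sd, q.expansion_sd)
            assert np.allclose(p.colonisation_mean, q.colonisation_mean)
            assert p.col_rate == pytest.approx(q.col_rate)
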