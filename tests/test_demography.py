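import numpy as np
import pytest

from paleoabc.demography import (FNE_SCALE, Prior, build_history,
                                 build_mutation_model, default_model,
                                 sample_prior, sample_prior_batch)
from paleoabc.serialcoal import DemographicHistory


def test_default_model_structure():
    closed = default_model("closed_bottleneck")
    assert (closed.priors["N_modern"].a, closed.priors["N_modern"].b) == (1, 50_000)
    assert (closed.priors["fNe_after"].a, closed.priors["fNe_after"].b) == (1, 5_000)
    assert (closed.priors["fNe_before"].b) == 200_000
    open_m = default_model("open_migration")
    assert (open_m.priors["T_s"].a, open_m.priors["T_s"].b) == (11_000, 15_000)
    assert open_m.n_demes == 4
    const = default_model("constant")
    assert set(const.priors) == {"N", "mu"}  # no event parameters
    with pytest.raises(KeyError):
        default_model("nope")


def test_uniform_prior_moments():
    spec = default_model("closed_bottleneck")
    draws = sample_prior_batch(spec, 100_000, seed=7)["N_modern"]
    assert draws.min() >= 1 and draws.max() <= 50_000
    assert draws.mean() == pytest.approx(25_000, abs=3 * 50_000 / np.sqrt(12e5))


def test_ratio_of_uniforms_support():
    prior = Prior("k", "ratio_uniform", 1, 200_000, 1, 5_000)
    rng = np.random.default_rng(3)
    draws = prior.sample(rng, 100_000)
    assert draws.min() > 1 / 5_000
    assert draws.max() <= 200_000
    assert prior.support == (1 / 5_000, 200_000)


def test_same_seed_same_draw():
    spec = default_model("open_migration")
    assert sample_prior(spec, 42).values == sample_prior(spec, 42).values
    assert sample_prior(spec, 42).values != sample_prior(spec, 43).values


def test_constant_history_has_no_events():
    spec = default_model("constant")
    hist = build_history(spec, sample_prior(spec, 0))
    assert hist.events == [] and hist.n_demes == 1


def test_closed_history_piecewise_sizes():
    from paleoabc.demography import ParameterDraw

    # N_modern == fNe_after means zero growth; severity 3x above the event
    draw = ParameterDraw("closed_bottleneck", dict(
        N_modern=10_000.0, T_b=5_000.0, fNe_after=10_000.0,
        fNe_before=30_000.0, mu=0.08))
    hist = build_history(default_model("closed_bottleneck"), draw)
    assert hist.growth[0] == pytest.approx(0.0)
    assert hist.size_at(4_999.0) == pytest.approx(FNE_SCALE * 10_000)
    assert hist.size_at(5_001.0) == pytest.approx(FNE_SCALE * 30_000)
    assert hist.size_at(40_000.0) == pytest.approx(FNE_SCALE * 30_000)


def test_closed_history_growth_continuity():
    from paleoabc.demography import ParameterDraw

    draw = ParameterDraw("closed_bottleneck", dict(
        N_modern=11_000.0, T_b=14_000.0, fNe_after=3_700.0,
        fNe_before=28_000.0, mu=0.08))
    hist = build_history(default_model("closed_bottleneck"), draw)
    # size just below the event equals fNe_after; just above, fNe_before
    assert hist.size_at(14_000.0 - 1e-6) == pytest.approx(FNE_SCALE * 3_700, rel=1e-4)
    assert hist.size_at(14_000.0 + 1e-6) == pytest.approx(FNE_SCALE * 28_000, rel=1e-4)


def test_open_history_migration_window():
    spec = default_model("open_migration")
    draw = sample_prior(spec, 5)
    hist = build_history(spec, draw)
    start, stop = hist.migration_window
    assert start == pytest.approx(draw["T_stop"])
    assert stop == pytest.approx(draw["T_s"])
    assert hist.migration[0, 1] == pytest.approx(draw["m_high"])
    assert hist.migration[1, 2] == pytest.approx(draw["m_low"])
    # three join events move every other deme into the focal deme
    assert sorted(e.move[0] for e in hist.events) == [1, 2, 3]
    assert all(e.move[1] == 0 and e.move[2] == 1.0 for e in hist.events)


@pytest.mark.parametrize("model_id", ["constant", "closed_bottleneck",
                                      "open_migration"])
def test_history_always_valid_over_prior(model_id):
    spec = default_model(model_id)
    for seed in range(300):
        draw = sample_prior(spec, seed)
        hist = build_history(spec, draw)
        assert isinstance(hist, DemographicHistory)
        assert all(s > 0 and np.isfinite(s) for s in hist.sizes)
        assert all(np.isfinite(g) for g in hist.growth)
        assert (hist.migration >= 0).all()
        mm = build_mutation_model(spec, draw)
        assert 0.01 <= mm.mu_site_myr <= 0.2
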