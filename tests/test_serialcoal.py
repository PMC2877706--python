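import numpy as np
import pytest

from paleoabc.seqdata import SamplingDesign
from paleoabc.serialcoal import (DemographicEvent, DemographicHistory,
                                 MutationModel, NonCoalescingError,
                                 apply_mutations, dataset_seeds,
                                 mu_per_site_per_generation,
                                 simulate_dataset, simulate_genealogy)
from paleoabc.sumstats import layer_summary


def design_one_layer(n, L=100):
    return SamplingDesign(layers=[(0.0, n)], total_length=L,
                          loci=[("all", 0, L)])


def serial_design():
    return SamplingDesign(layers=[(0.0, 5), (800.0, 5)], total_length=60,
                          loci=[("all", 0, 60)])


def test_single_lineage_is_a_tip():
    hist = DemographicHistory(sizes=[500.0])
    tree = simulate_genealogy(hist, design_one_layer(1), seed=0)
    assert tree.n_tips == 1
    assert tree.tmrca == 0.0


def test_rate_conversion():
    # 1 mutation/site/myr at a one-year generation time
    assert mu_per_site_per_generation(1.0) == pytest.approx(1e-6)
    assert mu_per_site_per_generation(0.08) == pytest.approx(8e-8)


def test_simulate_dataset_deterministic():
    hist = DemographicHistory(sizes=[2000.0])
    mm = MutationModel(mu_site_myr=0.1, alpha=1.0)
    d = serial_design()
    a1 = simulate_dataset(hist, mm, d, seed=7)
    a2 = simulate_dataset(hist, mm, d, seed=7)
    a3 = simulate_dataset(hist, mm, d, seed=8)
    assert a1.sequences == a2.sequences
    assert a1.sequences != a3.sequences
    assert a1.n == 10 and a1.length == 60


def test_zero_mutation_rate_identical_sequences():
    hist = DemographicHistory(sizes=[1000.0])
    mm = MutationModel(mu_site_myr=0.0)
    aln = simulate_dataset(hist, mm, design_one_layer(8), seed=3)
    assert len(set(aln.sequences)) == 1


def test_huge_alpha_behaves_like_homogeneous_rates():
    hist = DemographicHistory(sizes=[1000.0])
    aln = simulate_dataset(hist, MutationModel(mu_site_myr=0.2, alpha=1e9),
                           design_one_layer(6), seed=5)
    assert aln.n == 6  # smoke: the mean-1 gamma limit must not over/underflow


def test_apply_mutations_layer_metadata():
    hist = DemographicHistory(sizes=[1000.0])
    d = serial_design()
    tree = simulate_genealogy(hist, d, seed=11)
    aln = apply_mutations(tree, MutationModel(mu_site_myr=0.1), d, seed=12)
    assert aln.ages == [0.0] * 5 + [800.0] * 5
    assert len(aln.layers()) == 2


def test_dataset_feeds_sumstats():
    hist = DemographicHistory(sizes=[3000.0],
                              events=[DemographicEvent(time=900.0, deme=0,
                                                       size_scale=5.0)])
    aln = simulate_dataset(hist, MutationModel(mu_site_myr=0.1),
                           serial_design(), seed=2)
    vec = layer_summary(aln, "estimation12")
    assert len(vec) == 6  # 2 layers x 3 stats
    assert (vec.values >= 0).all()


def test_batch_path_matches_object_path():
    """A reference-table row equals simulate_dataset for the same seed pair."""
    from paleoabc import _kernels

    d = serial_design()
    hist = DemographicHistory(sizes=[1500.0])
    mm = MutationModel(mu_site_myr=0.15, alpha=2.0, kappa=10.0)
    seed = 99
    aln = simulate_dataset(hist, mm, d, seed=seed)
    vec = layer_summary(aln, "estimation12")

    gseed, mseed = dataset_seeds(seed)
    times = np.array([0.0] * 5 + [800.0] * 5)
    demes = np.zeros(10, dtype=np.int64)
    layer_ix = np.array([1] * 5 + [0] * 5)  # oldest first
    S, PD = _kernels.simulate_stats_batch(
        np.array([gseed]), np.array([mseed]),
        times, demes, layer_ix, 2,
        np.array([[1500.0]]), np.zeros((1, 1)),
        np.zeros((1, 0)), np.zeros(0, dtype=np.int64), np.zeros((1, 0)),
        np.zeros((1, 0)), np.zeros(0, dtype=np.int64),
        np.zeros(0, dtype=np.int64), np.zeros((1, 0)),
        np.zeros((1, 1, 1)), np.zeros(1), np.zeros(1),
        np.array([60], dtype=np.int64),
        np.full((1, 1), mu_per_site_per_generation(0.15)),
        np.array([2.0]), 10.0, 1e7)
    S_layers = S[0].sum(axis=0)
    PD_layers = PD[0].sum(axis=0)
    expect = vec.values.reshape(2, 3)  # (layer, [S, Pi, pi]) oldest first
    assert np.allclose(S_layers, expect[:, 0])
    assert np.allclose(PD_layers, expect[:, 1])


def test_isolated_demes_raise_non_coalescing():
    hist = DemographicHistory(sizes=[100.0, 100.0])
    # two lineages in each of two demes that never exchange migrants
    d = SamplingDesign(layers=[(0.0, 2), (10.0, 2)], total_length=10,
                       loci=[("all", 0, 10)])
    with pytest.raises(NonCoalescingError):
        simulate_genealogy(hist, d, deme_of_layers={0: 0, 1: 1}, seed=1,
                           t_max=1e5)


def test_exchangeability_within_layer():
    """Permuting tips within a layer leaves summary distributions unchanged."""
    hist = DemographicHistory(sizes=[1000.0])
    d = serial_design()
    pis = []
    for seed in range(40):
        aln = simulate_dataset(hist, MutationModel(mu_site_myr=0.1), d, seed=seed)
        rng = np.random.default_rng(seed)
        idx = np.concatenate([rng.permutation(5), 5 + rng.permutation(5)])
        from paleoabc.seqdata import SerialAlignment

        shuffled = SerialAlignment(
            sequences=[aln.sequences[i] for i in idx],
            ages=[aln.ages[i] for i in idx],
            layer_labels=[aln.layer_labels[i] for i in idx],
            loci=list(aln.loci))
        assert layer_summary(shuffled, "estimation12").values == pytest.approx(
            layer_summary(aln, "estimation12").values)
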