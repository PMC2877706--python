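import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleoabc.sumstats import (haplotype_diversity, layer_summary,
                               mean_pairwise_diff, nucleotide_diversity,
                               segregating_sites)

from conftest import make_alignment, random_alignment

UNAMB = set("ACGT")


def brute_force_pairwise(seqs):
    """Independent double-loop oracle for the mean pairwise difference."""
    n = len(seqs)
    total = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(1 for x, y in zip(a, b)
                     if x in UNAMB and y in UNAMB and x != y)
    return total / (n * (n - 1) / 2)


@pytest.mark.parametrize("seqs,expected", [
    (["AAA", "AAA"], 0),
    (["AAA", "AAT", "GAA"], 2),
    (["ACGT", "ACGN"], 0),          # N excluded by pairwise deletion
])
def test_segregating_sites(seqs, expected):
    assert segregating_sites(make_alignment({("m", 0.0): seqs})) == expected


def test_pairwise_diff_brute_force(rng):
    for _ in range(20):
        aln = random_alignment(rng, 4, 8)
        assert mean_pairwise_diff(aln) == pytest.approx(
            brute_force_pairwise(aln.sequences))


def test_pairwise_deletion_with_ambiguity():
    aln = make_alignment({("m", 0.0): ["ANGT", "ACGA"]})
    # site 1 excluded (N); only site 3 differs
    assert mean_pairwise_diff(aln) == 1.0


def test_identical_sequences_zero():
    aln = make_alignment({("m", 0.0): ["ACGT"] * 5})
    assert mean_pairwise_diff(aln) == 0.0
    assert nucleotide_diversity(aln) == 0.0


def test_pairwise_requires_two():
    with pytest.raises(ValueError):
        mean_pairwise_diff(make_alignment({("m", 0.0): ["ACGT"]}))


def test_haplotype_diversity_values():
    assert haplotype_diversity([7, 3]) == pytest.approx(10 / 9 * (1 - 0.49 - 0.09))
    assert haplotype_diversity([6, 3, 1]) == pytest.approx(0.600, abs=5e-4)
    assert haplotype_diversity([10]) == 0.0
    with pytest.raises(ValueError):
        haplotype_diversity([1])


def test_pi_times_length_equals_pairwise(rng):
    for _ in range(10):
        aln = random_alignment(rng, 5, 11)
        assert nucleotide_diversity(aln) * aln.length == pytest.approx(
            mean_pairwise_diff(aln))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_pairwise_invariant_under_reordering(seed):
    r = np.random.default_rng(seed)
    aln = random_alignment(r, 6, 10)
    perm = r.permutation(6)
    shuffled = make_alignment({("m", 0.0): [aln.sequences[i] for i in perm]})
    base = make_alignment({("m", 0.0): aln.sequences})
    assert mean_pairwise_diff(shuffled) == pytest.approx(mean_pairwise_diff(base))
    assert segregating_sites(shuffled) == segregating_sites(base)


def test_layer_summary_composition(rng):
    aln = random_alignment(rng, 24, 30, n_layers=4)
    vec = layer_summary(aln, "estimation12")
    assert len(vec) == 12
    # element-wise agreement with the scalar operations per layer
    i = 0
    for lab in aln.layers():
        sub = aln.layer_slice(lab)
        expect = {"S": float(segregating_sites(sub)),
                  "Pi": mean_pairwise_diff(sub),
                  "pi": mean_pairwise_diff(sub) / sub.length}
        for st_name in ("S", "Pi", "pi"):
            layer, name, value = vec.entries[i]
            assert (layer, name) == (lab, st_name)
            assert value == pytest.approx(expect[st_name])
            i += 1


def test_layer_summary_monomorphic_all_zero():
    aln = make_alignment({("old", 100.0): ["ACGT"] * 3,
                          ("m", 0.0): ["ACGT"] * 3})
    assert np.allclose(layer_summary(aln, "estimation12").values, 0.0)


def test_layer_summary_comparison_set_shape(rng):
    aln = random_alignment(rng, 16, 12, n_layers=4)
    assert len(layer_summary(aln, "comparison8")) == 8
    with pytest.raises(KeyError):
        layer_summary(aln, "nope")


def test_single_sequence_layer_warns_and_zeroes():
    aln = make_alignment({("old", 100.0): ["ACGT"],
                          ("m", 0.0): ["ACGT", "ACGA"]})
    with pytest.warns(UserWarning, match="n < 2"):
        vec = layer_summary(aln, "estimation12")
    old = {name: v for lab, name, v in vec.entries if lab == "old"}
    assert old["Pi"] == 0.0 and old["pi"] == 0.0
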