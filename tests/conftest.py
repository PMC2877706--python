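import numpy as np
import pytest

from paleoabc.seqdata import SerialAlignment


def make_alignment(seqs_by_layer: dict, loci=None) -> SerialAlignment:
    """Build a SerialAlignment from {(label, age): [sequences]}."""
    seqs, ages, labels = [], [], []
    for (label, age), ss in seqs_by_layer.items():
        seqs.extend(ss)
        ages.extend([age] * len(ss))
        labels.extend([label] * len(ss))
    return SerialAlignment(sequences=seqs, ages=ages, layer_labels=labels,
                           loci=loci or [])


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     n_layers: int = 1) -> SerialAlignment:
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, L)]) for _ in range(n)]
    layer = rng.integers(0, n_layers, n)
    return SerialAlignment(sequences=seqs,
                           ages=[float(1000 * l) for l in layer],
                           layer_labels=[f"L{l}" for l in layer])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def temporal_haplotype_fixture():
    """Four layers whose distinct-haplotype counts run 10/7/7/3 oldest->modern.

    Haplotypes are one-step variants of a shared backbone, with the two
    major haplotypes present in every layer (mirroring the structure of
    the serially sampled series the package targets).
    """
    L = 20
    base = "A" * L

    def hap(i):
        if i == 0:
            return base
        return base[:i] + "G" + base[i + 1:]

    def layer(hap_counts):
        out = []
        for h, c in hap_counts:
            out.extend([hap(h)] * c)
        return out

    return {
        ("25200", 25200.0): layer([(0, 3), (1, 3), (2, 1), (3, 1), (4, 1),
                                   (5, 1), (6, 1), (7, 1), (8, 1), (9, 1)]),
        ("15200", 15200.0): layer([(0, 7), (1, 5), (2, 2), (3, 2), (4, 2),
                                   (5, 1), (6, 1)]),
        ("11500", 11500.0): layer([(0, 8), (1, 6), (2, 2), (3, 1), (4, 1),
                                   (5, 1), (10, 1)]),
        ("modern", 0.0): layer([(0, 5), (1, 3), (2, 2)]),
    }
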