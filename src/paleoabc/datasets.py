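"""Bundled observed data: the Pymva Shor collared-lemming mtDNA series.

The package's headline reanalysis runs from the published per-layer
summary statistics of the serially sampled collared-lemming
(*Dicrostonyx torquatus*) alignment from Pymva Shor (northern Pre-Urals):
282 bp of cytochrome b plus 426 bp of control region (708 bp combined)
sampled at four time points — modern (n=10) and 11,500 / 15,200 / 25,200
calibrated years BP (n=20/20/14).  With a one-year generation time the
layer ages double as generations BP.

Statistics per layer: segregating sites S, number of haplotypes K, mean
pairwise difference Pi, nucleotide diversity pi, haplotype diversity H.
"""

from __future__ import annotations

import pandas as pd

from .seqdata import SamplingDesign, SerialAlignment
from .sumstats import SummaryVector, summary_vector_from_stats

__all__ = [
    "pymva_shor_design",
    "pymva_shor_table",
    "pymva_shor_observed",
    "two_haplotype_alignment",
    "LOCI",
]

#: locus partition of the combined alignment (0-based half-open)
LOCI = [("CytB", 0, 282), ("CR", 282, 708)]

#: (age in generations BP, sample size), modern first
LAYERS = [(0, 10), (11_500, 20), (15_200, 20), (25_200, 14)]

# printed per-layer statistics; rows oldest -> youngest within each block
_TABLE_ROWS = [
    # locus, layer, age, S, K, Pi, pi, H
    ("CytB", "25200", 25_200, 12, 7, 3.736, 0.01325, 0.901),
    ("CytB", "15200", 15_200, 8, 6, 1.868, 0.00663, 0.737),
    ("CytB", "11500", 11_500, 6, 6, 0.689, 0.00244, 0.516),
    ("CytB", "modern", 0, 1, 2, 0.467, 0.00165, 0.467),
    ("CR", "25200", 25_200, 6, 8, 2.451, 0.00575, 0.824),
    ("CR", "15200", 15_200, 5, 4, 0.679, 0.00159, 0.437),
    ("CR", "11500", 11_500, 1, 2, 0.100, 0.00023, 0.100),
    ("CR", "modern", 0, 1, 2, 0.200, 0.00047, 0.200),
    ("combined", "25200", 25_200, 18, 10, 6.187, 0.00874, 0.945),
    ("combined", "15200", 15_200, 13, 7, 2.547, 0.00360, 0.774),
    ("combined", "11500", 11_500, 7, 7, 0.789, 0.00112, 0.584),
    ("combined", "modern", 0, 2, 3, 0.667, 0.00094, 0.600),
]

_LOCUS_LENGTH = {"CytB": 282, "CR": 426, "combined": 708}


def pymva_shor_design() -> SamplingDesign:
    """The four-layer, 64-sequence, two-locus sampling design."""
    return SamplingDesign(layers=list(LAYERS), total_length=708,
                          loci=list(LOCI))


def pymva_shor_table(locus: str = "combined") -> pd.DataFrame:
    """Published per-layer diversity statistics for one locus block."""
    if locus not in _LOCUS_LENGTH:
        raise KeyError(f"unknown locus {locus!r}; known: {sorted(_LOCUS_LENGTH)}")
    df = pd.DataFrame([r for r in _TABLE_ROWS if r[0] == locus],
                      columns=["locus", "layer", "age", "S", "K", "Pi", "pi", "H"])
    return df.drop(columns="locus").set_index("layer")


def pymva_shor_observed(stat_set: str = "estimation12",
                        locus: str = "combined") -> SummaryVector:
    """The observed summary vector (layers oldest to youngest).

    ``locus`` may be one block (``"combined"``, ``"CytB"``, ``"CR"``) or
    ``"per_locus"``, which interleaves the CytB and CR statistics within
    each layer (matching per-locus reference tables).  Nucleotide
    diversity is recomputed as Pi/L from the printed mean pairwise
    difference so observed and simulated vectors share the exact same
    definition (the printed pi values are rounded to 5 decimals).
    """
    from .sumstats import STAT_SETS

    if locus != "per_locus":
        df = pymva_shor_table(locus)
        return summary_vector_from_stats(
            S=df["S"].to_numpy(), Pi=df["Pi"].to_numpy(),
            L=_LOCUS_LENGTH[locus], layer_labels=list(df.index),
            stat_set=stat_set)
    stats = STAT_SETS[stat_set]
    blocks = {name: pymva_shor_table(name) for name in ("CytB", "CR")}
    entries = []
    for layer in blocks["CytB"].index:
        for name in ("CytB", "CR"):
            row = blocks[name].loc[layer]
            vals = {"S": float(row["S"]), "Pi": float(row["Pi"]),
                    "pi": float(row["Pi"]) / _LOCUS_LENGTH[name]}
            for st in stats:
                entries.append((layer, f"{st}_{name}", vals[st]))
    return SummaryVector(entries=entries, stat_set=stat_set)


def two_haplotype_alignment(n: int = 10, counts: tuple[int, int] = (7, 3),
                            L: int = 282) -> SerialAlignment:
    """A one-layer alignment with two haplotypes differing at one site.

    The default reproduces the modern cytochrome-b configuration: 10
    sequences, one segregating site, haplotype counts 7 and 3 (mean
    pairwise difference 42/90 = 0.467, haplotype diversity 0.467).
    """
    if sum(counts) != n:
        raise ValueError("counts must sum to n")
    base = "A" * L
    variant = "G" + "A" * (L - 1)
    seqs = [base] * counts[0] + [variant] * counts[1]
    return SerialAlignment(sequences=seqs, ages=[0.0] * n,
                           layer_labels=["modern"] * n,
                           loci=[("CytB", 0, L)])
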