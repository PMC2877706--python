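"""Per-layer diversity statistics and summary-statistic vectors.

Implements the classic mitochondrial diversity measures — segregating
sites S, mean pairwise difference Pi, per-site nucleotide diversity
pi = Pi/L and haplotype diversity H — computed per temporal layer, plus
the fixed-order concatenation used as the ABC summary vector.

Ambiguous bases (IUPAC codes, N) and gaps are handled by pairwise
deletion: a site contributes to a pairwise comparison only when both
sequences carry an unambiguous base there; the pair denominator stays
C(n, 2) over all pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqdata import SerialAlignment, collapse_haplotypes

__all__ = [
    "SummaryVector",
    "segregating_sites",
    "mean_pairwise_diff",
    "nucleotide_diversity",
    "haplotype_diversity",
    "layer_stats_table",
    "layer_summary",
    "STAT_SETS",
]

#: statistics per layer for each named stat set, in vector order
STAT_SETS = {
    "estimation12": ("S", "Pi", "pi"),
    "comparison8": ("S", "pi"),
}

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i


def _encode(aln_or_seqs) -> np.ndarray:
    """(n, L) int8 matrix; unambiguous bases 0..3, everything else -1."""
    seqs = aln_or_seqs.sequences if isinstance(aln_or_seqs, SerialAlignment) \
        else list(aln_or_seqs)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _CODE[arr].reshape(len(seqs), -1)


@dataclass
class SummaryVector:
    """Ordered summary statistics for one dataset.

    Entries are ``(layer_label, statistic_name, value)`` with layers oldest
    to youngest and statistics in the declared order of the stat set, so
    observed and simulated vectors align element-wise.
    """

    entries: list[tuple[str, str, float]]
    stat_set: str

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


def _site_counts(codes: np.ndarray) -> np.ndarray:
    """(L, 4) counts of unambiguous bases per column."""
    n, L = codes.shape
    counts = np.zeros((L, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=0)
    return counts


def segregating_sites(aln: SerialAlignment | list[str]) -> int:
    """Number of columns with >= 2 distinct unambiguous bases."""
    codes = _encode(aln)
    if codes.shape[0] == 0:
        raise ValueError("empty alignment")
    counts = _site_counts(codes)
    return int(((counts > 0).sum(axis=1) >= 2).sum())


def mean_pairwise_diff(aln: SerialAlignment | list[str]) -> float:
    """Average number of differing sites over all C(n,2) sequence pairs.

    Sites where either sequence is ambiguous are excluded from that pair's
    count (pairwise deletion).
    """
    codes = _encode(aln)
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences for pairwise differences")
    counts = _site_counts(codes)
    valid = counts.sum(axis=1)
    # differing unordered pairs per site = (v^2 - sum_b c_b^2) / 2
    diff_pairs = (valid.astype(float) ** 2 - (counts.astype(float) ** 2).sum(axis=1)) / 2.0
    return float(diff_pairs.sum() / (n * (n - 1) / 2.0))


def nucleotide_diversity(aln: SerialAlignment | list[str]) -> float:
    """Mean pairwise difference per site, Pi / L."""
    codes = _encode(aln)
    return mean_pairwise_diff(aln) / codes.shape[1]


def haplotype_diversity(counts) -> float:
    """H = n/(n-1) * (1 - sum p_i^2) from per-haplotype counts."""
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("need at least two sequences for haplotype diversity")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - (p ** 2).sum()))


def layer_stats_table(aln: SerialAlignment):
    """Table-shaped per-layer statistics (rows oldest to youngest).

    Returns a :class:`pandas.DataFrame` with columns
    ``layer, age, n, S, K, Pi, pi, H`` mirroring the usual summary table of
    serially sampled diversity.
    """
    import pandas as pd

    table = collapse_haplotypes(aln)
    rows = []
    for lab in aln.layers():
        sub = aln.layer_slice(lab)
        hap_counts = table.layer_counts(lab)
        if sub.n >= 2:
            S = segregating_sites(sub)
            Pi = mean_pairwise_diff(sub)
            H = haplotype_diversity(hap_counts)
        else:
            warnings.warn(f"layer {lab!r} has n < 2; pair statistics set to 0")
            S, Pi, H = segregating_sites(sub), 0.0, 0.0
        rows.append({
            "layer": lab, "age": sub.ages[0], "n": sub.n,
            "S": S, "K": len(hap_counts), "Pi": Pi,
            "pi": Pi / aln.length, "H": H,
        })
    return pd.DataFrame(rows)


def layer_summary(aln: SerialAlignment, stat_set: str = "estimation12",
                  stats: tuple[str, ...] | None = None) -> SummaryVector:
    """Concatenate per-layer statistics into a fixed-order vector.

    Layers are ordered oldest to youngest; within a layer the statistics
    follow the declared order of ``stat_set`` (or an explicit ``stats``
    tuple drawn from ``{"S", "Pi", "pi", "H"}``).
    """
    if stats is None:
        try:
            stats = STAT_SETS[stat_set]
        except KeyError:
            raise KeyError(f"unknown stat set {stat_set!r}; "
                           f"known: {sorted(STAT_SETS)}") from None
    entries = []
    for lab in aln.layers():
        sub = aln.layer_slice(lab)
        if sub.n >= 2:
            S = segregating_sites(sub)
            Pi = mean_pairwise_diff(sub)
        else:
            warnings.warn(f"layer {lab!r} has n < 2; pair statistics set to 0")
            S, Pi = segregating_sites(sub), 0.0
        vals = {"S": float(S), "Pi": Pi, "pi": Pi / aln.length}
        if "H" in stats:
            hap_counts = collapse_haplotypes(sub).layer_counts(lab)
            vals["H"] = haplotype_diversity(hap_counts) if sub.n >= 2 else 0.0
        for st in stats:
            entries.append((lab, st, vals[st]))
    return SummaryVector(entries=entries, stat_set=stat_set)


def summary_vector_from_stats(S: np.ndarray, Pi: np.ndarray, L: int,
                              layer_labels: list[str],
                              stat_set: str = "estimation12") -> SummaryVector:
    """Build a SummaryVector from precomputed per-layer (S, Pi) arrays.

    ``S`` and ``Pi`` must be ordered oldest to youngest, matching
    ``layer_labels``.  Used for simulated data and for observed statistics
    supplied as printed numbers rather than sequences.
    """
    stats = STAT_SETS[stat_set]
    entries = []
    for i, lab in enumerate(layer_labels):
        vals = {"S": float(S[i]), "Pi": float(Pi[i]), "pi": float(Pi[i]) / L}
        for st in stats:
            entries.append((lab, st, vals[st]))
    return SummaryVector(entries=entries, stat_set=stat_set)
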