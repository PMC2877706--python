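"""Data model and I/O for serially sampled (heterochronous) alignments.

A :class:`SerialAlignment` couples an alignment of equal-length mtDNA
sequences with a sampling age per sequence (in generations before present;
with a one-year generation time these are numerically calibrated years BP),
a categorical layer label, and an ordered locus partition of the alignment.

Coordinates are 0-based half-open internally; reports and the CLI use
1-based inclusive positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "SerialAlignment",
    "SamplingDesign",
    "HaplotypeTable",
    "AlignmentError",
    "MetadataError",
    "read_serial_fasta",
    "write_serial_fasta",
    "collapse_haplotypes",
    "extract_locus",
]

#: IUPAC nucleotide codes accepted in input sequences (plus gap).
VALID_CHARS = set("ACGTRYSWKMBDHVN-")
#: Characters counted as unambiguous bases by the statistics code.
UNAMBIGUOUS = set("ACGT")


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment (e.g. unequal lengths)."""


class MetadataError(KeyError):
    """A sequence id is missing from, or inconsistent with, the metadata."""


@dataclass
class SerialAlignment:
    """An alignment of serially sampled sequences.

    Parameters
    ----------
    sequences
        Uppercase DNA strings, all of equal length.
    ages
        Age of each sequence in generations BP (generation time one year,
        so numerically equal to calibrated years BP).
    layer_labels
        Categorical layer id per sequence (e.g. ``"modern"``, ``"11500"``).
    loci
        Ordered ``(name, start, end)`` half-open intervals partitioning
        ``[0, L)``.
    ids
        Optional per-sequence identifiers.
    """

    sequences: list[str]
    ages: list[float]
    layer_labels: list[str]
    loci: list[tuple[str, int, int]] = field(default_factory=list)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequences:
            raise AlignmentError("alignment must contain at least one sequence")
        self.sequences = [s.upper() for s in self.sequences]
        L = len(self.sequences[0])
        for i, s in enumerate(self.sequences):
            if len(s) != L:
                raise AlignmentError(
                    f"sequence {i} has length {len(s)}, expected {L}")
            bad = set(s) - VALID_CHARS
            if bad:
                raise AlignmentError(f"sequence {i} contains {sorted(bad)}")
        if len(self.ages) != len(self.sequences):
            raise MetadataError("one age per sequence required")
        if len(self.layer_labels) != len(self.sequences):
            raise MetadataError("one layer label per sequence required")
        if any(a < 0 for a in self.ages):
            raise MetadataError("ages must be non-negative")
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]
        if not self.loci:
            self.loci = [("all", 0, L)]
        self._check_loci(L)

    def _check_loci(self, L: int) -> None:
        pos = 0
        for name, start, end in self.loci:
            if start != pos or end <= start:
                raise AlignmentError(
                    f"loci must be contiguous half-open intervals covering [0, {L}); "
                    f"got {name}: [{start}, {end}) after position {pos}")
            pos = end
        if pos != L:
            raise AlignmentError(f"loci cover [0, {pos}) but alignment length is {L}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    def layers(self) -> list[str]:
        """Layer labels ordered oldest to youngest."""
        by_label: dict[str, float] = {}
        for lab, age in zip(self.layer_labels, self.ages):
            prev = by_label.setdefault(lab, age)
            if prev != age:
                raise MetadataError(f"layer {lab!r} has inconsistent ages")
        return sorted(by_label, key=lambda lab: -by_label[lab])

    def layer_slice(self, label: str) -> "SerialAlignment":
        idx = [i for i, lab in enumerate(self.layer_labels) if lab == label]
        if not idx:
            raise MetadataError(f"unknown layer {label!r}")
        return SerialAlignment(
            sequences=[self.sequences[i] for i in idx],
            ages=[self.ages[i] for i in idx],
            layer_labels=[self.layer_labels[i] for i in idx],
            loci=list(self.loci),
            ids=[self.ids[i] for i in idx],
        )


@dataclass
class SamplingDesign:
    """Numbers of sequences per temporal layer.

    ``layers`` is a list of ``(age_generations, n_samples)`` stored with
    strictly increasing age (the modern layer first).
    """

    layers: list[tuple[float, int]]
    total_length: int
    loci: list[tuple[str, int, int]]

    def __post_init__(self):
        self.layers = sorted(self.layers)
        ages = [a for a, _ in self.layers]
        if len(set(ages)) != len(ages):
            raise ValueError("layer ages must be distinct")
        if any(n < 1 for _, n in self.layers):
            raise ValueError("each layer needs at least one sample")
        if any(a < 0 for a in ages):
            raise ValueError("ages must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(n for _, n in self.layers)

    def layer_labels(self) -> list[str]:
        return [("modern" if a == 0 else str(int(a))) for a, _ in self.layers]


@dataclass
class HaplotypeTable:
    """Distinct sequences with per-layer occurrence counts.

    ``counts[h][layer]`` is the number of copies of haplotype ``h`` (index
    into ``haplotypes``, first-occurrence order) in that layer.
    """

    haplotypes: list[str]
    counts: list[dict[str, int]]
    total_n: dict[str, int]

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    def layer_counts(self, layer: str) -> list[int]:
        """Per-haplotype counts within one layer (zeros dropped)."""
        return [c[layer] for c in self.counts if c.get(layer, 0) > 0]


def read_serial_fasta(fasta_path: str | os.PathLike,
                      metadata_path: str | os.PathLike,
                      loci: list[tuple[str, int, int]] | None = None,
                      ) -> SerialAlignment:
    """Read an alignment plus per-sequence age metadata.

    The metadata file is tab-separated with a header line
    ``id<TAB>layer<TAB>age_generations``.  Every FASTA record id must be
    present in the metadata.
    """
    meta: dict[str, tuple[str, float]] = {}
    with open(metadata_path) as fh:
        header = fh.readline()
        if not header.lower().startswith("id"):
            raise MetadataError("metadata must start with an 'id<TAB>layer<TAB>age_generations' header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MetadataError(f"malformed metadata line: {line!r}")
            meta[parts[0]] = (parts[1], float(parts[2]))

    ids, seqs, ages, labels = [], [], [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta:
            raise MetadataError(f"sequence {rec.id!r} missing from metadata")
        layer, age = meta[rec.id]
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        labels.append(layer)
        ages.append(age)
    if not seqs:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    return SerialAlignment(sequences=seqs, ages=ages, layer_labels=labels,
                           loci=list(loci) if loci else [], ids=ids)


def write_serial_fasta(aln: SerialAlignment, fasta_path, metadata_path) -> None:
    """Write the alignment and its metadata TSV (inverse of the reader)."""
    with open(fasta_path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")
    with open(metadata_path, "w") as fh:
        fh.write("id\tlayer\tage_generations\n")
        for sid, lab, age in zip(aln.ids, aln.layer_labels, aln.ages):
            fh.write(f"{sid}\t{lab}\t{age:g}\n")


def collapse_haplotypes(aln: SerialAlignment) -> HaplotypeTable:
    """Collapse identical full-length sequences into haplotypes.

    Identity is exact string equality after uppercasing; ambiguity codes
    only match themselves.  Haplotypes are ordered by first occurrence.
    """
    index: dict[str, int] = {}
    haps: list[str] = []
    counts: list[dict[str, int]] = []
    total: dict[str, int] = {}
    for seq, lab in zip(aln.sequences, aln.layer_labels):
        h = index.get(seq)
        if h is None:
            h = index[seq] = len(haps)
            haps.append(seq)
            counts.append({})
        counts[h][lab] = counts[h].get(lab, 0) + 1
        total[lab] = total.get(lab, 0) + 1
    return HaplotypeTable(haplotypes=haps, counts=counts, total_n=total)


def extract_locus(aln: SerialAlignment, locus_name: str) -> SerialAlignment:
    """Restrict the alignment to one declared locus."""
    for name, start, end in aln.loci:
        if name == locus_name:
            return SerialAlignment(
                sequences=[s[start:end] for s in aln.sequences],
                ages=list(aln.ages),
                layer_labels=list(aln.layer_labels),
                loci=[(name, 0, end - start)],
                ids=list(aln.ids),
            )
    raise KeyError(f"unknown locus {locus_name!r}; declared: "
                   f"{[n for n, _, _ in aln.loci]}")
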