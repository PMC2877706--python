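"""Serial (heterochronous) coalescent simulator with finite-sites mutations.

The simulator follows the classic backward-time structured coalescent for
temporally sampled lineages: lineages enter the genealogy at their layer
age, coalesce within demes at rate k(k-1)/(2 N_d(t)) — so two lineages in a
deme of constant size N wait N generations on average (haploid/mtDNA
convention; N is the female effective size) — and migrate between demes
while a migration matrix is active.  Demographic events scale deme sizes
and move lineages at fixed times.

Mutations are overlaid as a Poisson process along branches under a
Kimura 2-parameter model with continuous gamma rate heterogeneity across
sites (mean-1 multipliers, shape alpha per locus).

All stochastic operations take an explicit integer seed; independent
streams are derived by counter so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .seqdata import SamplingDesign, SerialAlignment

__all__ = [
    "DemographicEvent",
    "DemographicHistory",
    "MutationModel",
    "GenealogyTree",
    "NonCoalescingError",
    "simulate_genealogy",
    "apply_mutations",
    "simulate_dataset",
    "mu_per_site_per_generation",
]

#: generations per million years at a one-year generation time
GENERATIONS_PER_MYR = 1e6

#: default simulation horizon used to flag non-coalescing configurations
DEFAULT_T_MAX = 1e7

_BASES = "AGCT"


class NonCoalescingError(RuntimeError):
    """The lineages failed to find a common ancestor before the horizon."""


def mu_per_site_per_generation(mu_site_myr: float) -> float:
    """Convert a rate in mutations/site/myr to per site per generation.

    With a one-year generation time, 1 mutation/site/myr = 1e-6 per site
    per generation.  All rate-unit conversions go through this function.
    """
    return mu_site_myr / GENERATIONS_PER_MYR


@dataclass
class DemographicEvent:
    """A point event in backward time.

    ``size_scale`` multiplies deme ``deme``'s size at the event time and
    ``growth_after`` replaces its growth rate above (older than) the event
    (default 0, i.e. constant size further back).  ``move`` optionally
    relocates lineages: ``(source, sink, fraction)``, with fraction 1.0
    moving every lineage (a population join).
    """

    time: float
    deme: int = -1
    size_scale: float = 1.0
    growth_after: float = 0.0
    move: tuple[int, int, float] | None = None

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("event times must be >= 0")
        if self.size_scale <= 0:
            raise ValueError("size scaling must be > 0")


@dataclass
class DemographicHistory:
    """Piecewise demography: deme sizes, growth, events and migration.

    ``sizes[d]`` is the present female effective size of deme ``d`` and
    ``growth[d]`` its per-generation exponential rate: backward in time,
    ``N_d(t) = sizes[d] * exp(-growth[d] * t)`` until an event modifies it
    (r > 0 therefore means forward-time growth).  ``migration[i, j]`` is
    the per-generation probability that a lineage in deme ``i`` moves to
    deme ``j`` while ``migration_window`` is active.
    """

    sizes: list[float]
    growth: list[float] | None = None
    events: list[DemographicEvent] = field(default_factory=list)
    migration: np.ndarray | None = None
    migration_window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.sizes = [float(s) for s in self.sizes]
        if any(s <= 0 for s in self.sizes):
            raise ValueError("deme sizes must be > 0")
        if self.growth is None:
            self.growth = [0.0] * len(self.sizes)
        if len(self.growth) != len(self.sizes):
            raise ValueError("one growth rate per deme required")
        nd = len(self.sizes)
        if self.migration is None:
            self.migration = np.zeros((nd, nd))
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (nd, nd):
            raise ValueError("migration matrix must be n_demes x n_demes")
        if (self.migration < 0).any() or not np.isfinite(self.migration).all():
            raise ValueError("migration rates must be finite and >= 0")
        self.events = sorted(self.events, key=lambda e: e.time)

    @property
    def n_demes(self) -> int:
        return len(self.sizes)

    def size_at(self, t: float, deme: int = 0) -> float:
        """Deme size at backward time t (evaluating growth and events)."""
        size = self.sizes[deme]
        growth = self.growth[deme]
        t_cur = 0.0
        for ev in self.events:
            if ev.time > t:
                break
            size *= np.exp(-growth * (ev.time - t_cur))
            t_cur = ev.time
            if ev.deme == deme:
                size *= ev.size_scale
                growth = ev.growth_after
        return size * np.exp(-growth * (t - t_cur))

    def _arrays(self):
        ne = len(self.events)
        ev_time = np.array([e.time for e in self.events], dtype=float)
        ev_deme = np.array([e.deme for e in self.events], dtype=np.int64)
        ev_scale = np.array([e.size_scale for e in self.events], dtype=float)
        ev_growth = np.array([e.growth_after for e in self.events], dtype=float)
        ev_src = np.array([e.move[0] if e.move else -1 for e in self.events],
                          dtype=np.int64)
        ev_dst = np.array([e.move[1] if e.move else -1 for e in self.events],
                          dtype=np.int64)
        ev_frac = np.array([e.move[2] if e.move else 0.0 for e in self.events],
                           dtype=float)
        assert ev_time.shape == (ne,)
        return ev_time, ev_deme, ev_scale, ev_growth, ev_src, ev_dst, ev_frac


@dataclass
class MutationModel:
    """K2P substitution with per-locus gamma rate heterogeneity.

    ``mu_site_myr`` is the per-site rate in mutations/site/myr (converted
    internally with :func:`mu_per_site_per_generation`); ``alpha`` the
    gamma shape of the mean-1 site-rate multipliers per locus; ``kappa``
    the transition:transversion ratio (a mutation is a transition with
    probability kappa/(kappa+2)).
    """

    mu_site_myr: float
    alpha: dict[str, float] | float = 1.0
    kappa: float = 10.0

    def __post_init__(self):
        if self.mu_site_myr < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    def alpha_for(self, locus: str) -> float:
        a = self.alpha.get(locus, 1.0) if isinstance(self.alpha, dict) else self.alpha
        if a <= 0:
            raise ValueError("gamma shape must be > 0")
        return float(a)


@dataclass
class GenealogyTree:
    """A coalescent genealogy over serially sampled tips.

    Tips ``0..n-1`` follow the design's layer order (modern first, then
    increasing age); internal nodes are appended in coalescence order so
    the root is the last node.  Branch lengths are in generations.
    """

    parent: np.ndarray
    node_time: np.ndarray
    node_deme: np.ndarray
    n_tips: int
    tip_layer: np.ndarray
    tip_age: np.ndarray

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    @property
    def total_length(self) -> float:
        idx = np.arange(len(self.parent) - 1)
        return float((self.node_time[self.parent[idx]] - self.node_time[idx]).sum())


def _split_seed(seed: int, n: int) -> np.ndarray:
    """Derive n reproducible uint32 stream seeds from one integer seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32).astype(np.int64)


def _design_tips(design: SamplingDesign, deme_of_layers=None):
    """Tip sample times/demes/layer indices; layer indices oldest first."""
    n_layers = len(design.layers)
    times, demes, layer_ix = [], [], []
    for i, (age, n) in enumerate(design.layers):  # ascending age
        deme = 0 if deme_of_layers is None else deme_of_layers[i]
        times.extend([age] * n)
        demes.extend([deme] * n)
        layer_ix.extend([n_layers - 1 - i] * n)  # oldest layer -> index 0
    return (np.array(times, dtype=float), np.array(demes, dtype=np.int64),
            np.array(layer_ix, dtype=np.int64))


def simulate_genealogy(hist: DemographicHistory, design: SamplingDesign,
                       deme_of_layers=None, seed: int = 0,
                       t_max: float = DEFAULT_T_MAX) -> GenealogyTree:
    """Simulate one genealogy under the history and sampling design.

    ``deme_of_layers`` maps layer index (in ascending-age order) to the
    deme it is sampled from; default deme 0 for every layer.

    Raises
    ------
    NonCoalescingError
        if no common ancestor is reached before ``t_max`` generations.
    """
    times, demes, layer_ix = _design_tips(design, deme_of_layers)
    if (demes >= hist.n_demes).any():
        raise ValueError("sampling deme outside the history's demes")
    ev = hist._arrays()
    mig_start, mig_stop = hist.migration_window
    _kernels.seed(int(_split_seed(seed, 1)[0]))
    parent, node_time, node_deme, ok = _kernels.sim_genealogy(
        times, demes, np.array(hist.sizes, dtype=float),
        np.array(hist.growth, dtype=float), *ev,
        hist.migration, float(mig_start), float(mig_stop), float(t_max))
    if not ok:
        raise NonCoalescingError(
            f"no common ancestor within {t_max:g} generations; "
            "check for isolated demes or runaway growth")
    return GenealogyTree(parent=parent, node_time=node_time,
                         node_deme=node_deme, n_tips=len(times),
                         tip_layer=layer_ix, tip_age=times)


def _locus_arrays(design: SamplingDesign, mm: MutationModel):
    locus_len = np.array([end - start for _, start, end in design.loci],
                         dtype=np.int64)
    mu = mu_per_site_per_generation(mm.mu_site_myr)
    mu_site = np.full(len(locus_len), mu, dtype=float)
    alpha = np.array([mm.alpha_for(name) for name, _, _ in design.loci],
                     dtype=float)
    return locus_len, mu_site, alpha


def apply_mutations(tree: GenealogyTree, mm: MutationModel,
                    design: SamplingDesign, seed: int = 0) -> SerialAlignment:
    """Drop mutations on a genealogy and return the resulting alignment.

    The root sequence is uniform over {A, C, G, T}; each mutation applies a
    K2P change.  Sequences are returned in tip order with layer labels and
    ages from the design.
    """
    locus_len, mu_site, alpha = _locus_arrays(design, mm)
    _kernels.seed(int(_split_seed(seed, 1)[0]))
    root_base, sites, tip_state = _kernels.mutate_tree(
        tree.parent, tree.node_time, tree.n_tips, locus_len, mu_site, alpha,
        mm.kappa)
    return _states_to_alignment(root_base, sites, tip_state, design)


def _states_to_alignment(root_base, sites, tip_state,
                         design: SamplingDesign) -> SerialAlignment:
    n = design.n_total
    codes = np.tile(root_base, (n, 1))
    codes[:, sites] = tip_state.T
    labels = design.layer_labels()
    seq_labels, ages = [], []
    for (age, cnt), lab in zip(design.layers, labels):
        seq_labels.extend([lab] * cnt)
        ages.extend([age] * cnt)
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    seqs = [bytes(lut[row]).decode() for row in codes]
    return SerialAlignment(sequences=seqs, ages=ages, layer_labels=seq_labels,
                           loci=list(design.loci))


def simulate_dataset(hist: DemographicHistory, mm: MutationModel,
                     design: SamplingDesign, seed: int = 0,
                     deme_of_layers=None,
                     t_max: float = DEFAULT_T_MAX) -> SerialAlignment:
    """Genealogy plus mutations in one call; deterministic given the seed.

    Uses the same derived seed pair as the batched reference-table
    simulator, so a table row and this function agree bit-for-bit.
    """
    gseed, mseed = dataset_seeds(seed)
    times, demes, layer_ix = _design_tips(design, deme_of_layers)
    ev = hist._arrays()
    mig_start, mig_stop = hist.migration_window
    _kernels.seed(int(gseed))
    parent, node_time, node_deme, ok = _kernels.sim_genealogy(
        times, demes, np.array(hist.sizes, dtype=float),
        np.array(hist.growth, dtype=float), *ev,
        hist.migration, float(mig_start), float(mig_stop), float(t_max))
    if not ok:
        raise NonCoalescingError(
            f"no common ancestor within {t_max:g} generations")
    locus_len, mu_site, alpha = _locus_arrays(design, mm)
    _kernels.seed(int(mseed))
    root_base, sites, tip_state = _kernels.mutate_tree(
        parent, node_time, len(times), locus_len, mu_site, alpha, mm.kappa)
    return _states_to_alignment(root_base, sites, tip_state, design)


def dataset_seeds(seed: int) -> tuple[int, int]:
    """The (genealogy, mutation) stream seeds derived from one seed."""
    s = _split_seed(seed, 2)
    return int(s[0]), int(s[1])
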