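"""The three demographic models and their priors.

Three named models describe the history of a single serially sampled
mtDNA locality:

``constant``
    one population of constant female effective size.
``closed_bottleneck``
    one closed population: present size ``N_modern``; exponential change
    between the present and the bottleneck event at ``T_b`` generations BP
    such that the size on the recent side of the event is ``fNe_after``
    (the growth rate ``r = ln(N_modern/fNe_after)/T_b`` is derived by
    continuity); above the event the size is constant at ``fNe_before``.
    The event severity ``k = fNe_before/fNe_after`` is therefore the
    ratio of two independent uniforms, U(1, 200000)/U(1, 5000), and the
    identities ``fNe_after = N(T_b-)`` and ``fNe_before = k * N(T_b-)``
    hold exactly.
``open_migration``
    four demes (the sampled locality plus three neighbouring regions):
    one ancestral population splits at ``T_s`` into four demes of sizes
    ``N1..N4``; while the migration window ``[T_stop, T_s]`` is active, a
    hub-and-spoke matrix exchanges lineages at rate ``m_high`` between the
    focal deme and each neighbour and ``m_low`` between neighbours.  All
    temporal layers are sampled from the focal deme.

Priors are uniform, log-uniform, or a ratio of two independent uniforms
(the bottleneck severity ``k`` is U(1, 200000)/U(1, 5000)).  Mutation-rate
priors are expressed in mutations/site/myr and converted downstream.

Where the underlying study left prior bounds unstated (growth rate,
bottleneck time, migration rates) the defaults below are documented
reconstructions; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqdata import SamplingDesign
from .serialcoal import (DemographicEvent, DemographicHistory, MutationModel,
                         mu_per_site_per_generation)

__all__ = [
    "Prior",
    "ModelSpec",
    "ParameterDraw",
    "MODELS",
    "default_model",
    "sample_prior",
    "sample_prior_batch",
    "build_history",
    "build_mutation_model",
    "derived_parameters",
    "DEFAULT_ALPHA",
    "DEFAULT_KAPPA",
]

#: default gamma shapes per locus (which shape belongs to which locus is a
#: documented package choice; both values are exposed in configuration)
DEFAULT_ALPHA = {"CytB": 8.0, "CR": 0.02}
#: default transition:transversion ratio (typical mammalian mtDNA bias)
DEFAULT_KAPPA = 10.0

#: coalescent gene copies per unit of the fNe parameters.  The fNe sizes are
#: interpreted as BayeSSC-style effective-size inputs, under which a reported
#: size N corresponds to a pairwise coalescence time of 2N generations; the
#: simulator itself uses the E[T2] = size convention, so model-level sizes
#: are doubled when a history is built.
FNE_SCALE = 2.0


@dataclass
class Prior:
    """A one-dimensional prior distribution.

    ``kind`` is ``uniform`` (over ``[a, b]``), ``log_uniform`` (log10-scale
    uniform over ``[a, b]``) or ``ratio_uniform`` (U(a, b)/U(a2, b2)).
    """

    name: str
    kind: str = "uniform"
    a: float = 0.0
    b: float = 1.0
    a2: float | None = None
    b2: float | None = None
    units: str = ""

    def __post_init__(self):
        if self.a >= self.b:
            raise ValueError(f"{self.name}: require a < b")
        if self.kind == "ratio_uniform" and (self.a2 is None or self.a2 >= self.b2):
            raise ValueError(f"{self.name}: ratio prior needs a2 < b2")
        if self.kind not in ("uniform", "log_uniform", "ratio_uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size)
        if self.kind == "log_uniform":
            return 10.0 ** rng.uniform(np.log10(self.a), np.log10(self.b), size)
        num = rng.uniform(self.a, self.b, size)
        den = rng.uniform(self.a2, self.b2, size)
        return num / den

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "ratio_uniform":
            return self.a / self.b2, self.b / self.a2
        return self.a, self.b


@dataclass
class ModelSpec:
    """A named demographic model plus its priors and structure."""

    model_id: str
    priors: dict[str, Prior]
    n_demes: int = 1
    sampling_deme: int = 0
    #: parameters reported/regressed on a log scale (strictly positive)
    log_scale: tuple[str, ...] = ()
    alpha: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    kappa: float = DEFAULT_KAPPA

    @property
    def parameter_names(self) -> list[str]:
        return list(self.priors)


@dataclass
class ParameterDraw:
    """One draw from a model's priors: a name -> value map."""

    model_id: str
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


_MU_PRIOR = dict(kind="uniform", a=0.01, b=0.2, units="mutations/site/myr")


def default_model(model_id: str) -> ModelSpec:
    """The built-in specification of one of the three named models."""
    if model_id == "constant":
        priors = {
            "N": Prior("N", "uniform", 1, 50_000, units="females"),
            "mu": Prior("mu", **_MU_PRIOR),
        }
        return ModelSpec(model_id, priors, n_demes=1,
                         log_scale=("N", "mu"))
    if model_id == "closed_bottleneck":
        priors = {
            "N_modern": Prior("N_modern", "uniform", 1, 50_000, units="females"),
            "T_b": Prior("T_b", "uniform", 0, 45_000, units="generations"),
            "fNe_after": Prior("fNe_after", "uniform", 1, 5_000, units="females"),
            "fNe_before": Prior("fNe_before", "uniform", 1, 200_000,
                                units="females"),
            "mu": Prior("mu", **_MU_PRIOR),
        }
        return ModelSpec(model_id, priors, n_demes=1,
                         log_scale=("N_modern", "T_b", "fNe_after",
                                    "fNe_before", "mu"))
    if model_id == "open_migration":
        priors = {
            "T_s": Prior("T_s", "uniform", 11_000, 15_000, units="generations"),
            "N1": Prior("N1", "uniform", 1, 20_000, units="females"),
            "N2": Prior("N2", "uniform", 1, 20_000, units="females"),
            "N3": Prior("N3", "uniform", 1, 20_000, units="females"),
            "N4": Prior("N4", "uniform", 1, 20_000, units="females"),
            "T_stop": Prior("T_stop", "uniform", 0, 1_000, units="generations"),
            "m_high": Prior("m_high", "uniform", 1e-4, 1.0,
                            units="per lineage per generation"),
            "m_low": Prior("m_low", "uniform", 1e-6, 1e-4,
                           units="per lineage per generation"),
            "mu": Prior("mu", **_MU_PRIOR),
        }
        return ModelSpec(model_id, priors, n_demes=4,
                         log_scale=("T_s", "N1", "N2", "N3", "N4",
                                    "m_high", "m_low", "mu"))
    raise KeyError(f"unknown model {model_id!r}; "
                   "known: constant, closed_bottleneck, open_migration")


MODELS = ("constant", "closed_bottleneck", "open_migration")


def sample_prior(spec: ModelSpec, seed: int = 0) -> ParameterDraw:
    """One independent draw of every parameter."""
    rng = np.random.default_rng(seed)
    return ParameterDraw(spec.model_id,
                         {name: float(p.sample(rng)) for name, p in spec.priors.items()})


def sample_prior_batch(spec: ModelSpec, n: int, seed: int = 0) -> dict[str, np.ndarray]:
    """n independent draws per parameter as a name -> array map."""
    rng = np.random.default_rng(seed)
    return {name: np.asarray(p.sample(rng, n)) for name, p in spec.priors.items()}


def build_history(spec: ModelSpec, draw: ParameterDraw) -> DemographicHistory:
    """Turn one parameter draw into a concrete DemographicHistory."""
    if draw.model_id != spec.model_id:
        raise ValueError(f"draw is for model {draw.model_id!r}, spec is "
                         f"{spec.model_id!r}")
    v = draw.values
    if spec.model_id == "constant":
        return DemographicHistory(sizes=[FNE_SCALE * v["N"]])
    if spec.model_id == "closed_bottleneck":
        r, k = _closed_growth_and_severity(
            v["N_modern"], v["T_b"], v["fNe_after"], v["fNe_before"])
        return DemographicHistory(
            sizes=[FNE_SCALE * v["N_modern"]],
            growth=[float(r)],
            events=[DemographicEvent(time=v["T_b"], deme=0,
                                     size_scale=float(k), growth_after=0.0)],
        )
    if spec.model_id == "open_migration":
        mig = np.zeros((4, 4))
        for d in (1, 2, 3):
            mig[0, d] = mig[d, 0] = v["m_high"]
        for d in (1, 2, 3):
            for j in (1, 2, 3):
                if d != j:
                    mig[d, j] = v["m_low"]
        events = [DemographicEvent(time=v["T_s"], move=(d, 0, 1.0))
                  for d in (1, 2, 3)]
        return DemographicHistory(
            sizes=[FNE_SCALE * v["N1"], FNE_SCALE * v["N2"],
                   FNE_SCALE * v["N3"], FNE_SCALE * v["N4"]],
            events=events,
            migration=mig,
            migration_window=(v["T_stop"], v["T_s"]),
        )
    raise KeyError(spec.model_id)


def build_mutation_model(spec: ModelSpec, draw: ParameterDraw) -> MutationModel:
    return MutationModel(mu_site_myr=draw["mu"], alpha=dict(spec.alpha),
                         kappa=spec.kappa)


def _closed_growth_and_severity(n_modern, t_b, fne_after, fne_before):
    """Derived growth rate and event severity of the closed model.

    ``r`` makes ``N(T_b-) = fne_after`` under ``N(t) = N_modern e^(-r t)``;
    ``k`` multiplies the size at the event so that the ancestral side sits
    at ``fne_before``.
    """
    t = np.maximum(np.asarray(t_b, dtype=float), 1e-9)
    r = np.log(np.asarray(n_modern, dtype=float)
               / np.asarray(fne_after, dtype=float)) / t
    k = np.asarray(fne_before, dtype=float) / np.asarray(fne_after, dtype=float)
    return r, k


def derived_parameters(spec: ModelSpec, params: dict[str, np.ndarray],
                       total_length: int) -> dict[str, np.ndarray]:
    """Derived reporting quantities for a batch of draws.

    Every model reports the per-locus mutation rate ``mu_locus`` (per
    generation over the full alignment); the closed bottleneck model adds
    the derived growth rate and event severity ``k = fNe_before/fNe_after``.
    """
    out = {}
    mu_gen = mu_per_site_per_generation(np.asarray(params["mu"], dtype=float))
    out["mu_locus"] = mu_gen * total_length
    if spec.model_id == "closed_bottleneck":
        r, k = _closed_growth_and_severity(
            params["N_modern"], params["T_b"],
            params["fNe_after"], params["fNe_before"])
        out["growth_rate"] = r
        out["k"] = k
    return out


# ---------------------------------------------------------------------------
# vectorized kernel encodings for reference-table simulation


def batch_kernel_arrays(spec: ModelSpec, params: dict[str, np.ndarray],
                        design: SamplingDesign) -> dict:
    """Encode a batch of prior draws as arrays for the simulation kernel.

    Returns the per-simulation 2-D arrays (sizes, growth rates, event
    fields, migration matrices, per-locus site rates) plus the shared
    structural arrays, ready for ``_kernels.simulate_stats_batch``.
    """
    n = len(next(iter(params.values())))
    nd = spec.n_demes
    mu_gen = mu_per_site_per_generation(np.asarray(params["mu"], dtype=float))
    locus_len = np.array([end - start for _, start, end in design.loci],
                         dtype=np.int64)
    mu_site = np.repeat(mu_gen[:, None], len(locus_len), axis=1)
    alpha = np.array([spec.alpha.get(name, 1.0) for name, _, _ in design.loci],
                     dtype=float)

    common = dict(locus_len=locus_len, mu_site=mu_site, alpha=alpha,
                  kappa=float(spec.kappa))

    if spec.model_id == "constant":
        return dict(
            sizes=FNE_SCALE * np.asarray(params["N"], dtype=float)[:, None],
            growths=np.zeros((n, 1)),
            ev_time=np.zeros((n, 0)), ev_scale=np.zeros((n, 0)),
            ev_growth=np.zeros((n, 0)), ev_frac=np.zeros((n, 0)),
            ev_deme=np.zeros(0, dtype=np.int64),
            ev_src=np.zeros(0, dtype=np.int64),
            ev_dst=np.zeros(0, dtype=np.int64),
            mig=np.zeros((n, 1, 1)),
            mig_start=np.zeros(n), mig_stop=np.zeros(n),
            **common)
    if spec.model_id == "closed_bottleneck":
        r, k = _closed_growth_and_severity(
            params["N_modern"], params["T_b"],
            params["fNe_after"], params["fNe_before"])
        return dict(
            sizes=FNE_SCALE * np.asarray(params["N_modern"], dtype=float)[:, None],
            growths=np.asarray(r, dtype=float)[:, None].copy(),
            ev_time=np.asarray(params["T_b"], dtype=float)[:, None].copy(),
            ev_scale=np.asarray(k, dtype=float)[:, None].copy(),
            ev_growth=np.zeros((n, 1)), ev_frac=np.zeros((n, 1)),
            ev_deme=np.array([0], dtype=np.int64),
            ev_src=np.array([-1], dtype=np.int64),
            ev_dst=np.array([-1], dtype=np.int64),
            mig=np.zeros((n, 1, 1)),
            mig_start=np.zeros(n), mig_stop=np.zeros(n),
            **common)
    if spec.model_id == "open_migration":
        sizes = FNE_SCALE * np.stack([np.asarray(params[f"N{i}"], dtype=float)
                                      for i in (1, 2, 3, 4)], axis=1)
        ts = np.asarray(params["T_s"], dtype=float)
        mig = np.zeros((n, 4, 4))
        mh = np.asarray(params["m_high"], dtype=float)
        ml = np.asarray(params["m_low"], dtype=float)
        for d in (1, 2, 3):
            mig[:, 0, d] = mh
            mig[:, d, 0] = mh
        for d in (1, 2, 3):
            for j in (1, 2, 3):
                if d != j:
                    mig[:, d, j] = ml
        return dict(
            sizes=sizes,
            growths=np.zeros((n, 4)),
            ev_time=np.repeat(ts[:, None], 3, axis=1),
            ev_scale=np.ones((n, 3)),
            ev_growth=np.zeros((n, 3)),
            ev_frac=np.ones((n, 3)),
            ev_deme=np.array([-1, -1, -1], dtype=np.int64),
            ev_src=np.array([1, 2, 3], dtype=np.int64),
            ev_dst=np.array([0, 0, 0], dtype=np.int64),
            mig=mig,
            mig_start=np.asarray(params["T_stop"], dtype=float).copy(),
            mig_stop=ts.copy(),
            **common)
    raise KeyError(spec.model_id)
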