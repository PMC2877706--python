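"""Approximate Bayesian computation over serial-coalescent simulations.

The workflow follows classic rejection ABC with local-linear regression
adjustment (Beaumont, Zhang & Balding 2002) and categorical-regression
model choice:

1. :func:`build_reference_table` simulates (parameter draw, summary
   vector) rows under one model's priors;
2. :func:`reject` keeps the ``accept_count`` rows closest to the observed
   vector in MAD-normalized Euclidean distance, with Epanechnikov weights
   ``w_i = 1 - (d_i / delta)^2``;
3. :func:`regression_adjust` projects each accepted parameter to the
   observed statistics with a weighted local-linear regression
   (log-transforming strictly positive parameters);
4. :func:`posterior_summary` reports weighted-KDE modes and weighted
   empirical quantile intervals;
5. :func:`model_posterior` compares models by accepted-row proportions and
   by Epanechnikov-weighted multinomial logistic regression evaluated at
   the observed vector;
6. :func:`bias_test` is the constant-size sampling-bias test: one-sided
   lower-tail P-values of per-layer mean pairwise difference against a
   constant-population null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .demography import (ModelSpec, Prior, batch_kernel_arrays,
                         derived_parameters, sample_prior_batch)
from .seqdata import SamplingDesign
from .serialcoal import _design_tips
from .sumstats import STAT_SETS, SummaryVector

__all__ = [
    "ReferenceTable",
    "PosteriorSample",
    "ModelPosterior",
    "BiasTestReport",
    "build_reference_table",
    "simulate_summaries",
    "reject",
    "regression_adjust",
    "posterior_summary",
    "model_posterior",
    "bias_test",
    "constant_null_spec",
    "weighted_quantile",
]


# ---------------------------------------------------------------------------
# reference tables


@dataclass
class ReferenceTable:
    """Simulated (parameters, summary statistics) rows for one model."""

    model_id: str
    params: pd.DataFrame
    stats: np.ndarray
    stat_names: list[str]
    stat_set: str
    seed: int
    n_failed: int = 0

    @property
    def n(self) -> int:
        return len(self.params)

    def subset(self, n: int) -> "ReferenceTable":
        """The first n rows (rows are i.i.d., so any prefix is a valid table)."""
        return ReferenceTable(self.model_id, self.params.iloc[:n].reset_index(drop=True),
                              self.stats[:n], self.stat_names, self.stat_set,
                              self.seed, self.n_failed)

    def to_frame(self) -> pd.DataFrame:
        stats = pd.DataFrame(self.stats, columns=self.stat_names)
        return pd.concat([self.params.reset_index(drop=True), stats], axis=1)


def _stat_matrix(S: np.ndarray, PD: np.ndarray, design: SamplingDesign,
                 stat_set: str, loci: str) -> np.ndarray:
    """Column-stack per-layer stats in the fixed SummaryVector order.

    ``S`` and ``PD`` have shape (n, n_loci, n_layers) with layers oldest
    first.  ``loci="combined"`` sums over loci; ``loci="per_locus"`` keeps
    one block of statistics per locus within each layer.
    """
    stats = STAT_SETS[stat_set]
    lens = [end - start for _, start, end in design.loci]
    if loci == "combined":
        blocks = [(S.sum(axis=1), PD.sum(axis=1), design.total_length)]
    elif loci == "per_locus":
        blocks = [(S[:, lc], PD[:, lc], lens[lc]) for lc in range(len(lens))]
    else:
        raise ValueError(f"loci must be 'combined' or 'per_locus', got {loci!r}")
    cols = []
    for layer in range(S.shape[2]):  # oldest -> youngest
        for Sb, PDb, L in blocks:
            for st in stats:
                if st == "S":
                    cols.append(Sb[:, layer].astype(float))
                elif st == "Pi":
                    cols.append(PDb[:, layer])
                elif st == "pi":
                    cols.append(PDb[:, layer] / L)
                else:
                    raise KeyError(st)
    return np.column_stack(cols)


def _stat_names(design: SamplingDesign, stat_set: str, loci: str) -> list[str]:
    labels = design.layer_labels()[::-1]  # oldest first
    if loci == "combined":
        blocks = ["combined"]
    else:
        blocks = [name for name, _, _ in design.loci]
    return [f"{st}_{blk}_{lab}" for lab in labels for blk in blocks
            for st in STAT_SETS[stat_set]]


def simulate_summaries(spec: ModelSpec, design: SamplingDesign,
                       params: dict[str, np.ndarray], seed: int,
                       max_rounds: int = 100):
    """Simulate per-layer (S, Pi) for each parameter row.

    Rows whose genealogy hits the time horizon (non-coalescing draws, e.g.
    runaway backward growth) are redrawn from the priors; the number of
    redraws is reported.  Returns ``(params, S, PD, n_failed)`` where
    ``params`` contains the final (possibly redrawn) values.
    """
    n = len(next(iter(params.values())))
    times, demes, layer_ix = _design_tips(design)
    n_layers = len(design.layers)
    params = {k: np.array(v, dtype=float) for k, v in params.items()}

    ss = np.random.SeedSequence(seed)
    n_failed_total = 0
    n_loci = len(design.loci)
    S = np.zeros((n, n_loci, n_layers), dtype=np.int64)
    PD = np.zeros((n, n_loci, n_layers), dtype=float)
    active = np.arange(n)
    for rnd in range(max_rounds):
        child = ss.spawn(2)
        sub = {k: v[active] for k, v in params.items()}
        arrs = batch_kernel_arrays(spec, sub, design)
        seeds = child[0].generate_state(2 * len(active), dtype=np.uint32).astype(np.int64)
        S_a, PD_a = _kernels.simulate_stats_batch(
            seeds[:len(active)], seeds[len(active):],
            times, demes, layer_ix, n_layers,
            arrs["sizes"], arrs["growths"],
            arrs["ev_time"], arrs["ev_deme"], arrs["ev_scale"], arrs["ev_growth"],
            arrs["ev_src"], arrs["ev_dst"], arrs["ev_frac"],
            arrs["mig"], arrs["mig_start"], arrs["mig_stop"],
            arrs["locus_len"], arrs["mu_site"], arrs["alpha"], arrs["kappa"],
            1e7)
        failed = S_a[:, 0, 0] == _kernels.FAILED
        ok = ~failed
        S[active[ok]] = S_a[ok]
        PD[active[ok]] = PD_a[ok]
        active = active[failed]
        if len(active) == 0:
            break
        n_failed_total += len(active)
        fresh = sample_prior_batch(spec, len(active),
                                   int(child[1].generate_state(1)[0] % 2**31))
        for k in params:
            params[k][active] = fresh[k]
    else:
        raise RuntimeError("too many non-coalescing redraw rounds; "
                           "the model configuration may be degenerate")
    return params, S, PD, n_failed_total


def build_reference_table(spec: ModelSpec, design: SamplingDesign,
                          stat_set: str = "estimation12",
                          n_sims: int = 10_000, seed: int = 0,
                          chunk_size: int = 50_000,
                          loci: str = "combined") -> ReferenceTable:
    """Simulate a reference table of ``n_sims`` rows under one model.

    Work proceeds in chunks with counter-derived seeds, so the table is
    reproducible for a given seed and can be built incrementally.  Derived
    reporting quantities (per-locus mutation rate; sizes on both sides of
    a bottleneck event) are appended as extra parameter columns.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ss = np.random.SeedSequence(seed)
    frames, stats_parts = [], []
    n_failed = 0
    done = 0
    chunk_index = 0
    while done < n_sims:
        m = min(chunk_size, n_sims - done)
        child = ss.spawn(2)
        draw_seed = int(child[0].generate_state(1)[0] % 2**31)
        sim_seed = int(child[1].generate_state(1)[0] % 2**31)
        params = sample_prior_batch(spec, m, draw_seed)
        params, S, PD, nf = simulate_summaries(spec, design, params, sim_seed)
        n_failed += nf
        frame = pd.DataFrame(params)
        for name, vals in derived_parameters(spec, params, design.total_length).items():
            frame[name] = vals
        frames.append(frame)
        stats_parts.append(_stat_matrix(S, PD, design, stat_set, loci))
        done += m
        chunk_index += 1
    return ReferenceTable(
        model_id=spec.model_id,
        params=pd.concat(frames, ignore_index=True),
        stats=np.vstack(stats_parts),
        stat_names=_stat_names(design, stat_set, loci),
        stat_set=stat_set,
        seed=seed,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# rejection and regression adjustment


@dataclass
class PosteriorSample:
    """Accepted (optionally regression-adjusted) parameter draws."""

    model_id: str
    params: pd.DataFrame
    weights: np.ndarray
    distances: np.ndarray
    accept_count: int
    accept_fraction: float
    observed: np.ndarray
    stats: np.ndarray            # accepted rows, MAD-normalized scale
    stat_names: list[str]
    adjusted: bool = False
    log_params: tuple[str, ...] = ()

    @property
    def ess(self) -> float:
        """Kish effective sample size of the weights."""
        w = self.weights
        return float(w.sum() ** 2 / (w ** 2).sum())


def _observed_values(observed) -> np.ndarray:
    if isinstance(observed, SummaryVector):
        return observed.values
    return np.asarray(observed, dtype=float)


def _normalize_stats(stats: np.ndarray, obs: np.ndarray):
    """Scale columns by the table's median absolute deviation.

    Zero-MAD columns carry no distance information and are dropped with a
    warning.  Returns (scaled stats, scaled observed, kept column mask).
    """
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    keep = mad > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-MAD statistic column(s) "
                      "from the distance")
    if not keep.any():
        raise ValueError("all statistic columns are constant in the table")
    return stats[:, keep] / mad[keep], obs[keep] / mad[keep], keep


def reject(table: ReferenceTable, observed, accept_count: int) -> PosteriorSample:
    """Keep the ``accept_count`` rows nearest to the observed vector.

    Distance is Euclidean over MAD-normalized statistics (normalization
    estimated from the reference table only).  Accepted rows receive
    Epanechnikov weights ``1 - (d/delta)^2`` with ``delta`` the largest
    accepted distance.
    """
    obs = _observed_values(observed)
    if obs.shape[0] != table.stats.shape[1]:
        raise ValueError("observed vector length does not match the table")
    if not 1 <= accept_count <= table.n:
        raise ValueError("accept_count must be in [1, table rows]")
    scaled, sobs, keep = _normalize_stats(table.stats, obs)
    d = np.sqrt(((scaled - sobs) ** 2).sum(axis=1))
    idx = np.argpartition(d, accept_count - 1)[:accept_count]
    idx = idx[np.argsort(d[idx], kind="stable")]
    delta = d[idx].max()
    if delta > 0:
        w = 1.0 - (d[idx] / delta) ** 2
    else:
        w = np.ones(accept_count)
    if not (w > 0).any():
        w = np.ones(accept_count)
    names = [n for n, k in zip(table.stat_names, keep) if k]
    return PosteriorSample(
        model_id=table.model_id,
        params=table.params.iloc[idx].reset_index(drop=True),
        weights=w,
        distances=d[idx],
        accept_count=accept_count,
        accept_fraction=accept_count / table.n,
        observed=sobs,
        stats=scaled[idx],
        stat_names=names,
    )


def _auto_log_params(params: pd.DataFrame, override) -> tuple[str, ...]:
    if override is not None:
        return tuple(override)
    return tuple(c for c in params.columns if (params[c] > 0).all())


def regression_adjust(sample: PosteriorSample,
                      log_params=None,
                      ridge: float = 1e-8) -> PosteriorSample:
    """Local-linear regression adjustment of the accepted draws.

    Each parameter (log-transformed when strictly positive, unless
    overridden) is regressed on the centred statistics ``s_i - s_obs``
    with the Epanechnikov weights; the fitted linear trend is subtracted
    so every draw is projected to the observed vector:
    ``phi*_i = phi_i - (s_i - s_obs)^T beta``.

    A rank-deficient design (e.g. exactly collinear statistics) is solved
    by least squares with a minimal-norm solution; if that fails, a tiny
    ridge penalty is applied with a warning.
    """
    p = sample.params.shape[1]
    if sample.accept_count <= sample.stats.shape[1] + 1:
        raise ValueError("need more accepted rows than statistics + 1 "
                         "for the local regression")
    logs = _auto_log_params(sample.params, log_params)
    X = np.column_stack([np.ones(sample.accept_count),
                         sample.stats - sample.observed])
    sw = np.sqrt(sample.weights)
    Xw = X * sw[:, None]
    adjusted = {}
    for col in sample.params.columns:
        y = sample.params[col].to_numpy(dtype=float)
        take_log = col in logs
        yt = np.log(y) if take_log else y
        try:
            beta, *_ = np.linalg.lstsq(Xw, yt * sw, rcond=None)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular regression design for {col!r}; "
                          "using ridge fallback")
            A = Xw.T @ Xw + ridge * np.eye(X.shape[1])
            beta = np.linalg.solve(A, Xw.T @ (yt * sw))
        resid = yt - X[:, 1:] @ beta[1:]
        adjusted[col] = np.exp(resid) if take_log else resid
    out = PosteriorSample(
        model_id=sample.model_id,
        params=pd.DataFrame(adjusted),
        weights=sample.weights.copy(),
        distances=sample.distances.copy(),
        accept_count=sample.accept_count,
        accept_fraction=sample.accept_fraction,
        observed=sample.observed.copy(),
        stats=sample.stats.copy(),
        stat_names=list(sample.stat_names),
        adjusted=True,
        log_params=logs,
    )
    return out


# ---------------------------------------------------------------------------
# posterior summaries


def weighted_quantile(values, q, weights) -> np.ndarray:
    """Weighted empirical quantiles.

    Follows the linear-interpolation rule of ``numpy.quantile``: with
    integer weights the result is identical to expanding each value
    ``w_i`` times.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    total = cum[-1]
    h = q * (total - 1.0) if total > 1.0 else q * 0.0
    j0 = np.floor(h)
    frac = h - j0
    i0 = np.searchsorted(cum, j0, side="right")
    i1 = np.searchsorted(cum, np.minimum(j0 + 1.0, total - 1.0), side="right")
    i0 = np.clip(i0, 0, len(v) - 1)
    i1 = np.clip(i1, 0, len(v) - 1)
    return v[i0] + frac * (v[i1] - v[i0])


def _weighted_kde_mode(values: np.ndarray, weights: np.ndarray,
                       grid_size: int = 512) -> float:
    """Mode of a Gaussian weighted KDE (Silverman bandwidth)."""
    from scipy.stats import gaussian_kde

    if np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    pad = 0.5 * kde.factor * values.std()
    grid = np.linspace(values.min() - pad, values.max() + pad, grid_size)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def posterior_summary(sample: PosteriorSample,
                      intervals=(0.05, 0.25, 0.95)) -> pd.DataFrame:
    """Weighted-KDE mode and central quantile intervals per parameter.

    The KDE runs on the same (possibly log) scale used for regression and
    the mode is transformed back.  Interval limits are weighted empirical
    quantiles at ``(1 - p)/2`` and ``(1 + p)/2`` for each requested
    central probability ``p``.
    """
    if sample.ess < 10:
        warnings.warn(f"effective sample size {sample.ess:.1f} < 10; "
                      "posterior summaries are unreliable")
    logs = sample.log_params if sample.adjusted \
        else _auto_log_params(sample.params, None)
    rows = []
    for col in sample.params.columns:
        y = sample.params[col].to_numpy(dtype=float)
        take_log = col in logs and (y > 0).all()
        yt = np.log(y) if take_log else y
        mode_t = _weighted_kde_mode(yt, sample.weights)
        mode = float(np.exp(mode_t)) if take_log else mode_t
        row = {"parameter": col, "mode": mode}
        for p in intervals:
            lo, hi = weighted_quantile(y, [(1 - p) / 2, (1 + p) / 2],
                                       sample.weights)
            row[f"q{int(round(100 * p))}_low"] = lo
            row[f"q{int(round(100 * p))}_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelPosterior:
    """Posterior model probabilities by rejection share and by regression."""

    rejection: dict[str, float]
    regression: dict[str, float]
    accepted_counts: dict[str, int]
    accept_count: int

    def __post_init__(self):
        for probs in (self.rejection, self.regression):
            total = sum(probs.values())
            if total > 0 and abs(total - 1.0) > 1e-9:
                raise ValueError("model probabilities must sum to 1")


def model_posterior(tables: list[ReferenceTable], observed,
                    accept_count: int) -> ModelPosterior:
    """Compare >= 2 models against one observed vector.

    Rows of all tables are pooled, normalized by the pooled MAD, and the
    ``accept_count`` nearest rows are kept.  The rejection estimate is the
    per-model share of accepted rows (corrected for unequal table sizes);
    the regression estimate is an Epanechnikov-weighted multinomial
    logistic regression of the model label on the centred statistics,
    evaluated at the observed vector.
    """
    if len(tables) < 2:
        raise ValueError("need at least two models to compare")
    stat_names = tables[0].stat_names
    for t in tables[1:]:
        if t.stat_names != stat_names:
            raise ValueError("tables use different statistic sets")
    obs = _observed_values(observed)
    pooled = np.vstack([t.stats for t in tables])
    labels = np.concatenate([np.full(t.n, i) for i, t in enumerate(tables)])
    sizes = np.array([t.n for t in tables], dtype=float)

    scaled, sobs, _ = _normalize_stats(pooled, obs)
    d = np.sqrt(((scaled - sobs) ** 2).sum(axis=1))
    idx = np.argpartition(d, accept_count - 1)[:accept_count]
    delta = d[idx].max()
    w = 1.0 - (d[idx] / delta) ** 2 if delta > 0 else np.ones(len(idx))
    lab = labels[idx]

    counts = {t.model_id: int((lab == i).sum()) for i, t in enumerate(tables)}
    # rejection proportions, corrected for unequal table sizes
    share = np.array([counts[t.model_id] / sizes[i] for i, t in enumerate(tables)])
    share = share / share.sum() if share.sum() > 0 else share
    rejection = {t.model_id: float(share[i]) for i, t in enumerate(tables)}

    present = np.unique(lab)
    if len(present) == 1:
        regression = {t.model_id: (1.0 if i == present[0] else 0.0)
                      for i, t in enumerate(tables)}
    else:
        from sklearn.linear_model import LogisticRegression

        X = scaled[idx] - sobs
        clf = LogisticRegression(C=np.inf, max_iter=5000)
        pos = w > 0
        if pos.sum() < len(present) + 1 or len(np.unique(lab[pos])) < len(present):
            pos = np.ones(len(idx), dtype=bool)
            w = np.maximum(w, 1e-12)
        clf.fit(X[pos], lab[pos], sample_weight=w[pos])
        proba = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        regression = {t.model_id: 0.0 for t in tables}
        for cls, p in zip(clf.classes_, proba):
            regression[tables[int(cls)].model_id] = float(p)
    return ModelPosterior(rejection=rejection, regression=regression,
                          accepted_counts=counts, accept_count=accept_count)


# ---------------------------------------------------------------------------
# constant-size sampling-bias test


@dataclass
class BiasTestReport:
    """One-sided lower-tail P-values of per-layer pairwise difference."""

    layers: list[str]                 # oldest -> youngest
    observed_pd: np.ndarray
    p_values: np.ndarray
    null_pd: np.ndarray               # (n_reps, n_layers)
    n_reps: int
    null_config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"layer": self.layers,
                             "observed_Pi": self.observed_pd,
                             "P": self.p_values}).set_index("layer")


def constant_null_spec(n_low: float = 30_000, n_high: float = 50_000,
                       mu: str | float = "prior") -> ModelSpec:
    """Constant-size null model for the sampling-bias test.

    ``mu`` is either ``"prior"`` (drawn per replicate from the mutation
    prior, 0.01-0.2 mutations/site/myr) or a fixed rate in the same units.
    """
    from .demography import default_model

    spec = default_model("constant")
    spec.priors["N"] = Prior("N", "uniform", n_low, n_high, units="females")
    if mu != "prior":
        rate = float(mu)
        spec.priors["mu"] = Prior("mu", "uniform", rate * (1 - 1e-9), rate * (1 + 1e-9),
                                  units="mutations/site/myr")
    return spec


def bias_test(observed_pd, design: SamplingDesign, n_reps: int = 10_000,
              seed: int = 0, null_spec: ModelSpec | None = None) -> BiasTestReport:
    """Can a constant-size population produce such low diversity by chance?

    ``observed_pd`` is the per-layer mean pairwise difference ordered
    oldest to youngest.  Each replicate draws the null parameters, runs the
    full serial design, and records per-layer Pi; the one-sided lower-tail
    P-value uses the pseudo-count form
    ``P = (1 + #{sim Pi <= obs Pi}) / (1 + n_reps)``.
    """
    if n_reps < 100:
        raise ValueError("use at least 100 replicates")
    observed_pd = np.asarray(observed_pd, dtype=float)
    if observed_pd.shape[0] != len(design.layers):
        raise ValueError("one observed Pi per layer required")
    spec = null_spec if null_spec is not None else constant_null_spec()
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(x % 2**31) for x in ss.generate_state(2))
    params = sample_prior_batch(spec, n_reps, s1)
    _, _, PD, _ = simulate_summaries(spec, design, params, s2)
    PD = PD.sum(axis=1)  # combined over loci
    p = (1.0 + (PD <= observed_pd[None, :]).sum(axis=0)) / (1.0 + n_reps)
    return BiasTestReport(
        layers=design.layer_labels()[::-1],
        observed_pd=observed_pd,
        p_values=p,
        null_pd=PD,
        n_reps=n_reps,
        null_config={"model": spec.model_id,
                     "priors": {k: (pr.kind, pr.a, pr.b) for k, pr in spec.priors.items()}},
    )
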