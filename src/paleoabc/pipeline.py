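"""End-to-end orchestration: statistics -> networks -> bias test -> ABC.

:func:`run_analysis` reproduces the full analysis from a single
configuration: per-layer diversity statistics, temporal parsimony
networks, the constant-size sampling-bias test, ABC posterior fits per
model (optionally the two-stage protocol where the closed-model
bottleneck-time posterior sets the open model's split-time window), and
the three-model comparison.  Every stage writes plain-text artifacts plus
a provenance log with resolved priors and seeds.

Observed data can enter as sequences (FASTA + metadata TSV), as a built-in
scenario name, or as a pre-computed per-layer statistics TSV (columns
``layer, age, S, Pi``) — the latter makes the headline reanalysis run from
printed numbers alone, in which case sequence-level stages (networks) are
skipped.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .abc import (bias_test, build_reference_table, model_posterior,
                  posterior_summary, reject, regression_adjust)
from .demography import MODELS, Prior, default_model
from .datasets import pymva_shor_design
from .network import network_from_alignment, write_dot, write_graphml
from .seqdata import read_serial_fasta, SamplingDesign
from .sumstats import layer_stats_table, layer_summary, summary_vector_from_stats
from .synthetic_data import scenario, simulate_scenario

__all__ = ["RunConfig", "run_analysis", "load_observed_stats"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    out_dir: str
    seed: int = 1
    # exactly one input route:
    scenario_name: str | None = None
    fasta: str | None = None
    metadata: str | None = None
    observed_stats: str | None = None      # TSV: layer, age, S, Pi
    # model fitting
    fit_models: tuple[str, ...] = ("closed_bottleneck",)
    compare_models: tuple[str, ...] = MODELS
    n_sims_fit: int = 20_000
    n_sims_compare: int = 10_000
    accept_fit: int = 500
    accept_compare: int = 300
    two_stage: bool = False
    # other stages
    n_bias_reps: int = 10_000
    network_confidence: float = 0.95
    skip_existing: bool = False

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        for key in ("fit_models", "compare_models"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def load_observed_stats(path: str, design: SamplingDesign):
    """Read a per-layer statistics TSV (columns layer, age, S, Pi)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("age", ascending=False)  # oldest first
    return df


def _observed_from_config(cfg: RunConfig):
    """Resolve the observed data: (alignment or None, design, vec builder)."""
    if cfg.scenario_name:
        scn = scenario(cfg.scenario_name)
        aln = simulate_scenario(scn, seed=cfg.seed)
        return aln, scn.design, None
    if cfg.fasta:
        aln = read_serial_fasta(cfg.fasta, cfg.metadata)
        ages = sorted({(a, sum(1 for x in aln.ages if x == a)) for a in aln.ages})
        design = SamplingDesign(layers=list(ages), total_length=aln.length,
                                loci=list(aln.loci))
        return aln, design, None
    if cfg.observed_stats:
        design = pymva_shor_design()
        df = load_observed_stats(cfg.observed_stats, design)
        return None, design, df
    raise ValueError("config needs a scenario, a FASTA+metadata pair, "
                     "or an observed-statistics TSV")


def _vec(aln, stats_df, design, stat_set):
    if aln is not None:
        return layer_summary(aln, stat_set)
    return summary_vector_from_stats(
        S=stats_df["S"].to_numpy(), Pi=stats_df["Pi"].to_numpy(),
        L=design.total_length, layer_labels=[str(x) for x in stats_df["layer"]],
        stat_set=stat_set)


def run_analysis(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns the artifact paths."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    rng = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(s % 2**31) for name, s in zip(
        ("bias", "fit", "compare"), rng.generate_state(3))}
    artifacts: dict[str, str] = {}
    log: dict = {"version": __version__, "seed": cfg.seed,
                 "derived_seeds": seeds, "config": asdict(cfg)}

    aln, design, stats_df = _observed_from_config(cfg)

    def _path(name):
        return os.path.join(cfg.out_dir, name)

    def _skip(path):
        return cfg.skip_existing and os.path.exists(path)

    # 1. per-layer statistics table
    stats_path = _path("layer_stats.tsv")
    if not _skip(stats_path):
        if aln is not None:
            layer_stats_table(aln).to_csv(stats_path, sep="\t", index=False)
        else:
            stats_df.to_csv(stats_path, sep="\t", index=False)
    artifacts["layer_stats"] = stats_path

    # 2. temporal parsimony networks (needs sequences)
    if aln is not None:
        gml = _path("temporal_network.graphml")
        if not _skip(gml):
            net = network_from_alignment(aln, cfg.network_confidence)
            write_graphml(net, gml)
            write_dot(net, _path("temporal_network.dot"))
            log["network"] = {
                "limit": net.networks[net.layers[0]].limit,
                "haplotypes_per_layer": net.layer_haplotype_counts(),
            }
        artifacts["network_graphml"] = gml
    else:
        log["network"] = "skipped (no sequences supplied)"

    # 3. constant-size sampling-bias test
    bias_path = _path("bias_test.tsv")
    if not _skip(bias_path):
        obs12 = _vec(aln, stats_df, design, "estimation12")
        pi_obs = np.array([v for _, s, v in obs12.entries if s == "Pi"])
        report = bias_test(pi_obs, design, n_reps=cfg.n_bias_reps,
                           seed=seeds["bias"])
        report.to_frame().to_csv(bias_path, sep="\t")
        log["bias_test"] = {"n_reps": cfg.n_bias_reps,
                            "P": dict(zip(report.layers, report.p_values.tolist()))}
    artifacts["bias_test"] = bias_path

    # 4. ABC posterior fits
    obs12 = _vec(aln, stats_df, design, "estimation12")
    closed_tb = None
    for model_id in cfg.fit_models:
        fit_path = _path(f"posterior_{model_id}.tsv")
        artifacts[f"posterior_{model_id}"] = fit_path
        if _skip(fit_path):
            continue
        spec = default_model(model_id)
        if cfg.two_stage and model_id == "open_migration" and closed_tb is not None:
            lo, hi = closed_tb
            spec.priors["T_s"] = Prior("T_s", "uniform", max(lo, 1.0), hi,
                                       units="generations")
            log["two_stage_T_s_window"] = [lo, hi]
        table = build_reference_table(spec, design, "estimation12",
                                      n_sims=cfg.n_sims_fit,
                                      seed=seeds["fit"])
        post = regression_adjust(reject(table, obs12, cfg.accept_fit))
        summary = posterior_summary(post)
        summary.to_csv(fit_path, sep="\t")
        log.setdefault("fits", {})[model_id] = {
            "n_sims": cfg.n_sims_fit, "accept": cfg.accept_fit,
            "n_failed_redrawn": table.n_failed,
            "priors": {k: (p.kind, p.a, p.b) for k, p in spec.priors.items()},
        }
        if model_id == "closed_bottleneck":
            row = summary.loc["T_b"]
            closed_tb = (float(row["q25_low"]), float(row["q25_high"]))

    # 5. model comparison
    cmp_path = _path("model_posterior.tsv")
    if not _skip(cmp_path):
        obs8 = _vec(aln, stats_df, design, "comparison8")
        tables = [build_reference_table(default_model(m), design, "comparison8",
                                        n_sims=cfg.n_sims_compare,
                                        seed=seeds["compare"] + i)
                  for i, m in enumerate(cfg.compare_models)]
        mp = model_posterior(tables, obs8, cfg.accept_compare)
        import pandas as pd

        pd.DataFrame({"model": list(mp.rejection),
                      "P_rejection": list(mp.rejection.values()),
                      "P_regression": list(mp.regression.values()),
                      "accepted": list(mp.accepted_counts.values()),
                      }).to_csv(cmp_path, sep="\t", index=False)
        log["model_comparison"] = {"n_sims": cfg.n_sims_compare,
                                   "accept": cfg.accept_compare,
                                   "regression": mp.regression}
    artifacts["model_posterior"] = cmp_path

    prov = _path("provenance.json")
    with open(prov, "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    artifacts["provenance"] = prov
    return artifacts
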