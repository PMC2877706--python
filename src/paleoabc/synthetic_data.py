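"""Synthetic serially sampled datasets with known generating parameters.

Built-in scenarios emulate the statistical structure of the Pymva Shor
collared-lemming series (4 temporal layers, 10/20/20/14 sequences, 708 bp
two-locus alignment with K2P + gamma heterogeneity) under each of the
three demographic models, so every analysis stage can be exercised and
parameter recovery can be tested without any external data.

Fixed parameter values for ``pymva_like_bottleneck`` sit at the posterior
modes of the package's headline reanalysis (bottleneck at 14,000
generations BP; modern size 11,000; sizes ~3,700 / ~28,000 on the recent
and ancient side of the event; 5.6e-5 mutations/locus/generation).  They
are a plausible generating point for recovery tests, not ground truth.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

from .demography import (ModelSpec, ParameterDraw, build_history,
                         build_mutation_model, default_model)
from .seqdata import SamplingDesign, SerialAlignment, write_serial_fasta
from .serialcoal import simulate_dataset
from .datasets import pymva_shor_design

__all__ = ["Scenario", "scenario", "SCENARIOS", "generate", "simulate_scenario"]


@dataclass
class Scenario:
    """A fully resolved simulation setting (no free priors)."""

    name: str
    spec: ModelSpec
    draw: ParameterDraw
    design: SamplingDesign
    truth: dict = field(default_factory=dict)


def _bottleneck_draw() -> tuple[ParameterDraw, dict]:
    mu_locus = 5.6e-5                      # per locus (708 bp) per generation
    mu_myr = mu_locus / 708 * 1e6          # mutations/site/myr
    draw = ParameterDraw("closed_bottleneck", {
        "N_modern": 11_000.0, "T_b": 14_000.0,
        "fNe_after": 3_700.0, "fNe_before": 28_000.0, "mu": mu_myr,
    })
    truth = dict(draw.values,
                 k=28_000.0 / 3_700.0,
                 growth_rate=math.log(11_000.0 / 3_700.0) / 14_000.0,
                 mu_locus=mu_locus)
    return draw, truth


_DEMO_MU_MYR = 5.6e-5 / 708 * 1e6  # same per-site rate for all scenarios


def _constant_draw() -> tuple[ParameterDraw, dict]:
    draw = ParameterDraw("constant", {"N": 40_000.0, "mu": _DEMO_MU_MYR})
    return draw, dict(draw.values)


def _open_draw() -> tuple[ParameterDraw, dict]:
    draw = ParameterDraw("open_migration", {
        "T_s": 13_000.0, "N1": 5_000.0, "N2": 5_000.0, "N3": 5_000.0,
        "N4": 5_000.0, "T_stop": 500.0, "m_high": 0.01, "m_low": 1e-5,
        "mu": _DEMO_MU_MYR,
    })
    return draw, dict(draw.values)


SCENARIOS = {
    "pymva_like_bottleneck": ("closed_bottleneck", _bottleneck_draw),
    "constant_null": ("constant", _constant_draw),
    "open_migration_demo": ("open_migration", _open_draw),
}


def scenario(name: str) -> Scenario:
    """A built-in, fully resolved scenario by name."""
    try:
        model_id, maker = SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; known: "
                       f"{sorted(SCENARIOS)}") from None
    draw, truth = maker()
    return Scenario(name=name, spec=default_model(model_id), draw=draw,
                    design=pymva_shor_design(), truth=truth)


def simulate_scenario(scn: Scenario, seed: int = 0) -> SerialAlignment:
    """One simulated alignment under the scenario (deterministic per seed)."""
    hist = build_history(scn.spec, scn.draw)
    mm = build_mutation_model(scn.spec, scn.draw)
    return simulate_dataset(hist, mm, scn.design, seed=seed)


def generate(scn: Scenario, seed: int, out_dir) -> dict:
    """Write a scenario dataset: FASTA + metadata TSV + truth JSON.

    The truth sidecar records the generating parameters (and derived
    quantities) so recovery tests can compare posteriors against them.
    Returns the file paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    aln = simulate_scenario(scn, seed)
    paths = {
        "fasta": os.path.join(out_dir, f"{scn.name}_{seed}.fasta"),
        "metadata": os.path.join(out_dir, f"{scn.name}_{seed}.tsv"),
        "truth": os.path.join(out_dir, f"{scn.name}_{seed}.truth.json"),
    }
    write_serial_fasta(aln, paths["fasta"], paths["metadata"])
    with open(paths["truth"], "w") as fh:
        json.dump({"scenario": scn.name, "seed": seed, "model": scn.spec.model_id,
                   "parameters": scn.truth}, fh, indent=2)
    return paths
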