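"""Synthetic EMT expression compendia with known ground truth.

Emulates a collection of EMT-induction microarray datasets: each
dataset carries an EMT strength *s*; up-signature genes shift by
log₂FC ~ Normal(+a·s, σ) and down-signature genes by Normal(−a·s, σ).
Stat3 is universally but modestly up-regulated (Normal(b, σ_b),
independent of s) while Sox2 and the neuron-projection markers respond
only above a strength threshold (Normal(c·max(0, s−s₀), σ_c)). Datasets
are emitted as raw linear replicate/control columns, so the
meta-analysis stage must do the replicate averaging and control
normalization itself. Truth records each dataset's s and every drawn
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..meta import RawDataset

DEFAULT_UP = ["Vim", "Cdh2", "Fn1", "Zeb1", "Zeb2", "Snai1", "Slug", "Twist1",
              "Mmp2", "Col1a1"]
DEFAULT_DOWN = ["Cdh1", "Epcam", "Ocln", "Cldn3", "Cldn4", "Cldn7", "Dsp",
                "Krt18", "Krt19", "Tjp1"]
STRONG_EMT_RESPONDERS = ["Sox2", "Map1b", "Reln", "Robo1", "Tubb3"]
NEUTRAL_FILLERS = ["Actb", "B2m", "Hprt1", "Tbp", "Rpl13a", "Gusb"]


def default_gene_list() -> list[str]:
    return DEFAULT_UP + DEFAULT_DOWN + ["Stat3"] + STRONG_EMT_RESPONDERS + NEUTRAL_FILLERS


@dataclass
class CompendiumConfig:
    """Study conditions of the synthetic compendium.

    Defaults: 30 datasets with EMT strength s ~ Uniform(0.2, 2); effect
    slope a = 1 with gene noise σ = 0.3; Stat3 log₂FC ~ Normal(0.8, 0.2)
    (a universal ~150–200% up-regulation); Sox2 and the projection
    markers respond as Normal(max(0, s−1), 0.3), i.e. only in
    strongly-induced datasets; 3 replicates per treatment and 3 control
    replicates, emitted on a linear scale.
    """

    n_datasets: int = 30
    genes: list[str] = field(default_factory=default_gene_list)
    up_genes: list[str] = field(default_factory=lambda: list(DEFAULT_UP))
    down_genes: list[str] = field(default_factory=lambda: list(DEFAULT_DOWN))
    s_range: tuple[float, float] = (0.2, 2.0)
    a: float = 1.0
    sigma: float = 0.3
    stat3_b: float = 0.8
    stat3_sigma: float = 0.2
    sox2_c: float = 1.0
    sox2_s0: float = 1.0
    sox2_sigma: float = 0.3
    strong_responders: list[str] = field(default_factory=lambda: list(STRONG_EMT_RESPONDERS))
    replicates: int = 3
    n_controls: int = 3
    replicate_log2_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        for name, v in (("sigma", self.sigma), ("stat3_sigma", self.stat3_sigma),
                        ("sox2_sigma", self.sox2_sigma)):
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        for g in ("Stat3", *self.strong_responders, *self.up_genes, *self.down_genes):
            if self.genes.count(g) != 1:
                raise ValueError(f"gene {g} must appear exactly once in the gene list")


def generate_compendium(
    config: CompendiumConfig,
) -> tuple[list[RawDataset], pd.DataFrame]:
    """Simulate the compendium.

    Returns raw datasets (linear-scale replicate/control columns) and a
    truth table with one row per dataset: id, s, and the drawn Stat3 and
    Sox2 log₂ effects. Seeded and deterministic.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    up = set(config.up_genes)
    down = set(config.down_genes)
    strong = set(config.strong_responders)

    datasets: list[RawDataset] = []
    truth_rows = []
    for d in range(config.n_datasets):
        ds_id = f"DS{d:03d}"
        s = float(rng.uniform(*config.s_range))
        base = 2.0 ** rng.uniform(4.0, 9.0, size=len(genes))
        effects = np.empty(len(genes))
        stat3_eff = sox2_eff = float("nan")
        for i, g in enumerate(genes):
            if g == "Stat3":
                e = rng.normal(config.stat3_b, config.stat3_sigma)
                stat3_eff = float(e)
            elif g in strong:
                e = rng.normal(config.sox2_c * max(0.0, s - config.sox2_s0),
                               config.sox2_sigma)
                if g == "Sox2":
                    sox2_eff = float(e)
            elif g in up:
                e = rng.normal(config.a * s, config.sigma)
            elif g in down:
                e = rng.normal(-config.a * s, config.sigma)
            else:
                e = rng.normal(0.0, config.sigma)
            effects[i] = e

        cols = {}
        meta_rows = []
        for r in range(config.n_controls):
            name = f"ctrl_{r}"
            noise = rng.normal(0, config.replicate_log2_sd, size=len(genes))
            cols[name] = base * 2.0**noise
            meta_rows.append((name, "control", r, True))
        for r in range(config.replicates):
            name = f"emt_{r}"
            noise = rng.normal(0, config.replicate_log2_sd, size=len(genes))
            cols[name] = base * 2.0 ** (effects + noise)
            meta_rows.append((name, "EMT", r, False))

        expr = pd.DataFrame(cols, index=genes)
        meta = pd.DataFrame(
            meta_rows, columns=["sample", "treatment", "replicate", "is_control"]
        )
        datasets.append(RawDataset(ds_id, expr, meta, scale="linear"))
        truth_rows.append((ds_id, s, stat3_eff, sox2_eff))

    truth = pd.DataFrame(
        truth_rows, columns=["dataset", "s", "stat3_log2fc", "sox2_log2fc"]
    )
    return datasets, truth
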