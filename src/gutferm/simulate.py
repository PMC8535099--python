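"""Synthetic batch-fermentation experiments with known ground truth.

The generator emulates a 24 h in vitro colon fermentation: 3 substrates
(a fast reference prebiotic, a slower test fiber, and a blank control)
x 4 sampling times x 2 independent runs, measured in technical
triplicate (qPCR) and duplicate (GC-MS).

Taxa follow a saturating (Michaelis-type) ramp on the Log10 scale::

    L(tau) = baseline + effect * tau / (tau + K) + Normal(0, sd)

with the half-time K per treatment (6 h for the fast substrate, 16 h for
the slow one), reproducing the late-bloomer pattern of a fiber whose
essential-oil fraction delays microbial growth.  VOC concentrations are
coupled to the noiseless mean taxa trajectories through a signed matrix
A (mg/kg per unit relative linear-load increase)::

    C(tau) = baseline_v + sum_t A[v, t] * (10^(effect_t*ramp) - 1) + noise

clipped at 0 with a non-detect flag.  Default baselines and effect sizes
are taken from the published qPCR panel scale (Log10 GCN/mL loads and
their 24 h treatment deltas); couplings put short-chain fatty acids on
the saccharolytic taxa and proteolytic markers (branched-chain acids,
skatole, indole) on enterobacteria and Clostridium group I.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .design import DesignRegistry
from .errors import ValidationError
from .io import TaxonAbundanceTable, VocClassMap, VocTable

# Baseline Log10 GCN/mL loads of the core panel (printed-table scale).
DEFAULT_TAXA_BASELINE: dict[str, float] = {
    "Eubacteria": 8.27, "Firmicutes": 7.37, "Bacteroidetes": 6.41,
    "Lactobacillales": 6.67, "Bifidobacteriaceae": 7.21,
    "Enterobacteriaceae": 6.77, "Clostridium gI": 2.13,
    "Clostridium gIV": 7.43, "E. coli": 3.96, "F. prausnitzii": 7.53,
    "A. muciniphila": 4.19,
}

# 24 h Log10 deltas vs baseline per treatment (asymptotic effect sizes,
# from the published panel's end-point arithmetic).
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "FOS": {"Eubacteria": 0.69, "Firmicutes": 1.06, "Bacteroidetes": 1.85,
            "Lactobacillales": 1.56, "Bifidobacteriaceae": 0.75,
            "Enterobacteriaceae": -0.46, "Clostridium gI": 0.22,
            "Clostridium gIV": -0.23, "E. coli": -0.15,
            "F. prausnitzii": 1.04, "A. muciniphila": 0.39},
    "FLS": {"Eubacteria": 0.55, "Firmicutes": 1.31, "Bacteroidetes": 1.34,
            "Lactobacillales": 1.50, "Bifidobacteriaceae": 0.90,
            "Enterobacteriaceae": -0.22, "Clostridium gI": 2.20,
            "Clostridium gIV": -0.86, "E. coli": 0.07,
            "F. prausnitzii": 0.59, "A. muciniphila": 0.76},
    "BC": {"Eubacteria": 0.07, "Firmicutes": -0.21, "Bacteroidetes": -1.64,
           "Lactobacillales": -0.04, "Bifidobacteriaceae": -2.01,
           "Enterobacteriaceae": 1.56, "Clostridium gI": 4.03,
           "Clostridium gIV": -0.06, "E. coli": 2.83,
           "F. prausnitzii": -1.04, "A. muciniphila": -0.99},
}

#: Ramp half-times: fast reference substrate, slow test fiber, blank drift.
DEFAULT_RAMP_HALFTIME_H: dict[str, float] = {"FOS": 6.0, "FLS": 16.0,
                                             "BC": 10.0}

# The 14 prebiotic-activity-related volatiles and their classes.
PRE_VOC_CLASS_MAP: dict[str, str] = {
    "Acetic acid": "SCFA", "Propanoic acid": "SCFA", "Butanoic acid": "SCFA",
    "Pentanoic acid": "MCFA", "Hexanoic acid": "MCFA",
    "Heptanoic acid": "MCFA", "Octanoic acid": "MCFA",
    "Nonanoic acid": "MCFA", "n-Decanoic acid": "MCFA",
    "Propanoic acid, 2-methyl": "BCFA", "Butanoic acid, 3-methyl": "BCFA",
    "Pentanoic acid, 3-methyl": "BCFA",
    "Indole": "indole", "Skatole": "indole",
}

# Baseline concentrations, mg/kg, typical of fecal fermentation supernatant.
DEFAULT_VOC_BASELINE: dict[str, float] = {
    "Acetic acid": 45.0, "Propanoic acid": 18.0, "Butanoic acid": 12.0,
    "Pentanoic acid": 2.5, "Hexanoic acid": 1.8, "Heptanoic acid": 0.6,
    "Octanoic acid": 0.9, "Nonanoic acid": 0.4, "n-Decanoic acid": 0.5,
    "Propanoic acid, 2-methyl": 1.5, "Butanoic acid, 3-methyl": 1.2,
    "Pentanoic acid, 3-methyl": 0.8, "Indole": 1.0, "Skatole": 0.6,
}

# Signed coupling (compound, taxon) -> mg/kg per unit relative linear-load
# increase.  SCFAs ride on the saccharolytic guild; BCFAs/indoles on the
# proteolytic one (small magnitudes where the linear increase is huge).
DEFAULT_COUPLING: dict[tuple[str, str], float] = {
    ("Acetic acid", "Lactobacillales"): 1.2,
    ("Acetic acid", "Bifidobacteriaceae"): 1.5,
    ("Acetic acid", "Bacteroidetes"): 0.4,
    ("Acetic acid", "F. prausnitzii"): 0.8,
    ("Propanoic acid", "Bacteroidetes"): 0.5,
    ("Propanoic acid", "Lactobacillales"): 0.5,
    ("Propanoic acid", "F. prausnitzii"): 0.3,
    ("Butanoic acid", "F. prausnitzii"): 1.0,
    ("Butanoic acid", "Lactobacillales"): 0.8,
    ("Butanoic acid", "Bifidobacteriaceae"): 0.4,
    ("Pentanoic acid", "Bifidobacteriaceae"): 0.15,
    ("Hexanoic acid", "Bifidobacteriaceae"): 0.15,
    ("n-Decanoic acid", "Bifidobacteriaceae"): 0.15,
    ("Heptanoic acid", "Bifidobacteriaceae"): 0.08,
    ("Octanoic acid", "Bifidobacteriaceae"): 0.08,
    ("Nonanoic acid", "Bifidobacteriaceae"): 0.08,
    ("Propanoic acid, 2-methyl", "Enterobacteriaceae"): 0.08,
    ("Propanoic acid, 2-methyl", "Clostridium gI"): 0.0015,
    ("Propanoic acid, 2-methyl", "Lactobacillales"): -0.02,
    ("Butanoic acid, 3-methyl", "Enterobacteriaceae"): 0.08,
    ("Butanoic acid, 3-methyl", "Clostridium gI"): 0.0015,
    ("Butanoic acid, 3-methyl", "Lactobacillales"): -0.02,
    ("Pentanoic acid, 3-methyl", "Enterobacteriaceae"): 0.06,
    ("Pentanoic acid, 3-methyl", "Clostridium gI"): 0.001,
    ("Indole", "E. coli"): 0.01,
    ("Indole", "Enterobacteriaceae"): 0.03,
    ("Skatole", "Enterobacteriaceae"): 0.05,
    ("Skatole", "Clostridium gI"): 0.001,
    ("Skatole", "Lactobacillales"): -0.01,
}

#: Planted couplings the correlation stage is expected to recover: strong,
#: single-taxon-dominated associations used for sign-recovery checks.
BENCHMARK_COUPLINGS: tuple[tuple[str, str], ...] = (
    ("Butanoic acid", "Lactobacillales"),
    ("Skatole", "Enterobacteriaceae"),
)

SCENARIOS = ("prebiotic_fast", "prebiotic_slow", "null")


@dataclass
class SyntheticConfig:
    """Generative model parameters; ``seed`` is explicit and required."""

    seed: int
    registry: DesignRegistry = field(default_factory=DesignRegistry)
    taxa_baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAXA_BASELINE))
    effect: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(e) for g, e in DEFAULT_EFFECTS.items()})
    ramp_halftime_h: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RAMP_HALFTIME_H))
    taxon_noise_sd: float = 0.15
    voc_baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VOC_BASELINE))
    coupling: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING))
    voc_noise_sd: float = 0.25
    scenario: str = "custom"

    def __post_init__(self) -> None:
        if self.taxon_noise_sd < 0 or self.voc_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if any(k <= 0 for k in self.ramp_halftime_h.values()):
            raise ValidationError("ramp_halftime_h must be > 0")
        missing = set(self.registry.treatments) - set(self.ramp_halftime_h)
        if missing:
            raise ValidationError(f"no ramp half-time for {sorted(missing)}")

    def class_map(self) -> VocClassMap:
        return VocClassMap({c: PRE_VOC_CLASS_MAP.get(c, "other")
                            for c in self.voc_baseline})


def scenario_config(name: str, seed: int) -> SyntheticConfig:
    """A ready-made configuration for a named scenario.

    ``prebiotic_fast`` benchmarks the fast reference substrate (FOS),
    ``prebiotic_slow`` the slow test fiber (FLS); ``null`` zeroes all
    effects and couplings (noise kept) for type-I-error calibration.
    """
    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; pick from {SCENARIOS}")
    cfg = SyntheticConfig(seed=seed, scenario=name)
    if name == "null":
        cfg = null_scenario(cfg)
        cfg.scenario = "null"
    return cfg


def null_scenario(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of ``config`` with all effects and couplings zeroed (idempotent)."""
    return dataclasses.replace(
        config,
        effect={g: {t: 0.0 for t in e} for g, e in config.effect.items()},
        coupling={k: 0.0 for k in config.coupling},
        scenario="null",
    )


def with_null_vocs(config: SyntheticConfig, n_compounds: int,
                   baseline: float = 5.0) -> SyntheticConfig:
    """Replace the VOC panel with ``n_compounds`` uncoupled compounds.

    Used for type-I-error calibration of the ANOVA screen, where a large
    panel of pure-noise compounds is needed.
    """
    width = len(str(n_compounds))
    return dataclasses.replace(
        config,
        voc_baseline={f"null_voc_{i:0{width}d}": baseline
                      for i in range(1, n_compounds + 1)},
        coupling={},
    )


def _ramp(tau: np.ndarray, k: float) -> np.ndarray:
    return tau / (tau + k)


def simulate_fermentation(config: SyntheticConfig,
                          ) -> tuple[TaxonAbundanceTable, VocTable, dict]:
    """Generate one experiment; same seed gives bit-identical tables.

    Returns the replicate-level taxa table (qPCR technical replication),
    the VOC table in mg/kg (GC-MS technical replication), and a ground-
    truth record with the planted effects, coupling signs and benchmark
    couplings.
    """
    reg = config.registry
    rng = np.random.default_rng(config.seed)
    taxa = sorted(config.taxa_baseline)
    compounds = sorted(config.voc_baseline)

    taxa_rows = []
    for taxon, treatment, time_h in itertools.product(
            taxa, reg.treatments, reg.time_points_h):
        base = config.taxa_baseline[taxon]
        eff = config.effect.get(treatment, {}).get(taxon, 0.0)
        k = config.ramp_halftime_h[treatment]
        mean = base + eff * _ramp(np.float64(time_h), k)
        for exp, rep in itertools.product(
                range(1, reg.experimental_replicas + 1),
                range(1, reg.technical_replicas_qpcr + 1)):
            val = mean + rng.normal(0.0, config.taxon_noise_sd)
            taxa_rows.append(dict(taxon=taxon, treatment=treatment,
                                  time_h=time_h, experiment=exp,
                                  replicate=rep,
                                  log10_gcn=float(np.clip(val, 0.0, 12.0))))
    taxa_table = TaxonAbundanceTable(pd.DataFrame(taxa_rows))

    voc_rows = []
    for comp, treatment, time_h in itertools.product(
            compounds, reg.treatments, reg.time_points_h):
        k = config.ramp_halftime_h[treatment]
        signal = config.voc_baseline[comp]
        for taxon in taxa:
            a = config.coupling.get((comp, taxon), 0.0)
            if a == 0.0:
                continue
            eff = config.effect.get(treatment, {}).get(taxon, 0.0)
            # relative linear-load increase of the noiseless mean trajectory
            signal += a * (10.0 ** (eff * _ramp(np.float64(time_h), k)) - 1.0)
        for exp, rep in itertools.product(
                range(1, reg.experimental_replicas + 1),
                range(1, reg.technical_replicas_gcms + 1)):
            val = signal + rng.normal(0.0, config.voc_noise_sd)
            detected = val > 0.0
            voc_rows.append(dict(compound=comp, treatment=treatment,
                                 time_h=time_h, experiment=exp,
                                 replicate=rep,
                                 value=float(max(val, 0.0)),
                                 detected=bool(detected)))
    voc_table = VocTable(pd.DataFrame(voc_rows), unit="mg_per_kg")

    truth: dict[str, Any] = {
        "scenario": config.scenario,
        "seed": config.seed,
        "effects": {g: dict(e) for g, e in config.effect.items()},
        "ramp_halftime_h": dict(config.ramp_halftime_h),
        "coupling": {f"{c}|{t}": v for (c, t), v in config.coupling.items()},
        "coupling_signs": {f"{c}|{t}": int(np.sign(v))
                           for (c, t), v in config.coupling.items() if v != 0},
        "benchmark_couplings": [list(bc) for bc in BENCHMARK_COUPLINGS
                                if config.coupling.get(bc, 0.0) != 0.0],
        "benchmark_treatment": {"prebiotic_fast": "FOS",
                                "prebiotic_slow": "FLS"}.get(config.scenario),
        "blank_treatment": "BC" if "BC" in reg.treatments else None,
    }
    return taxa_table, voc_table, truth
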