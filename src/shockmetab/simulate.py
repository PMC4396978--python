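"""Synthetic two-group study generator with known discriminatory ground truth.

Emulates the shape of a two-arm (carbohydrate-prefed vs fasted) porcine
hemorrhagic-shock study: four sampled compartments with fixed panel sizes,
six timepoints (baseline, end of shock, and four resuscitation/recovery
points), per-animal dropout concentrated in the resuscitation phase, and
urine abundances spanning several orders of magnitude including exact zeros.

Concentrations are log-normal: metabolite-level log10 means are drawn once
per compartment, and each measurement adds a per-animal intercept (shared
across timepoints, so it cancels in interval differences) plus
block-equicorrelated Gaussian noise on the log10 scale.  Group-discriminatory
effects are planted per (compartment, contrast) so that the standardized
effect on the *analysis* scale of that compartment equals the requested d:
multiplicative (log10-shift) for urine, additive on the concentration scale
(delta-method sd) for liver/muscle/serum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import (COMPARTMENTS, GROUPS, INTERVAL_PAIRS, RAW_UNITS,
                      TIMEPOINTS, MetabolomicsDataset)

DEFAULT_PANEL_SIZES = {"liver": 51, "muscle": 39, "serum": 53, "urine": 60}

#: fixed per-compartment stream keys so adding/removing one compartment
#: never perturbs the draws of another
_COMP_STREAM = {"liver": 11, "muscle": 12, "serum": 13, "urine": 14}
_SURVIVAL_STREAM = 977

#: last observed timepoint for a death in each phase
_PHASE_TRUNCATION = {"shock": "S45", "resus": "FR8"}
LN10 = math.log(10.0)


class SimulationError(ValueError):
    """Invalid simulation configuration or degenerate outcome."""


@dataclass(frozen=True)
class PlantedEffect:
    """A group-discriminatory metabolite at one contrast.

    ``d`` is the standardized mean difference (CPF minus FS) on the analysis
    scale of the compartment; for interval contrasts (labels like
    ``"S45-B"``) the effect is planted on the timepoint-to-timepoint change.
    """

    compartment: str
    contrast: str
    metabolite: int
    d: float


@dataclass
class SimulationConfig:
    """Study-shaped generator configuration.

    Defaults mirror the study design: 16 animals per arm, panel sizes
    51/39/53/60 for liver/muscle/serum/urine, and per-group total death
    rates of 47% (CPF) and 28% (FS) weighted toward the resuscitation
    phase.  ``dropout`` maps group to either a total death probability
    (internally split 25%/75% of the hazard across the shock and
    resuscitation phases) or an explicit ``(p_shock, p_resus)`` pair.
    """

    n_per_group: int = 16
    panel_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_SIZES))
    planted_effects: Sequence[PlantedEffect] = ()
    base_log_mean: float = 0.0      # log10 mM, metabolite-level grand mean
    base_log_sd: float = 0.25       # within-animal log10 noise sd
    mean_log_spread: float = 1.25   # sd of metabolite-level log10 means
    animal_log_sd: float = 0.15     # per-animal intercept sd (log10)
    block_corr: float = 0.3
    block_size: int = 5
    urine_output_profile: Mapping[str, float] = field(default_factory=lambda: {
        "B": 2.0, "S45": 0.5, "FR2": 1.0, "FR8": 2.0, "FR20": 2.5, "PR48": 2.0})
    urine_output_cv: float = 0.4    # lognormal CV of flow around the profile
    zero_rate_urine: float = 0.05   # probability a urine concentration is exactly 0
    dropout: Mapping[str, float | tuple[float, float]] = field(
        default_factory=lambda: {"CPF": 0.47, "FS": 0.28})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise SimulationError("n_per_group must be >= 1")
        for comp, p in self.panel_sizes.items():
            if comp not in COMPARTMENTS:
                raise SimulationError(f"unknown compartment {comp!r}")
            if p < 2:
                raise SimulationError(f"panel size for {comp} must be >= 2")
        for eff in self.planted_effects:
            if not math.isfinite(eff.d):
                raise SimulationError("planted effect sizes must be finite")
            if eff.compartment not in self.panel_sizes:
                raise SimulationError(f"effect targets absent compartment {eff.compartment!r}")
            if not 0 <= eff.metabolite < self.panel_sizes[eff.compartment]:
                raise SimulationError("planted metabolite index outside the panel")
        if not 0.0 <= self.zero_rate_urine <= 1.0:
            raise SimulationError("zero_rate_urine must lie in [0, 1]")
        if not 0.0 <= self.block_corr < 1.0:
            raise SimulationError("block_corr must lie in [0, 1)")
        for group, spec in self.dropout.items():
            for p in _phase_probs(spec):
                if not 0.0 <= p <= 1.0:
                    raise SimulationError(f"dropout for {group} outside [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery downstream."""

    effects: dict[tuple[str, str], dict[int, float]]
    survivors: dict[str, list[str]]
    death_phase: dict[str, str | None]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "effects": [
                {"compartment": c, "contrast": lab,
                 "metabolites": {str(k): v for k, v in eff.items()}}
                for (c, lab), eff in sorted(self.effects.items())],
            "survivors": self.survivors,
            "death_phase": self.death_phase,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path


def _phase_probs(spec: float | tuple[float, float]) -> tuple[float, float]:
    """Split a total death probability into (shock, resuscitation) hazards.

    A scalar p is split so the shock phase carries 25% and the resuscitation
    phase 75% of the log-survival hazard; the total death probability stays
    exactly p.  A 2-tuple is used as-is.
    """
    if isinstance(spec, (tuple, list)):
        p1, p2 = float(spec[0]), float(spec[1])
        return p1, p2
    p = float(spec)
    if p >= 1.0:
        return 1.0, 1.0
    return 1.0 - (1.0 - p) ** 0.25, 1.0 - (1.0 - p) ** 0.75


def _draw_fates(cfg: SimulationConfig) -> dict[str, str | None]:
    """Per-animal death phase (None = survivor), deterministic per seed.

    One shared stream across compartments: an animal that dies is missing
    from every compartment after its truncation point.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _SURVIVAL_STREAM]))
    fates: dict[str, str | None] = {}
    for group in GROUPS:
        p_shock, p_resus = _phase_probs(cfg.dropout.get(group, 0.0))
        for i in range(cfg.n_per_group):
            animal = f"{group}{i + 1:02d}"
            u_shock, u_resus = rng.uniform(size=2)
            if u_shock < p_shock:
                fates[animal] = "shock"
            elif u_resus < p_resus:
                fates[animal] = "resus"
            else:
                fates[animal] = None
    return fates


def _observed_timepoints(phase: str | None) -> list[str]:
    if phase is None:
        return list(TIMEPOINTS)
    last = _PHASE_TRUNCATION[phase]
    return list(TIMEPOINTS[: TIMEPOINTS.index(last) + 1])


def _effect_shifts(cfg: SimulationConfig, compartment: str
                   ) -> dict[str, dict[int, tuple[float, float]]]:
    """Map timepoint -> {metabolite index: (d_timepoint, d_interval)} for CPF.

    Timepoint contrasts shift that timepoint by d standard deviations of a
    single measurement; interval contrasts shift the *later* timepoint so
    that the timepoint-to-timepoint change differs by d standard deviations
    of the change (whose variance components differ: the per-animal
    intercept cancels in a difference).  The two kinds are accumulated
    separately so the caller can apply the right sd to each.
    """
    shifts: dict[str, dict[int, tuple[float, float]]] = {}

    def _add(tp: str, j: int, d_tp: float, d_iv: float) -> None:
        cur = shifts.setdefault(tp, {}).get(j, (0.0, 0.0))
        shifts[tp][j] = (cur[0] + d_tp, cur[1] + d_iv)

    for eff in cfg.planted_effects:
        if eff.compartment != compartment:
            continue
        if "-" in eff.contrast:
            later, earlier = eff.contrast.split("-", 1)
            if (later, earlier) not in INTERVAL_PAIRS:
                raise SimulationError(f"invalid interval contrast {eff.contrast!r}")
            _add(later, eff.metabolite, 0.0, eff.d)
        else:
            if eff.contrast not in TIMEPOINTS:
                raise SimulationError(f"invalid timepoint contrast {eff.contrast!r}")
            _add(eff.contrast, eff.metabolite, eff.d, 0.0)
    return shifts


def simulate_study(cfg: SimulationConfig
                   ) -> tuple[dict[str, MetabolomicsDataset], GroundTruth]:
    """Generate one dataset per configured compartment plus its ground truth.

    Reproducible bit-exactly from ``cfg.seed``; per-compartment and
    per-animal substreams are keyed so that changing the panel of one
    compartment leaves every other compartment's draws untouched.
    """
    fates = _draw_fates(cfg)
    survivors = {g: [a for a, ph in fates.items() if ph is None and a.startswith(g)]
                 for g in GROUPS}
    for g in GROUPS:
        if not survivors[g]:
            raise SimulationError(
                f"no surviving animals in group {g}; increase n_per_group or lower dropout")

    # sd of a single log10 measurement between animals (intercept + noise)
    s_single = math.hypot(cfg.animal_log_sd, cfg.base_log_sd)
    flow_log_sd = math.sqrt(math.log(1.0 + cfg.urine_output_cv ** 2)) / LN10

    datasets: dict[str, MetabolomicsDataset] = {}
    effects_truth: dict[tuple[str, str], dict[int, float]] = {}
    for eff in cfg.planted_effects:
        key = (eff.compartment, eff.contrast)
        effects_truth.setdefault(key, {})
        effects_truth[key][eff.metabolite] = \
            effects_truth[key].get(eff.metabolite, 0.0) + eff.d

    animals = [f"{g}{i + 1:02d}" for g in GROUPS for i in range(cfg.n_per_group)]

    for comp in COMPARTMENTS:
        if comp not in cfg.panel_sizes:
            continue
        p = int(cfg.panel_sizes[comp])
        ss = np.random.SeedSequence([cfg.seed, _COMP_STREAM[comp]])
        children = ss.spawn(1 + len(animals))
        rng_panel = np.random.default_rng(children[0])
        mu = cfg.base_log_mean + cfg.mean_log_spread * rng_panel.standard_normal(p)
        names = [f"met{j + 1:03d}" for j in range(p)]
        shifts = _effect_shifts(cfg, comp)

        n_blocks = -(-p // cfg.block_size)
        block_of = np.repeat(np.arange(n_blocks), cfg.block_size)[:p]
        rho = cfg.block_corr

        rows: list[np.ndarray] = []
        meta_rows: list[dict] = []
        for k, animal in enumerate(animals):
            group = animal[:-2]
            rng_a = np.random.default_rng(children[1 + k])
            a_i = rng_a.normal(0.0, cfg.animal_log_sd)
            for tp in _observed_timepoints(fates[animal]):
                g_block = rng_a.standard_normal(n_blocks)
                eps = rng_a.standard_normal(p)
                z = math.sqrt(rho) * g_block[block_of] + math.sqrt(1.0 - rho) * eps
                logval = mu + a_i + cfg.base_log_sd * z

                flow = np.nan
                if comp == "urine":
                    flow = cfg.urine_output_profile[tp] * 10.0 ** rng_a.normal(
                        0.0, flow_log_sd)
                    zero_mask = rng_a.uniform(size=p) < cfg.zero_rate_urine
                else:
                    zero_mask = None

                conc = 10.0 ** logval
                tp_shifts = shifts.get(tp, {})
                if tp_shifts and group == "CPF":
                    for j, (d_tp, d_iv) in tp_shifts.items():
                        if comp == "urine":
                            # analysis scale = log10 abundance; flow noise adds
                            # to every measurement, the animal intercept
                            # cancels only in differences
                            s_tp = math.hypot(s_single, flow_log_sd)
                            s_iv = math.hypot(cfg.base_log_sd, flow_log_sd)
                            delta = d_tp * s_tp + d_iv * math.sqrt(2.0) * s_iv
                            conc[j] *= 10.0 ** delta
                        else:
                            # analysis scale = raw concentration; delta-method
                            # sd of a lognormal is ln(10)*sd_log10*mean
                            mean_j = 10.0 ** mu[j] * math.exp((s_single * LN10) ** 2 / 2)
                            shift = (d_tp * s_single
                                     + d_iv * math.sqrt(2.0) * cfg.base_log_sd
                                     ) * LN10 * mean_j
                            conc[j] = max(conc[j] + shift, 0.0)
                if zero_mask is not None:
                    conc = np.where(zero_mask, 0.0, conc)

                rows.append(conc)
                meta_rows.append({"animal_id": animal, "group": group,
                                  "compartment": comp, "timepoint": tp,
                                  "urine_output": flow})

        meta = pd.DataFrame(meta_rows)
        if comp != "urine":
            meta = meta.drop(columns=["urine_output"])
        datasets[comp] = MetabolomicsDataset(
            values=np.vstack(rows), metabolite_names=names,
            sample_meta=meta, units=RAW_UNITS[comp], kind="raw")

    truth = GroundTruth(effects=effects_truth, survivors=survivors,
                        death_phase=fates)
    return datasets, truth


def simulate_survival_counts(cfg: SimulationConfig,
                             n_per_group: int | None = None) -> dict[str, float]:
    """Empirical per-group death proportions under the dropout model.

    Used only to sanity-check/parameterize ``dropout``; draws its own
    vectorized stream (same seed key as the study's fate stream).
    """
    n = int(n_per_group if n_per_group is not None else cfg.n_per_group)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _SURVIVAL_STREAM]))
    rates: dict[str, float] = {}
    for group in GROUPS:
        p_shock, p_resus = _phase_probs(cfg.dropout.get(group, 0.0))
        u = rng.uniform(size=(n, 2))
        died = (u[:, 0] < p_shock) | (u[:, 1] < p_resus)
        rates[group] = float(died.mean())
    return rates
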