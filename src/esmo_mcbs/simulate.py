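"""Seeded generator of synthetic trial-summary records.

Emulates the statistical shape of published recurrent-ovarian-cancer trial
rows — control-arm medians by setting, hazard ratios with CI widths driven
by the (approximate) event count, gains consistent with the hazard ratio
up to noise, and Bernoulli QoL/toxicity evidence flags — so every pipeline
stage is testable without any external data.

The CI is built with the standard normal approximation on the log hazard
ratio, SE(log HR) ~= 2/sqrt(events), the textbook large-sample variance for
a 1:1 randomised comparison.  An endpoint is marked significant exactly
when its 95% CI excludes 1 in favour of the study arm, so the fraction of
"significant" synthetic trials rises with the event count at a fixed true
hazard ratio below 1 — power behaves the way it does in real corpora.

Generator algorithm identifier: ``synthetic-trials/1`` (recorded in each
record's study_name so batches are traceable to the generator version).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .records import (
    ComparatorClass,
    ConfidenceInterval,
    Design,
    Endpoint,
    EndpointSummary,
    EvidenceFlags,
    PrimaryEndpoint,
    Setting,
    Significance,
    TrialRecord,
)

ALGORITHM_ID = "synthetic-trials/1"

_Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: Months; spans of the control-arm medians printed for each setting.
DEFAULT_CONTROL_MEDIAN_RANGES: dict[Setting, tuple[float, float]] = {
    Setting.PLATINUM_SENSITIVE: (5.0, 31.0),
    Setting.MAINTENANCE: (4.0, 39.0),
    Setting.PLATINUM_RESISTANT: (2.0, 19.0),
}


class SimulationConfig(BaseModel):
    """Knobs of the synthetic-trial generator (all ranges inclusive)."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_trials: int = 100
    control_median_range: dict[Setting, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MEDIAN_RANGES)
    )
    true_hr_range: tuple[float, float] = (0.2, 1.25)
    events_range: tuple[int, int] = (50, 500)
    endpoint_mix: dict[Endpoint, float] = Field(
        default_factory=lambda: {Endpoint.OS: 0.2, Endpoint.PFS: 0.7, Endpoint.ORR: 0.1}
    )
    evidence_flag_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "qol_reported": 0.6,
            "qol_global_improved": 0.05,
            "qol_subscale_improved": 0.15,
            "toxicity_reduced": 0.05,
            "toxicity_increased": 0.2,
            "early_discontinuation_reduced": 0.05,
        }
    )
    gain_noise_sd: float = 0.2  # sd of multiplicative log-normal noise on the gain

    @field_validator("n_trials")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 0:
            raise ValueError("n_trials: must be >= 0")
        return v

    @model_validator(mode="after")
    def _ranges_and_probabilities(self) -> "SimulationConfig":
        for name in ("true_hr_range", "events_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: range must be ordered, got ({lo}, {hi})")
        if self.true_hr_range[0] <= 0:
            raise ValueError("true_hr_range: hazard ratios must be positive")
        if self.events_range[0] < 1:
            raise ValueError("events_range: needs at least one event")
        for setting, (lo, hi) in self.control_median_range.items():
            if not 0 < lo <= hi:
                raise ValueError(
                    f"control_median_range[{setting.value}]: must be ordered and positive"
                )
        total = sum(self.endpoint_mix.values())
        if any(p < 0 for p in self.endpoint_mix.values()) or not math.isclose(
            total, 1.0, abs_tol=1e-9
        ):
            raise ValueError(f"endpoint_mix: probabilities must sum to 1, got {total}")
        for flag, p in self.evidence_flag_rates.items():
            if flag not in EvidenceFlags.model_fields:
                raise ValueError(f"evidence_flag_rates: unknown flag {flag!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"evidence_flag_rates[{flag}]: not a probability: {p}")
        return self


def _survival_summary(
    rng: np.random.Generator, cfg: SimulationConfig, kind: Endpoint, setting: Setting
) -> EndpointSummary:
    lo, hi = cfg.control_median_range[setting]
    control = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    true_hr = float(rng.uniform(*cfg.true_hr_range))
    events = int(rng.integers(cfg.events_range[0], cfg.events_range[1] + 1))
    se = 2.0 / math.sqrt(events)
    observed = float(np.exp(np.log(true_hr) + rng.normal(0.0, se)))
    ci = ConfidenceInterval(
        lower=float(np.exp(np.log(observed) - _Z95 * se)),
        upper=float(np.exp(np.log(observed) + _Z95 * se)),
    )
    gain = control * (1.0 / observed - 1.0) * float(
        np.exp(rng.normal(0.0, cfg.gain_noise_sd))
    )
    significant = (
        Significance.CONFIRMED if ci.upper < 1.0 else Significance.NOT_SIGNIFICANT
    )
    return EndpointSummary(
        endpoint=kind,
        control_median=round(control, 2),
        gain=round(gain, 2),
        hazard_ratio=round(observed, 4),
        hr_ci=ConfidenceInterval(lower=round(ci.lower, 4), upper=round(ci.upper, 4)),
        significant=significant,
    )


def _evidence(rng: np.random.Generator, cfg: SimulationConfig) -> EvidenceFlags:
    r = cfg.evidence_flag_rates
    draw = lambda flag: bool(rng.random() < r.get(flag, 0.0))
    reported = draw("qol_reported")
    return EvidenceFlags(
        qol_reported=reported,
        # improvement can only be observed where QoL was measured at all
        qol_global_improved=reported and draw("qol_global_improved"),
        qol_subscale_improved=reported and draw("qol_subscale_improved"),
        toxicity_reduced=draw("toxicity_reduced"),
        toxicity_increased=draw("toxicity_increased"),
        early_discontinuation_reduced=draw("early_discontinuation_reduced"),
    )


def generate_trials(config: Optional[SimulationConfig] = None, **overrides) -> list[TrialRecord]:
    """Generate ``config.n_trials`` valid records, deterministic per seed."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**config.model_dump(), **overrides})
    rng = np.random.default_rng(config.seed)
    settings = list(Setting)
    kinds = list(config.endpoint_mix)
    probs = np.array([config.endpoint_mix[k] for k in kinds], dtype=float)
    records: list[TrialRecord] = []
    for i in range(config.n_trials):
        setting = settings[int(rng.integers(len(settings)))]
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        events = 0
        if kind is Endpoint.ORR:
            orr = round(float(rng.uniform(5.0, 70.0)), 1)
            summary = EndpointSummary(
                endpoint=Endpoint.ORR,
                orr_pct=orr,
                significant=(
                    Significance.CONFIRMED
                    if rng.random() < 0.3
                    else Significance.NOT_SIGNIFICANT
                ),
            )
            endpoints = [summary]
            primary = PrimaryEndpoint.ORR
        else:
            summary = _survival_summary(rng, config, kind, setting)
            endpoints = [summary]
            primary = PrimaryEndpoint(kind.value)
            # half of the PFS-primary trials also publish a (usually null) OS result
            if kind is Endpoint.PFS and rng.random() < 0.5:
                endpoints.append(
                    _survival_summary(rng, config, Endpoint.OS, setting)
                )
        n = int(rng.integers(60, 1101))
        records.append(
            TrialRecord(
                trial_id=f"synthetic-{config.seed}-{i:05d}",
                study_name=ALGORITHM_ID,
                setting=setting,
                design=Design.PHASE3_RCT if rng.random() < 0.7 else Design.PHASE2_RCT,
                n=n,
                experimental_label=f"agent-{i:05d}/backbone",
                comparator_label=f"backbone-{i:05d}",
                primary_endpoint=primary,
                endpoints=endpoints,
                evidence=_evidence(rng, config),
                comparator_adequate=True,
                comparator_class=ComparatorClass.GUIDELINE_LISTED,
            )
        )
    return records


#: Deterministic boundary grid over the threshold tables.
GRID_CI_LOWERS = [round(0.30 + 0.05 * i, 2) for i in range(11)]  # 0.30 .. 0.80
GRID_GAINS = [round(0.5 + 0.5 * i, 1) for i in range(12)]  # 0.5 .. 6.0
GRID_CONTROLS = [3.0, 5.9, 6.0, 6.1, 11.9, 12.0, 12.1, 24.0]
GRID_ENDPOINTS = [Endpoint.OS, Endpoint.PFS]


def generate_grade_grid() -> list[TrialRecord]:
    """Exhaustive 11 x 12 x 8 x 2 = 2112-cell grid for boundary testing.

    Every cell is a minimal valid record with a confirmed primary result,
    the CI lower bound, gain and control median of the cell, and no
    QoL/toxicity evidence (so final == preliminary for survival forms).
    """
    records: list[TrialRecord] = []
    for kind in GRID_ENDPOINTS:
        for control in GRID_CONTROLS:
            for gain in GRID_GAINS:
                for lower in GRID_CI_LOWERS:
                    hr = round(lower * 1.15, 4)
                    summary = EndpointSummary(
                        endpoint=kind,
                        control_median=control,
                        gain=gain,
                        hazard_ratio=hr,
                        hr_ci=ConfidenceInterval(lower=lower, upper=round(lower * 1.35, 4)),
                        significant=Significance.CONFIRMED,
                    )
                    records.append(
                        TrialRecord(
                            trial_id=f"grid-{kind.value}-c{control}-g{gain}-l{lower}",
                            study_name="grade-grid/1",
                            setting=Setting.PLATINUM_RESISTANT,
                            design=Design.PHASE3_RCT,
                            n=400,
                            experimental_label="grid experimental",
                            comparator_label="grid comparator",
                            primary_endpoint=PrimaryEndpoint(kind.value),
                            endpoints=[summary],
                            comparator_adequate=True,
                            comparator_class=ComparatorClass.GUIDELINE_LISTED,
                        )
                    )
    return records
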