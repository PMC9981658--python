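"""Synthetic monitoring cohorts with the statistical structure the analyses assume.

The generator emulates a small elite squad followed daily over one season:
six naturally cycling athletes plus one amenorrheic athlete and five
combined-pill users (one monophasic, three biphasic, one triphasic; 21
active days + 7-day withdrawal break), ~150 days of follow-up (about five
28 +- 2 day cycles), a 78% daily response rate, sparse coach evaluations,
phase-dependent shifts in 1-10 Likert wellness/performance scores,
phase-dependent symptom probabilities, and salivary hormone draws at cycle
days 8/14/24 +- 2 whose lognormal parameters are moment-matched to published
phase means/SDs.

Scores are latent-Gaussian-then-discretized: latent = baseline + athlete
effect + shared day factor + phase effect + noise, rounded and clipped to
1..10. RPE is generated independently of phase/status so the ordinal model
should find no menses effect on it. Withdrawal bleeding for pill users is
placed on pause days 2-5, so the binary menses scheme is exercised in both
groups.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    CANONICAL_SYMPTOMS,
    AthleteProfile,
    DailyRecord,
    Group,
    HormoneSample,
    PillType,
    write_athletes_csv,
    write_daily_csv,
    write_hormones_csv,
)
from .phases import CycleSpan, HcPhase, Mc6Phase, classify_hc_phase, classify_mc_phase, predict_ovulation

__all__ = [
    "SyntheticConfig",
    "midcycle_effect_preset",
    "preset_symptom_rates",
    "generate_cohort",
    "null_cohort",
    "write_cohort",
    "sample_hormone_levels",
    "MC_HORMONE_PARAMS",
    "HC_HORMONE_PARAMS",
]

#: salivary hormone mean/SD (pg/mL) per nominal sampling day, natural cycles
MC_HORMONE_PARAMS: dict[int, dict[str, tuple[float, float]]] = {
    8: {"estradiol": (2.5, 1.5), "progesterone": (38.1, 31.3)},
    14: {"estradiol": (6.9, 4.2), "progesterone": (42.8, 56.9)},
    24: {"estradiol": (6.0, 3.8), "progesterone": (81.85, 35.7)},
}

#: salivary hormone mean/SD (pg/mL) per active pill phase, HC users
HC_HORMONE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "phase1": {"estradiol": (1.6, 0.3), "progesterone": (20.4, 7.6)},
    "phase2": {"estradiol": (1.8, 0.9), "progesterone": (29.6, 10.9)},
}

SCORE_VARIABLES = ("sleep_quality", "fitness", "mood", "self_performance")


def midcycle_effect_preset() -> dict[tuple[str, str], float]:
    """Latent Likert-point shifts emulating the qualitative published pattern.

    Mood, fitness and self-rated performance are boosted around mid-cycle
    (late-follicular/early-luteal) and depressed during menses and the
    premenstrual days; sleep quality dips premenstrually; for pill users the
    self-rated performance is lowest during the withdrawal pause and highest
    in the second active phase. Magnitudes are tunable defaults, not
    published estimates.
    """
    effects: dict[tuple[str, str], float] = {}
    for var in ("mood", "fitness", "self_performance"):
        effects[(var, Mc6Phase.LATE_FOLLICULAR.value)] = 1.5
        effects[(var, Mc6Phase.EARLY_LUTEAL.value)] = 1.0
        effects[(var, Mc6Phase.MENSES.value)] = -1.5
        effects[(var, Mc6Phase.PREMENSTRUAL.value)] = -1.0
    effects[("sleep_quality", Mc6Phase.PREMENSTRUAL.value)] = -1.5
    effects[("self_performance", HcPhase.PAUSE.value)] = -1.5
    effects[("self_performance", HcPhase.PHASE2.value)] = 1.0
    return effects


def preset_symptom_rates() -> dict[str, float]:
    """Per-day symptom probabilities by phase (menses/pause most symptomatic)."""
    return {
        Mc6Phase.MENSES.value: 0.45,
        Mc6Phase.PREMENSTRUAL.value: 0.30,
        Mc6Phase.MID_LUTEAL.value: 0.22,
        Mc6Phase.LATE_FOLLICULAR.value: 0.06,
        HcPhase.PAUSE.value: 0.45,
    }


def _default_symptom_mix() -> dict[str, float]:
    # digestive troubles, cramps and headaches lead the mix
    weights = (0.16, 0.12, 0.11, 0.11, 0.11, 0.14, 0.13, 0.12)
    return dict(zip(CANONICAL_SYMPTOMS, weights))


@dataclass(frozen=True)
class SyntheticConfig:
    """All distributional knobs of the cohort generator.

    Defaults emulate the study conditions: 6 natural-cycle athletes + 1
    amenorrheic + 5 pill users, 150 days of follow-up, 28 +- 2 day cycles
    with ~5 bleeding days, a 78% response rate, sparse (~10% of days) coach
    scores coupled to the athlete's own performance rating, and hormone
    draws matched to published phase means/SDs.
    """

    n_mc_athletes: int = 6
    n_amenorrheic: int = 1
    n_hc_athletes: int = 5
    follow_up_days: int = 150
    cycle_length_mean: float = 28.0
    cycle_length_sd: float = 2.0
    cycle_length_min: int = 22
    cycle_length_max: int = 35
    bleed_length_mean: float = 5.0
    bleed_length_sd: float = 0.8
    response_rate: float = 0.78
    phase_effects: Mapping[tuple[str, str], float] = field(default_factory=midcycle_effect_preset)
    symptom_base_rate: float = 0.12
    symptom_rates: Mapping[str, float] = field(default_factory=preset_symptom_rates)
    symptom_mix: Mapping[str, float] = field(default_factory=_default_symptom_mix)
    hormone_params_mc: Mapping[int, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: MC_HORMONE_PARAMS
    )
    hormone_params_hc: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: HC_HORMONE_PARAMS
    )
    coach_rate: float = 0.10
    coach_coupling: float = 0.7
    baseline_mean: float = 6.5
    athlete_sd: float = 0.7
    day_factor_sd: float = 0.8
    noise_sd: float = 1.5
    rpe_mean: float = 5.0
    rpe_sd: float = 2.0
    start_date: dt.date = dt.date(2021, 2, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.response_rate, self.coach_rate, self.symptom_base_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.cycle_length_mean < 21:
            raise ValueError("cycle_length_mean must be >= 21")
        if min(self.n_mc_athletes, self.n_amenorrheic, self.n_hc_athletes) < 0:
            raise ValueError("athlete counts must be >= 0")


def null_cohort_config(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of ``config`` with phase effects and symptom-rate differences zeroed."""
    return dataclasses.replace(config, phase_effects={}, symptom_rates={})


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean/SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def sample_hormone_levels(
    nominal_day: int, n: int, rng: np.random.Generator, config: SyntheticConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (estradiol, progesterone) pg/mL for a nominal MC sampling day."""
    params = (config or SyntheticConfig()).hormone_params_mc[nominal_day]
    mu_e, sg_e = _lognormal_params(*params["estradiol"])
    mu_p, sg_p = _lognormal_params(*params["progesterone"])
    return rng.lognormal(mu_e, sg_e, size=n), rng.lognormal(mu_p, sg_p, size=n)


def _make_profiles(config: SyntheticConfig) -> list[AthleteProfile]:
    profiles = []
    for i in range(config.n_mc_athletes):
        profiles.append(AthleteProfile(f"MC{i + 1:02d}", Group.NATURAL_MC))
    for i in range(config.n_amenorrheic):
        profiles.append(AthleteProfile(f"AM{i + 1:02d}", Group.NATURAL_MC))
    pill_pattern = [
        PillType.MONOPHASIC,
        PillType.BIPHASIC,
        PillType.BIPHASIC,
        PillType.BIPHASIC,
        PillType.TRIPHASIC,
    ]
    for i in range(config.n_hc_athletes):
        profiles.append(
            AthleteProfile(f"HC{i + 1:02d}", Group.HC_USER, pill_pattern[i % len(pill_pattern)])
        )
    return profiles


def _mc_calendar(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str | None]]:
    """(bleeding mask, true phase label per day) for one natural-cycle athlete."""
    T = config.follow_up_days
    bleeding = np.zeros(T, dtype=bool)
    phase: list[str | None] = [None] * T
    offset = 0
    while offset < T:
        length = int(round(
            float(np.clip(
                rng.normal(config.cycle_length_mean, config.cycle_length_sd),
                config.cycle_length_min,
                config.cycle_length_max,
            ))
        ))
        bleed = int(np.clip(round(rng.normal(config.bleed_length_mean, config.bleed_length_sd)), 3, 7))
        po = predict_ovulation(length, bleed)
        span = CycleSpan("tmp", 1, config.start_date, length, bleed, po)
        for day in range(1, length + 1):
            idx = offset + day - 1
            if idx >= T:
                break
            bleeding[idx] = day <= bleed
            phase[idx] = classify_mc_phase(day, span).value
        offset += length
    return bleeding, phase


def _hc_calendar(
    config: SyntheticConfig, profile: AthleteProfile
) -> tuple[np.ndarray, list[str | None]]:
    """(bleeding mask, phase label per day); follow-up starts at pause day 1."""
    T = config.follow_up_days
    pack = profile.pack_length
    bleeding = np.zeros(T, dtype=bool)
    phase: list[str | None] = [None] * T
    for idx in range(T):
        regimen_day = idx % pack + 1
        phase[idx] = classify_hc_phase(regimen_day, profile).value
        # withdrawal bleeding on pause days 2-5
        bleeding[idx] = 2 <= regimen_day <= min(5, profile.pause_days)
    return bleeding, phase


def _hormone_draw(
    rng: np.random.Generator, params: Mapping[str, tuple[float, float]]
) -> tuple[float, float]:
    mu_e, sg_e = _lognormal_params(*params["estradiol"])
    mu_p, sg_p = _lognormal_params(*params["progesterone"])
    return float(rng.lognormal(mu_e, sg_e)), float(rng.lognormal(mu_p, sg_p))


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[AthleteProfile], list[DailyRecord], list[HormoneSample]]:
    """Generate a full cohort: roster, daily records and hormone samples.

    Fully reproducible from ``config.seed``. Each follow-up day yields a
    record with probability ``response_rate``; the amenorrheic athletes
    never bleed and carry no phase effects; pill users bleed only during
    the withdrawal pause.
    """
    rng = np.random.default_rng(config.seed)
    profiles = _make_profiles(config)
    records: list[DailyRecord] = []
    samples: list[HormoneSample] = []
    T = config.follow_up_days

    for profile in profiles:
        amenorrheic = profile.athlete_id.startswith("AM")
        if profile.group is Group.NATURAL_MC:
            if amenorrheic:
                bleeding = np.zeros(T, dtype=bool)
                phase: list[str | None] = [None] * T
            else:
                bleeding, phase = _mc_calendar(config, rng)
        else:
            bleeding, phase = _hc_calendar(config, profile)

        athlete_eff = rng.normal(0.0, config.athlete_sd, size=len(SCORE_VARIABLES))
        day_factor = rng.normal(0.0, config.day_factor_sd, size=T)
        noise = rng.normal(0.0, config.noise_sd, size=(T, len(SCORE_VARIABLES)))

        # symptoms per day
        sym_rate = np.array(
            [
                config.symptom_rates.get(ph, config.symptom_base_rate)
                if ph is not None
                else config.symptom_base_rate
                for ph in phase
            ]
        )
        symptomatic = rng.random(T) < sym_rate
        n_extra = rng.poisson(0.6, size=T)
        names = list(config.symptom_mix)
        weights = np.array([config.symptom_mix[s] for s in names], dtype=float)
        weights = weights / weights.sum()

        bedtime = rng.normal(600.0, 45.0, size=T)  # minutes after noon; 600 = 22:00
        sleep_dur = np.clip(8.0 - (bedtime - 600.0) / 90.0 + rng.normal(0, 0.5, size=T), 4.0, 11.0)
        rpe = np.clip(np.round(rng.normal(config.rpe_mean, config.rpe_sd, size=T)), 0, 10)
        observed = rng.random(T) < config.response_rate
        coached = rng.random(T) < config.coach_rate
        coach_noise = rng.normal(0.0, 1.0, size=T)
        pain_extra = rng.random(T)

        for idx in range(T):
            date = config.start_date + dt.timedelta(days=idx)
            ph = phase[idx]
            n_sym = int(min(1 + n_extra[idx], len(names))) if symptomatic[idx] else 0
            if n_sym:
                day_symptoms = frozenset(
                    rng.choice(names, size=n_sym, replace=False, p=weights)
                )
            else:
                day_symptoms = frozenset()

            scores = {}
            for v_i, var in enumerate(SCORE_VARIABLES):
                latent = (
                    config.baseline_mean
                    + athlete_eff[v_i]
                    + day_factor[idx]
                    + (config.phase_effects.get((var, ph), 0.0) if ph else 0.0)
                    + 0.3 * (sleep_dur[idx] - 8.0)
                    - (0.35 if var == "self_performance" else 0.2) * len(day_symptoms)
                    + noise[idx, v_i]
                )
                scores[var] = int(np.clip(round(latent), 1, 10))

            pain = int(np.clip(
                round(len(day_symptoms) * 1.2 + (2.0 if pain_extra[idx] < 0.05 else 0.0)), 0, 10
            ))

            coach = None
            if coached[idx]:
                c = config.coach_coupling
                perf_centered = scores["self_performance"] - config.baseline_mean
                coach_latent = (
                    config.baseline_mean
                    + c * perf_centered
                    + np.sqrt(max(0.0, 1 - c * c)) * 1.5 * coach_noise[idx]
                )
                coach = int(np.clip(round(coach_latent), 1, 10))

            if not observed[idx]:
                continue
            records.append(
                DailyRecord(
                    athlete_id=profile.athlete_id,
                    date=date,
                    bleeding=bool(bleeding[idx]),
                    sleep_quality=scores["sleep_quality"],
                    fitness=scores["fitness"],
                    mood=scores["mood"],
                    self_performance=scores["self_performance"],
                    rpe=float(rpe[idx]),
                    sleep_duration=float(round(sleep_dur[idx] * 60) / 60),
                    bedtime=float(round(bedtime[idx])),
                    symptoms=day_symptoms,
                    pain_intensity=pain,
                    coach_performance=coach,
                )
            )

        # hormone sampling at nominal days 8/14/24 +- 2 of each cycle/pack
        if profile.group is Group.NATURAL_MC and not amenorrheic:
            onsets = _onsets_from_mask(bleeding)
            for onset in onsets:
                for nominal in (8, 14, 24):
                    actual = nominal + int(rng.integers(-2, 3))
                    idx = onset + actual - 1
                    if idx >= T:
                        continue
                    e2, p4 = _hormone_draw(rng, config.hormone_params_mc[nominal])
                    samples.append(
                        HormoneSample(
                            athlete_id=profile.athlete_id,
                            date=config.start_date + dt.timedelta(days=idx),
                            cycle_day=actual,
                            nominal_day=nominal,
                            estradiol=e2,
                            progesterone=p4,
                        )
                    )
        elif profile.group is Group.HC_USER:
            pack = profile.pack_length
            for onset in range(0, T, pack):
                for nominal in (8, 14, 24):
                    actual = nominal + int(rng.integers(-2, 3))
                    idx = onset + actual - 1
                    if idx >= T:
                        continue
                    ph = classify_hc_phase(min(actual, pack), profile)
                    key = ph.value if ph is not HcPhase.PAUSE else "phase1"
                    e2, p4 = _hormone_draw(rng, config.hormone_params_hc[key])
                    samples.append(
                        HormoneSample(
                            athlete_id=profile.athlete_id,
                            date=config.start_date + dt.timedelta(days=idx),
                            cycle_day=actual,
                            nominal_day=nominal,
                            estradiol=e2,
                            progesterone=p4,
                        )
                    )
    return profiles, records, samples


def _onsets_from_mask(bleeding: np.ndarray) -> list[int]:
    """Indices of bleeding days whose 14 preceding days are bleed-free."""
    onsets = []
    for idx in np.flatnonzero(bleeding):
        lo = max(0, idx - 14)
        if not bleeding[lo:idx].any():
            onsets.append(int(idx))
    return onsets


def null_cohort(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[AthleteProfile], list[DailyRecord], list[HormoneSample]]:
    """Cohort with scores and symptoms independent of phase (type-I harness)."""
    return generate_cohort(null_cohort_config(config))


def write_cohort(
    out_dir: str | Path,
    profiles: Sequence[AthleteProfile],
    records: Sequence[DailyRecord],
    samples: Sequence[HormoneSample],
    config: SyntheticConfig | None = None,
) -> None:
    """Write athletes.csv, daily.csv, hormones.csv and a config manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_athletes_csv(out / "athletes.csv", profiles)
    write_daily_csv(out / "daily.csv", records)
    write_hormones_csv(out / "hormones.csv", samples)
    if config is not None:
        manifest = dataclasses.asdict(config)
        manifest["start_date"] = config.start_date.isoformat()
        manifest["phase_effects"] = {f"{v}|{p}": e for (v, p), e in config.phase_effects.items()}
        manifest["hormone_params_mc"] = {str(k): dict(v) for k, v in config.hormone_params_mc.items()}
        manifest["hormone_params_hc"] = {str(k): dict(v) for k, v in config.hormone_params_hc.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
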