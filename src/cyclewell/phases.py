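"""Cycle segmentation and phase classification.

Bleeding calendars are segmented into cycles (day 1 = first bleeding day of
an onset) and each athlete-day is labelled under one of three schemes:

``mc6``
    six phases of the natural menstrual cycle — menses, mid-follicular,
    late-follicular, early-luteal, mid-luteal, premenstrual — anchored on a
    calendar-predicted ovulation day P.O = cycle length − 14 (fixed-luteal
    convention, configurable),
``hc``
    two to three phases of a combined-pill regimen — the withdrawal ``pause``
    plus one active phase for monophasic pills or two (split at the
    dose-change boundary) for bi-/triphasic pills,
``binary``
    menses / no-menses from the daily bleeding flag alone, applicable to the
    whole cohort.

Default windows place the salivary-sampling anchor days of a 28-day cycle in
their expected phases: day 8 mid-follicular, day 14 late-follicular, day 24
mid-luteal.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import AthleteProfile, DailyRecord, Group, HormoneSample, PillType

__all__ = [
    "Scheme",
    "Mc6Phase",
    "HcPhase",
    "BinaryPhase",
    "MC6_PHASES",
    "CycleSpan",
    "PhaseWindows",
    "segment_cycles",
    "predict_ovulation",
    "classify_mc_phase",
    "classify_hc_phase",
    "classify_binary",
    "label_cohort",
    "HormonePhaseSummary",
    "hormone_phase_summaries",
    "OrderingCheck",
    "check_hormone_ordering",
]


class Scheme(str, Enum):
    MC6 = "mc6"
    HC = "hc"
    BINARY = "binary"


class Mc6Phase(str, Enum):
    MENSES = "menses"
    MID_FOLLICULAR = "mid_follicular"
    LATE_FOLLICULAR = "late_follicular"
    EARLY_LUTEAL = "early_luteal"
    MID_LUTEAL = "mid_luteal"
    PREMENSTRUAL = "premenstrual"


class HcPhase(str, Enum):
    PAUSE = "pause"
    PHASE1 = "phase1"
    PHASE2 = "phase2"


class BinaryPhase(str, Enum):
    MENSES = "menses"
    NO_MENSES = "no_menses"


MC6_PHASES = tuple(p.value for p in Mc6Phase)

#: Nominal hormone-sampling day -> expected mc6 phase (28-day reference cycle).
NOMINAL_DAY_PHASE = {8: Mc6Phase.MID_FOLLICULAR, 14: Mc6Phase.LATE_FOLLICULAR, 24: Mc6Phase.MID_LUTEAL}


@dataclass(frozen=True)
class CycleSpan:
    """One complete cycle: day 1 = first bleeding day of the onset."""

    athlete_id: str
    cycle_index: int
    start_date: dt.date
    length: int
    bleed_length: int
    predicted_ovulation: int

    def __post_init__(self) -> None:
        if not 1 <= self.bleed_length < self.length:
            raise ValueError("need 1 <= bleed_length < length")
        if not 1 <= self.predicted_ovulation <= self.length:
            raise ValueError("predicted_ovulation outside the cycle")

    def cycle_day(self, date: dt.date) -> int | None:
        """1-based cycle day of ``date``, or None if outside the cycle."""
        offset = (date - self.start_date).days
        return offset + 1 if 0 <= offset < self.length else None


@dataclass(frozen=True)
class PhaseWindows:
    """Tunable day-window parameters of the six-phase division.

    ``luteal_days`` is the assumed fixed luteal length behind the calendar
    ovulation rule P.O = length − luteal_days. ``late_follicular``,
    ``early_luteal`` and ``premenstrual`` are window lengths in days; the
    mid-follicular and mid-luteal phases absorb the remainder. Cycles
    shorter than ``min_length`` get all windows rescaled proportionally to
    length/28 (with a warning) instead of being rejected.
    """

    luteal_days: int = 14
    late_follicular: int = 4
    early_luteal: int = 4
    premenstrual: int = 4
    min_length: int = 21


DEFAULT_WINDOWS = PhaseWindows()


def segment_cycles(
    records: Sequence[DailyRecord],
    windows: PhaseWindows = DEFAULT_WINDOWS,
    onset_gap: int = 14,
) -> list[CycleSpan]:
    """Segment one athlete's day records into complete cycles.

    A cycle onset is a bleeding day whose ``onset_gap`` preceding calendar
    days contain no declared bleeding (robust to one-day gaps in a menses
    run). A complete cycle spans one onset to the day before the next onset;
    trailing days after the last onset form no cycle, and a calendar with
    fewer than two onsets yields no cycles. ``bleed_length`` counts bleeding
    days within the first 10 days of the cycle.
    """
    recs = sorted(records, key=lambda r: r.date)
    if len({r.athlete_id for r in recs}) > 1:
        raise ValueError("segment_cycles expects records of a single athlete")
    bleeding_dates = sorted(r.date for r in recs if r.bleeding)
    if not bleeding_dates:
        return []
    bleeding_set = set(bleeding_dates)
    onsets: list[dt.date] = []
    for d in bleeding_dates:
        if not any((d - dt.timedelta(days=g)) in bleeding_set for g in range(1, onset_gap + 1)):
            onsets.append(d)
    cycles: list[CycleSpan] = []
    athlete_id = recs[0].athlete_id
    for i in range(len(onsets) - 1):
        start, nxt = onsets[i], onsets[i + 1]
        length = (nxt - start).days
        bleed = sum(
            1
            for k in range(min(10, length))
            if (start + dt.timedelta(days=k)) in bleeding_set
        )
        bleed = max(1, bleed)
        po = predict_ovulation(length, bleed, windows)
        cycles.append(
            CycleSpan(
                athlete_id=athlete_id,
                cycle_index=i + 1,
                start_date=start,
                length=length,
                bleed_length=bleed,
                predicted_ovulation=po,
            )
        )
    return cycles


def predict_ovulation(
    length: int, bleed_length: int, windows: PhaseWindows = DEFAULT_WINDOWS
) -> int:
    """Calendar-predicted ovulation day P.O for a cycle of given length.

    Fixed-luteal rule: P.O = length − luteal_days, clamped to at least
    ``bleed_length + 1``. Cycles shorter than ``windows.min_length`` fall
    back to a proportional position (length × (1 − luteal/28)) with a
    warning rather than being rejected.
    """
    if length < windows.min_length:
        warnings.warn(
            f"cycle length {length} < {windows.min_length}: using proportional "
            "phase scaling",
            stacklevel=2,
        )
        po = round(length * (1 - windows.luteal_days / 28.0))
    else:
        po = length - windows.luteal_days
    return min(max(po, bleed_length + 1), length)


def _scaled(windows: PhaseWindows, length: int) -> tuple[int, int, int]:
    """Effective (late_fol, early_lut, premenstrual) window lengths."""
    if length >= windows.min_length:
        return windows.late_follicular, windows.early_luteal, windows.premenstrual
    f = length / 28.0
    return (
        max(1, round(windows.late_follicular * f)),
        max(1, round(windows.early_luteal * f)),
        max(1, round(windows.premenstrual * f)),
    )


def classify_mc_phase(
    day: int, cycle: CycleSpan, windows: PhaseWindows = DEFAULT_WINDOWS
) -> Mc6Phase:
    """Assign a cycle day to one of the six natural-cycle phases.

    Windows (boundary precedence menses > premenstrual > late-follicular >
    early-luteal > mid-follicular > mid-luteal):

    - menses: days 1..bleed_length
    - premenstrual: the last ``premenstrual`` days of the cycle
    - late-follicular: the ``late_follicular`` days ending at P.O
    - early-luteal: the ``early_luteal`` days after P.O
    - mid-follicular: after menses, before the late-follicular window
    - mid-luteal: the remainder between early-luteal and premenstrual
    """
    if not 1 <= day <= cycle.length:
        raise ValueError(f"day {day} outside cycle of length {cycle.length}")
    lf, el, pm = _scaled(windows, cycle.length)
    po = cycle.predicted_ovulation
    if day <= cycle.bleed_length:
        return Mc6Phase.MENSES
    if day > cycle.length - pm:
        return Mc6Phase.PREMENSTRUAL
    if po - lf + 1 <= day <= po:
        return Mc6Phase.LATE_FOLLICULAR
    if po < day <= po + el:
        return Mc6Phase.EARLY_LUTEAL
    if day < po - lf + 1:
        return Mc6Phase.MID_FOLLICULAR
    return Mc6Phase.MID_LUTEAL


def classify_hc_phase(
    day: int, profile: AthleteProfile, split_after_active: int = 10
) -> HcPhase:
    """Assign a regimen day (day 1 = first pill-pause day) to an HC phase.

    Days 1..pause_days are the withdrawal ``pause``. Monophasic pills have a
    single active phase; bi-/triphasic regimens are split after active day
    ``split_after_active`` (used when the pill's true dose-change boundary is
    unknown) into ``phase1`` then ``phase2``.
    """
    if profile.group is not Group.HC_USER:
        raise ValueError(f"athlete {profile.athlete_id} is not an HC user")
    if not 1 <= day <= profile.pack_length:
        raise ValueError(f"regimen day {day} outside pack of {profile.pack_length} days")
    if day <= profile.pause_days:
        return HcPhase.PAUSE
    active_day = day - profile.pause_days
    if profile.pill_type is PillType.MONOPHASIC:
        return HcPhase.PHASE1
    return HcPhase.PHASE1 if active_day <= split_after_active else HcPhase.PHASE2


def classify_binary(record: DailyRecord) -> BinaryPhase:
    """Menses / no-menses from the bleeding flag (contraception-agnostic)."""
    return BinaryPhase.MENSES if record.bleeding else BinaryPhase.NO_MENSES


def hc_phase_count(profile: AthleteProfile) -> int:
    return 2 if profile.pill_type is PillType.MONOPHASIC else 3


def label_cohort(
    records: Sequence[DailyRecord],
    profiles: Sequence[AthleteProfile],
    scheme: Scheme | str,
    windows: PhaseWindows = DEFAULT_WINDOWS,
    split_after_active: int = 10,
    onset_pause_day: int = 2,
) -> pd.DataFrame:
    """Label every applicable athlete-day with its phase.

    Returns a DataFrame with columns ``athlete_id, date, cycle_index,
    cycle_day, scheme, phase``. Under ``mc6`` only natural-cycle athletes
    with at least one complete cycle contribute (amenorrheic athletes drop
    out by construction); under ``hc`` only pill users, whose regimen is
    anchored by assuming withdrawal bleeding starts on pause day
    ``onset_pause_day``; under ``binary`` every record is labelled from its
    bleeding flag.
    """
    scheme = Scheme(scheme)
    prof_by_id = {p.athlete_id: p for p in profiles}
    rows: list[dict] = []
    if scheme is Scheme.BINARY:
        for r in records:
            rows.append(
                dict(
                    athlete_id=r.athlete_id,
                    date=r.date,
                    cycle_index=None,
                    cycle_day=None,
                    scheme=scheme.value,
                    phase=classify_binary(r).value,
                )
            )
        return pd.DataFrame(rows, columns=["athlete_id", "date", "cycle_index", "cycle_day", "scheme", "phase"])

    by_athlete: dict[str, list[DailyRecord]] = {}
    for r in records:
        by_athlete.setdefault(r.athlete_id, []).append(r)

    want = Group.NATURAL_MC if scheme is Scheme.MC6 else Group.HC_USER
    for athlete_id, recs in by_athlete.items():
        profile = prof_by_id.get(athlete_id)
        if profile is None or profile.group is not want:
            continue
        cycles = segment_cycles(recs, windows)
        for cycle in cycles:
            for r in recs:
                day = cycle.cycle_day(r.date)
                if day is None:
                    continue
                if scheme is Scheme.MC6:
                    phase = classify_mc_phase(day, cycle, windows).value
                else:
                    pack = profile.pack_length
                    regimen_day = (day - 1 + onset_pause_day - 1) % pack + 1
                    phase = classify_hc_phase(regimen_day, profile, split_after_active).value
                rows.append(
                    dict(
                        athlete_id=athlete_id,
                        date=r.date,
                        cycle_index=cycle.cycle_index,
                        cycle_day=day,
                        scheme=scheme.value,
                        phase=phase,
                    )
                )
    return pd.DataFrame(rows, columns=["athlete_id", "date", "cycle_index", "cycle_day", "scheme", "phase"])


# ---------------------------------------------------------------------------
# hormone cross-check


@dataclass(frozen=True)
class HormonePhaseSummary:
    """Per-phase mean ± SD of salivary estradiol and progesterone (pg/mL)."""

    phase: Mc6Phase
    estradiol_mean: float
    estradiol_sd: float
    progesterone_mean: float
    progesterone_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.estradiol_sd < 0 or self.progesterone_sd < 0:
            raise ValueError("sd must be >= 0")


def hormone_phase_summaries(samples: Iterable[HormoneSample]) -> dict[Mc6Phase, HormonePhaseSummary]:
    """Summarise hormone draws per sampled phase (nominal day 8/14/24)."""
    import numpy as np

    buckets: dict[Mc6Phase, list[HormoneSample]] = {}
    for s in samples:
        buckets.setdefault(NOMINAL_DAY_PHASE[s.nominal_day], []).append(s)
    out = {}
    for phase, ss in buckets.items():
        e = np.array([s.estradiol for s in ss])
        p = np.array([s.progesterone for s in ss])
        out[phase] = HormonePhaseSummary(
            phase=phase,
            estradiol_mean=float(e.mean()),
            estradiol_sd=float(e.std(ddof=1)) if len(e) > 1 else 0.0,
            progesterone_mean=float(p.mean()),
            progesterone_sd=float(p.std(ddof=1)) if len(p) > 1 else 0.0,
            n=len(ss),
        )
    return out


@dataclass(frozen=True)
class OrderingCheck:
    """Consistency of observed hormone levels with the expected phase ordering.

    Expected physiology: progesterone peaks in the mid-luteal phase,
    estradiol peaks in the late-follicular phase, and both hormones are at
    their lowest in the mid-follicular phase. Each field is True (pass),
    False (fail) or None (indeterminate: a required phase is missing).
    """

    progesterone_peak_mid_luteal: bool | None
    estradiol_peak_late_follicular: bool | None
    both_lowest_mid_follicular: bool | None

    @property
    def all_pass(self) -> bool:
        return all(
            v is True
            for v in (
                self.progesterone_peak_mid_luteal,
                self.estradiol_peak_late_follicular,
                self.both_lowest_mid_follicular,
            )
        )


def check_hormone_ordering(
    summaries: Mapping[Mc6Phase, HormonePhaseSummary]
) -> OrderingCheck:
    """Check observed per-phase hormone means against the expected ordering.

    Ties fail (a peak/trough must be strict); a missing phase makes the
    affected check indeterminate (None).
    """
    mf = summaries.get(Mc6Phase.MID_FOLLICULAR)
    lf = summaries.get(Mc6Phase.LATE_FOLLICULAR)
    ml = summaries.get(Mc6Phase.MID_LUTEAL)

    def prog_peak() -> bool | None:
        if ml is None or mf is None or lf is None:
            return None
        return ml.progesterone_mean > max(mf.progesterone_mean, lf.progesterone_mean)

    def e2_peak() -> bool | None:
        if lf is None or mf is None or ml is None:
            return None
        return lf.estradiol_mean > max(mf.estradiol_mean, ml.estradiol_mean)

    def lowest_mf() -> bool | None:
        if mf is None or lf is None or ml is None:
            return None
        return mf.estradiol_mean < min(lf.estradiol_mean, ml.estradiol_mean) and (
            mf.progesterone_mean < min(lf.progesterone_mean, ml.progesterone_mean)
        )

    return OrderingCheck(
        progesterone_peak_mid_luteal=prog_peak(),
        estradiol_peak_late_follicular=e2_peak(),
        both_lowest_mid_follicular=lowest_mf(),
    )
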