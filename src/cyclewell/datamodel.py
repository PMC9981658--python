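"""Domain types, CSV readers/writers and validation for longitudinal monitoring data.

The package works with three long-format tables:

``daily.csv``
    one row per athlete-day of self-report (bleeding flag, 1-10 Likert
    wellness/performance scores, Borg CR10 RPE, sleep, symptoms, pain,
    optional coach score),
``athletes.csv``
    the roster (contraception group and pill regimen), and
``hormones.csv``
    salivary estradiol/progesterone samples at nominal cycle days 8/14/24 +- 2.

All files are comma-separated UTF-8 with ISO-8601 dates; missing values are
empty cells. Bedtime is stored internally as minutes after 12:00 noon so that
late-night bedtimes stay monotone (22:00 -> 600 precedes 01:00 -> 780), which
keeps rank correlations meaningful; on disk it is a wall-clock ``HH:MM``.
Sleep duration is stored as decimal hours, on disk as ``HH:MM``.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Group",
    "PillType",
    "AthleteProfile",
    "DailyRecord",
    "HormoneSample",
    "ValidationReport",
    "CANONICAL_SYMPTOMS",
    "DAILY_COLUMNS",
    "read_daily_csv",
    "write_daily_csv",
    "read_athletes_csv",
    "write_athletes_csv",
    "read_hormones_csv",
    "write_hormones_csv",
    "validate_cohort",
]


class Group(str, Enum):
    """Contraception status of an athlete."""

    NATURAL_MC = "natural_mc"
    HC_USER = "hc_user"


class PillType(str, Enum):
    NONE = "none"
    MONOPHASIC = "monophasic"
    BIPHASIC = "biphasic"
    TRIPHASIC = "triphasic"


#: Canonical symptom vocabulary. The list is a seed, not a closed set: any
#: free-text symptom code found in the data is accepted.
CANONICAL_SYMPTOMS = (
    "digestive_troubles",
    "cramps",
    "headaches",
    "breast_tenderness",
    "back_pain",
    "fatigue",
    "bloating",
    "mood_swings",
)

DAILY_COLUMNS = (
    "athlete_id",
    "date",
    "bleeding",
    "sleep_quality",
    "fitness",
    "mood",
    "self_performance",
    "rpe",
    "sleep_duration",
    "bedtime",
    "symptoms",
    "pain_intensity",
    "coach_performance",
)

_LIKERT_FIELDS = ("sleep_quality", "fitness", "mood", "self_performance")


@dataclass(frozen=True)
class AthleteProfile:
    """Roster entry: contraception group and, for pill users, the regimen.

    ``active_days``/``pause_days`` describe the pill pack (default 21 pill
    days followed by a 7-day withdrawal break).
    """

    athlete_id: str
    group: Group
    pill_type: PillType = PillType.NONE
    active_days: int = 21
    pause_days: int = 7

    def __post_init__(self) -> None:
        if self.group is Group.NATURAL_MC and self.pill_type is not PillType.NONE:
            raise ValueError(
                f"athlete {self.athlete_id}: natural_mc group requires pill_type=none"
            )
        if self.group is Group.HC_USER:
            if self.pill_type is PillType.NONE:
                raise ValueError(
                    f"athlete {self.athlete_id}: hc_user group requires a pill_type"
                )
            if self.active_days < 1 or self.pause_days < 0:
                raise ValueError(
                    f"athlete {self.athlete_id}: need active_days >= 1, pause_days >= 0"
                )

    @property
    def pack_length(self) -> int:
        return self.active_days + self.pause_days


@dataclass(frozen=True)
class DailyRecord:
    """One athlete-day of self-reported monitoring.

    Likert scores (``sleep_quality``, ``fitness``, ``mood``,
    ``self_performance``, ``coach_performance``) are 1-10 integers; ``rpe``
    is the Borg CR10 0-10 scale and may take half points;
    ``pain_intensity`` is 0-10. Any of these may be ``None`` (not reported).
    """

    athlete_id: str
    date: dt.date
    bleeding: bool
    sleep_quality: int | None = None
    fitness: int | None = None
    mood: int | None = None
    self_performance: int | None = None
    rpe: float | None = None
    sleep_duration: float | None = None  # hours
    bedtime: float | None = None  # minutes after 12:00 noon
    symptoms: frozenset[str] = frozenset()
    pain_intensity: int | None = None
    coach_performance: int | None = None

    def __post_init__(self) -> None:
        for name in _LIKERT_FIELDS + ("coach_performance",):
            v = getattr(self, name)
            if v is not None and not 1 <= v <= 10:
                raise ValueError(f"{name} must be in 1..10, got {v!r}")
        if self.rpe is not None and not 0 <= self.rpe <= 10:
            raise ValueError(f"rpe must be in 0..10, got {self.rpe!r}")
        if self.pain_intensity is not None and not 0 <= self.pain_intensity <= 10:
            raise ValueError(f"pain_intensity must be in 0..10, got {self.pain_intensity!r}")
        if self.sleep_duration is not None and self.sleep_duration < 0:
            raise ValueError(f"sleep_duration must be >= 0, got {self.sleep_duration!r}")
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))


@dataclass(frozen=True)
class HormoneSample:
    """One salivary hormone draw (estradiol/progesterone in pg/mL).

    Samples target nominal cycle days 8 (mid-follicular), 14 (late
    follicular) and 24 (mid-luteal), each within a +-2 day window.
    """

    athlete_id: str
    date: dt.date
    cycle_day: int
    nominal_day: int
    estradiol: float
    progesterone: float

    def __post_init__(self) -> None:
        if self.nominal_day not in (8, 14, 24):
            raise ValueError(f"nominal_day must be 8, 14 or 24, got {self.nominal_day}")
        if self.cycle_day < 1:
            raise ValueError("cycle_day must be >= 1")
        if abs(self.cycle_day - self.nominal_day) > 2:
            raise ValueError(
                f"cycle_day {self.cycle_day} outside the +-2 day window of "
                f"nominal day {self.nominal_day}"
            )
        if self.estradiol <= 0 or self.progesterone <= 0:
            raise ValueError("hormone concentrations must be positive")


# ---------------------------------------------------------------------------
# field-level parsing helpers


def _parse_hhmm_or_float(text: str) -> float:
    """Return hours as a float from either 'HH:MM' or a decimal string."""
    if ":" in text:
        h, m = text.split(":")
        return (int(h) * 60 + int(m)) / 60.0
    return float(text)


def clock_to_minutes_after_noon(text: str) -> float:
    """Map a wall-clock 'HH:MM' bedtime to minutes after 12:00 noon.

    Times from noon to midnight map to 0..719; times after midnight continue
    720..1439, so a 01:00 bedtime sorts later than 22:00.
    """
    if ":" not in text:
        return float(text)  # already encoded numerically
    h, m = (int(p) for p in text.split(":"))
    minutes = h * 60 + m
    return float(minutes - 720 if minutes >= 720 else minutes + 720)


def minutes_after_noon_to_clock(minutes: float) -> str:
    total = int(round(minutes)) + 720
    total %= 1440
    return f"{total // 60:02d}:{total % 60:02d}"


def _hours_to_hhmm(hours: float) -> str:
    total = int(round(hours * 60))
    return f"{total // 60:02d}:{total % 60:02d}"


def _parse_daily_row(row: dict[str, str], rownum: int) -> DailyRecord:
    def fail(fieldname: str, detail: str) -> ValueError:
        return ValueError(f"daily.csv row {rownum}, field '{fieldname}': {detail}")

    def opt(fieldname: str, conv):
        cell = (row.get(fieldname) or "").strip()
        if cell == "":
            return None
        try:
            return conv(cell)
        except (ValueError, TypeError) as exc:
            raise fail(fieldname, f"cannot parse {cell!r}") from exc

    athlete_id = (row.get("athlete_id") or "").strip()
    if not athlete_id:
        raise fail("athlete_id", "empty")
    try:
        date = dt.date.fromisoformat((row.get("date") or "").strip())
    except ValueError as exc:
        raise fail("date", f"not ISO-8601: {row.get('date')!r}") from exc
    bleed_cell = (row.get("bleeding") or "").strip().lower()
    if bleed_cell in ("1", "true", "yes"):
        bleeding = True
    elif bleed_cell in ("0", "false", "no", ""):
        bleeding = False
    else:
        raise fail("bleeding", f"not a boolean: {bleed_cell!r}")

    symptoms_cell = (row.get("symptoms") or "").strip()
    symptoms = frozenset(
        s.strip() for s in symptoms_cell.split(";") if s.strip()
    )

    kwargs = dict(
        athlete_id=athlete_id,
        date=date,
        bleeding=bleeding,
        sleep_quality=opt("sleep_quality", lambda c: int(c)),
        fitness=opt("fitness", lambda c: int(c)),
        mood=opt("mood", lambda c: int(c)),
        self_performance=opt("self_performance", lambda c: int(c)),
        rpe=opt("rpe", float),
        sleep_duration=opt("sleep_duration", _parse_hhmm_or_float),
        bedtime=opt("bedtime", clock_to_minutes_after_noon),
        symptoms=symptoms,
        pain_intensity=opt("pain_intensity", lambda c: int(c)),
        coach_performance=opt("coach_performance", lambda c: int(c)),
    )
    # range-check one field at a time so the error names the offending field
    probe = dict(kwargs)
    for name in _LIKERT_FIELDS + ("coach_performance",):
        v = probe[name]
        if v is not None and not 1 <= v <= 10:
            raise fail(name, f"Likert value {v} outside 1..10")
    if probe["rpe"] is not None and not 0 <= probe["rpe"] <= 10:
        raise fail("rpe", f"CR10 value {probe['rpe']} outside 0..10")
    if probe["pain_intensity"] is not None and not 0 <= probe["pain_intensity"] <= 10:
        raise fail("pain_intensity", f"value {probe['pain_intensity']} outside 0..10")
    return DailyRecord(**kwargs)


def read_daily_csv(path: str | Path) -> list[DailyRecord]:
    """Read ``daily.csv`` into a list of :class:`DailyRecord`.

    Empty cells map to missing; the symptoms cell is split on ``;``.
    Malformed rows raise ``ValueError`` naming the row number and field.
    """
    records: list[DailyRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        for rownum, row in enumerate(reader, start=2):
            records.append(_parse_daily_row(row, rownum))
    return records


def write_daily_csv(path: str | Path, records: Iterable[DailyRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DAILY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.athlete_id,
                    r.date.isoformat(),
                    int(r.bleeding),
                    "" if r.sleep_quality is None else r.sleep_quality,
                    "" if r.fitness is None else r.fitness,
                    "" if r.mood is None else r.mood,
                    "" if r.self_performance is None else r.self_performance,
                    "" if r.rpe is None else (int(r.rpe) if float(r.rpe).is_integer() else r.rpe),
                    "" if r.sleep_duration is None else _hours_to_hhmm(r.sleep_duration),
                    "" if r.bedtime is None else minutes_after_noon_to_clock(r.bedtime),
                    ";".join(sorted(r.symptoms)),
                    "" if r.pain_intensity is None else r.pain_intensity,
                    "" if r.coach_performance is None else r.coach_performance,
                ]
            )


def read_athletes_csv(path: str | Path) -> list[AthleteProfile]:
    profiles: list[AthleteProfile] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rownum, row in enumerate(csv.DictReader(fh), start=2):
            try:
                group = Group(row["group"].strip())
                pill = PillType((row.get("pill_type") or "none").strip() or "none")
                profiles.append(
                    AthleteProfile(
                        athlete_id=row["athlete_id"].strip(),
                        group=group,
                        pill_type=pill,
                        active_days=int(row["active_days"]) if (row.get("active_days") or "").strip() else 21,
                        pause_days=int(row["pause_days"]) if (row.get("pause_days") or "").strip() else 7,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"athletes.csv row {rownum}: {exc}") from exc
    return profiles


def write_athletes_csv(path: str | Path, profiles: Iterable[AthleteProfile]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["athlete_id", "group", "pill_type", "active_days", "pause_days"])
        for p in profiles:
            if p.group is Group.HC_USER:
                writer.writerow([p.athlete_id, p.group.value, p.pill_type.value, p.active_days, p.pause_days])
            else:
                writer.writerow([p.athlete_id, p.group.value, p.pill_type.value, "", ""])


def read_hormones_csv(path: str | Path) -> list[HormoneSample]:
    samples: list[HormoneSample] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rownum, row in enumerate(csv.DictReader(fh), start=2):
            try:
                samples.append(
                    HormoneSample(
                        athlete_id=row["athlete_id"].strip(),
                        date=dt.date.fromisoformat(row["date"].strip()),
                        cycle_day=int(row["cycle_day"]),
                        nominal_day=int(row["nominal_day"]),
                        estradiol=float(row["estradiol"]),
                        progesterone=float(row["progesterone"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"hormones.csv row {rownum}: {exc}") from exc
    return samples


def write_hormones_csv(path: str | Path, samples: Iterable[HormoneSample]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["athlete_id", "date", "cycle_day", "nominal_day", "estradiol", "progesterone"])
        for s in samples:
            writer.writerow(
                [s.athlete_id, s.date.isoformat(), s.cycle_day, s.nominal_day,
                 f"{s.estradiol:.6g}", f"{s.progesterone:.6g}"]
            )


# ---------------------------------------------------------------------------
# cohort validation


@dataclass
class ValidationReport:
    """Report-only consistency check of a cohort; never mutates data.

    ``amenorrhea_candidates`` lists athletes who never declared bleeding over
    their whole follow-up; such athletes are excluded from phase-based
    analyses downstream.
    """

    amenorrhea_candidates: list[str] = field(default_factory=list)
    duplicate_days: list[tuple[str, dt.date]] = field(default_factory=list)
    unknown_athletes: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.amenorrhea_candidates or self.duplicate_days or self.unknown_athletes)


def validate_cohort(
    profiles: Sequence[AthleteProfile], records: Sequence[DailyRecord]
) -> ValidationReport:
    report = ValidationReport()
    known = {p.athlete_id for p in profiles}
    seen: set[tuple[str, dt.date]] = set()
    bled: dict[str, bool] = {p.athlete_id: False for p in profiles}
    responded: set[str] = set()
    for r in records:
        if r.athlete_id not in known:
            if r.athlete_id not in report.unknown_athletes:
                report.unknown_athletes.append(r.athlete_id)
            continue
        key = (r.athlete_id, r.date)
        if key in seen:
            report.duplicate_days.append(key)
        seen.add(key)
        responded.add(r.athlete_id)
        bled[r.athlete_id] = bled[r.athlete_id] or r.bleeding
    for athlete_id in sorted(responded):
        if not bled[athlete_id]:
            report.amenorrhea_candidates.append(athlete_id)
    return report


def records_to_frame(records: Sequence[DailyRecord]):
    """Long-format pandas DataFrame view of the records (for analyses)."""
    import pandas as pd

    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["symptoms"] = r.symptoms
        d["n_symptoms"] = len(r.symptoms)
        rows.append(d)
    return pd.DataFrame(rows)
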