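"""Top-quintile enrichment of monitoring scores across cycle phases.

The statistic works per athlete and per variable:

1. each athlete-day is flagged 1 when the day's score strictly exceeds the
   athlete's own 0.8-quantile for that variable (their "top 20%" days),
2. per-phase flag *rates* (flagged days / observed days in the phase) are
   averaged over athletes and rescaled to the raw total of flagged days, so
   that unequal phase lengths and unequal follow-up do not masquerade as
   phase effects,
3. the resulting per-phase counts are tested against a discrete uniform
   distribution with parameter 1/k (k = number of phases) by a chi-square
   goodness-of-fit test, and
4. when the omnibus test is significant at alpha = 0.05, per-phase Pearson
   residuals (O−E)/sqrt(E) are read against the standard-normal critical
   values 1.96 (alpha = 0.05) and 1.64 (alpha = 0.1) to flag the phases in
   which top scores are over- or under-represented.

Symptom declarations are tabulated as raw sums per phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AthleteProfile, DailyRecord, Group, PillType
from .phases import MC6_PHASES, BinaryPhase, HcPhase, PhaseWindows, DEFAULT_WINDOWS, Scheme, label_cohort

__all__ = [
    "Flag",
    "EnrichmentResult",
    "binarize_top_quintile",
    "normalized_phase_counts",
    "chisq_uniform_gof",
    "residual_flags",
    "symptom_sums",
    "run_enrichment",
    "phase_order_for",
]

#: two-sided standard-normal critical values used to read Pearson residuals
Z_CRIT_05 = float(stats.norm.ppf(1 - 0.05 / 2))  # 1.96
Z_CRIT_10 = float(stats.norm.ppf(1 - 0.10 / 2))  # 1.64


class Flag(str, Enum):
    OVER_05 = "over_05"
    OVER_10 = "over_10"
    UNDER_05 = "under_05"
    UNDER_10 = "under_10"
    NONE = "none"


@dataclass
class EnrichmentResult:
    """Chi-square goodness-of-fit of top-quintile days across phases."""

    variable: str
    scheme: str
    phase_order: tuple[str, ...]
    observed: np.ndarray  # normalized count per phase
    expected: np.ndarray  # total/k per phase
    chi2: float
    df: int
    p_value: float
    residuals: np.ndarray  # per-phase signed Pearson residuals
    flags: tuple[str, ...]
    n_athletes: int
    total_top_days: float

    @property
    def k(self) -> int:
        return len(self.phase_order)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                variable=self.variable,
                scheme=self.scheme,
                phase=list(self.phase_order),
                observed=self.observed,
                expected=self.expected,
                residual=self.residuals,
                flag=list(self.flags),
                chi2=self.chi2,
                df=self.df,
                p=self.p_value,
            )
        )


def binarize_top_quintile(
    values: Sequence[float], quantile: float = 0.8, min_n: int = 5
) -> np.ndarray | None:
    """Flag values strictly above the athlete's own empirical 0.8-quantile.

    The quantile is the ceil(q*n)-th order statistic of the athlete's
    non-missing values; the strict ``>`` means ties at the quantile are not
    flagged, so heavily tied Likert data never flag more than (1-q) of days.
    Returns an int array aligned with ``values`` (missing days get 0 but
    should be excluded upstream), or None with a warning when fewer than
    ``min_n`` values are available.
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n < min_n:
        warnings.warn(f"only {n} non-missing values (< {min_n}): skipped", stacklevel=2)
        return None
    order = np.sort(arr[mask])
    rank = int(np.ceil(quantile * n))  # 1-based order statistic
    q = order[rank - 1]
    out = np.zeros(arr.shape, dtype=int)
    out[mask] = (arr[mask] > q).astype(int)
    return out


def normalized_phase_counts(
    table: pd.DataFrame,
    phase_order: Sequence[str],
    normalize: bool = True,
    by_cycle: bool = False,
) -> np.ndarray:
    """Exposure-normalized per-phase counts of top-flagged days.

    ``table`` needs columns ``athlete_id``, ``phase``, ``top`` (0/1) and,
    when ``by_cycle``, ``cycle_index``. Per averaging unit (athlete by
    default, athlete-cycle when ``by_cycle``) the per-phase flag rate is
    computed over that unit's observed days; rates are averaged across units
    (units with no exposure in a phase contribute nothing there) and rescaled
    so the counts sum to the raw total of flagged days. With
    ``normalize=False`` the raw flagged counts are returned instead (a
    sensitivity variant).
    """
    for phase in phase_order:
        if (table["phase"] == phase).sum() == 0:
            raise ValueError(f"phase '{phase}' has no observed days cohort-wide")
    total = float(table["top"].sum())
    if not normalize:
        counts = table.groupby("phase")["top"].sum()
        return np.array([float(counts.get(p, 0.0)) for p in phase_order])
    unit_cols = ["athlete_id", "cycle_index"] if by_cycle else ["athlete_id"]
    grouped = table.groupby(unit_cols + ["phase"], sort=False)["top"].agg(["sum", "count"])
    rates = (grouped["sum"] / grouped["count"]).rename("rate").reset_index()
    mean_rates = rates.groupby("phase")["rate"].mean()
    raw = np.array([float(mean_rates.get(p, 0.0)) for p in phase_order])
    s = raw.sum()
    if s == 0 or total == 0:
        return np.zeros(len(phase_order))
    return raw * (total / s)


def chisq_uniform_gof(observed: Sequence[float], k: int | None = None) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit against a discrete uniform 1/k.

    Expected count is total/k in every phase; returns (chi2, df, p) with
    df = k − 1 and p from the chi-square upper tail.
    """
    obs = np.asarray(observed, dtype=float)
    if k is None:
        k = len(obs)
    if k < 2:
        raise ValueError("need k >= 2 phases")
    if len(obs) != k:
        raise ValueError("observed length must equal k")
    total = obs.sum()
    if total <= 0:
        raise ValueError("sum of observed counts must be positive")
    expected = np.full(k, total / k)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def residual_flags(
    observed: Sequence[float],
    expected: Sequence[float],
    global_p: float | None = None,
    gate_alpha: float = 0.05,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Pearson residuals (O−E)/sqrt(E) and over/under flags per phase.

    ``|r| > 1.96`` flags at alpha = 0.05, ``1.64 < |r| <= 1.96`` at
    alpha = 0.1. Residual flags are only meaningful when the omnibus
    chi-square test rejects: when ``global_p`` is given and is not below
    ``gate_alpha``, all flags are suppressed to ``none`` (the residuals are
    still returned).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    r = (obs - exp) / np.sqrt(exp)
    gated = global_p is not None and not (global_p < gate_alpha)
    flags = []
    for z in r:
        if gated:
            flags.append(Flag.NONE.value)
        elif z > Z_CRIT_05:
            flags.append(Flag.OVER_05.value)
        elif z > Z_CRIT_10:
            flags.append(Flag.OVER_10.value)
        elif z < -Z_CRIT_05:
            flags.append(Flag.UNDER_05.value)
        elif z < -Z_CRIT_10:
            flags.append(Flag.UNDER_10.value)
        else:
            flags.append(Flag.NONE.value)
    return r, tuple(flags)


def symptom_sums(records: Sequence[DailyRecord], labels: pd.DataFrame) -> pd.DataFrame:
    """Raw counts of declared symptoms per phase (no normalization).

    ``labels`` is a frame from :func:`cyclewell.phases.label_cohort`. Returns
    a phase × symptom count table with a ``total`` column.
    """
    key = {(row.athlete_id, row.date): row.phase for row in labels.itertuples()}
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        phase = key.get((r.athlete_id, r.date))
        if phase is None:
            continue
        bucket = counts.setdefault(phase, {})
        for s in r.symptoms:
            bucket[s] = bucket.get(s, 0) + 1
    phases = list(labels["phase"].unique())
    symptoms = sorted({s for b in counts.values() for s in b})
    out = pd.DataFrame(
        [[counts.get(p, {}).get(s, 0) for s in symptoms] for p in phases],
        index=pd.Index(phases, name="phase"),
        columns=symptoms,
    )
    out["total"] = out.sum(axis=1)
    return out


def phase_order_for(scheme: Scheme | str, profiles: Sequence[AthleteProfile]) -> tuple[str, ...]:
    """Phase label order (and hence k) for a scheme on a given roster."""
    scheme = Scheme(scheme)
    if scheme is Scheme.MC6:
        return MC6_PHASES
    if scheme is Scheme.BINARY:
        return (BinaryPhase.MENSES.value, BinaryPhase.NO_MENSES.value)
    hc = [p for p in profiles if p.group is Group.HC_USER]
    if any(p.pill_type in (PillType.BIPHASIC, PillType.TRIPHASIC) for p in hc):
        return (HcPhase.PAUSE.value, HcPhase.PHASE1.value, HcPhase.PHASE2.value)
    return (HcPhase.PAUSE.value, HcPhase.PHASE1.value)


def run_enrichment(
    records: Sequence[DailyRecord],
    profiles: Sequence[AthleteProfile],
    scheme: Scheme | str,
    variables: Sequence[str] = ("sleep_quality", "fitness", "mood", "self_performance"),
    quantile: float = 0.8,
    windows: PhaseWindows = DEFAULT_WINDOWS,
    normalize: bool = True,
    by_cycle: bool = False,
    gate_on_significance: bool = True,
    bonferroni: bool = False,
    labels: pd.DataFrame | None = None,
) -> list[EnrichmentResult]:
    """Full enrichment pipeline for one scheme.

    Labels phases (mc6 for the natural-cycle group, hc for pill users,
    binary pooled across all athletes), binarizes each variable per athlete
    at their own top quintile, and tests the exposure-normalized phase
    distribution of top days against uniformity. Athletes lacking enough
    data for a variable drop out of that variable only; amenorrheic athletes
    never receive mc6 labels so they are excluded by construction.
    """
    scheme = Scheme(scheme)
    if labels is None:
        labels = label_cohort(records, profiles, scheme, windows)
    if labels.empty:
        raise ValueError(f"no phase-labelled days for scheme {scheme.value}")
    phase_order = phase_order_for(scheme, profiles)
    phase_order = tuple(p for p in phase_order if (labels["phase"] == p).any())

    rec_rows = []
    for r in records:
        rec_rows.append(
            dict(
                athlete_id=r.athlete_id,
                date=r.date,
                **{v: getattr(r, v) for v in variables},
            )
        )
    rec_df = pd.DataFrame(rec_rows)
    merged = labels.merge(rec_df, on=["athlete_id", "date"], how="left")

    gate_alpha = 0.05 / len(variables) if bonferroni else 0.05
    results: list[EnrichmentResult] = []
    for variable in variables:
        parts = []
        for athlete_id, sub in merged.groupby("athlete_id", sort=False):
            vals = sub[variable].to_numpy(dtype=float)
            present = ~np.isnan(vals)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                top = binarize_top_quintile(vals[present], quantile)
            if top is None:
                continue
            part = sub.loc[present, ["athlete_id", "cycle_index", "phase"]].copy()
            part["top"] = top
            parts.append(part)
        if not parts:
            warnings.warn(f"variable '{variable}': no athlete had enough data", stacklevel=2)
            continue
        table = pd.concat(parts, ignore_index=True)
        observed = normalized_phase_counts(table, phase_order, normalize=normalize, by_cycle=by_cycle)
        if observed.sum() <= 0:
            warnings.warn(f"variable '{variable}': no top-flagged days", stacklevel=2)
            continue
        chi2, df, p = chisq_uniform_gof(observed, k=len(phase_order))
        expected = np.full(len(phase_order), observed.sum() / len(phase_order))
        resid, flags = residual_flags(
            observed,
            expected,
            global_p=p if gate_on_significance else None,
            gate_alpha=gate_alpha,
        )
        results.append(
            EnrichmentResult(
                variable=variable,
                scheme=scheme.value,
                phase_order=phase_order,
                observed=observed,
                expected=expected,
                chi2=chi2,
                df=df,
                p_value=p,
                residuals=resid,
                flags=flags,
                n_athletes=table["athlete_id"].nunique(),
                total_top_days=float(table["top"].sum()),
            )
        )
    return results
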