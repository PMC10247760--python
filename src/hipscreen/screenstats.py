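"""Screening-program statistics: per-infant ledger, cohort summary, referral
confirmation, and rolling follow-up-rate learning curves.

The ledger holds one row per infant (latest status) with the initial scan
outcome (``COULD_NOT_SCAN`` / ``NORMAL`` / ``SUBOPTIMAL`` / ``FOLLOW_UP``),
the internal follow-up outcome where one happened, and the external referral
outcome.  Percentages are always recomputed from integer counts with
half-away-from-zero rounding at a declared number of decimals per field, so
a summary can never disagree with its own counts.

A packaged 306-infant fixture ledger reproduces the pilot-study cohort
arithmetic: 18 could not be scanned (5.9%), 244 normal at first scan (80%),
12 suboptimal scans (3.9%), 32 AI follow-up recommendations (10%) of which
26 resolved normal at internal follow-up and 6 (2.0%) were referred and all
treated for dysplasia; 156 infants (51%) are female.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UndefinedRateError, ValidationError

# initial_outcome values
COULD_NOT_SCAN = "COULD_NOT_SCAN"
NORMAL = "NORMAL"
SUBOPTIMAL = "SUBOPTIMAL"
FOLLOW_UP = "FOLLOW_UP"
INITIAL_OUTCOMES = (COULD_NOT_SCAN, NORMAL, SUBOPTIMAL, FOLLOW_UP)

# internal_fu_outcome / referral_outcome values
DYSPLASTIC = "DYSPLASTIC"
NONE = "NONE"
TREATED = "TREATED"
NOT_TREATED = "NOT_TREATED"

USER_ROLES = ("RN", "LPN", "sonographer", "physician", "unknown")

LEDGER_COLUMNS = [
    "subject_id", "scan_date", "site", "user_role", "sex",
    "initial_outcome", "internal_fu_outcome", "referred", "referral_outcome",
]

#: outcomes that trigger an internal follow-up visit
FU_TRIGGERING = (SUBOPTIMAL, FOLLOW_UP)

#: decimals reported per summary field: one decimal for the low-prevalence
#: categories, integers for the large ones
DEFAULT_ROUNDING = {
    "could_not_scan": 1,
    "normal": 0,
    "suboptimal": 1,
    "follow_up": 0,
    "fu_resolved_normal": 1,
    "dysplastic_treated": 1,
    "female": 0,
}


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (the convention printed tables follow)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScreeningRecord:
    """One infant's screening outcome (latest status)."""

    subject_id: str
    scan_date: str                 # ISO-8601
    site: str
    user_role: str
    sex: str                       # F / M / U
    initial_outcome: str
    internal_fu_outcome: str = NONE
    referred: bool = False
    referral_outcome: str = NONE

    def __post_init__(self) -> None:
        if self.initial_outcome not in INITIAL_OUTCOMES:
            raise ValidationError(f"unknown initial_outcome {self.initial_outcome!r}")
        if self.user_role not in USER_ROLES:
            raise ValidationError(f"unknown user_role {self.user_role!r}")
        if self.internal_fu_outcome != NONE and self.initial_outcome not in FU_TRIGGERING:
            raise ValidationError(
                "internal_fu_outcome set without a follow-up-triggering initial outcome")
        if self.referral_outcome != NONE and not self.referred:
            raise ValidationError("referral_outcome set on a non-referred infant")


@dataclass
class CohortSummary:
    total_infants: int
    counts: dict[str, int]
    percentages: dict[str, float]
    rounding_spec: dict[str, int] = field(default_factory=dict)

    def to_json(self, **extra) -> str:
        return json.dumps(dict(total_infants=self.total_infants, counts=self.counts,
                               percentages=self.percentages,
                               rounding_spec=self.rounding_spec, **extra), indent=2)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    missing = set(LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"ledger is missing columns: {sorted(missing)}")
    return df


def read_ledger(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"referred": bool})
    missing = set(LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"ledger is missing columns: {sorted(missing)}")
    return df


def fixture_ledger_path() -> Path:
    """Path of the packaged 306-infant pilot-cohort fixture ledger."""
    return Path(resources.files("hipscreen").joinpath("data/pilot_cohort_ledger.csv"))


def summarize(records, rounding_spec: dict[str, int] | None = None) -> CohortSummary:
    """Tabulate the cohort: counts and percentages per outcome category.

    Percentages use the number of unique infants as denominator and are
    rounded half-away-from-zero at the per-field precision of
    ``rounding_spec`` (defaults to :data:`DEFAULT_ROUNDING`).
    """
    if hasattr(records, "__len__") and len(records) == 0:
        raise ValidationError("ledger is empty")
    df = _as_frame(records)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id in ledger: {dup!r}")
    rounding = dict(DEFAULT_ROUNDING)
    if rounding_spec:
        rounding.update(rounding_spec)

    n = len(df)
    out = df["initial_outcome"]
    counts = {
        "could_not_scan": int((out == COULD_NOT_SCAN).sum()),
        "normal": int((out == NORMAL).sum()),
        "suboptimal": int((out == SUBOPTIMAL).sum()),
        "follow_up": int((out == FOLLOW_UP).sum()),
        "fu_resolved_normal": int(((out == FOLLOW_UP)
                                   & (df["internal_fu_outcome"] == NORMAL)).sum()),
        "dysplastic_treated": int((df["referral_outcome"] == TREATED).sum()),
        "female": int((df["sex"] == "F").sum()),
    }
    pct = {k: round_half_away(100.0 * c / n, rounding[k]) for k, c in counts.items()}
    return CohortSummary(total_infants=n, counts=counts, percentages=pct,
                         rounding_spec=rounding)


def referral_confirmation_rate(records) -> float:
    """Percent of referred infants whose referral ended in treatment."""
    df = _as_frame(records)
    n_ref = int(df["referred"].sum())
    if n_ref == 0:
        raise UndefinedRateError("no referrals in ledger; confirmation rate undefined")
    n_treated = int((df["referral_outcome"] == TREATED).sum())
    return 100.0 * n_treated / n_ref


def rolling_fu_rate(records, window_size: int,
                    group_by: str | None = None) -> pd.DataFrame:
    """Trailing-window proportion of scans needing internal follow-up.

    Records are ordered by (scan_date, subject_id); at each position
    ``i >= window_size`` the rate is the fraction of the previous
    ``window_size`` records whose initial outcome was SUBOPTIMAL or
    FOLLOW_UP.  With ``group_by`` ("site" or "user_role") one series per
    group is returned.  Returns a DataFrame with columns
    (group, position, rate); positions are 1-based record counts.
    """
    if window_size < 1:
        raise ValidationError("window_size must be >= 1")
    if group_by not in (None, "site", "user_role"):
        raise ValidationError(f"unsupported group_by {group_by!r}")
    df = _as_frame(records).sort_values(["scan_date", "subject_id"], kind="mergesort")
    df["_fu"] = df["initial_outcome"].isin(FU_TRIGGERING).astype(float)

    def series(sub: pd.DataFrame, name: str) -> pd.DataFrame:
        vals = sub["_fu"].to_numpy()
        if len(vals) < window_size:
            return pd.DataFrame(columns=["group", "position", "rate"])
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        pos = np.arange(window_size, len(vals) + 1)
        rate = (csum[pos] - csum[pos - window_size]) / window_size
        return pd.DataFrame({"group": name, "position": pos, "rate": rate})

    if group_by is None:
        return series(df, "all").reset_index(drop=True)
    parts = [series(g, str(k)) for k, g in df.groupby(group_by, sort=True)]
    return pd.concat(parts, ignore_index=True)


def infant_outcome(left, right) -> str:
    """Roll two per-hip sweep decisions up to one infant-level outcome.

    The worst hip governs: any FOLLOW_UP hip refers the infant for internal
    follow-up; otherwise any INCONCLUSIVE hip means the scan was suboptimal
    and must be repeated; otherwise the infant screens NORMAL.
    """
    labels = {getattr(d, "label", d) for d in (left, right)}
    from .decision import FOLLOW_UP as HIP_FU, INCONCLUSIVE
    if HIP_FU in labels:
        return FOLLOW_UP
    if INCONCLUSIVE in labels:
        return SUBOPTIMAL
    return NORMAL


def build_pilot_cohort_ledger() -> pd.DataFrame:
    """Deterministically build the packaged 306-infant fixture ledger.

    Category sizes reproduce the pilot cohort: 18 COULD_NOT_SCAN, 244
    NORMAL, 12 SUBOPTIMAL (all resolving normal at internal follow-up), 32
    FOLLOW_UP of which 26 resolve normal and 6 are referred and treated;
    156 infants female (5 of the 6 treated); user roles RN 158 / LPN 49 /
    sonographer 24 / physician 65 / unknown 10.  Dates span the pilot
    period with follow-ups front-loaded, emulating the learning curve.
    """
    rng = np.random.default_rng(20210201)
    outcomes = ([COULD_NOT_SCAN] * 18 + [NORMAL] * 244 + [SUBOPTIMAL] * 12
                + [FOLLOW_UP] * 32)
    n = len(outcomes)
    # front-load follow-ups: draw each infant's position weight by outcome
    weight = np.where(np.isin(outcomes, (SUBOPTIMAL, FOLLOW_UP)),
                      rng.uniform(0.0, 0.7, n), rng.uniform(0.0, 1.0, n))
    order = np.argsort(weight, kind="stable")
    outcomes = [outcomes[i] for i in order]

    roles = ["RN"] * 158 + ["LPN"] * 49 + ["sonographer"] * 24 + ["physician"] * 65 \
        + ["unknown"] * 10
    rng.shuffle(roles)
    site_of = {"RN": "center1", "LPN": "center2", "physician": "center3"}

    dates = pd.date_range("2021-02-01", "2022-03-31", periods=n).strftime("%Y-%m-%d")
    fu_idx = [i for i, o in enumerate(outcomes) if o == FOLLOW_UP]
    referred_idx = set(rng.choice(fu_idx, size=6, replace=False).tolist())

    # 156 female; 5 of the 6 treated infants are female
    female = set(rng.choice([i for i in range(n) if i not in referred_idx],
                            size=156 - 5, replace=False).tolist())
    female |= set(sorted(referred_idx)[:5])

    rows = []
    for i, outcome in enumerate(outcomes):
        role = roles[i]
        referred = i in referred_idx
        rows.append(dict(
            subject_id=f"INF{i:04d}",
            scan_date=dates[i],
            site=site_of.get(role, f"center{1 + i % 3}"),
            user_role=role,
            sex="F" if i in female else "M",
            initial_outcome=outcome,
            internal_fu_outcome=(
                DYSPLASTIC if referred
                else NORMAL if outcome in FU_TRIGGERING
                else NONE),
            referred=referred,
            referral_outcome=TREATED if referred else NONE,
        ))
    return pd.DataFrame(rows, columns=LEDGER_COLUMNS)
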