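"""Domain types, file readers/validators, and covariate preparation.

The unit of observation is a dyadic grooming-handclasp event: two chimpanzees
clasp raised arms, and the arm region each one clasps (wrist, elbow, forearm,
palm, or a pooled "other" category) is recorded per performer.  Alongside the
event table, the data model carries a participant table (group membership, sex,
mother link, birth year), an observation-window table (field seasons), and a
long-format table of ordinal dominance-rank assessments provided independently
by several caretakers per window.

Covariate preparation turns the raw tables into the quantities the model uses:
per-window average ordinal rank, rank normalized to [0, 1] within each
group-window (1 = highest-ranking), age standardized over the pooled
individual-window rows, and a young/old age category split at a configurable
threshold (default 8 years).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed bijection between variant codes and arm-region labels.
VARIANT_LABELS: dict[int, str] = {
    1: "wrist",
    2: "elbow",
    3: "forearm",
    4: "other",
    5: "palm",
}
VARIANT_CODES: dict[str, int] = {v: k for k, v in VARIANT_LABELS.items()}
N_VARIANTS = 5

EVENT_COLUMNS = ["event_id", "window_id", "g1_id", "g2_id", "y_g1", "y_g2"]
INDIVIDUAL_COLUMNS = ["id", "group", "sex", "mother_id", "birth_year"]
RANK_COLUMNS = ["window_id", "individual_id", "rater_id", "ordinal_rank"]
WINDOW_COLUMNS = ["window_id", "year"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input value violates a data-model invariant."""


class DegenerateScaleError(ValueError):
    """A rescaling step has zero spread (all values identical)."""


def variant_code(value) -> int:
    """Map a variant label or code to its integer code (1..5).

    Labels are matched case-insensitively; integer-like inputs must already be
    a valid code.
    """
    if isinstance(value, str):
        s = value.strip().lower()
        if s in VARIANT_CODES:
            return VARIANT_CODES[s]
        if s.isdigit() and int(s) in VARIANT_LABELS:
            return int(s)
        raise ValidationError(f"unknown style variant {value!r}")
    code = int(value)
    if code not in VARIANT_LABELS:
        raise ValidationError(f"unknown style variant code {value!r}")
    return code


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_events(path: str | Path, *, sep: str = ",") -> pd.DataFrame:
    """Read and validate the handclasp event table.

    Expected columns: event_id, window_id, g1_id, g2_id, y_g1, y_g2.  Variant
    values may be given as labels (``palm``) or codes (``5``); the returned
    frame always carries integer codes.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    _require_columns(df, EVENT_COLUMNS, "events")
    df = df[EVENT_COLUMNS].copy()
    for col in ("y_g1", "y_g2"):
        codes = []
        for rownum, value in enumerate(df[col], start=2):  # 1-based + header
            try:
                codes.append(variant_code(value))
            except ValidationError as err:
                raise ValidationError(f"{path}, line {rownum}, column {col}: {err}") from None
        df[col] = np.asarray(codes, dtype=np.int64)
    same = df["g1_id"] == df["g2_id"]
    if same.any():
        bad = df.loc[same, "event_id"].iloc[0]
        raise ValidationError(f"event {bad!r} lists the same individual as both performers")
    if df["event_id"].duplicated().any():
        dup = df.loc[df["event_id"].duplicated(), "event_id"].iloc[0]
        raise ValidationError(f"duplicate event_id {dup!r}")
    return df


def read_individuals(path: str | Path, *, sep: str = ",") -> pd.DataFrame:
    """Read the participant table (id, group, sex, mother_id, birth_year)."""
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "mother_id": str})
    _require_columns(df, INDIVIDUAL_COLUMNS, "individuals")
    df = df[INDIVIDUAL_COLUMNS].copy()
    df["group"] = df["group"].astype(np.int64)
    df["sex"] = df["sex"].astype(np.int64)
    if not df["sex"].isin([0, 1]).all():
        raise ValidationError("sex must be coded 1 = male, 0 = female")
    df["birth_year"] = df["birth_year"].astype(float)
    df["mother_id"] = df["mother_id"].where(df["mother_id"].notna() & (df["mother_id"] != ""), None)
    if df["id"].duplicated().any():
        raise ValidationError("duplicate individual id")
    return df


def read_ranks(path: str | Path, *, sep: str = ",") -> pd.DataFrame:
    """Read the long-format rank table (window_id, individual_id, rater_id, ordinal_rank)."""
    df = pd.read_csv(path, sep=sep, dtype={"window_id": str, "individual_id": str, "rater_id": str})
    _require_columns(df, RANK_COLUMNS, "ranks")
    df = df[RANK_COLUMNS].copy()
    df["ordinal_rank"] = df["ordinal_rank"].astype(np.int64)
    if (df["ordinal_rank"] < 1).any():
        raise ValidationError("ordinal ranks must be positive integers (1 = highest)")
    return df


def read_windows(path: str | Path, *, sep: str = ",") -> pd.DataFrame:
    """Read the observation-window table (window_id, year[, period_label])."""
    df = pd.read_csv(path, sep=sep, dtype={"window_id": str})
    _require_columns(df, WINDOW_COLUMNS, "windows")
    df["year"] = df["year"].astype(float)
    if df["window_id"].duplicated().any():
        raise ValidationError("duplicate window_id")
    return df


# ---------------------------------------------------------------------------
# Covariate preparation
# ---------------------------------------------------------------------------

def aggregate_rank(ratings: Iterable[float]) -> float:
    """Average the per-rater ordinal rank assessments for one individual-window.

    The study design calls for three raters; fewer are tolerated with a logged
    warning, zero is an error.
    """
    vals = [float(r) for r in ratings if r is not None and np.isfinite(r)]
    if not vals:
        raise ValidationError("no rank ratings available for this individual-window")
    if any(v < 1 for v in vals):
        raise ValidationError("ordinal ranks must be >= 1")
    if len(vals) < 3:
        logger.warning("only %d rank rating(s) available; expected 3", len(vals))
    return float(np.mean(vals))


def normalize_rank(avg_ranks: Mapping[str, float], *, on_degenerate: str = "error") -> dict[str, float]:
    """Linearly rescale averaged ordinal ranks within one group-window to [0, 1].

    The best (lowest ordinal) average maps to 1, the worst to 0:
    ``norm = (max_avg - avg) / (max_avg - min_avg)``.

    If every average is identical the scale is degenerate; by default this is
    an error, or with ``on_degenerate="midpoint"`` every individual is assigned
    0.5 with a warning.
    """
    if len(avg_ranks) < 2:
        raise ValidationError("rank normalization needs at least two individuals in scope")
    vals = np.asarray(list(avg_ranks.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        if on_degenerate == "midpoint":
            warnings.warn("all average ranks equal; assigning 0.5 to every individual")
            return {k: 0.5 for k in avg_ranks}
        raise DegenerateScaleError("all average ranks equal within this group-window")
    return {k: float((hi - v) / (hi - lo)) for k, v in avg_ranks.items()}


def standardize_age(ages: np.ndarray | Iterable[float]) -> np.ndarray:
    """Z-score ages over the pooled covariate rows from all groups.

    Uses the population standard deviation; output has mean 0 and SD 1.
    """
    a = np.asarray(list(ages), dtype=float)
    if a.size < 2:
        raise ValidationError("age standardization needs at least two rows")
    sd = a.std()
    if sd == 0:
        raise DegenerateScaleError("all ages identical; cannot standardize")
    return (a - a.mean()) / sd


def assign_age_category(age_years: float, threshold: float = 8.0) -> str:
    """Classify an age as ``young`` (<= threshold) or ``old`` (> threshold)."""
    if age_years < 0:
        raise ValidationError(f"negative age {age_years}")
    return "young" if age_years <= threshold else "old"


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A validated handclasp study dataset.

    Holds the four input tables; `covariates()` derives the per
    (individual, window) model covariates from them.
    """

    individuals: pd.DataFrame
    windows: pd.DataFrame
    ranks: pd.DataFrame
    events: pd.DataFrame
    n_groups: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_groups == 0:
            self.n_groups = int(self.individuals["group"].nunique()) if len(self.individuals) else 0
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        ids = set(self.individuals["id"])
        wids = set(self.windows["window_id"])
        ev = self.events
        if len(ev):
            for col in ("g1_id", "g2_id"):
                unknown = set(ev[col]) - ids
                if unknown:
                    raise ValidationError(f"event column {col} references unknown individual(s): {sorted(unknown)[:3]}")
            unknown_w = set(ev["window_id"]) - wids
            if unknown_w:
                raise ValidationError(f"events reference unknown window(s): {sorted(unknown_w)[:3]}")
            group_of = dict(zip(self.individuals["id"], self.individuals["group"]))
            g1 = ev["g1_id"].map(group_of)
            g2 = ev["g2_id"].map(group_of)
            if (g1 != g2).any():
                bad = ev.loc[(g1 != g2), "event_id"].iloc[0]
                raise ValidationError(f"event {bad!r} pairs individuals from different groups")
        if len(self.individuals):
            info = self.individuals.set_index("id")
            for iid, mid in zip(self.individuals["id"], self.individuals["mother_id"]):
                if mid is not None and mid in info.index:
                    if info.loc[mid, "sex"] != 0:
                        raise ValidationError(f"mother {mid!r} of {iid!r} is not female")
                    if info.loc[mid, "group"] != info.loc[iid, "group"]:
                        raise ValidationError(f"mother {mid!r} of {iid!r} is in a different group")
        unknown_r = set(self.ranks["individual_id"]) - ids if len(self.ranks) else set()
        if unknown_r:
            raise ValidationError(f"rank table references unknown individual(s): {sorted(unknown_r)[:3]}")

    # -- bookkeeping --------------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_style_productions(self) -> int:
        """Two style productions per dyadic event."""
        return 2 * len(self.events)

    def summary(self) -> dict:
        return {
            "n_individuals": len(self.individuals),
            "n_groups": self.n_groups,
            "n_windows": len(self.windows),
            "n_events": self.n_events,
            "n_style_productions": self.n_style_productions,
        }

    # -- covariates ---------------------------------------------------------
    def covariates(self, age_threshold: float = 8.0) -> pd.DataFrame:
        """Derive model covariates per (individual, window) row.

        Columns: individual_id, window_id, group, sex, age_years, age_std,
        age_cat ("young"/"old"), avg_rank, rank_norm.  Rows are the
        (individual, window) pairs present in the rank table; ages come from
        birth years and window years; age is standardized over the pooled rows.
        """
        if not len(self.ranks):
            return pd.DataFrame(
                columns=["individual_id", "window_id", "group", "sex", "age_years",
                         "age_std", "age_cat", "avg_rank", "rank_norm"])
        info = self.individuals.set_index("id")
        year_of = dict(zip(self.windows["window_id"], self.windows["year"]))
        agg = (self.ranks.groupby(["window_id", "individual_id"])["ordinal_rank"]
               .apply(lambda s: aggregate_rank(s.values)).rename("avg_rank").reset_index())
        agg["group"] = agg["individual_id"].map(info["group"])
        agg["sex"] = agg["individual_id"].map(info["sex"])
        agg["age_years"] = [
            year_of[w] - info.loc[i, "birth_year"]
            for w, i in zip(agg["window_id"], agg["individual_id"])
        ]
        if (np.asarray(agg["age_years"]) < 0).any():
            raise ValidationError("negative age implied by birth_year and window year")
        norm = np.empty(len(agg))
        for (_, _), idx in agg.groupby(["group", "window_id"]).groups.items():
            sub = agg.loc[idx]
            nr = normalize_rank(dict(zip(sub["individual_id"], sub["avg_rank"])))
            norm[np.asarray(idx)] = [nr[i] for i in sub["individual_id"]]
        agg["rank_norm"] = norm
        agg["age_std"] = standardize_age(agg["age_years"].values)
        agg["age_cat"] = [assign_age_category(a, age_threshold) for a in agg["age_years"]]
        return agg[["individual_id", "window_id", "group", "sex", "age_years",
                    "age_std", "age_cat", "avg_rank", "rank_norm"]]

    # -- I/O ----------------------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        """Write the four tables as CSV files into a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ind = self.individuals.copy()
        ind["mother_id"] = ind["mother_id"].fillna("")
        ind.to_csv(path / "individuals.csv", index=False)
        self.windows.to_csv(path / "windows.csv", index=False)
        self.ranks.to_csv(path / "ranks.csv", index=False)
        self.events.to_csv(path / "events.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        return cls(
            individuals=read_individuals(path / "individuals.csv"),
            windows=read_windows(path / "windows.csv"),
            ranks=read_ranks(path / "ranks.csv"),
            events=read_events(path / "events.csv"),
        )
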