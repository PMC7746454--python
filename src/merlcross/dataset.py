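"""Data model for 2x2 crossover trials with time-to-event outcomes.

A trial records, for every subject, a sequence label (``AB`` = treatment A
in period 1, ``BA`` = treatment B first), an optional age, and four
positive times: baselines ``b1``, ``b2`` taken before treatment in each
period and post-treatment event times ``y1``, ``y2``.  Post-treatment
times may be right-censored administratively at the follow-up cap ``tau``
(event indicators ``delta1``, ``delta2``); baselines are never censored.

CSV input is wide, one row per subject.  A censored time may be written
either as the token ``>X`` (read as time ``X`` with the event indicator
cleared) or as a plain time together with an explicit ``delta`` column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "CrossoverDataset",
    "ValidationError",
    "load_dataset",
    "treadmill_fixture",
    "column_medians",
]

SEQUENCES = ("AB", "BA")

#: canonical wide-format column order
COLUMNS = ["subject_id", "sequence", "age", "b1", "y1", "delta1", "b2", "y2", "delta2"]


class ValidationError(ValueError):
    """Raised when trial data violate the crossover data model."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject of a 2x2 crossover trial."""

    subject_id: str
    sequence: str
    b1: float
    y1: float
    delta1: bool
    b2: float
    y2: float
    delta2: bool
    age: float | None = None


class CrossoverDataset:
    """Validated container of crossover subjects plus the follow-up cap.

    Parameters
    ----------
    frame : pandas.DataFrame
        Wide table with columns ``subject_id, sequence, [age,] b1, y1,
        delta1, b2, y2, delta2``.
    tau : float, optional
        Follow-up cap per period.  When omitted it is inferred as the
        common value of the censored post-treatment times; a fully
        observed dataset gets ``tau = inf``.
    """

    def __init__(self, frame: pd.DataFrame, tau: float | None = None,
                 validate: bool = True):
        # validate=False is an internal fast path for frames produced by
        # code that already guarantees the invariants (simulator, imputer)
        self._frame = _validate_frame(frame) if validate else frame.reset_index(drop=True)
        self.tau = _resolve_tau(self._frame, tau) if validate else (
            math.inf if tau is None else float(tau))

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[SubjectRecord], tau: float | None = None
    ) -> "CrossoverDataset":
        rows = [
            {
                "subject_id": r.subject_id,
                "sequence": r.sequence,
                "age": np.nan if r.age is None else r.age,
                "b1": r.b1,
                "y1": r.y1,
                "delta1": r.delta1,
                "b2": r.b2,
                "y2": r.y2,
                "delta2": r.delta2,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows), tau=tau)

    # -- views ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying wide table."""
        return self._frame.copy()

    @property
    def subjects(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(
                subject_id=row.subject_id,
                sequence=row.sequence,
                age=None if pd.isna(row.age) else float(row.age),
                b1=float(row.b1),
                y1=float(row.y1),
                delta1=bool(row.delta1),
                b2=float(row.b2),
                y2=float(row.y2),
                delta2=bool(row.delta2),
            )
            for row in self._frame.itertuples(index=False)
        ]

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def n_subjects(self) -> int:
        return len(self._frame)

    @property
    def has_age(self) -> bool:
        return bool(self._frame["age"].notna().all())

    @property
    def n_censored(self) -> int:
        f = self._frame
        return int((~f["delta1"]).sum() + (~f["delta2"]).sum())

    @property
    def is_complete(self) -> bool:
        """True when no post-treatment time is censored."""
        return self.n_censored == 0

    def sequence_counts(self) -> dict[str, int]:
        c = self._frame["sequence"].value_counts()
        return {s: int(c.get(s, 0)) for s in SEQUENCES}

    def __eq__(self, other) -> bool:
        if not isinstance(other, CrossoverDataset):
            return NotImplemented
        if not (self.tau == other.tau or (math.isinf(self.tau) and math.isinf(other.tau))):
            return False
        a, b = self._frame, other._frame
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    def __repr__(self) -> str:
        return (
            f"CrossoverDataset(n={len(self)}, tau={self.tau:g}, "
            f"censored={self.n_censored})"
        )

    # -- IO -------------------------------------------------------------
    def write_csv(self, path) -> None:
        """Write the canonical wide CSV (explicit delta columns)."""
        out = self._frame.copy()
        out["delta1"] = out["delta1"].astype(int)
        out["delta2"] = out["delta2"].astype(int)
        out.to_csv(path, index=False)


def _resolve_tau(frame: pd.DataFrame, tau: float | None) -> float:
    censored = np.concatenate(
        [
            frame.loc[~frame["delta1"], "y1"].to_numpy(float),
            frame.loc[~frame["delta2"], "y2"].to_numpy(float),
        ]
    )
    if tau is None:
        if censored.size == 0:
            return math.inf
        tau = float(censored.max())
    if tau <= 0:
        raise ValidationError("tau must be positive")
    if censored.size and censored.max() > tau + 1e-12:
        raise ValidationError(
            f"censored time {censored.max():g} exceeds follow-up cap tau={tau:g}"
        )
    return float(tau)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    f = frame.copy().reset_index(drop=True)
    if "age" not in f.columns:
        f["age"] = np.nan
    missing = [c for c in COLUMNS if c not in f.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    f = f[COLUMNS]
    f["subject_id"] = f["subject_id"].astype(str)
    f["sequence"] = f["sequence"].astype(str).str.upper()
    bad_seq = ~f["sequence"].isin(SEQUENCES)
    if bad_seq.any():
        raise ValidationError(
            f"unknown sequence label(s) {sorted(f.loc[bad_seq, 'sequence'].unique())}; "
            f"expected one of {SEQUENCES}"
        )
    for col in ("b1", "y1", "b2", "y2", "age"):
        f[col] = pd.to_numeric(f[col], errors="raise")
    for col in ("delta1", "delta2"):
        f[col] = f[col].astype(bool)
    for col in ("b1", "y1", "b2", "y2"):
        nonpos = ~(f[col] > 0)
        if nonpos.any():
            sid = f.loc[nonpos, "subject_id"].iloc[0]
            raise ValidationError(
                f"nonpositive time in column {col!r} for subject {sid!r}; "
                "all times must be strictly positive (log scale)"
            )
    if (f["age"].dropna() < 0).any():
        raise ValidationError("negative age")
    return f


def _parse_time_token(value, subject_id: str, column: str) -> tuple[float, bool]:
    """Parse one time cell: a number, or ``>X`` meaning censored at X."""
    if isinstance(value, str) and value.strip().startswith(">"):
        return float(value.strip()[1:]), False
    return float(value), True


def load_dataset(
    path,
    dialect: Mapping[str, str] | None = None,
    tau: float | None = None,
) -> CrossoverDataset:
    """Read a wide-format crossover CSV.

    ``dialect`` maps canonical column names (``subject_id``, ``sequence``,
    ``age``, ``b1``, ``y1``, ``delta1``, ...) to the headers actually used
    in the file.  ``delta`` columns are optional: without them a time
    written ``>X`` is censored at ``X`` and all other times are events.
    """
    raw = pd.read_csv(path, dtype=str).rename(
        columns={v: k for k, v in (dialect or {}).items()}
    )
    for col in ("subject_id", "sequence", "b1", "y1", "b2", "y2"):
        if col not in raw.columns:
            raise ValidationError(f"missing required column {col!r}")

    rows = []
    for _, r in raw.iterrows():
        sid = str(r["subject_id"])
        rec: dict = {"subject_id": sid, "sequence": r["sequence"]}
        rec["age"] = float(r["age"]) if "age" in raw.columns and pd.notna(r["age"]) else np.nan
        for b in ("b1", "b2"):
            t, observed = _parse_time_token(r[b], sid, b)
            if not observed:
                raise ValidationError(
                    f"censored baseline {b!r} for subject {sid!r}; "
                    "baselines are assumed uncensored"
                )
            rec[b] = t
        for y, d in (("y1", "delta1"), ("y2", "delta2")):
            t, observed = _parse_time_token(r[y], sid, y)
            if d in raw.columns and pd.notna(r[d]):
                flag = str(r[d]).strip().lower() in ("1", "true", "t", "yes")
                observed = observed and flag
            rec[y], rec[d] = t, observed
        rows.append(rec)
    return CrossoverDataset(pd.DataFrame(rows), tau=tau)


def treadmill_fixture() -> CrossoverDataset:
    """The bundled 10-minute treadmill crossover trial (40 subjects).

    A drug vs. placebo 2x2 crossover with a cardiopulmonary event time
    outcome capped at 10 minutes; 20 subjects per sequence, six
    post-treatment times censored at the cap.  Treatment A is the drug,
    so the drug-first subjects carry sequence label ``AB``.
    """
    with resources.as_file(
        resources.files("merlcross.data").joinpath("treadmill.csv")
    ) as p:
        return load_dataset(p)


def column_medians(ds: CrossoverDataset, cap_censored: bool = True) -> pd.DataFrame:
    """Per-sequence medians of b1, y1, b2, y2.

    With ``cap_censored`` (default), censored post-treatment times enter
    as ``tau`` — the convention of summary tables for administratively
    capped trials.  Without it they are dropped.
    """
    if len(ds) == 0:
        raise ValidationError("empty dataset")
    f = ds.to_frame()
    out = {}
    for seq, grp in f.groupby("sequence"):
        med = {}
        for col in ("b1", "y1", "b2", "y2"):
            vals = grp[col].to_numpy(float)
            if col in ("y1", "y2"):
                delta = grp["delta" + col[1]].to_numpy(bool)
                if cap_censored:
                    vals = np.where(delta, vals, ds.tau)
                else:
                    vals = vals[delta]
            med[col] = float(np.median(vals))
        out[seq] = med
    return pd.DataFrame(out).T[["b1", "y1", "b2", "y2"]].rename_axis("sequence")
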