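"""Cohort container and strict CSV I/O.

A cohort is the common currency between the simulator, the classifier and the
evaluator: one row per (subject, time) with a concentration in ng/mL and an
optional phenotype label (``NA`` for blinded data).

CSV schema (header mandatory, UTF-8)::

    subject_id,phenotype,time_h,conc_ng_ml

``phenotype`` is one of ``EM``, ``IM``, ``PM`` or ``NA``.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .phenotype import Phenotype, coerce_phenotype

CSV_COLUMNS = ("subject_id", "phenotype", "time_h", "conc_ng_ml")

_TRIAL_RE = re.compile(r"t(\d+)s\d+$")


class CohortValidationError(ValueError):
    """Raised when a cohort file or frame violates the schema."""


@dataclass
class CohortDataset:
    """Collection of concentration records sharing one dose.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``subject_id`` (str), ``phenotype`` (str or NA), ``time_h``
        (float), ``conc_ng_ml`` (float) and ``trial`` (int; in-memory only,
        reconstructed from subject ids on read).
    dose : float
        Oral dose in mg, common to all records.
    design : tuple[int, int]
        (number of trials, subjects per trial).
    seed : int | None
        Master seed the cohort was simulated with, if any.
    """

    df: pd.DataFrame
    dose: float
    design: tuple[int, int] = (1, 0)
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortValidationError(f"cohort frame missing columns {missing}")
        if "trial" not in self.df.columns:
            self.df = self.df.assign(trial=_infer_trials(self.df["subject_id"]))
        dup = self.df.duplicated(subset=["subject_id", "time_h"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["subject_id", "time_h"]].tolist()
            raise CohortValidationError(f"duplicate (subject, time) pair {tuple(pair)}")

    # ------------------------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return np.sort(self.df["time_h"].unique())

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    def at_time(self, time_h: float, atol: float = 1e-9) -> pd.DataFrame:
        """Records at one sampling time (exact within ``atol``)."""
        sel = np.isclose(self.df["time_h"].to_numpy(float), time_h, atol=atol)
        out = self.df.loc[sel]
        if out.empty:
            raise KeyError(f"no records at time {time_h} h")
        return out

    def subject_phenotypes(self) -> pd.Series:
        """Phenotype per subject (first record wins; consistent by invariant)."""
        return self.df.groupby("subject_id", sort=True)["phenotype"].first()

    def blinded(self) -> "CohortDataset":
        """Copy with phenotype labels removed (set to NA)."""
        df = self.df.copy()
        df["phenotype"] = pd.NA
        return CohortDataset(df=df, dose=self.dose, design=self.design, seed=self.seed)

    def wide(self) -> pd.DataFrame:
        """Subjects x times concentration matrix (for NCA summaries)."""
        return self.df.pivot(index="subject_id", columns="time_h", values="conc_ng_ml")


def _infer_trials(subject_ids: Iterable[str]) -> list[int]:
    out = []
    for sid in subject_ids:
        m = _TRIAL_RE.search(str(sid))
        out.append(int(m.group(1)) if m else 0)
    return out


# ----------------------------------------------------------------------
# CSV I/O


def write_cohort_csv(dataset: CohortDataset, path: str | Path) -> None:
    """Write the four schema columns; concentrations are kept full precision
    so a write/read round trip is the identity."""
    out = dataset.df.loc[:, list(CSV_COLUMNS)].copy()
    out["phenotype"] = out["phenotype"].fillna("NA")
    out.to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path | io.TextIOBase, dose: float = 600.0
) -> CohortDataset:
    """Read and validate a cohort CSV.

    Raises :class:`CohortValidationError` with the offending row number
    (1-based, counting the header as row 1) on any schema violation.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CohortValidationError("empty file: header row is mandatory") from None
    if list(raw.columns) != list(CSV_COLUMNS):
        raise CohortValidationError(
            f"bad or missing header: expected {','.join(CSV_COLUMNS)}, "
            f"got {','.join(map(str, raw.columns))}"
        )
    phenotypes: list[object] = []
    times: list[float] = []
    concs: list[float] = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):
        tok = row.phenotype.strip()
        if tok in ("NA", ""):
            phenotypes.append(pd.NA)
        else:
            try:
                phenotypes.append(coerce_phenotype(tok).value)
            except ValueError as exc:
                raise CohortValidationError(f"row {i}: {exc}") from None
        try:
            t = float(row.time_h)
        except ValueError:
            raise CohortValidationError(
                f"row {i}: non-numeric time {row.time_h!r}"
            ) from None
        if t < 0:
            raise CohortValidationError(f"row {i}: negative time {t}")
        if row.conc_ng_ml.strip() == "":
            raise CohortValidationError(f"row {i}: missing concentration")
        try:
            c = float(row.conc_ng_ml)
        except ValueError:
            raise CohortValidationError(
                f"row {i}: non-numeric concentration {row.conc_ng_ml!r}"
            ) from None
        if c < 0:
            raise CohortValidationError(f"row {i}: negative concentration {c}")
        times.append(t)
        concs.append(c)
    df = pd.DataFrame(
        {
            "subject_id": raw["subject_id"].astype(str),
            "phenotype": pd.array(phenotypes, dtype="string"),
            "time_h": times,
            "conc_ng_ml": concs,
        }
    )
    return CohortDataset(df=df, dose=dose)
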