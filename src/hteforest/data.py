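"""Cohort data model: variable dictionary, per-participant tables, CSV I/O,
pooling of the two trials, and the stratified half-sampling used by honest
fitting.

A :class:`CohortTable` wraps a pandas DataFrame together with a
:class:`VariableDictionary` describing the role and type of every column.
Missing covariate values are kept as NaN (no silent imputation); treatment
arm and study label must parse cleanly for every row.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import (
    HarmonizationError,
    RowParseError,
    SchemaError,
    StratificationError,
)

log = logging.getLogger(__name__)

KINDS = ("continuous", "binary", "categorical")
ROLES = ("covariate", "treatment", "outcome", "time", "identifier", "study")

#: strings treated as missing when parsing CSV cells
MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "null", "NULL", "."}


@dataclass(frozen=True)
class Variable:
    """One entry of the variable dictionary."""

    name: str
    kind: str
    units: str = ""
    role: str = "covariate"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown variable role {self.role!r} for {self.name!r}")


class VariableDictionary:
    """Schema of a cohort table.

    Invariants: names unique; exactly one treatment, one study and one time
    variable; at least one outcome.
    """

    def __init__(self, entries):
        entries = tuple(entries)
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names: {dupes}")

        def _role(role):
            return [e for e in entries if e.role == role]

        for role in ("treatment", "study", "time"):
            if len(_role(role)) != 1:
                raise SchemaError(f"dictionary must contain exactly one {role} variable")
        if not _role("outcome"):
            raise SchemaError("dictionary must contain at least one outcome variable")
        if len(_role("identifier")) > 1:
            raise SchemaError("at most one identifier variable allowed")
        self.entries = entries

    # -- accessors -------------------------------------------------------
    @property
    def names(self):
        return [e.name for e in self.entries]

    def _one(self, role):
        return next(e.name for e in self.entries if e.role == role)

    @property
    def treatment(self):
        return self._one("treatment")

    @property
    def study(self):
        return self._one("study")

    @property
    def time(self):
        return self._one("time")

    @property
    def outcomes(self):
        return [e.name for e in self.entries if e.role == "outcome"]

    @property
    def covariates(self):
        return [e.name for e in self.entries if e.role == "covariate"]

    def __getitem__(self, name):
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name):
        return any(e.name == name for e in self.entries)

    def __eq__(self, other):
        return isinstance(other, VariableDictionary) and self.entries == other.entries

    def __hash__(self):
        return hash(self.entries)

    def with_entries(self, *variables):
        """Return a new dictionary with extra entries appended."""
        return VariableDictionary(self.entries + tuple(variables))

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path):
        payload = [
            {"name": e.name, "kind": e.kind, "units": e.units, "role": e.role}
            for e in self.entries
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(Variable(**row) for row in payload)


class CohortTable:
    """A harmonized per-participant trial table.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per participant. Must contain every dictionary column.
    dictionary : VariableDictionary
        Schema. Continuous columns are coerced to float, binary columns to
        {0, 1, NaN}; the treatment arm must be 0/1 and non-missing.
    """

    def __init__(self, df, dictionary, validate=True):
        if validate:
            missing = [n for n in dictionary.names if n not in df.columns]
            if missing:
                raise SchemaError(f"missing mandatory column(s): {missing}")
            df = df.copy()
            for e in dictionary.entries:
                if e.role in ("study", "identifier") or e.kind == "categorical":
                    continue
                col = pd.to_numeric(df[e.name], errors="coerce")
                if e.role == "treatment":
                    bad = ~col.isin([0, 1])
                    if bad.any():
                        idx = int(np.flatnonzero(bad.to_numpy())[0])
                        raise RowParseError(
                            f"unparseable treatment value at row {idx}",
                            row=idx, column=e.name,
                        )
                if e.kind == "binary":
                    bad = col.notna() & ~col.isin([0, 1])
                    if bad.any():
                        idx = int(np.flatnonzero(bad.to_numpy())[0])
                        raise RowParseError(
                            f"non-binary value in {e.name!r} at row {idx}",
                            row=idx, column=e.name,
                        )
                df[e.name] = col.astype(float)
        self.df = df.reset_index(drop=True)
        self.dictionary = dictionary

    @property
    def n(self):
        return len(self.df)

    def __len__(self):
        return len(self.df)

    @property
    def arm(self):
        return self.df[self.dictionary.treatment].to_numpy()

    @property
    def study_labels(self):
        return self.df[self.dictionary.study].astype(str).to_numpy()

    def strata(self):
        """study x arm labels, one per row (used for stratified sampling)."""
        return np.char.add(
            self.study_labels.astype(str),
            np.char.mod(":%d", self.arm.astype(int)),
        )

    def n_missing(self, name):
        return int(self.df[name].isna().sum())

    def complete_rows(self, columns):
        """Positional indices of rows with no missing value among ``columns``."""
        mask = ~self.df[list(columns)].isna().any(axis=1)
        return np.flatnonzero(mask.to_numpy())

    def subset(self, rows):
        """Row-subset view (new CohortTable, positions reset)."""
        return CohortTable(self.df.iloc[rows], self.dictionary, validate=False)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_cohort_csv(path, dictionary):
    """Read a cohort CSV against a dictionary.

    Rows with unparseable treatment values are rejected (RowParseError);
    missing covariate values ("" or NA tokens) are preserved as NaN.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [n for n in dictionary.names if n not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    df = {}
    for e in dictionary.entries:
        col = raw[e.name]
        if e.role in ("study", "identifier") or e.kind == "categorical":
            df[e.name] = col
            continue
        cleaned = col.where(~col.isin(MISSING_TOKENS), other=np.nan)
        numeric = pd.to_numeric(cleaned, errors="coerce")
        bad = cleaned.notna() & numeric.isna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowParseError(
                f"non-numeric value {col.iloc[idx]!r} in column {e.name!r} at row {idx}",
                row=idx, column=e.name,
            )
        df[e.name] = numeric
    return CohortTable(pd.DataFrame(df), dictionary)


def write_cohort_csv(cohort, path):
    """Write a cohort to RFC-4180 CSV (UTF-8, header row)."""
    cohort.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pooling and stratified half-sampling
# ---------------------------------------------------------------------------

def pool_studies(a, b):
    """Concatenate two cohorts sharing a dictionary into one analysis table.

    The study column keeps its per-trial labels, so the indicator remains an
    eligible splitting covariate downstream.
    """
    if a.dictionary != b.dictionary:
        da, db = set(a.dictionary.names), set(b.dictionary.names)
        discordant = sorted(da.symmetric_difference(db))
        if not discordant:  # same names, different kinds/roles
            discordant = sorted(
                e.name for e in a.dictionary.entries if e not in b.dictionary.entries
            )
        raise HarmonizationError(
            f"dictionaries disagree on variables: {discordant}", discordant
        )
    df = pd.concat([a.df, b.df], ignore_index=True)
    return CohortTable(df, a.dictionary, validate=False)


def _stratified_half_indices(labels, rows, rng):
    """Split ``rows`` into two disjoint halves balanced within each label."""
    rows = np.asarray(rows)
    first, second = [], []
    for lab in np.unique(labels):
        stratum = rows[labels == lab]
        perm = rng.permutation(stratum)
        k = (len(stratum) + 1) // 2
        first.append(perm[:k])
        second.append(perm[k:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


def stratified_half_sample(cohort, seed):
    """Two disjoint index sets, each holding half (+-1) of every study x arm
    stratum. Deterministic given ``seed``."""
    labels = cohort.strata()
    studies = np.unique(cohort.study_labels)
    for s in studies:
        for arm in (0, 1):
            size = int(np.sum(labels == f"{s}:{arm}"))
            if size == 0:
                raise StratificationError(f"empty stratum {s}:{arm}")
            if size < 4:
                raise StratificationError(
                    f"stratum {s}:{arm} has {size} rows; need at least 4"
                )
    rng = np.random.default_rng(seed)
    rows = np.arange(cohort.n)
    return _stratified_half_indices(labels, rows, rng)
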