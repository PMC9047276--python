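"""Derived baseline covariates: MDRD eGFR and the hemoglobin glycation index.

The hemoglobin glycation index (HGI) is the residual of measured HbA1c from
the HbA1c predicted by an ordinary least squares regression of HbA1c on
fasting glucose fitted in a reference population (here: all ACCORD rows at
baseline). A positive HGI means the participant's HbA1c is higher than their
fasting glucose would predict.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .data import CohortTable, Variable
from .errors import DomainError, SingularFitError

log = logging.getLogger(__name__)

#: IDMS-traceable 4-variable MDRD constant; the older calibration used 186.
MDRD_CONSTANT = 175.0


def egfr_mdrd(creatinine, age, female, black, constant=MDRD_CONSTANT):
    """Estimated GFR (mL/min/1.73 m^2) from the 4-variable MDRD equation.

    constant * creatinine^-1.154 * age^-0.203 * 0.742^female * 1.212^black

    Parameters are scalars or arrays; creatinine in mg/dL, age in years,
    female/black as 0/1 indicators. Missing inputs yield NaN; non-positive
    creatinine or age raise :class:`DomainError`.
    """
    creatinine = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=float)
    black = np.asarray(black, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(creatinine <= 0) or np.any(age <= 0):
            raise DomainError("creatinine and age must be strictly positive")
    out = (
        constant
        * creatinine ** -1.154
        * age ** -0.203
        * np.where(female == 1, 0.742, 1.0)
        * np.where(black == 1, 1.212, 1.0)
    )
    # missing sex/race indicators propagate as NaN
    out = np.where(np.isnan(female) | np.isnan(black), np.nan, out)
    return out if out.shape else float(out)


def add_egfr(cohort, creatinine="creatinine", age="age", female="female",
             black="black", constant=MDRD_CONSTANT, name="egfr"):
    """Return a new cohort with an eGFR column derived via MDRD."""
    df = cohort.df.copy()
    df[name] = egfr_mdrd(
        df[creatinine].to_numpy(), df[age].to_numpy(),
        df[female].to_numpy(), df[black].to_numpy(), constant=constant,
    )
    dictionary = cohort.dictionary
    if name not in dictionary:
        dictionary = dictionary.with_entries(
            Variable(name, "continuous", "mL/min/1.73m2", "covariate")
        )
    return CohortTable(df, dictionary, validate=False)


@dataclass(frozen=True)
class HgiModel:
    """Reference regression HbA1c ~ fasting glucose.

    beta0 in % HbA1c; beta1 in % HbA1c per mg/dL glucose; n_fit is the
    number of complete reference rows used.
    """

    beta0: float
    beta1: float
    n_fit: int

    def predict(self, glucose):
        return self.beta0 + self.beta1 * np.asarray(glucose, dtype=float)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"beta0": float(self.beta0), "beta1": float(self.beta1),
                 "n_fit": int(self.n_fit)}, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(float(d["beta0"]), float(d["beta1"]), int(d["n_fit"]))


def fit_hgi_reference(cohort, reference_study="ACCORD", hba1c="hba1c",
                      glucose="glucose"):
    """OLS of HbA1c on fasting glucose over the reference-study rows.

    Residuals over the fitting rows average exactly zero (normal equations).
    Raises :class:`SingularFitError` if the reference glucose is constant and
    :class:`DomainError` with fewer than 3 complete reference rows.
    """
    mask = (cohort.study_labels == reference_study)
    sub = cohort.df.loc[mask, [hba1c, glucose]].dropna()
    if len(sub) < 3:
        raise DomainError(
            f"need at least 3 complete {reference_study} rows to fit HGI; "
            f"got {len(sub)}"
        )
    g = sub[glucose].to_numpy()
    h = sub[hba1c].to_numpy()
    if np.ptp(g) == 0:
        raise SingularFitError("reference fasting glucose is constant")
    res = sm.OLS(h, sm.add_constant(g)).fit()
    return HgiModel(float(res.params[0]), float(res.params[1]), int(len(sub)))


def apply_hgi(model, cohort, hba1c="hba1c", glucose="glucose", name="hgi"):
    """Add hgi = HbA1c - (beta0 + beta1 * glucose) to every row.

    Rows missing either input get a missing HGI (flagged, not imputed).
    """
    df = cohort.df.copy()
    h = df[hba1c].to_numpy(dtype=float)
    g = df[glucose].to_numpy(dtype=float)
    df[name] = h - model.predict(g)
    n_miss = int(np.isnan(df[name].to_numpy()).sum())
    if n_miss:
        log.info("apply_hgi: %d rows missing HbA1c or glucose -> hgi NaN", n_miss)
    dictionary = cohort.dictionary
    if name not in dictionary:
        dictionary = dictionary.with_entries(
            Variable(name, "continuous", "unitless", "covariate")
        )
    return CohortTable(df, dictionary, validate=False)


def derive_covariates(cohort, reference_study="ACCORD", constant=MDRD_CONSTANT):
    """Convenience: add eGFR (MDRD) and HGI (reference fit + application).

    Returns ``(cohort_with_derived, hgi_model)``.
    """
    cohort = add_egfr(cohort, constant=constant)
    model = fit_hgi_reference(cohort, reference_study=reference_study)
    return apply_hgi(model, cohort), model
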