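"""Residual age-at-onset phenotyping.

Huntington disease age at motor onset falls steeply with inherited CAG
length; association analysis therefore uses the *residual* onset — observed
minus the onset expected from CAG under a phenotype model — as a
quantitative trait in natural-scale years.  A positive residual means later
onset than expected for that CAG length.

The expectation model is pluggable.  The default is a log-linear model,
ln(onset) = a + b*CAG, with coefficients fit to a synthetic reference
cohort shipped with the package (the study's own model coefficients come
from prior work and are not restated here).  A shifted-exponential form,
onset = c + exp(a - b*CAG), is also available.

Cohort-level helpers compute residuals, recompute them under corrected
(true) CAG lengths for carriers of non-canonical repeat structures, apply
the 40-55 CAG analysis window, and build the 30%/30% late/early
dichotomous phenotype.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .repeat_model import StructureClass

__all__ = [
    "OnsetModel",
    "Subject",
    "default_model",
    "expected_onset",
    "residual_onset",
    "recompute_with_true_cag",
    "add_residuals",
    "filter_cohort",
    "dichotomize",
    "model_from_yaml",
    "model_to_yaml",
]

#: Cohort table column layout.
COHORT_COLUMNS = ["id", "sex", "onset_years", "est_cag", "true_cag", "cls"]


@dataclass(frozen=True)
class OnsetModel:
    """CAG -> expected age-at-onset model.

    form 'log_linear': onset = exp(a + b*CAG), coef = (a, b), b < 0.
    form 'shifted_exponential': onset = c + exp(a - b*CAG), coef = (a, b, c), b > 0.
    Expected onset must be positive and strictly decreasing over
    ``cag_range`` (checked at construction on the integer grid).
    """

    form: str
    coef: tuple[float, ...]
    cag_range: tuple[int, int] = (36, 60)

    def __post_init__(self) -> None:
        lo, hi = self.cag_range
        values = [self._evaluate(c) for c in range(lo, hi + 1)]
        if any(v <= 0 for v in values):
            raise ValueError("expected onset must be positive over the valid range")
        if any(b >= a for a, b in zip(values, values[1:])):
            raise ValueError("expected onset must be strictly decreasing in CAG")

    def _evaluate(self, cag: float) -> float:
        if self.form == "log_linear":
            a, b = self.coef
            return math.exp(a + b * cag)
        if self.form == "shifted_exponential":
            a, b, c = self.coef
            return c + math.exp(a - b * cag)
        raise ValueError(f"unknown onset model form {self.form!r}")

    def expected(self, cag: float) -> float:
        lo, hi = self.cag_range
        if not (lo <= cag <= hi):
            raise ValueError(f"CAG {cag} outside model range {self.cag_range}")
        return self._evaluate(cag)


@dataclass(frozen=True)
class Subject:
    """One HD subject; residuals are derived fields."""

    id: str
    sex: str
    onset_years: float
    est_cag: int
    true_cag: Optional[int] = None
    cls: Optional[StructureClass] = None
    residual: Optional[float] = None
    residual_est: Optional[float] = None

    def __post_init__(self) -> None:
        if self.onset_years <= 0:
            raise ValueError("onset must be positive")


@functools.lru_cache(maxsize=1)
def default_model() -> OnsetModel:
    """Log-linear model fit to the packaged synthetic reference cohort."""
    with resources.files("httrepeat.data").joinpath(
        "synthetic_reference_cohort.tsv"
    ).open() as fh:
        ref = pd.read_csv(fh, sep="\t")
    x = ref["cag"].to_numpy(dtype=float)
    y = np.log(ref["onset_years"].to_numpy(dtype=float))
    b, a = np.polyfit(x, y, 1)
    return OnsetModel("log_linear", (float(a), float(b)))


def expected_onset(cag: float, model: OnsetModel) -> float:
    """Expected age at motor onset (years) for a CAG length."""
    return model.expected(cag)


def residual_onset(observed: float, expected: float) -> float:
    """Observed minus expected onset, in years (positive = later onset)."""
    return observed - expected


def recompute_with_true_cag(subject: Subject, model: OnsetModel) -> Subject:
    """Recompute the residual from the true (sequence-confirmed) CAG length.

    The estimated-CAG residual is retained in ``residual_est`` for
    comparison.  Subjects without a true CAG are returned unchanged.
    Idempotent.
    """
    base_est = (
        subject.residual_est
        if subject.residual_est is not None
        else residual_onset(subject.onset_years, model.expected(subject.est_cag))
    )
    if subject.true_cag is None:
        return replace(subject, residual=base_est, residual_est=base_est)
    r = residual_onset(subject.onset_years, model.expected(subject.true_cag))
    return replace(subject, residual=r, residual_est=base_est)


def add_residuals(
    cohort: pd.DataFrame, model: OnsetModel, use_true: bool = False
) -> pd.DataFrame:
    """Attach a ``residual`` column to a cohort table.

    With ``use_true=True`` the residual uses ``true_cag`` where available
    (falling back to ``est_cag``); the estimated-CAG residual is kept as
    ``residual_est``.
    """
    out = cohort.copy()
    est = out["est_cag"].to_numpy(dtype=float)
    exp_est = np.array([model.expected(c) for c in est])
    out["residual_est"] = out["onset_years"].to_numpy(dtype=float) - exp_est
    if use_true:
        cag = np.where(
            out["true_cag"].notna(), out["true_cag"].to_numpy(dtype=float), est
        )
        exp = np.array([model.expected(c) for c in cag])
        out["residual"] = out["onset_years"].to_numpy(dtype=float) - exp
    else:
        out["residual"] = out["residual_est"]
    return out


def filter_cohort(
    cohort: pd.DataFrame, lo: int = 40, hi: int = 55
) -> pd.DataFrame:
    """Restrict to subjects carrying ``lo``-``hi`` CAG repeats (inclusive),
    using the true CAG where available, else the estimated one."""
    cag = np.where(
        cohort["true_cag"].notna(),
        cohort["true_cag"].to_numpy(dtype=float),
        cohort["est_cag"].to_numpy(dtype=float),
    )
    return cohort[(cag >= lo) & (cag <= hi)]


def dichotomize(
    cohort: pd.DataFrame, fraction: float = 0.30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a residual-phenotyped cohort into late/early extreme groups.

    Each group holds floor(fraction*n) subjects; groups are disjoint and
    order-consistent (every late residual >= every middle residual, and
    symmetrically for early).  Boundary ties are broken by subject id.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    if "residual" not in cohort.columns:
        raise ValueError("cohort must carry a 'residual' column")
    n = len(cohort)
    k = int(fraction * n)
    ranked = cohort.sort_values(["residual", "id"], ascending=[False, True])
    late = ranked.iloc[:k]
    early = ranked.iloc[n - k:]
    return late, early


def model_from_yaml(path) -> OnsetModel:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return OnsetModel(
        form=cfg["form"],
        coef=tuple(float(c) for c in cfg["coef"]),
        cag_range=tuple(cfg.get("cag_range", (36, 60))),
    )


def model_to_yaml(model: OnsetModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "form": model.form,
                "coef": list(model.coef),
                "cag_range": list(model.cag_range),
            },
            fh,
        )
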