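"""Desk-scale modifier statistics.

Three pieces:

* A Hardy-Weinberg enrichment test for a selected subgroup: expected
  genotype counts are computed from an externally fixed minor allele
  frequency (the full-cohort MAF), and the chi-square statistic
  sum((O-E)^2/E) is referred to a chi-square distribution with 2 degrees of
  freedom (the MAF is external, so no parameter is estimated from the
  subgroup).

* Marginal and conditional association of SNP dosage with the residual
  age-at-onset phenotype by fixed-effect least squares, with optional
  covariates; conditional analysis adds the dosages of conditioning SNPs
  as covariates to test independence of signals at a locus.

* A declarative rule engine that classifies SNPs into modifier-haplotype
  tags (5AM1-3 at MSH3/DHFR, 15AM1-4 at FAN1, 19AM1-3 at LIG1) from their
  marginal/conditional p-values, allele frequency and direction of effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats as sps

from .trace_expansion import rank_top_quartile

__all__ = [
    "GenotypeCounts",
    "SnpStats",
    "TagRule",
    "Condition",
    "AssocResult",
    "HweResult",
    "hwe_expected_counts",
    "hwe_chisq",
    "marginal_association",
    "conditional_association",
    "classify_tag_snps",
    "top_quartile_hwe_report",
    "BUILTIN_TAG_RULES",
    "rules_from_yaml",
    "rules_to_yaml",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts (major hom, het, minor hom)."""

    major_hom: int
    het: int
    minor_hom: int

    def __post_init__(self) -> None:
        if min(self.major_hom, self.het, self.minor_hom) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.major_hom + self.het + self.minor_hom

    def as_array(self) -> np.ndarray:
        return np.array([self.major_hom, self.het, self.minor_hom], dtype=float)


@dataclass(frozen=True)
class HweResult:
    statistic: float
    df: int
    p: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]

    @property
    def expected_display(self) -> tuple[int, int, int]:
        """Expected counts rounded to integers for display."""
        return tuple(int(round(e)) for e in self.expected)


def hwe_expected_counts(n: int, maf: float) -> np.ndarray:
    """Hardy-Weinberg expected genotype counts from an external MAF.

    Returns (n(1-q)^2, 2nq(1-q), nq^2) with q = maf, as real values.
    """
    if not (0 < maf < 1):
        raise ValueError("maf must be in (0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    q = maf
    return np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q ** 2])


def hwe_chisq(observed: GenotypeCounts, expected: Sequence[float]) -> HweResult:
    """Chi-square deviation of observed genotype counts from HWE expectation.

    statistic = sum((O-E)^2/E) over the three genotype classes; the p-value
    is the upper tail of chi-square with 2 degrees of freedom (the expected
    counts derive from an externally fixed MAF).
    """
    exp = np.asarray(expected, dtype=float)
    if exp.shape != (3,):
        raise ValueError("expected must have three classes")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    obs = observed.as_array()
    stat = float(np.sum((obs - exp) ** 2 / exp))
    p = float(sps.chi2.sf(stat, df=2))
    return HweResult(
        statistic=stat,
        df=2,
        p=p,
        observed=(observed.major_hom, observed.het, observed.minor_hom),
        expected=tuple(exp),
    )


@dataclass(frozen=True)
class AssocResult:
    beta: float      # years per minor allele
    se: float
    p: float
    n: int


def _design(
    dosage: np.ndarray, covariates: Optional[np.ndarray]
) -> np.ndarray:
    cols = [dosage.reshape(-1, 1)]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(covariates)
        if cov.shape[0] != dosage.shape[0]:
            cov = cov.T
        cols.append(cov)
    X = np.column_stack(cols)
    return sm.add_constant(X, has_constant="add")


def marginal_association(
    dosage: Sequence[float],
    phenotype: Sequence[float],
    covariates: Optional[np.ndarray] = None,
) -> AssocResult:
    """Least-squares regression of the residual-onset phenotype on minor
    allele count, with optional covariates; two-sided p for the dosage term."""
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if d.std() == 0:
        raise ValueError("dosage has zero variance")
    X = _design(d, covariates)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few observations for the design")
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n=len(y),
    )


def conditional_association(
    dosage: Sequence[float],
    phenotype: Sequence[float],
    covariates: Optional[np.ndarray] = None,
    conditioning: Optional[np.ndarray] = None,
) -> AssocResult:
    """Association of the test SNP with the dosages of conditioning SNPs
    added as covariates.  Empty conditioning reduces to the marginal test."""
    if conditioning is None or np.asarray(conditioning).size == 0:
        return marginal_association(dosage, phenotype, covariates)
    d = np.asarray(dosage, dtype=float)
    cond = np.atleast_2d(np.asarray(conditioning, dtype=float))
    if cond.shape[0] != d.shape[0]:
        cond = cond.T
    full = np.column_stack([d.reshape(-1, 1), cond])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            "test dosage is collinear with the conditioning dosages; "
            "the conditional effect is not identifiable"
        )
    cov = cond if covariates is None else np.column_stack(
        [np.atleast_2d(covariates).reshape(len(d), -1), cond]
    )
    return marginal_association(d, phenotype, cov)


# --------------------------------------------------------------------------
# Tag-SNP rule engine


@dataclass(frozen=True)
class Condition:
    """A threshold on the p-value conditioned on one SNP ('lt' or 'gt', strict)."""

    snp: str
    comparator: str
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in ("lt", "gt"):
            raise ValueError("comparator must be 'lt' or 'gt'")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")

    def matches(self, p: float) -> bool:
        return p < self.threshold if self.comparator == "lt" else p > self.threshold


@dataclass(frozen=True)
class SnpStats:
    """Per-SNP association summary used by the rule engine."""

    snp: str
    maf: float
    effect: float                      # years per minor allele
    direction: str                     # 'hastening' or 'delaying'
    p_marginal: float
    p_conditional: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError("MAF must be in (0, 0.5]")
        if self.direction not in ("hastening", "delaying"):
            raise ValueError("direction must be 'hastening' or 'delaying'")


@dataclass(frozen=True)
class TagRule:
    """Declarative modifier-haplotype tagging rule.

    All thresholds are strict inequalities; MAF bounds, when given, are
    strict as well.  ``direction`` of None matches either direction.
    """

    label: str
    direction: Optional[str]
    p_marginal: Condition              # Condition.snp ignored for the marginal term
    conditions: tuple[Condition, ...] = ()
    maf_min: Optional[float] = None
    maf_max: Optional[float] = None

    def matches(self, s: SnpStats) -> Optional[bool]:
        """True/False, or None when a referenced conditional p is missing."""
        if self.direction is not None and s.direction != self.direction:
            return False
        if self.maf_min is not None and not (s.maf > self.maf_min):
            return False
        if self.maf_max is not None and not (s.maf < self.maf_max):
            return False
        if not self.p_marginal.matches(s.p_marginal):
            return False
        for cond in self.conditions:
            if cond.snp not in s.p_conditional:
                return None
            if not cond.matches(s.p_conditional[cond.snp]):
                return False
        return True


def _lt(th: float, snp: str = "") -> Condition:
    return Condition(snp, "lt", th)


def _gt(th: float, snp: str = "") -> Condition:
    return Condition(snp, "gt", th)


#: Shipped rule sets, in declared evaluation order.
BUILTIN_TAG_RULES: tuple[TagRule, ...] = (
    # MSH3/DHFR locus, chromosome 5
    TagRule("5AM1", "hastening", _lt(1e-5),
            (Condition("rs701383", "gt", 1e-5),)),
    TagRule("5AM2", "delaying", _lt(1e-3),
            (Condition("rs701383", "lt", 1e-3),), maf_max=0.05),
    TagRule("5AM3", "delaying", _lt(1e-3),
            (Condition("rs701383", "gt", 1e-3),), maf_min=0.20, maf_max=0.35),
    # FAN1 locus, chromosome 15
    TagRule("15AM1", "hastening", _lt(5e-8),
            (Condition("rs150393409", "gt", 5e-8),
             Condition("rs35811129", "lt", 5e-8)), maf_max=0.05),
    TagRule("15AM2", "delaying", _lt(5e-8),
            (Condition("rs150393409", "lt", 5e-8),
             Condition("rs35811129", "gt", 5e-8)), maf_min=0.20),
    TagRule("15AM3", "hastening", _lt(1e-5),
            (Condition("rs150393409", "lt", 1e-5),
             Condition("rs35811129", "lt", 1e-5)), maf_max=0.03),
    TagRule("15AM4", None, _lt(1e-5),
            (Condition("rs150393409", "lt", 5e-8),), maf_min=0.30),
    # LIG1 locus, chromosome 19
    TagRule("19AM1", "delaying", _lt(1e-4),
            (Condition("rs274883", "gt", 1e-2),)),
    TagRule("19AM2", "hastening", _lt(1e-5),
            (Condition("rs3730945", "gt", 1e-5),), maf_min=0.30),
    TagRule("19AM3", "delaying", _lt(1e-2),
            (Condition("rs145821638", "gt", 1e-2),), maf_max=0.02),
)


def classify_tag_snps(
    snp_stats: Iterable[SnpStats],
    rules: Sequence[TagRule] = BUILTIN_TAG_RULES,
) -> dict[str, Optional[str]]:
    """First-matching-rule label per SNP (None when no rule matches).

    A rule referencing a conditional p-value the SNP does not carry is
    inapplicable to that SNP: it is skipped with a warning and evaluation
    continues with the remaining rules.
    """
    labels: dict[str, Optional[str]] = {}
    for s in snp_stats:
        label: Optional[str] = None
        for rule in rules:
            m = rule.matches(s)
            if m is None:
                warnings.warn(
                    f"SNP {s.snp}: missing conditional p-value required by "
                    f"rule {rule.label}; rule skipped for this SNP"
                )
                continue
            if m:
                label = rule.label
                break
        labels[s.snp] = label
    return labels


def rules_from_yaml(path) -> tuple[TagRule, ...]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for r in raw:
        rules.append(
            TagRule(
                label=r["label"],
                direction=r.get("direction"),
                p_marginal=Condition("", r["p_marginal"]["comparator"],
                                     float(r["p_marginal"]["threshold"])),
                conditions=tuple(
                    Condition(c["snp"], c["comparator"], float(c["threshold"]))
                    for c in r.get("conditions", ())
                ),
                maf_min=r.get("maf_min"),
                maf_max=r.get("maf_max"),
            )
        )
    return tuple(rules)


def rules_to_yaml(rules: Sequence[TagRule], path) -> None:
    raw = []
    for r in rules:
        raw.append(
            {
                "label": r.label,
                "direction": r.direction,
                "p_marginal": {
                    "comparator": r.p_marginal.comparator,
                    "threshold": r.p_marginal.threshold,
                },
                "conditions": [
                    {"snp": c.snp, "comparator": c.comparator, "threshold": c.threshold}
                    for c in r.conditions
                ],
                "maf_min": r.maf_min,
                "maf_max": r.maf_max,
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# --------------------------------------------------------------------------
# Composite: HWE enrichment in the top somatic-expansion quartile


def top_quartile_hwe_report(
    scores: pd.DataFrame,
    genotypes: pd.Series,
    cohort_maf: Optional[float] = None,
    stratify_by_cag: bool = False,
) -> HweResult:
    """HWE enrichment test of a SNP in the top somatic-expansion quartile.

    ``scores`` is the per-sample output of
    :func:`httrepeat.trace_expansion.score_samples`; ``genotypes`` maps
    sample id to minor allele count (0/1/2).  The expected counts use the
    MAF of the whole scored cohort unless ``cohort_maf`` is given.

    With ``stratify_by_cag`` the top quartile is taken within each main-CAG
    length and pooled; the default ranks the whole cohort at once.
    """
    scores = scores[scores["sample"].isin(genotypes.index)]
    if stratify_by_cag:
        tops = [
            rank_top_quartile(g)
            for _, g in scores.groupby("main_cag")
            if len(g) >= 4
        ]
        top = pd.Index(np.concatenate([t.to_numpy() for t in tops]))
    else:
        top = rank_top_quartile(scores)
    g_all = genotypes.loc[scores["sample"]]
    if cohort_maf is None:
        cohort_maf = float(g_all.sum()) / (2 * len(g_all))
    g_top = genotypes.loc[top]
    observed = GenotypeCounts(
        int((g_top == 0).sum()), int((g_top == 1).sum()), int((g_top == 2).sum())
    )
    expected = hwe_expected_counts(observed.n, cohort_maf)
    return hwe_chisq(observed, expected)
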