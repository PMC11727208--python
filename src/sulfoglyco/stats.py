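"""Glycan-class summarization per sample and the differential comparisons.

Glycan feature classes are compared between groups with unpaired
two-sample t-tests on TIC-normalized class fractions; glycogene
expression (RPKM) is compared with a paired two-sample t-test across
patient-matched normal/tumor samples.  Two-sided p-values; p < 0.05 is
flagged significant.  Expression values are tested untransformed by
default (a log2(x+1) option exists); no multiple-testing correction is
applied by default (a Benjamini-Hochberg option exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from sulfoglyco.annotate import Annotation
from sulfoglyco.composition import ClassificationError, classify

ALPHA = 0.05

#: Feature classes profiled per sample.  The first four partition assigned
#: intensity; the rest are overlapping feature fractions.
CATEGORY_CLASSES = ("oligomannose", "paucimannose", "hybrid", "complex")
FEATURE_CLASSES = CATEGORY_CLASSES + (
    "branched", "bisect_candidate", "sialylated", "core_fucosylated",
    "sulfated", "di_sulfated",
)


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class ClassProfile:
    """Per-sample TIC-normalized fractions of glycan feature classes."""

    sample_id: str
    group: str                       # "normal" or "PTC"
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.get(c, 0.0) for c in CATEGORY_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ProfileError(
                f"category fractions sum to {total}, expected 1 "
                "(oligomannose + paucimannose + hybrid + complex)"
            )


def class_profile(
    annotations: list[Annotation], sample_id: str = "", group: str = ""
) -> ClassProfile:
    """Summarize one annotated spectrum into class fractions.

    Each fraction is the summed intensity of rank-1-assigned peaks in the
    class divided by the summed intensity of all rank-1-assigned peaks.
    Unassigned peaks and non-N-glycan assignments contribute to neither.

    Raises
    ------
    ProfileError
        If no peak carries an N-glycan assignment.
    """
    weights: dict[str, float] = {c: 0.0 for c in FEATURE_CLASSES}
    total = 0.0
    for a in annotations:
        if not a.assigned:
            continue
        comp = a.top.composition
        try:
            cls = classify(comp)
        except ClassificationError:
            continue
        w = a.peak.intensity
        total += w
        weights[cls.category.value] += w
        if cls.antennarity >= 3:
            weights["branched"] += w
        if cls.bisect_candidate:
            weights["bisect_candidate"] += w
        if cls.sialylation_count >= 1:
            weights["sialylated"] += w
        if cls.core_fucosylated:
            weights["core_fucosylated"] += w
        if cls.sulfation_count >= 1:
            weights["sulfated"] += w
        if cls.sulfation_count >= 2:
            weights["di_sulfated"] += w
    if total <= 0:
        raise ProfileError("no assigned N-glycan peaks in this spectrum")
    return ClassProfile(
        sample_id=sample_id, group=group,
        fractions={c: weights[c] / total for c in FEATURE_CLASSES},
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")
        assert self.significant == (self.pvalue < ALPHA)


class DegenerateDataError(ValueError):
    """Zero-variance input on which the t statistic is undefined."""


def _result(t: float, df: float, p: float) -> TestResult:
    return TestResult(
        statistic=float(t), df=float(df), pvalue=float(p),
        significant=bool(p < ALPHA),
    )


def ttest_unpaired(x, y, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test on class fractions.

    Pooled-variance (classic) by default; ``equal_var=False`` selects
    Welch.  Degenerate inputs: if both groups have zero variance and
    equal means the statistic is undefined (raises); with unequal means
    the difference is infinitely many standard errors away and p is
    reported as 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            raise DegenerateDataError(
                "both groups constant and equal: t statistic undefined"
            )
        warnings.warn(
            "both groups constant with unequal means; reporting p = 0",
            stacklevel=2,
        )
        sign = np.sign(x.mean() - y.mean())
        df = x.size + y.size - 2 if equal_var else x.size + y.size - 2
        return _result(sign * np.inf, df, 0.0)
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = x.size + y.size - 2
    else:
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (
            vx**2 / (x.size - 1) + vy**2 / (y.size - 1)
        )
    return _result(t, df, p)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample RPKM table with a paired normal/tumor design.

    ``pairing`` maps patient id -> (normal sample id, tumor sample id);
    every patient contributes exactly one sample per group.
    """

    values: pd.DataFrame                       # genes x samples, RPKM
    pairing: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")
        seen: set[str] = set()
        for patient, (normal, tumor) in self.pairing.items():
            for s in (normal, tumor):
                if s not in self.values.columns:
                    raise ValueError(f"sample {s!r} of patient {patient!r} "
                                     "missing from the expression table")
                if s in seen:
                    raise ValueError(f"sample {s!r} used twice in pairing")
                seen.add(s)

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def paired_values(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """(normal, tumor) value vectors in patient order."""
        row = self.values.loc[gene]
        normals = np.array([row[n] for n, _ in self.pairing.values()])
        tumors = np.array([row[t] for _, t in self.pairing.values()])
        return normals, tumors


def ttest_paired(
    matrix: ExpressionMatrix, gene: str, log2_transform: bool = False
) -> TestResult:
    """Paired two-sample t-test of tumor vs normal for one gene.

    Implemented as the one-sample t on per-patient differences
    (tumor - normal), two-sided.  ``log2_transform`` tests
    log2(RPKM + 1) instead of raw RPKM.
    """
    normals, tumors = matrix.paired_values(gene)
    if normals.size < 2:
        raise ValueError("need at least two complete pairs")
    if log2_transform:
        normals, tumors = np.log2(normals + 1), np.log2(tumors + 1)
    diffs = tumors - normals
    if diffs.var(ddof=1) == 0:
        if diffs[0] == 0:
            raise DegenerateDataError(
                "all paired differences are zero: t statistic undefined"
            )
        warnings.warn(
            "all paired differences identical and nonzero; reporting p = 0",
            stacklevel=2,
        )
        return _result(np.sign(diffs[0]) * np.inf, diffs.size - 1, 0.0)
    t, p = sps.ttest_1samp(diffs, 0.0)
    return _result(t, diffs.size - 1, p)


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = pvalues.size
    order = np.argsort(pvalues)
    ranked = pvalues[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def compare_profiles(
    profiles: list[ClassProfile],
    classes=FEATURE_CLASSES,
    equal_var: bool = True,
    adjust: bool = False,
) -> pd.DataFrame:
    """Unpaired group comparison of every feature class across samples.

    Returns a table (feature, t, df, p, significant) comparing the
    "normal" against the non-normal group.  Classes that are degenerate
    (constant in both groups) are reported with NaN statistics.
    """
    groups = sorted({p.group for p in profiles})
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    a, b = ("normal", next(g for g in groups if g != "normal")) \
        if "normal" in groups else tuple(groups)
    rows = []
    for cls in classes:
        x = [p.fractions.get(cls, 0.0) for p in profiles if p.group == a]
        y = [p.fractions.get(cls, 0.0) for p in profiles if p.group == b]
        try:
            res = ttest_unpaired(x, y, equal_var=equal_var)
            rows.append((cls, res.statistic, res.df, res.pvalue,
                         res.significant))
        except DegenerateDataError:
            rows.append((cls, np.nan, np.nan, np.nan, False))
    df = pd.DataFrame(
        rows, columns=["feature", "t", "df", "p", "significant"]
    )
    if adjust:
        ok = df["p"].notna()
        df.loc[ok, "p_adjusted"] = _bh_adjust(df.loc[ok, "p"].to_numpy())
        df["significant"] = df.get("p_adjusted", df["p"]) < ALPHA
    return df


def compare_expression(
    matrix: ExpressionMatrix,
    genes=None,
    log2_transform: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Paired tumor-vs-normal comparison for each gene in the matrix."""
    genes = list(genes) if genes is not None else list(matrix.values.index)
    rows = []
    for gene in genes:
        try:
            res = ttest_paired(matrix, gene, log2_transform=log2_transform)
            normals, tumors = matrix.paired_values(gene)
            rows.append((gene, res.statistic, res.df, res.pvalue,
                         res.significant,
                         float(np.mean(tumors) - np.mean(normals))))
        except DegenerateDataError:
            rows.append((gene, np.nan, np.nan, np.nan, False, 0.0))
    df = pd.DataFrame(
        rows,
        columns=["gene", "t", "df", "p", "significant", "mean_difference"],
    )
    if adjust:
        ok = df["p"].notna()
        df.loc[ok, "p_adjusted"] = _bh_adjust(df.loc[ok, "p"].to_numpy())
        df["significant"] = df.get("p_adjusted", df["p"]) < ALPHA
    return df
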