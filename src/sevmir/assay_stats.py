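"""Cytokine panel statistics and small behavioural/characterization formulas.

The cytokine workflow mirrors standard multiplex-immunoassay practice:
censored (below-LLOQ) wells are imputed at the analyte's lower limit of
quantitation, concentrations are normalized to each sample's total protein
content (pg/mL -> pg/mg), group differences are tested with a two-tailed
Welch t test, and Benjamini-Hochberg adjustment is applied within each
assayed fraction at FDR 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CytokineTable, SampleSheet, ValidationError


@dataclass
class CytokineStatResult:
    """Per-analyte group summaries and Welch test results (one table row)."""

    analyte: str
    n_control: int
    mean_control: float
    sd_control: float
    n_case: int
    mean_case: float
    sd_case: float
    difference: float  # case - control
    t: float
    df: float
    p: float
    p_adj: float = np.nan
    significant: bool = False


# ---------------------------------------------------------------------------
# table transforms
# ---------------------------------------------------------------------------


def impute_lloq(table: CytokineTable) -> CytokineTable:
    """Replace censored entries with the analyte's LLOQ.

    Uncensored entries are untouched; the number of imputations per analyte is
    recorded on the returned table.
    """
    missing = table.censored.any(axis=1) & table.lloq.isna()
    if missing.any():
        bad = table.lloq.index[missing].tolist()
        raise ValidationError(f"impute_lloq: censored entries but no LLOQ for analyte(s) {bad}")
    values = table.values.copy()
    for analyte in table.analytes:
        mask = table.censored.loc[analyte]
        values.loc[analyte, mask[mask].index] = table.lloq[analyte]
    n_imputed = table.censored.sum(axis=1)
    return CytokineTable(
        values=values,
        censored=table.censored.copy(),
        lloq=table.lloq.copy(),
        unit=table.unit,
        n_imputed=n_imputed,
    )


def protein_normalize(table: CytokineTable, sample_sheet: SampleSheet) -> CytokineTable:
    """Convert pg/mL concentrations to pg/mg of total protein."""
    sample_sheet.require_samples(table.samples)
    protein = sample_sheet.table.loc[table.samples, "protein_mg_per_ml"]
    bad = protein.index[protein.isna() | (protein <= 0)].tolist()
    if bad:
        raise ValidationError(
            f"protein_normalize: missing or non-positive protein content for sample(s) {bad}"
        )
    values = table.values.div(protein, axis=1)
    lloq = table.lloq  # LLOQ stays on the assay (pg/mL) scale
    return CytokineTable(
        values=values,
        censored=table.censored.copy(),
        lloq=lloq.copy(),
        unit="pg/mg",
        n_imputed=table.n_imputed,
    )


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def welch_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t test from group summaries: returns (t, df, two-tailed p).

    ``t`` is oriented as group2 - group1.  With both SDs zero and equal means
    the convention is (t, df, p) = (0, n1+n2-2, 1).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("welch_from_summary: each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValidationError("welch_from_summary: negative standard deviation")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValidationError("welch_from_summary: zero variance with unequal means")
    t = (m2 - m1) / np.sqrt(v1 + v2)
    with np.errstate(invalid="ignore", over="ignore", under="ignore"):
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if not np.isfinite(df):  # squared variances can underflow to 0/0
        df = float(n1 + n2 - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_from_samples(group1, group2) -> tuple[float, float, float]:
    """Welch t test from raw per-sample values (t oriented group2 - group1)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    return welch_from_summary(
        g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
    )


def students_t(group1, group2) -> tuple[float, float, float]:
    """Pooled-variance two-sample t test, two-tailed (t oriented group1 - group2)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("students_t: each group needs n >= 2")
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
        df = float(len(g1) + len(g2) - 2)
        if g1.mean() == g2.mean():
            return 0.0, df, 1.0
        raise ValidationError("students_t: zero pooled variance with unequal means")
    res = stats.ttest_ind(g1, g2, equal_var=True)
    df = float(len(g1) + len(g2) - 2)
    return float(res.statistic), df, float(res.pvalue)


def bh_adjust(p_values, m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj(i) = min over j >= i in sorted order of p(j) * m / j``, capped at 1;
    output order matches the input.  ``m`` defaults to the number of p-values
    and may be set larger when the tested family exceeds the reported list.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("bh_adjust: p-values must lie in (0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size:
        raise ValidationError("bh_adjust: m must be at least the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()


# ---------------------------------------------------------------------------
# panel pipeline
# ---------------------------------------------------------------------------


def analyze_cytokine_panel(
    table: CytokineTable,
    sample_sheet: SampleSheet,
    reference: str = "control",
    fdr: float = 0.05,
    normalize_protein: bool = True,
) -> pd.DataFrame:
    """Full per-fraction panel analysis: impute -> normalize -> Welch -> BH.

    Returns one row per analyte with the group summaries (mean, SD, n), the
    case-minus-control difference, Welch t / df / p, BH-adjusted p over the
    fraction's analytes, and the significance flag at ``fdr``.
    """
    work = impute_lloq(table)
    if normalize_protein:
        work = protein_normalize(work, sample_sheet)
    sample_sheet.require_samples(work.samples)
    groups = sorted(sample_sheet.groups.loc[work.samples].unique())
    if len(groups) != 2 or reference not in groups:
        raise ValidationError(
            f"analyze_cytokine_panel: need two groups including {reference!r}, got {groups}"
        )
    case = next(g for g in groups if g != reference)
    ctrl_samples = [s for s in work.samples if sample_sheet.groups[s] == reference]
    case_samples = [s for s in work.samples if sample_sheet.groups[s] == case]

    rows = []
    for analyte in work.analytes:
        g1 = work.values.loc[analyte, ctrl_samples].to_numpy(dtype=float)
        g2 = work.values.loc[analyte, case_samples].to_numpy(dtype=float)
        t, df, p = welch_from_samples(g1, g2)
        rows.append(
            CytokineStatResult(
                analyte=analyte,
                n_control=len(g1),
                mean_control=float(g1.mean()),
                sd_control=float(g1.std(ddof=1)),
                n_case=len(g2),
                mean_case=float(g2.mean()),
                sd_case=float(g2.std(ddof=1)),
                difference=float(g2.mean() - g1.mean()),
                t=t,
                df=df,
                p=p,
            )
        )
    adj = bh_adjust([r.p for r in rows])
    rows = [replace(r, p_adj=a, significant=bool(a < fdr)) for r, a in zip(rows, adj)]
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("analyte")
    return out


# ---------------------------------------------------------------------------
# small formulas
# ---------------------------------------------------------------------------


def hindpaw_weight_ratio(right_g: float, left_g: float) -> float:
    """Hind-paw weight-bearing ratio, 2R/(R+L) x 100 (percent).

    100 means symmetric loading; values below 100 indicate unweighting of the
    right (injured) limb.
    """
    if right_g < 0 or left_g < 0:
        raise ValidationError("hindpaw_weight_ratio: weights must be non-negative")
    if right_g + left_g == 0:
        raise ValidationError("hindpaw_weight_ratio: R + L must be positive")
    return 2.0 * right_g / (right_g + left_g) * 100.0
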