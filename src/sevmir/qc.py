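"""Sample-level quality control and TPM normalization.

A sample fails QC when any of the following holds:

* total reads below ``min_total_reads`` (default 1e6),
* fraction of reads from positive-control spike probes at or above
  ``max_spike_fraction`` (default 0.10),
* coefficient of variation (sd/mean) of its housekeeping-probe counts at or
  above ``max_cv`` (default 0.15).

The CV is computed over the sample's housekeeping probes by default
(configurable to positive-control probes); housekeeping probes are the
intended invariant signal of the panel, so a noisy housekeeping profile marks
a degraded sample.  The spike comparator is the conservative ``>=``.

TPM (transcripts per kilobase million) divides each count by its probe length
in kilobases and rescales every sample to sum to 1e6.  Positive-control spike
probes are excluded from both the numerator set and the scaling denominator:
their content is a feature of the assay design, not of the biology, and would
distort the compositional scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import CountMatrix, ExpressionMatrix, SampleSheet, ValidationError


@dataclass
class QCThresholds:
    min_total_reads: int = 1_000_000
    max_spike_fraction: float = 0.10
    max_cv: float = 0.15
    cv_probe_class: str = "housekeeping"  # or "positive_control"

    def __post_init__(self) -> None:
        if self.min_total_reads <= 0:
            raise ValidationError("QCThresholds: min_total_reads must be positive")
        if not (0 < self.max_spike_fraction < 1):
            raise ValidationError("QCThresholds: max_spike_fraction must be in (0, 1)")
        if not (0 < self.max_cv < 1):
            raise ValidationError("QCThresholds: max_cv must be in (0, 1)")


@dataclass
class SampleQCReport:
    metrics: pd.DataFrame  # index sample; total_reads, spike_fraction, cv, passed
    reasons: dict[str, list[str]]
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def passed(self) -> list[str]:
        return list(self.metrics.index[self.metrics["passed"]])

    @property
    def failed(self) -> list[str]:
        return list(self.metrics.index[~self.metrics["passed"]])

    def to_dict(self) -> dict:
        return {
            "thresholds": asdict(self.thresholds),
            "samples": {
                s: {
                    "total_reads": int(self.metrics.at[s, "total_reads"]),
                    "spike_fraction": float(self.metrics.at[s, "spike_fraction"]),
                    "cv": float(self.metrics.at[s, "cv"]),
                    "passed": bool(self.metrics.at[s, "passed"]),
                    "reasons": self.reasons[s],
                }
                for s in self.metrics.index
            },
        }


def sample_qc(cm: CountMatrix, thresholds: QCThresholds | None = None) -> SampleQCReport:
    """Compute per-sample QC metrics and pass/fail calls."""
    thresholds = thresholds or QCThresholds()
    spikes = cm.probe_ids("positive_control")
    if not spikes:
        raise ValidationError(
            "sample_qc: no positive_control probes annotated; the spike-fraction "
            "filter cannot run — annotate spike probes or disable the check"
        )
    cv_probes = cm.probe_ids(thresholds.cv_probe_class)
    if len(cv_probes) < 2:
        raise ValidationError(
            f"sample_qc: need >=2 probes of class {thresholds.cv_probe_class!r} to compute a CV"
        )

    total = cm.counts.sum(axis=0)
    spike_fraction = cm.counts.loc[spikes].sum(axis=0) / total.replace(0, np.nan)
    spike_fraction = spike_fraction.fillna(0.0)
    sub = cm.counts.loc[cv_probes].astype(float)
    means = sub.mean(axis=0)
    cv = sub.std(axis=0, ddof=1) / means.replace(0, np.nan)
    cv = cv.fillna(np.inf)

    reasons: dict[str, list[str]] = {}
    for s in cm.samples:
        r = []
        if total[s] < thresholds.min_total_reads:
            r.append("low_total_reads")
        if spike_fraction[s] >= thresholds.max_spike_fraction:
            r.append("high_spike")
        if cv[s] >= thresholds.max_cv:
            r.append("high_cv")
        reasons[s] = r
    metrics = pd.DataFrame(
        {
            "total_reads": total,
            "spike_fraction": spike_fraction,
            "cv": cv,
            "passed": [not reasons[s] for s in cm.samples],
        }
    )
    return SampleQCReport(metrics, reasons, thresholds)


def drop_failed_samples(
    cm: CountMatrix, report: SampleQCReport, sample_sheet: SampleSheet | None = None
) -> CountMatrix:
    """Remove QC-failing sample columns.

    With a sample sheet, refuses to leave any group with fewer than two
    samples (two-group inference would be impossible downstream).
    """
    missing = [s for s in cm.samples if s not in report.metrics.index]
    if missing:
        raise ValidationError(f"drop_failed_samples: report lacks sample(s) {missing}")
    keep = [s for s in cm.samples if bool(report.metrics.at[s, "passed"])]
    if sample_sheet is not None:
        sample_sheet.require_samples(cm.samples)
        groups = sample_sheet.groups.loc[keep]
        for g, n in groups.value_counts().items():
            if n < 2:
                raise ValidationError(
                    f"drop_failed_samples: group {g!r} would retain {n} sample(s); >=2 required"
                )
    return cm.select_samples(keep)


def tpm_normalize(cm: CountMatrix) -> ExpressionMatrix:
    """Length-normalize counts and scale each sample to 1e6.

    Positive-control probes are dropped before scaling; the returned matrix
    contains only biological (mirna / housekeeping / other) probes and each
    retained sample's TPM column sums to 1e6.
    """
    spikes = set(cm.probe_ids("positive_control"))
    keep = [p for p in cm.probes if p not in spikes]
    counts = cm.counts.loc[keep].astype(float)
    lengths = cm.annotation.loc[keep, "length_kb"].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValidationError(f"tpm_normalize: non-positive probe length for {bad}")
    rates = counts.div(lengths, axis=0)
    denom = rates.sum(axis=0)
    zero = denom.index[denom == 0].tolist()
    if zero:
        raise ValidationError(f"tpm_normalize: sample(s) {zero} have zero total signal")
    tpm = rates.div(denom, axis=1) * 1e6
    return ExpressionMatrix(
        values=tpm,
        annotation=cm.annotation.loc[keep].copy(),
        unit="tpm",
        provenance={"excluded_positive_controls": sorted(spikes)},
    )


def log_transform(em: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount); the default pseudocount of 1 maps TPM 0 to 0."""
    if em.unit != "tpm":
        raise ValidationError(f"log_transform: expected unit 'tpm', got {em.unit!r}")
    if pseudocount < 0:
        raise ValidationError("log_transform: pseudocount must be >= 0")
    if pseudocount == 0 and (em.values.to_numpy() <= 0).any():
        raise ValidationError("log_transform: zero values require a positive pseudocount")
    values = np.log2(em.values + pseudocount)
    return ExpressionMatrix(
        values=values,
        annotation=em.annotation.copy(),
        unit="log2tpm",
        pseudocount=pseudocount,
        provenance=dict(em.provenance),
    )


def low_expression_filter(
    em: ExpressionMatrix,
    sample_sheet: SampleSheet,
    mode: str = "all_samples_below",
    threshold: float = 1.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop probes with negligible expression.

    ``all_samples_below`` (default) removes a probe only when every sample in
    both groups is below ``threshold`` TPM; ``any_sample_below`` removes a
    probe when any single sample falls below it.  Housekeeping probes are
    never removed (they anchor downstream normalization).
    """
    if em.unit != "tpm":
        raise ValidationError(f"low_expression_filter: expected unit 'tpm', got {em.unit!r}")
    if mode not in ("all_samples_below", "any_sample_below"):
        raise ValidationError(f"low_expression_filter: unknown mode {mode!r}")
    sample_sheet.require_samples(em.samples)
    below = em.values < threshold
    if mode == "all_samples_below":
        remove = below.all(axis=1)
    else:
        remove = below.any(axis=1)
    hk = em.annotation["probe_class"] == "housekeeping"
    remove &= ~hk
    removed = list(em.values.index[remove])
    kept = em.values.index[~remove]
    out = ExpressionMatrix(
        values=em.values.loc[kept],
        annotation=em.annotation.loc[kept].copy(),
        unit=em.unit,
        pseudocount=em.pseudocount,
        provenance={**em.provenance, "low_expression_removed": len(removed), "filter_mode": mode},
    )
    return out, removed
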