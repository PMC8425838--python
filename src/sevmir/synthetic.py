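"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a nuclease-protection miRNA counting panel run on
serum small-EV samples from two small groups of inbred mice, plus the
matching multiplex cytokine panel and annotation resources, and emits the
planted ground truth so recovery can be measured.

Counts are negative-binomial around probe-specific expected proportions
scaled by a per-sample library size.  Up-regulated miRNAs are planted by
multiplying the case-group expected proportion by a fold change drawn from
``de_fc_range``; proportions are renormalized per sample, so the planted fold
change is preserved exactly on the housekeeping-relative scale (composition
cancels).  Housekeeping probes share a common expected abundance and a low
dispersion so the within-sample housekeeping CV is a pure noise metric.
Quality-control failures are planted explicitly (low_reads, high_spike,
high_cv) rather than left to chance, so QC tests are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    CountMatrix,
    CytokineTable,
    GeneSetCollection,
    SampleSheet,
    SignatureTable,
    TargetTable,
    ValidationError,
)

#: Analytes of a mouse 23-plex bead immunoassay panel.
CYTOKINE_PANEL = (
    "IL-1a", "IL-1b", "IL-2", "IL-3", "IL-4", "IL-5", "IL-6", "IL-9", "IL-10",
    "IL-12p40", "IL-12p70", "IL-13", "IL-17", "Eotaxin", "G-CSF", "GM-CSF",
    "IFNg", "KC", "MCP-1", "MIP-1a", "MIP-1b", "RANTES", "TNFa",
)

#: sEV-deplete-fraction analytes planted with a group shift by default.
DEFAULT_SEV_MINUS_SHIFTED = ("IL-1b", "IL-2", "IL-6", "MCP-1", "TNFa", "KC")


@dataclass
class SignatureSpec:
    """One synthetic reference signature: its design attributes and how many
    of its names overlap the planted DE set."""

    study_id: str
    sample_type: str = "exosome"
    comparison: str = "case_vs_control"
    treatment: str = "none"
    n_overlap: int = 8
    n_extra: int = 12


def _default_signature_specs() -> list[SignatureSpec]:
    return [
        SignatureSpec("exosome_crps", "exosome", "case_vs_control", "untreated", 8, 12),
        SignatureSpec("wholeblood_crps", "whole_blood", "case_vs_control", "untreated", 22, 30),
        SignatureSpec("wholeblood_ketamine", "whole_blood", "pre_post", "ketamine", 27, 40),
        SignatureSpec("exosome_plasma_exchange", "exosome", "pre_post", "plasma_exchange", 3, 10),
    ]


@dataclass
class SyntheticConfig:
    n_control: int = 5
    n_case: int = 4
    n_mirna: int = 2000
    n_housekeeping: int = 13
    n_spike: int = 5
    n_de: int = 57
    de_fc_range: tuple[float, float] = (2.0, 6.0)
    library_size_mean: float = 3e6
    library_size_sigma: float = 0.1  # lognormal sigma of library sizes
    nb_dispersion: float = 0.05  # miRNA probes
    hk_dispersion: float = 0.005  # housekeeping probes
    spike_dispersion: float = 0.005  # positive-control spikes
    abundance_sigma: float = 2.5  # lognormal spread of baseline abundances
    hk_tpm_target: float = 3000.0  # expected TPM of each housekeeping probe
    de_min_tpm: float = 5.0  # DE planted only on probes at least this abundant
    spike_fraction_normal: float = 0.02
    spike_fraction_planted: float = 0.15
    low_reads_planted: float = 5e5
    planted_qc_failures: list[tuple[str, str]] = field(
        default_factory=lambda: [("control_1", "high_spike")]
    )
    # cytokine panel
    n_cytokine_control: int = 6
    n_cytokine_case: int = 8
    cytokine_sigma: float = 0.5  # lognormal within-group sigma
    cytokine_shift_sev_plus: dict[str, float] | float = 0.7
    cytokine_shift_sev_minus: dict[str, float] | float | None = None  # default: 2.5 on a few
    lloq_fraction: float = 0.3  # LLOQ relative to the analyte's baseline median
    # annotation resources
    n_genes: int = 400
    targets_per_mirna: float = 8.0
    n_terms: int = 30
    n_enriched_terms: int = 10
    signature_specs: list[SignatureSpec] = field(default_factory=_default_signature_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_mirna:
            raise ValidationError("SyntheticConfig: n_de cannot exceed n_mirna")
        if self.de_fc_range[0] < 1.0 or self.de_fc_range[1] < self.de_fc_range[0]:
            raise ValidationError("SyntheticConfig: de_fc_range must satisfy 1 <= low <= high")
        if not (0 < self.spike_fraction_normal < 1) or not (0 < self.spike_fraction_planted < 1):
            raise ValidationError("SyntheticConfig: spike fractions must be in (0, 1)")
        for n in (self.n_control, self.n_case, self.n_mirna, self.n_housekeeping, self.n_spike):
            if n <= 0:
                raise ValidationError("SyntheticConfig: panel dimensions must be positive")


@dataclass
class PlantedTruth:
    de_mirnas: dict[str, float]  # probe_id -> planted fold change
    qc_failures: list[tuple[str, str]]
    cytokine_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    signature_overlaps: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "de_mirnas": self.de_mirnas,
                    "qc_failures": [list(x) for x in self.qc_failures],
                    "cytokine_shifts": self.cytokine_shifts,
                    "signature_overlaps": self.signature_overlaps,
                },
                handle,
                indent=2,
            )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _probe_ids(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    mirna = [f"mir-{i:04d}" for i in range(1, config.n_mirna + 1)]
    hk = [f"hk-{i:02d}" for i in range(1, config.n_housekeeping + 1)]
    spike = [f"spike-{i}" for i in range(1, config.n_spike + 1)]
    return mirna, hk, spike


def _baseline_and_de(config: SyntheticConfig, rng: np.random.Generator):
    """Baseline miRNA abundance weights and the planted DE probe selection."""
    w_mirna = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_mirna)
    hk_share = config.n_housekeeping * config.hk_tpm_target / 1e6
    hk_each = (config.hk_tpm_target / 1e6) * w_mirna.sum() / (1.0 - hk_share)
    total_bio = w_mirna.sum() + config.n_housekeeping * hk_each
    baseline_tpm = w_mirna / total_bio * 1e6
    eligible = np.flatnonzero(baseline_tpm >= config.de_min_tpm)
    if len(eligible) < config.n_de:
        raise ValidationError(
            f"SyntheticConfig: only {len(eligible)} probes reach {config.de_min_tpm} TPM; "
            f"cannot plant {config.n_de} DE probes"
        )
    de_idx = np.sort(rng.choice(eligible, size=config.n_de, replace=False))
    de_fc = rng.uniform(*config.de_fc_range, size=config.n_de)
    return w_mirna, hk_each, de_idx, de_fc


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def simulate_counts(
    config: SyntheticConfig | None = None,
) -> tuple[CountMatrix, SampleSheet, PlantedTruth]:
    """Simulate the probe-level count matrix, sample sheet and planted truth."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    mirna_ids, hk_ids, spike_ids = _probe_ids(config)
    samples = [f"control_{i}" for i in range(1, config.n_control + 1)] + [
        f"case_{i}" for i in range(1, config.n_case + 1)
    ]
    groups = ["control"] * config.n_control + ["case"] * config.n_case
    failures = dict(config.planted_qc_failures)
    unknown = set(failures) - set(samples)
    if unknown:
        raise ValidationError(f"SyntheticConfig: planted failure on unknown sample(s) {sorted(unknown)}")

    w_mirna, hk_each, de_idx, de_fc = _baseline_and_de(config, rng)

    library = rng.lognormal(
        mean=np.log(config.library_size_mean) - config.library_size_sigma**2 / 2,
        sigma=config.library_size_sigma,
        size=len(samples),
    )

    counts = np.zeros((config.n_mirna + config.n_housekeeping + config.n_spike, len(samples)), dtype=np.int64)
    for j, (sample, group) in enumerate(zip(samples, groups)):
        w = w_mirna.copy()
        if group == "case":
            w[de_idx] *= de_fc
        bio = np.concatenate([w, np.full(config.n_housekeeping, hk_each)])
        bio_p = bio / bio.sum()
        mode = failures.get(sample)
        spike_frac = config.spike_fraction_planted if mode == "high_spike" else config.spike_fraction_normal
        lib = config.low_reads_planted if mode == "low_reads" else library[j]
        p = np.concatenate(
            [bio_p * (1.0 - spike_frac), np.full(config.n_spike, spike_frac / config.n_spike)]
        )
        mu = lib * p
        n_bio = config.n_mirna
        hk_disp = 0.25 if mode == "high_cv" else config.hk_dispersion
        col = np.concatenate(
            [
                _nb_draw(rng, mu[:n_bio], config.nb_dispersion),
                _nb_draw(rng, mu[n_bio : n_bio + config.n_housekeeping], hk_disp),
                _nb_draw(rng, mu[n_bio + config.n_housekeeping :], config.spike_dispersion),
            ]
        )
        counts[:, j] = col

    probe_ids = mirna_ids + hk_ids + spike_ids
    annotation = pd.DataFrame(
        {
            "probe_class": ["mirna"] * config.n_mirna
            + ["housekeeping"] * config.n_housekeeping
            + ["positive_control"] * config.n_spike,
            "length_kb": 1.0,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=annotation.index, columns=samples), annotation
    )
    protein = rng.lognormal(mean=np.log(2.0), sigma=0.2, size=len(samples))
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": groups, "protein_mg_per_ml": protein},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = PlantedTruth(
        de_mirnas={mirna_ids[i]: float(fc) for i, fc in zip(de_idx, de_fc)},
        qc_failures=list(config.planted_qc_failures),
    )
    return cm, sheet, truth


# ---------------------------------------------------------------------------
# cytokines
# ---------------------------------------------------------------------------


def _shift_map(spec, default: float = 1.0) -> dict[str, float]:
    if spec is None:
        return {a: (2.5 if a in DEFAULT_SEV_MINUS_SHIFTED else 1.0) for a in CYTOKINE_PANEL}
    if isinstance(spec, (int, float)):
        return {a: float(spec) for a in CYTOKINE_PANEL}
    return {a: float(spec.get(a, default)) for a in CYTOKINE_PANEL}


def simulate_cytokines(
    config: SyntheticConfig | None = None,
) -> tuple[CytokineTable, CytokineTable, SampleSheet, PlantedTruth]:
    """Simulate sEV+ and sEV- fraction cytokine panels with censoring.

    Concentrations are log-normal around a per-analyte baseline; the case
    group's median is multiplied by the configured ratio.  Values below the
    analyte's LLOQ are flagged censored (their numeric value is masked, as a
    plate reader would report "<LLOQ").  Also returns the panel's sample
    sheet (groups and protein content) and the planted shift truth.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    samples = [f"cyt_control_{i}" for i in range(1, config.n_cytokine_control + 1)] + [
        f"cyt_case_{i}" for i in range(1, config.n_cytokine_case + 1)
    ]
    groups = ["control"] * config.n_cytokine_control + ["case"] * config.n_cytokine_case
    baseline = pd.Series(
        rng.lognormal(mean=np.log(500.0), sigma=1.5, size=len(CYTOKINE_PANEL)),
        index=list(CYTOKINE_PANEL),
    )
    lloq = baseline * config.lloq_fraction
    shifts = {
        "sev_plus": _shift_map(config.cytokine_shift_sev_plus),
        "sev_minus": _shift_map(config.cytokine_shift_sev_minus),
    }

    tables = {}
    for fraction, shift in shifts.items():
        values = np.empty((len(CYTOKINE_PANEL), len(samples)))
        for i, analyte in enumerate(CYTOKINE_PANEL):
            for j, group in enumerate(groups):
                med = baseline[analyte] * (shift[analyte] if group == "case" else 1.0)
                values[i, j] = rng.lognormal(np.log(med), config.cytokine_sigma)
        df = pd.DataFrame(values, index=list(CYTOKINE_PANEL), columns=samples)
        censored = df.lt(lloq, axis=0)
        tables[fraction] = CytokineTable(
            values=df.where(~censored, np.nan),
            censored=censored,
            lloq=lloq.copy(),
        )
    protein = rng.lognormal(mean=np.log(2.0), sigma=0.2, size=len(samples))
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": groups, "protein_mg_per_ml": protein},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = PlantedTruth(de_mirnas={}, qc_failures=[], cytokine_shifts=shifts)
    return tables["sev_plus"], tables["sev_minus"], sheet, truth


# ---------------------------------------------------------------------------
# annotation resources (targets, gene sets, reference signatures)
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SyntheticConfig | None = None,
    de_mirnas: list[str] | None = None,
) -> tuple[TargetTable, GeneSetCollection, list[SignatureTable], PlantedTruth]:
    """Simulate target tables, a GMT collection, and reference signatures.

    ``de_mirnas`` defaults to the planted DE set of :func:`simulate_counts`
    under the same config (the same seed reproduces the same selection).
    Reference signatures carry a species prefix ("hsa-") to exercise
    harmonization, and each overlaps the DE set by its configured count.
    """
    config = config or SyntheticConfig()
    if de_mirnas is None:
        _, _, truth = simulate_counts(config)
        de_mirnas = sorted(truth.de_mirnas)
    rng = np.random.default_rng(None if config.seed is None else config.seed + 2)
    mirna_ids, _, _ = _probe_ids(config)
    non_de = [m for m in mirna_ids if m not in set(de_mirnas)]
    genes = [f"gene-{i:04d}" for i in range(1, config.n_genes + 1)]

    # predicted and validated miRNA -> gene interactions
    covered = list(de_mirnas) + list(rng.choice(non_de, size=min(100, len(non_de)), replace=False))
    pred_rows, val_rows = [], []
    for mirna in covered:
        k = max(1, rng.poisson(config.targets_per_mirna))
        targets = rng.choice(genes, size=min(k, len(genes)), replace=False)
        scores = rng.uniform(0.5, 1.0, size=len(targets))
        for g, s in zip(targets, scores):
            pred_rows.append({"mirna": mirna, "gene": g, "score": float(s), "evidence": "predicted"})
        validated = targets[rng.random(len(targets)) < 0.6]
        for g in validated:
            val_rows.append({"mirna": mirna, "gene": g, "score": np.nan, "evidence": "validated"})
    targets_table = TargetTable(pd.DataFrame(pred_rows + val_rows))

    # gene sets: some enriched for the DE miRNAs' high-confidence targets
    pred_df = pd.DataFrame(pred_rows)
    de_targets = sorted(
        set(pred_df[(pred_df["mirna"].isin(de_mirnas)) & (pred_df["score"] > 0.9)]["gene"])
    )
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(1, config.n_terms + 1):
        term = f"GO:{t:07d}"
        size = int(rng.integers(10, 41))
        if t <= config.n_enriched_terms and de_targets:
            n_hit = min(len(de_targets), max(3, int(round(size * 0.7))))
            hit = list(rng.choice(de_targets, size=n_hit, replace=False))
            rest = [g for g in genes if g not in hit]
            fill = list(rng.choice(rest, size=max(0, size - n_hit), replace=False))
            members = frozenset(hit + fill)
            name = f"synthetic enriched process {t}"
        else:
            members = frozenset(rng.choice(genes, size=size, replace=False))
            name = f"synthetic background process {t}"
        sets[term] = (name, members)
    gsc = GeneSetCollection(sets, background=frozenset(genes))

    # reference signatures with configured overlap against the DE set
    signatures = []
    overlaps: dict[str, int] = {}
    for spec in config.signature_specs:
        if spec.n_overlap > len(de_mirnas):
            raise ValidationError(
                f"simulate_annotation: signature {spec.study_id!r} requests overlap "
                f"{spec.n_overlap} > {len(de_mirnas)} DE miRNAs"
            )
        hit = list(rng.choice(de_mirnas, size=spec.n_overlap, replace=False))
        extra = list(rng.choice(non_de, size=min(spec.n_extra, len(non_de)), replace=False))
        names = [f"hsa-{m}" for m in hit + extra]
        signatures.append(
            SignatureTable(
                study_id=spec.study_id,
                sample_type=spec.sample_type,
                comparison=spec.comparison,
                treatment=spec.treatment,
                mirnas=sorted(names),
            )
        )
        overlaps[spec.study_id] = spec.n_overlap
    truth = PlantedTruth(
        de_mirnas={}, qc_failures=[], signature_overlaps=overlaps
    )
    return targets_table, gsc, signatures, truth


def write_simulation_inputs(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Simulate every pipeline input and write it under ``outdir``.

    Returns a mapping of logical input name to written path; the planted
    ground truth goes to ``truth.json``.
    """
    from pathlib import Path

    from .core_io import (
        write_count_matrix,
        write_cytokines,
        write_gmt,
        write_sample_sheet,
        write_signatures,
        write_targets,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, sheet, truth = simulate_counts(config)
    sev_plus, sev_minus, cyt_sheet, cyt_truth = simulate_cytokines(config)
    targets, gsc, signatures, sig_truth = simulate_annotation(
        config, de_mirnas=sorted(truth.de_mirnas)
    )
    paths = {
        "counts": outdir / "counts.tsv",
        "annotation": outdir / "annotation.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "cytokines_sev_plus": outdir / "cytokines_sev_plus.tsv",
        "cytokines_sev_minus": outdir / "cytokines_sev_minus.tsv",
        "cytokine_sample_sheet": outdir / "cytokine_samples.tsv",
        "targets": outdir / "targets.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "signatures": outdir / "signatures.tsv",
    }
    write_count_matrix(cm, paths["counts"], annotation_path=paths["annotation"])
    write_sample_sheet(sheet, paths["sample_sheet"])
    write_cytokines(sev_plus, paths["cytokines_sev_plus"])
    write_cytokines(sev_minus, paths["cytokines_sev_minus"])
    write_sample_sheet(cyt_sheet, paths["cytokine_sample_sheet"])
    write_targets(targets, paths["targets"])
    write_gmt(gsc, paths["gene_sets"])
    write_signatures(signatures, paths["signatures"])
    truth.cytokine_shifts = cyt_truth.cytokine_shifts
    truth.signature_overlaps = sig_truth.signature_overlaps
    truth.to_json(outdir / "truth.json")
    return {k: str(v) for k, v in paths.items()} | {"truth": str(outdir / "truth.json")}


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["signature_specs"] = [asdict(s) for s in config.signature_specs]
    return d
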