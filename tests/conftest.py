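import numpy as np
import pandas as pd
import pytest

from sevmir import CountMatrix, SampleSheet


def make_count_matrix(counts: dict, classes: dict | None = None, lengths: dict | None = None):
    """Small CountMatrix from {probe: [counts per sample]} dicts."""
    df = pd.DataFrame(counts).T
    df.columns = [f"s{i+1}" for i in range(df.shape[1])]
    df.index.name = "probe_id"
    classes = classes or {}
    lengths = lengths or {}
    ann = pd.DataFrame(
        {
            "probe_class": [classes.get(p, "mirna") for p in df.index],
            "length_kb": [lengths.get(p, 1.0) for p in df.index],
        },
        index=df.index,
    )
    return CountMatrix(df.astype(np.int64), ann)


def make_sheet(groups: dict, protein: dict | None = None) -> SampleSheet:
    protein = protein or {}
    return SampleSheet(
        pd.DataFrame(
            {
                "group": pd.Series(groups),
                "protein_mg_per_ml": pd.Series({s: protein.get(s, np.nan) for s in groups}),
            }
        ).rename_axis("sample_id")
    )


@pytest.fixture(scope="session")
def default_run():
    """One full synthetic run (seed 1) shared across tests: counts -> DE table."""
    from sevmir import (
        GroupDesign,
        call_differential,
        drop_failed_samples,
        fold_change,
        housekeeping_normalize,
        low_expression_filter,
        permutation_t_test,
        sample_qc,
        tpm_normalize,
    )
    from sevmir.synthetic import SyntheticConfig, simulate_counts

    config = SyntheticConfig(seed=1)
    cm, sheet, truth = simulate_counts(config)
    qc_report = sample_qc(cm)
    kept = drop_failed_samples(cm, qc_report, sheet)
    em = tpm_normalize(kept)
    filtered, removed = low_expression_filter(em, sheet)
    design = GroupDesign.from_sample_sheet(sheet, filtered.samples)
    norm = housekeeping_normalize(filtered, pseudocount=1.0)
    log_norm = pd.DataFrame(
        np.log2(norm.values), index=norm.values.index, columns=norm.values.columns
    )
    fc = fold_change(norm, design)
    p = permutation_t_test(log_norm, design, scheme="pooled")
    de = call_differential(fc, p, annotation=norm.annotation)
    return {
        "config": config,
        "cm": cm,
        "sheet": sheet,
        "truth": truth,
        "qc": qc_report,
        "kept": kept,
        "em": em,
        "filtered": filtered,
        "removed": removed,
        "design": design,
        "norm": norm,
        "log_norm": log_norm,
        "fc": fc,
        "p": p,
        "de": de,
    }
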