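"""Bundled reference datasets.

Three small tables transcribed from the published results of a serum-sEV
miRNA/cytokine profiling study of the mouse tibia fracture model of CRPS.
They serve as worked-example inputs and as fixed ground truth for validating
the statistics in this package against independently computed, published
numbers:

* ``load_cytokine_summary`` — per-analyte group summaries (mean, SD, n) and
  the published Welch p / BH-adjusted p for the 23-plex panel on the sEV
  fraction (control n=6, fracture n=8, pg per mg protein).
* ``load_de_table`` — the 57 probes reported up-regulated in fracture-model
  sEVs (housekeeping-relative fold change and permutation p).
* ``load_reference_signatures`` — four prior-study CRPS miRNA signatures
  (patient exosome and whole-blood cohorts, untreated and treated designs)
  used for cross-cohort overlap.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core_io import SignatureTable, read_signatures


def _data_path(name: str):
    return resources.files("sevmir").joinpath("data", name)


def load_cytokine_summary() -> pd.DataFrame:
    """Published cytokine panel summaries: one row per analyte.

    Columns: control_mean, control_n, control_sd, tfm_mean, tfm_n, tfm_sd,
    difference (case - control), p, p_adj.  Units pg/mg protein.
    """
    with resources.as_file(_data_path("tfm_sev_cytokine_summary.tsv")) as path:
        return pd.read_csv(path, sep="\t").set_index("analyte")


def load_de_table() -> pd.DataFrame:
    """Published DE miRNA table: mirna, fold_change (case/control), p."""
    with resources.as_file(_data_path("tfm_sev_de_mirnas.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_reference_signatures() -> list[SignatureTable]:
    """Prior-study CRPS miRNA signatures for cross-cohort overlap."""
    with resources.as_file(_data_path("crps_reference_signatures.tsv")) as path:
        return read_signatures(path)
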