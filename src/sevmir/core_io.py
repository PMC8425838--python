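"""Domain containers and readers/writers for every table the pipeline touches.

All tabular inputs are tab-separated by default (``sep`` is configurable); the
containers are thin dataclasses around :class:`pandas.DataFrame` that validate
at the boundary.  miRNA names are stored verbatim here — cross-study name
harmonization is deliberately deferred to :mod:`sevmir.cross_cohort` so that
provenance is preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("sevmir")

PROBE_CLASSES = ("mirna", "housekeeping", "positive_control", "other")

#: Column order of a probe annotation table.
ANNOTATION_COLUMNS = ("probe_class", "length_kb")


class ValidationError(ValueError):
    """An input file or container violated its contract.

    The message always names the offending file/cell and the rule violated.
    """


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _check_annotation(annotation: pd.DataFrame, context: str = "annotation") -> pd.DataFrame:
    if annotation.index.has_duplicates:
        dupes = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValidationError(f"{context}: duplicate probe_id(s) {dupes}")
    bad = set(annotation["probe_class"]) - set(PROBE_CLASSES)
    if bad:
        raise ValidationError(f"{context}: unknown probe_class value(s) {sorted(bad)}")
    if (annotation["length_kb"] <= 0).any():
        offenders = annotation.index[annotation["length_kb"] <= 0].tolist()
        raise ValidationError(f"{context}: non-positive length_kb for probe(s) {offenders}")
    return annotation


@dataclass
class CountMatrix:
    """Raw integer read counts (probes x samples) plus probe annotation.

    ``annotation`` is indexed by probe_id with columns ``probe_class``
    (one of mirna / housekeeping / positive_control / other) and ``length_kb``.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.annotation.index):
            raise ValidationError(
                "CountMatrix: counts rows and annotation rows disagree "
                f"({len(self.counts)} probes vs {len(self.annotation)} annotated)"
            )
        if self.counts.columns.has_duplicates:
            raise ValidationError("CountMatrix: duplicate sample names")
        _check_annotation(self.annotation, "CountMatrix annotation")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            frac, _ = np.modf(values.astype(float))
            if np.any(frac != 0):
                r, c = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"CountMatrix: non-integer count at probe "
                    f"{self.counts.index[r]!r}, sample {self.counts.columns[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"CountMatrix: negative count at probe "
                f"{self.counts.index[r]!r}, sample {self.counts.columns[c]!r}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.counts.index)

    def probe_ids(self, probe_class: str) -> list[str]:
        """Probe ids belonging to one annotation class."""
        mask = self.annotation["probe_class"] == probe_class
        return list(self.annotation.index[mask])

    def select_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.annotation.copy())


@dataclass
class SampleSheet:
    """Sample metadata: group label and optional protein content (mg/mL)."""

    table: pd.DataFrame  # index sample_id; columns group, protein_mg_per_ml

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("SampleSheet: duplicate sample_id")
        if "group" not in self.table.columns:
            raise ValidationError("SampleSheet: missing required column 'group'")
        if "protein_mg_per_ml" not in self.table.columns:
            self.table = self.table.assign(protein_mg_per_ml=np.nan)
        protein = self.table["protein_mg_per_ml"]
        if ((protein <= 0) & protein.notna()).any():
            bad = self.table.index[(protein <= 0) & protein.notna()].tolist()
            raise ValidationError(f"SampleSheet: non-positive protein content for sample(s) {bad}")

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def require_samples(self, samples: list[str]) -> None:
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise ValidationError(f"SampleSheet: no row for sample(s) {missing}")


@dataclass
class ExpressionMatrix:
    """Normalized expression values with provenance.

    ``unit`` is ``"tpm"``, ``"log2tpm"`` or ``"hk_relative"`` /
    ``"log2_hk_relative"`` after housekeeping normalization.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    unit: str = "tpm"
    pseudocount: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.annotation.index):
            raise ValidationError("ExpressionMatrix: values/annotation probe mismatch")

    def probe_ids(self, probe_class: str) -> list[str]:
        mask = self.annotation["probe_class"] == probe_class
        return list(self.annotation.index[mask])

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SignatureTable:
    """A named miRNA list from one prior study, with its design attributes."""

    study_id: str
    sample_type: str = ""
    comparison: str = ""
    treatment: str = ""
    mirnas: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(not m for m in self.mirnas):
            raise ValidationError(f"Signature {self.study_id!r}: empty miRNA name")
        if len(set(self.mirnas)) != len(self.mirnas):
            seen: set[str] = set()
            dupes = sorted({m for m in self.mirnas if m in seen or seen.add(m)})
            raise ValidationError(f"Signature {self.study_id!r}: duplicate miRNA name(s) {dupes}")


@dataclass
class TargetTable:
    """miRNA -> gene target records, either predicted (with score) or validated."""

    records: pd.DataFrame  # columns: mirna, gene, score, evidence

    def __post_init__(self) -> None:
        req = {"mirna", "gene", "evidence"}
        if not req.issubset(self.records.columns):
            raise ValidationError(f"TargetTable: missing column(s) {sorted(req - set(self.records.columns))}")
        if "score" not in self.records.columns:
            self.records = self.records.assign(score=np.nan)
        bad = set(self.records["evidence"]) - {"predicted", "validated"}
        if bad:
            raise ValidationError(f"TargetTable: unknown evidence value(s) {sorted(bad)}")
        dup = self.records.duplicated(subset=["mirna", "gene", "evidence"])
        if dup.any():
            row = self.records[dup].iloc[0]
            raise ValidationError(
                f"TargetTable: duplicate ({row['mirna']}, {row['gene']}) in evidence class {row['evidence']}"
            )

    def subset(self, evidence: str) -> pd.DataFrame:
        return self.records[self.records["evidence"] == evidence]


@dataclass
class GeneSetCollection:
    """GO-style gene sets: term_id -> (term_name, frozen gene set)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"GeneSetCollection: term {term!r} has an empty gene set")
        if self.background is not None:
            stray = self.union() - self.background
            if stray:
                raise ValidationError(
                    f"GeneSetCollection: background does not cover gene(s) {sorted(stray)[:5]}"
                )

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class CytokineTable:
    """Multiplex immunoassay concentrations (analyte x sample, pg/mL or pg/mg).

    ``censored`` flags entries below the analyte's lower limit of quantitation
    (LLOQ); ``lloq`` is indexed by analyte.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    lloq: pd.Series
    unit: str = "pg/mL"
    n_imputed: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.censored.index) or not self.values.columns.equals(
            self.censored.columns
        ):
            raise ValidationError("CytokineTable: values/censored shape mismatch")
        if not self.values.index.equals(self.lloq.index):
            raise ValidationError("CytokineTable: lloq index must match analytes")
        if (self.lloq <= 0).any():
            bad = self.lloq.index[self.lloq <= 0].tolist()
            raise ValidationError(f"CytokineTable: non-positive LLOQ for analyte(s) {bad}")
        vals = self.values.to_numpy(dtype=float)
        cens = self.censored.to_numpy(dtype=bool)
        if np.any((vals < 0) & ~cens & ~np.isnan(vals)):
            r, c = np.argwhere((vals < 0) & ~cens)[0]
            raise ValidationError(
                f"CytokineTable: negative uncensored value at analyte "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )

    @property
    def analytes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Read a probe annotation table (probe_id, probe_class, length_kb)."""
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if "probe_id" not in df.columns:
        raise ValidationError(f"{path}: annotation must have a 'probe_id' column")
    df = df.set_index("probe_id")
    if "probe_class" not in df.columns:
        raise ValidationError(f"{path}: annotation must have a 'probe_class' column")
    if "length_kb" not in df.columns:
        df["length_kb"] = 1.0
    df["length_kb"] = df["length_kb"].astype(float)
    return _check_annotation(df[list(ANNOTATION_COLUMNS)], str(path))


def read_count_matrix(path, annotation_path=None, sep: str = "\t") -> CountMatrix:
    """Read a probe x sample count TSV, optionally with a probe annotation TSV.

    Probes absent from the annotation default to class ``mirna`` with length
    1.0 kb (a warning is logged), matching uniform nuclease-protection probes.
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "probe_id"
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate probe_id(s) {dupes}")
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            probe = df.index[series.isna()][0]
            raise ValidationError(f"{path}: non-numeric count at probe {probe!r}, sample {col!r}")
        if (series < 0).any():
            probe = df.index[series < 0][0]
            raise ValidationError(f"{path}: negative count at probe {probe!r}, sample {col!r}")
        if (series % 1 != 0).any():
            probe = df.index[series % 1 != 0][0]
            raise ValidationError(f"{path}: non-integer count at probe {probe!r}, sample {col!r}")
        df[col] = series.astype(np.int64)

    if annotation_path is not None:
        ann = read_annotation(annotation_path, sep=sep)
        missing = df.index.difference(ann.index)
        extra = ann.index.difference(df.index)
        if len(extra):
            raise ValidationError(
                f"{annotation_path}: annotated probe(s) {extra.tolist()[:5]} not in count matrix"
            )
        if len(missing):
            logger.warning(
                "%d probe(s) missing from annotation; defaulting to class 'mirna', length 1.0 kb",
                len(missing),
            )
            filler = pd.DataFrame(
                {"probe_class": "mirna", "length_kb": 1.0}, index=missing
            )
            ann = pd.concat([ann, filler])
        ann = ann.reindex(df.index)
    else:
        ann = pd.DataFrame({"probe_class": "mirna", "length_kb": 1.0}, index=df.index)
    return CountMatrix(df, ann)


def write_count_matrix(cm: CountMatrix, path, annotation_path=None, sep: str = "\t") -> None:
    cm.counts.to_csv(path, sep=sep, index_label="probe_id")
    if annotation_path is not None:
        cm.annotation.to_csv(annotation_path, sep=sep, index_label="probe_id")


def read_sample_sheet(path, sep: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValidationError(f"{path}: sample sheet needs 'sample_id' and 'group' columns")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path, sep: str = "\t") -> None:
    sheet.table.to_csv(path, sep=sep, index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT dialect: term, description, then genes, tab-separated."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), needs >=3")
            term, desc = fields[0], fields[1]
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ValidationError(f"{path}:{lineno}: term {term!r} lists no genes")
            if term in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = (desc, genes)
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for term, (desc, genes) in gsc.sets.items():
            handle.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_signatures(path, sep: str = "\t") -> list[SignatureTable]:
    """Read reference miRNA signatures, one study per row.

    Columns: study_id, sample_type, comparison, treatment, mirnas
    (comma-separated names).
    """
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    req = {"study_id", "mirnas"}
    if not req.issubset(df.columns):
        raise ValidationError(f"{path}: signature table needs columns {sorted(req)}")
    if df["study_id"].duplicated().any():
        dupes = df.loc[df["study_id"].duplicated(), "study_id"].tolist()
        raise ValidationError(f"{path}: duplicate study_id(s) {dupes}")
    out = []
    for _, row in df.iterrows():
        names = [n.strip() for n in row["mirnas"].split(",") if n.strip()]
        if not names:
            warnings.warn(f"{path}: study {row['study_id']!r} has an empty miRNA list", stacklevel=2)
        out.append(
            SignatureTable(
                study_id=row["study_id"],
                sample_type=row.get("sample_type", ""),
                comparison=row.get("comparison", ""),
                treatment=row.get("treatment", ""),
                mirnas=names,
            )
        )
    return out


def write_signatures(signatures: list[SignatureTable], path, sep: str = "\t") -> None:
    rows = [
        {
            "study_id": s.study_id,
            "sample_type": s.sample_type,
            "comparison": s.comparison,
            "treatment": s.treatment,
            "mirnas": ",".join(s.mirnas),
        }
        for s in signatures
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_targets(path, sep: str = "\t") -> TargetTable:
    df = pd.read_csv(path, sep=sep, dtype={"mirna": str, "gene": str, "evidence": str})
    return TargetTable(df)


def write_targets(tt: TargetTable, path, sep: str = "\t") -> None:
    tt.records.to_csv(path, sep=sep, index=False)


def read_cytokines(path, sep: str = "\t") -> CytokineTable:
    """Read an analyte x sample cytokine table.

    Layout: first column ``analyte``, second ``lloq``, remaining columns one
    per sample.  Entries below the LLOQ may be written as ``<LLOQ`` or any
    value prefixed with ``<``; they are flagged censored.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.columns[0] != "analyte" or "lloq" not in df.columns:
        raise ValidationError(f"{path}: cytokine table needs 'analyte' and 'lloq' columns")
    df = df.set_index("analyte")
    lloq = df.pop("lloq").astype(float)
    raw = df
    censored = raw.map(lambda v: isinstance(v, str) and v.strip().startswith("<"))
    values = raw.map(
        lambda v: float(str(v).strip().lstrip("<")) if str(v).strip().lstrip("<") else np.nan
    )
    values = values.where(~censored, np.nan)
    return CytokineTable(values.astype(float), censored.astype(bool), lloq)


def write_cytokines(table: CytokineTable, path, sep: str = "\t") -> None:
    out = table.values.copy().astype(object)
    for analyte in table.values.index:
        for sample in table.values.columns:
            if table.censored.at[analyte, sample]:
                out.at[analyte, sample] = f"<{table.lloq.at[analyte]}"
    out.insert(0, "lloq", table.lloq)
    out.to_csv(path, sep=sep, index_label="analyte")
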