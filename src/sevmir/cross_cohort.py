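"""miRNA name harmonization across species/studies and signature overlap.

Different cohorts report miRNA names with inconsistent species prefixes
("hsa-miR-26b-5p" vs "mmu-miR-26b-5p" vs "miR-26b-5p"), capitalisation, and
arm annotation ("miR-320a" vs "miR-320a-3p").  Harmonization lowercases the
name and strips a known species prefix, keeping the arm suffix.  Matching is
``strict`` by default — arms must agree, since merging the -5p and -3p
products of one hairpin would conflate distinct mature sequences — with a
``relaxed`` policy under which an arm-less legacy name matches either arm.
Names are matched at name level only; no sequence/accession resolution is
attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .core_io import SignatureTable, ValidationError

#: miRBase species prefixes seen in the cohorts this pipeline compares.
SPECIES_PREFIXES = (
    "hsa", "mmu", "rno", "ssc", "bta", "gga", "dre", "cel", "dme",
    "mml", "ptr", "ocu", "cfa", "eca", "oar", "chi",
)

_PREFIX_RE = re.compile(r"^(%s)-(?=\S)" % "|".join(SPECIES_PREFIXES))
_ARM_RE = re.compile(r"-(5p|3p)$")


@dataclass(frozen=True)
class HarmonizedName:
    canonical: str
    original: str
    species_prefix_removed: bool
    arm: str  # "5p", "3p" or "unspecified"

    @property
    def base(self) -> str:
        """Canonical name with the arm suffix removed."""
        return _ARM_RE.sub("", self.canonical)


def harmonize(name: str, policy: str = "strict") -> HarmonizedName:
    """Canonicalize one miRNA name (policy is validated but applied at match time)."""
    if policy not in ("strict", "relaxed"):
        raise ValidationError(f"harmonize: unknown policy {policy!r}")
    if not name or not name.strip():
        raise ValidationError("harmonize: empty miRNA name")
    canonical = name.strip().lower()
    stripped = _PREFIX_RE.sub("", canonical)
    removed = stripped != canonical
    arm_match = _ARM_RE.search(stripped)
    arm = arm_match.group(1) if arm_match else "unspecified"
    return HarmonizedName(
        canonical=stripped, original=name, species_prefix_removed=removed, arm=arm
    )


def names_match(a: HarmonizedName, b: HarmonizedName, policy: str = "strict") -> bool:
    """Equality under a harmonization policy."""
    if a.canonical == b.canonical:
        return True
    if policy == "relaxed":
        return a.base == b.base and "unspecified" in (a.arm, b.arm)
    return False


@dataclass
class OverlapMatrix:
    """Membership of harmonized query miRNAs in each reference signature.

    Rows are restricted to query miRNAs found in at least one reference;
    ``attributes`` carries each reference study's design annotations.
    """

    membership: pd.DataFrame  # canonical query name x study_id, bool
    attributes: pd.DataFrame  # study_id x (sample_type, comparison, treatment)
    policy: str = "strict"

    @property
    def column_counts(self) -> pd.Series:
        return self.membership.sum(axis=0).astype(int)

    @property
    def row_counts(self) -> pd.Series:
        return self.membership.sum(axis=1).astype(int)

    @property
    def n_any(self) -> int:
        """Query miRNAs found in at least one reference."""
        return int(len(self.membership))

    def counts(self) -> dict:
        return {
            "any_reference": self.n_any,
            **{study: int(c) for study, c in self.column_counts.items()},
        }


def overlap_matrix(
    query: list[str],
    references: list[SignatureTable],
    policy: str = "strict",
) -> OverlapMatrix:
    """Membership matrix of a DE miRNA list against reference signatures.

    Duplicate names (before or after harmonization) are collapsed, so counts
    are invariant to repeated entries on either side.
    """
    harmonized_query: dict[str, HarmonizedName] = {}
    for name in query:
        h = harmonize(name, policy)
        harmonized_query.setdefault(h.canonical, h)

    attributes = pd.DataFrame(
        {
            "sample_type": [r.sample_type for r in references],
            "comparison": [r.comparison for r in references],
            "treatment": [r.treatment for r in references],
        },
        index=[r.study_id for r in references],
    )
    if attributes.index.has_duplicates:
        raise ValidationError("overlap_matrix: duplicate study_id among references")

    columns = {}
    for ref in references:
        ref_names = [harmonize(n, policy) for n in ref.mirnas]
        hits = {}
        for canonical, h in harmonized_query.items():
            hits[canonical] = any(names_match(h, r, policy) for r in ref_names)
        columns[ref.study_id] = hits
    membership = pd.DataFrame(columns, index=list(harmonized_query), dtype=bool)
    membership = membership.loc[membership.any(axis=1)] if len(references) else membership.iloc[0:0]
    membership.index.name = "mirna"
    return OverlapMatrix(membership=membership, attributes=attributes, policy=policy)


def write_overlap_table(om: OverlapMatrix, path, sep: str = "\t") -> None:
    """Write the membership matrix in reference-table layout.

    Three attribute header rows (sample_type / comparison / treatment) under
    the study-id header, then one row per miRNA with "X" marking membership.
    """
    with open(path, "w") as handle:
        studies = list(om.membership.columns)
        handle.write(sep.join(["mirna", *studies]) + "\n")
        for attr in ("sample_type", "comparison", "treatment"):
            row = [f"#{attr}"] + [str(om.attributes.at[s, attr]) for s in studies]
            handle.write(sep.join(row) + "\n")
        for mirna, row in om.membership.iterrows():
            cells = ["X" if row[s] else "" for s in studies]
            handle.write(sep.join([str(mirna), *cells]) + "\n")


def read_overlap_table(path, sep: str = "\t") -> OverlapMatrix:
    """Read a membership table written by :func:`write_overlap_table`."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)
        studies = header[1:]
        attrs: dict[str, list[str]] = {}
        rows, index = [], []
        for line in handle:
            fields = line.rstrip("\n").split(sep)
            if fields[0].startswith("#"):
                attrs[fields[0][1:]] = fields[1 : 1 + len(studies)]
                continue
            index.append(fields[0])
            cells = fields[1:] + [""] * (len(studies) - (len(fields) - 1))
            rows.append([c == "X" for c in cells])
    membership = pd.DataFrame(rows, index=index, columns=studies, dtype=bool)
    membership.index.name = "mirna"
    attributes = pd.DataFrame(attrs, index=studies).reindex(
        columns=["sample_type", "comparison", "treatment"], fill_value=""
    )
    return OverlapMatrix(membership=membership, attributes=attributes)
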