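"""Group-wise presence calls and the two-group Venn partition.

A miRNA is *present* in a group when every QC-passed replicate of that group
has TPM at or above the threshold (default 1.0).  Presence is computed on the
full probed universe, before low-expression filtering, since the detected /
not-detected partition is a statement about the assay's whole panel.
Housekeeping and positive-control probes are excluded from the miRNA Venn
counts and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import ExpressionMatrix, SampleSheet, ValidationError


@dataclass
class PresencePartition:
    """Per-probe presence patterns over groups plus the derived set counts."""

    membership: pd.DataFrame  # probes x groups, bool (miRNA probes only)
    groups: list[str]
    presence_threshold: float = 1.0
    non_mirna_membership: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_common(self) -> int:
        return int(self.membership.all(axis=1).sum())

    def n_unique(self, group: str) -> int:
        others = [g for g in self.groups if g != group]
        return int((self.membership[group] & ~self.membership[others].any(axis=1)).sum())

    @property
    def n_absent_in_all(self) -> int:
        return int((~self.membership.any(axis=1)).sum())

    def counts(self) -> dict:
        out = {
            "n_probes": int(len(self.membership)),
            "common": self.n_common,
            "absent_in_all": self.n_absent_in_all,
        }
        for g in self.groups:
            out[f"unique_{g}"] = self.n_unique(g)
            out[f"present_{g}"] = int(self.membership[g].sum())
        return out


def presence_sets(
    em: ExpressionMatrix,
    sample_sheet: SampleSheet,
    threshold: float = 1.0,
) -> PresencePartition:
    """Call presence per group: min TPM over the group's samples >= threshold."""
    if em.unit != "tpm":
        raise ValidationError(f"presence_sets: expected unit 'tpm', got {em.unit!r}")
    sample_sheet.require_samples(em.samples)
    groups = sorted(sample_sheet.groups.loc[em.samples].unique())
    membership = {}
    for g in groups:
        samples = [s for s in em.samples if sample_sheet.groups[s] == g]
        if not samples:
            raise ValidationError(f"presence_sets: group {g!r} has no samples")
        membership[g] = (em.values[samples] >= threshold).all(axis=1)
    member = pd.DataFrame(membership)
    is_mirna = em.annotation["probe_class"] == "mirna"
    return PresencePartition(
        membership=member.loc[is_mirna],
        groups=groups,
        presence_threshold=threshold,
        non_mirna_membership=member.loc[~is_mirna],
    )


def venn_counts(partition: PresencePartition) -> tuple[int, int, int]:
    """The two-group Venn counts: (common, unique to group 1, unique to group 2).

    Group order is the partition's (sorted) group order.
    """
    if len(partition.groups) != 2:
        raise ValidationError(
            f"venn_counts: two-group partition required, got {len(partition.groups)} group(s)"
        )
    g1, g2 = partition.groups
    return partition.n_common, partition.n_unique(g1), partition.n_unique(g2)
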