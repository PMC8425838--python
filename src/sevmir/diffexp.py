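"""Housekeeping-relative fold change, permutation t tests, DE calls, and the
sample clustergram.

Model
-----
Expression is made comparable across samples by dividing every probe's TPM by
the geometric mean of the housekeeping probes in that sample ("aggregate
housekeeping" normalization); fold change between groups is then the ratio of
geometric means, computed as ``2**(mean log2 case - mean log2 control)``.

The test statistic is the Welch t on log2 housekeeping-normalized values —
with four animals per group an equal-variance assumption is not defensible.
Three permutation schemes are available:

``exhaustive``
    Per-probe enumeration of all C(n1+n2, n1) group-label assignments;
    p = #{|T*| >= |T_obs|} / C.  The identity assignment is in the
    enumeration, so p > 0 and p has granularity 1/C (1/70 at 4 vs 4).
``monte_carlo``
    B random assignments with the add-one correction
    p = (1 + #{|T*| >= |T_obs|}) / (B + 1).
``pooled``
    All C assignments are enumerated for every probe and the |T*| values of
    all probes are pooled into one common null (the approach of
    significance-analysis-of-microarrays-style tests).  Each probe's p is its
    observed |T|'s upper-tail fraction in the pool.  Pooling buys resolution
    of 1/(C x n_probes), which a per-probe exhaustive test cannot reach at
    small n: with 4 vs 4 the per-probe floor is 1/70 = 0.014, above the 0.01
    calling threshold.  ``pooled`` is therefore the pipeline default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from ._cluster import average_linkage, leaf_order, to_newick
from .assay_stats import bh_adjust
from .core_io import ExpressionMatrix, SampleSheet, ValidationError

EXHAUSTIVE_LIMIT = 20_000  # max C(n, n1) enumerated by the exhaustive scheme


@dataclass
class GroupDesign:
    """Two-group design: sample -> group label, with a named reference group."""

    labels: pd.Series  # index sample_id, values group label
    reference: str = "control"

    def __post_init__(self) -> None:
        groups = sorted(self.labels.unique())
        if len(groups) != 2:
            raise ValidationError(f"GroupDesign: exactly two groups required, got {groups}")
        if self.reference not in groups:
            raise ValidationError(f"GroupDesign: reference {self.reference!r} not in {groups}")
        for g in groups:
            if (self.labels == g).sum() < 2:
                raise ValidationError(f"GroupDesign: group {g!r} has fewer than 2 samples")

    @classmethod
    def from_sample_sheet(
        cls, sheet: SampleSheet, samples: list[str], reference: str = "control"
    ) -> "GroupDesign":
        sheet.require_samples(samples)
        return cls(sheet.groups.loc[list(samples)], reference)

    @property
    def case(self) -> str:
        return next(g for g in sorted(self.labels.unique()) if g != self.reference)

    def samples_in(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


@dataclass
class DETable:
    """Per-probe DE results sorted by permutation p, plus the thresholds used."""

    table: pd.DataFrame  # probe_id index; fold_change, p_perm, p_adj, de_call, direction
    alpha: float = 0.01
    fc_min: float = 2.0
    scheme: dict = field(default_factory=dict)

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["de_call"]]

    @property
    def n_called(self) -> int:
        return int(self.table["de_call"].sum())


@dataclass
class Clustergram:
    distances: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str
    method: str = "average"


# ---------------------------------------------------------------------------
# normalization and fold change
# ---------------------------------------------------------------------------


def housekeeping_normalize(em: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Divide each sample by the geometric mean of its housekeeping probes.

    After normalization the housekeeping aggregate equals 1 in every sample.
    A positive ``pseudocount`` is added to every value first; without one a
    zero housekeeping value is an error (its geometric mean would be zero).
    """
    if em.unit != "tpm":
        raise ValidationError(f"housekeeping_normalize: expected unit 'tpm', got {em.unit!r}")
    if pseudocount < 0:
        raise ValidationError("housekeeping_normalize: pseudocount must be >= 0")
    hk = em.probe_ids("housekeeping")
    if not hk:
        raise ValidationError("housekeeping_normalize: no housekeeping probes annotated")
    values = em.values + pseudocount
    hk_values = values.loc[hk]
    if (hk_values.to_numpy() <= 0).any():
        bad = hk_values.columns[(hk_values <= 0).any(axis=0)].tolist()
        raise ValidationError(
            f"housekeeping_normalize: zero housekeeping value in sample(s) {bad}; "
            "supply a positive pseudocount"
        )
    aggregate = np.exp(np.log(hk_values).mean(axis=0))
    out = values.div(aggregate, axis=1)
    return ExpressionMatrix(
        values=out,
        annotation=em.annotation.copy(),
        unit="hk_relative",
        pseudocount=pseudocount,
        provenance={
            **em.provenance,
            "housekeeping_set": list(hk),
            "hk_pseudocount": pseudocount,
        },
    )


def fold_change(norm_em: ExpressionMatrix, design: GroupDesign) -> pd.Series:
    """Case/control ratio of geometric means, per probe.

    Computed as ``2**(mean log2 case - mean log2 control)`` on the
    housekeeping-normalized values.
    """
    if norm_em.unit != "hk_relative":
        raise ValidationError(
            f"fold_change: expected housekeeping-normalized values, got unit {norm_em.unit!r}"
        )
    if (norm_em.values.to_numpy() <= 0).any():
        raise ValidationError(
            "fold_change: zero normalized values; use a pseudocount in housekeeping_normalize"
        )
    logv = np.log2(norm_em.values)
    case = logv[design.samples_in(design.case)].mean(axis=1)
    ctrl = logv[design.samples_in(design.reference)].mean(axis=1)
    return pd.Series(2.0 ** (case - ctrl), index=norm_em.values.index, name="fold_change")


# ---------------------------------------------------------------------------
# permutation t test
# ---------------------------------------------------------------------------


def _welch_t(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Welch t for every probe (rows of X) under every assignment (rows of masks).

    ``masks`` is (n_assignments x n_samples) boolean; True marks the case
    group.  Returns (n_probes x n_assignments).  Zero-variance assignments
    yield t = 0 when the means tie and +/-inf otherwise.
    """
    A = masks.astype(float)
    n1 = A.sum(axis=1)  # case sizes (constant across rows here)
    n0 = A.shape[1] - n1
    X2 = X**2
    s1 = X @ A.T
    s2 = X2 @ A.T
    tot = X.sum(axis=1, keepdims=True)
    tot2 = X2.sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m0 = (tot - s1) / n0
    v1 = np.maximum(s2 - n1 * m1**2, 0.0) / (n1 - 1)
    v0 = np.maximum((tot2 - s2) - n0 * m0**2, 0.0) / (n0 - 1)
    denom = np.sqrt(v1 / n1 + v0 / n0)
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom == 0, np.sign(diff) * np.inf, t)
    t = np.where((denom == 0) & (diff == 0), 0.0, t)
    return t


def _assignment_masks(
    n_samples: int, case_idx: np.ndarray, scheme: str, n_permutations: int, rng
) -> np.ndarray:
    n_case = len(case_idx)
    if scheme in ("exhaustive", "pooled"):
        total = comb(n_samples, n_case)
        if total > EXHAUSTIVE_LIMIT:
            raise ValidationError(
                f"permutation_t_test: C({n_samples},{n_case}) = {total} assignments exceed "
                f"the enumeration limit {EXHAUSTIVE_LIMIT}; use scheme='monte_carlo'"
            )
        masks = np.zeros((total, n_samples), dtype=bool)
        for i, combo in enumerate(combinations(range(n_samples), n_case)):
            masks[i, list(combo)] = True
        return masks
    if scheme == "monte_carlo":
        masks = np.zeros((n_permutations, n_samples), dtype=bool)
        for i in range(n_permutations):
            masks[i, rng.choice(n_samples, size=n_case, replace=False)] = True
        return masks
    raise ValidationError(f"permutation_t_test: unknown scheme {scheme!r}")


def permutation_t_test(
    em: ExpressionMatrix | pd.DataFrame,
    design: GroupDesign,
    scheme: str = "exhaustive",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> pd.Series:
    """Two-sided permutation p-values for a Welch t on each probe.

    ``em`` holds log-scale values (log2 of housekeeping-normalized TPM in the
    pipeline).  See the module docstring for the three schemes.
    """
    values = em.values if isinstance(em, ExpressionMatrix) else em
    samples = list(values.columns)
    if set(samples) != set(design.labels.index):
        raise ValidationError("permutation_t_test: design samples do not match matrix columns")
    case_samples = set(design.samples_in(design.case))
    case_idx = np.array([i for i, s in enumerate(samples) if s in case_samples])

    X = values.to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} probe(s) are constant across all samples; "
            "their permutation p is 1",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    masks = _assignment_masks(len(samples), case_idx, scheme, n_permutations, rng)
    T = np.abs(_welch_t(X, masks))

    obs_mask = np.zeros((1, len(samples)), dtype=bool)
    obs_mask[0, case_idx] = True
    t_obs = np.abs(_welch_t(X, obs_mask))[:, 0]
    # absorb last-ulp noise so that mirror assignments tie with the observed one
    thresh = t_obs - 1e-12 * (1.0 + t_obs)
    thresh = np.where(np.isinf(t_obs), t_obs, thresh)

    if scheme == "exhaustive":
        p = (T >= thresh[:, None]).sum(axis=1) / masks.shape[0]
    elif scheme == "monte_carlo":
        p = (1.0 + (T >= thresh[:, None]).sum(axis=1)) / (n_permutations + 1.0)
    else:  # pooled
        pool = np.sort(T.ravel())
        pool = pool[~np.isnan(pool)]
        # upper-tail count via binary search on the sorted pool
        idx = np.searchsorted(pool, thresh, side="left")
        p = (len(pool) - idx) / len(pool)
    p = np.where(constant, 1.0, p)
    return pd.Series(np.minimum(p, 1.0), index=values.index, name="p_perm")


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------


def call_differential(
    fc_map: pd.Series,
    p_map: pd.Series,
    annotation: pd.DataFrame | None = None,
    alpha: float = 0.01,
    fc_min: float = 2.0,
    call_on: str = "p_perm",
    scheme: dict | None = None,
) -> DETable:
    """Apply the significance thresholds: p < alpha and |fold change| >= fc_min.

    ``fc_min`` is applied symmetrically (fold change >= fc_min or
    <= 1/fc_min).  Benjamini-Hochberg adjusted p-values are reported for
    reference; calling uses the raw permutation p by default
    (``call_on="p_adj"`` switches to the adjusted values).  When an
    annotation is given, only mirna-class probes count toward the BH family;
    other tested probes are reported with p_adj = NaN.
    """
    if not fc_map.index.equals(p_map.index):
        raise ValidationError("call_differential: fold-change and p maps disagree on probes")
    if call_on not in ("p_perm", "p_adj"):
        raise ValidationError(f"call_differential: unknown call_on {call_on!r}")
    p_adj = pd.Series(np.nan, index=p_map.index, name="p_adj")
    if annotation is not None:
        family = annotation.index[annotation["probe_class"] == "mirna"]
        family = family.intersection(p_map.index)
    else:
        family = p_map.index
    if len(family):
        p_adj.loc[family] = bh_adjust(p_map.loc[family].tolist())

    crit = p_map if call_on == "p_perm" else p_adj
    fc_ok = (fc_map >= fc_min) | (fc_map <= 1.0 / fc_min)
    call = (crit < alpha) & fc_ok
    if call_on == "p_adj":
        call &= p_adj.notna()
    table = pd.DataFrame(
        {
            "fold_change": fc_map,
            "p_perm": p_map,
            "p_adj": p_adj,
            "de_call": call,
            "direction": np.where(fc_map >= 1.0, "up", "down"),
        }
    ).sort_values(["p_perm", "fold_change"], ascending=[True, False])
    table.index.name = "probe_id"
    return DETable(table, alpha=alpha, fc_min=fc_min, scheme=scheme or {})


# ---------------------------------------------------------------------------
# clustergram
# ---------------------------------------------------------------------------


def sample_clustergram(em: ExpressionMatrix | pd.DataFrame) -> Clustergram:
    """Average-linkage clustering of samples on 1 - Pearson correlation."""
    values = em.values if isinstance(em, ExpressionMatrix) else em
    samples = list(values.columns)
    if len(samples) < 2:
        raise ValidationError("sample_clustergram: need >=2 samples")
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [samples[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(
            f"sample_clustergram: constant sample column(s) {bad}; correlation undefined"
        )
    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = average_linkage(dist)
    order = leaf_order(Z, len(samples))
    return Clustergram(
        distances=pd.DataFrame(dist, index=samples, columns=samples),
        linkage=Z,
        leaf_order=[samples[i] for i in order],
        newick=to_newick(Z, samples),
    )
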