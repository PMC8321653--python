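"""Chromosomal-instability expression signatures (CIN25 / CIN70).

Samples are scored on a transcriptional instability signature — a set of
genes whose elevated expression tracks chromosomal instability and
functional aneuploidy (Carter et al. 2006) — and the score distributions
of deletion-stratified groups are compared with a Mann-Whitney U test.

The score of a sample is the mean z-score of the signature genes found in
the panel: the minimal monotone aggregate under which higher values
indicate higher instability. The shipped CIN25/CIN70 lists are plain-text
data files and can be replaced by any user list.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .association import ZScorePanel

ELEMENT_DELETED = "element_deleted"
NOT_DELETED = "not_deleted"

EXACT_MAX_GROUP = 7  # exact null enumeration up to this group size


@dataclass(frozen=True)
class SignatureDefinition:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene list contains duplicates")


def load_builtin_signature(name: str) -> SignatureDefinition:
    """Load a shipped signature by name ("CIN25" or "CIN70")."""
    fname = {"CIN25": "cin25.txt", "CIN70": "cin70.txt"}.get(name.upper())
    if fname is None:
        raise ValueError(f"no built-in signature named {name!r}")
    text = resources.files("fragilexpress.data").joinpath(fname).read_text()
    genes = tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    return SignatureDefinition(name=name.upper(), genes=genes)


@dataclass
class SignatureScoreTable:
    """Per-sample signature scores with deletion-stratified group labels."""

    scores: pd.Series
    groups: pd.Series
    signature: str
    n_signature_genes_found: int
    missing_genes: list[str]


def score_signature(
    zpanel: ZScorePanel,
    signature: SignatureDefinition,
    groups: Mapping[str, str],
) -> SignatureScoreTable:
    """Mean signature-gene z-score per sample.

    Signature genes absent from the panel are reported, never imputed;
    at least one must be present. ``groups`` assigns each scored sample
    its stratification label.
    """
    present = [g for g in signature.genes if g in zpanel.z.index]
    missing = [g for g in signature.genes if g not in zpanel.z.index]
    if not present:
        raise ValueError(
            f"none of the {len(signature.genes)} {signature.name} genes "
            "are present in the z-score panel"
        )
    scores = zpanel.z.loc[present].mean(axis=0)
    labels = pd.Series({s: groups[s] for s in scores.index if s in groups})
    scores = scores.loc[labels.index]
    return SignatureScoreTable(
        scores=scores,
        groups=labels,
        signature=signature.name,
        n_signature_genes_found=len(present),
        missing_genes=missing,
    )


def stratify_by_element(
    deleted: Mapping[str, bool], samples: list[str]
) -> dict[str, str]:
    """Group labels from the deletion call over the element region."""
    missing = [s for s in samples if s not in deleted]
    if missing:
        raise ValueError(f"no deletion call for samples: {missing}")
    return {
        s: (ELEMENT_DELETED if deleted[s] else NOT_DELETED) for s in samples
    }


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact Mann-Whitney by full enumeration of group labelings.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to the
    first group; handles ties through midranks. Two-sided p is the
    probability, under the permutation null, of a U at least as far from
    its mean n1*n2/2 as the observed one.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def compare_groups(
    table: SignatureScoreTable,
    group_a: str = ELEMENT_DELETED,
    group_b: str = NOT_DELETED,
) -> tuple[float, float]:
    """Mann-Whitney U test between the two score groups.

    Returns ``(U, p)`` where U is the statistic of ``group_a`` (the
    element-deleted group by default) and p is always two-sided. Groups
    with at most 7 samples each are tested against the exact permutation
    null (full enumeration, midranks for ties); larger groups use the
    tie-corrected normal approximation.
    """
    a = table.scores[table.groups == group_a].to_numpy(dtype=float)
    b = table.scores[table.groups == group_b].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"both groups must be non-empty ({group_a}: {len(a)}, "
            f"{group_b}: {len(b)})"
        )
    if max(len(a), len(b)) <= EXACT_MAX_GROUP:
        return _exact_two_sided_p(a, b)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(u), float(p)
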