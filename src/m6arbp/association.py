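"""Co-binding structure and expression-level association of RBPs.

Two views of how candidate m6A-associated RBPs relate to each other and to
the known m6A machinery:

* co-binding: cosine similarity between the binary binding profiles of RBPs
  over the m6A regions, followed by average-linkage hierarchical clustering
  on 1 - cosine distance;
* expression: Spearman rank correlation of each RBP's tissue expression
  profile with a known effector's profile, compared between the associated
  group and the remaining RBPs by a one-sided two-sample rank-sum
  (Mann-Whitney) test. The same rank-sum machinery serves the comparison of
  protein-protein interaction scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, spearmanr

from .core import BindingMatrix, ExpressionTable, InputError, ParameterError

logger = logging.getLogger(__name__)


def cosine_matrix(bm: BindingMatrix) -> pd.DataFrame:
    """Pairwise cosine similarity between RBP binding-indicator columns.

    Binary inputs give values in [0, 1]. Columns with no bound region have no
    direction: their rows/columns are NaN (flagged, not silently zero).
    """
    if len(bm.rbps) < 2:
        raise ParameterError("cosine_matrix needs >= 2 RBPs")
    X = bm.bound.astype(float)
    norms = np.linalg.norm(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (X.T @ X) / np.outer(norms, norms)
    sim[:, norms == 0] = np.nan
    sim[norms == 0, :] = np.nan
    np.fill_diagonal(sim, np.where(norms > 0, 1.0, np.nan))
    return pd.DataFrame(sim, index=list(bm.rbps), columns=list(bm.rbps))


def cluster_order(sim: pd.DataFrame) -> tuple[list[str], np.ndarray, str]:
    """Average-linkage clustering on distance 1 - cosine.

    RBPs with undefined similarity (all-NaN rows) must be dropped by the
    caller. Input columns are name-sorted before linkage so the result does
    not depend on the incoming RBP order; scipy's linkage is then
    deterministic. Returns (leaf-ordered names, linkage matrix, newick text).
    """
    if sim.isna().any().any():
        raise InputError("similarity matrix contains NaN; drop flagged RBPs first")
    names = sorted(sim.index)
    if len(names) < 2:
        raise ParameterError("clustering needs >= 2 RBPs")
    s = sim.loc[names, names].to_numpy(dtype=float)
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrise away float jitter
    Z = linkage(squareform(d, checks=False), method="average")
    order = [names[i] for i in leaves_list(Z)]
    return order, Z, _to_newick(Z, names)


def _to_newick(Z: np.ndarray, names: Sequence[str]) -> str:
    root = to_tree(Z)

    def fmt(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        return f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)}):{length:.6g}"

    return f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)});"


def spearman_to_effector(
    expr: ExpressionTable, effector: str, entities: Sequence[str]
) -> pd.Series:
    """Spearman rank correlation of each entity's tissue profile with the
    effector's profile (average ranks for ties). Constant profiles give NaN."""
    all_entities = list(expr.entities)
    if effector not in all_entities:
        raise InputError(f"effector {effector!r} not in expression table")
    missing = [e for e in entities if e not in all_entities]
    if missing:
        logger.warning("entities missing from expression table, dropped: %s", missing)
    entities = [e for e in entities if e in all_entities]
    ref = expr.profile(effector)
    out = {}
    for e in entities:
        prof = expr.profile(e)
        if np.all(prof == prof[0]) or np.all(ref == ref[0]):
            logger.warning("constant profile for %s or %s; rho undefined", e, effector)
            out[e] = np.nan
            continue
        rho = spearmanr(ref, prof).statistic
        out[e] = float(rho)
    return pd.Series(out, name=f"rho_vs_{effector}")


@dataclass
class GroupComparison:
    effector: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    alternative: str
    method: str


def compare_groups(
    vals_a: Sequence[float],
    vals_b: Sequence[float],
    alternative: str = "a_greater",
    method: str = "auto",
    effector: str = "",
) -> GroupComparison:
    """One-sided two-sample rank-sum test between two value groups.

    ``alternative`` is 'a_greater' or 'a_less' (direction of group A relative
    to group B). Exact p for small tie-free samples (<= 25 total), normal
    approximation with tie correction otherwise; ``method`` may force
    'exact' or 'asymptotic'. NaNs are removed first.
    """
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups must be non-empty after NaN removal")
    if alternative not in ("a_greater", "a_less"):
        raise ParameterError("alternative must be 'a_greater' or 'a_less'")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # complete ties: the rank-sum is at its null mean with zero variance;
        # report the symmetric no-evidence p rather than a degenerate tail
        return GroupComparison(
            effector=effector, n_a=len(a), n_b=len(b),
            statistic=len(a) * len(b) / 2.0, p_value=0.5,
            alternative=alternative, method="degenerate",
        )
    has_ties = len(np.unique(pooled)) < len(a) + len(b)
    if method == "auto":
        method = "exact" if (len(a) + len(b) <= 25 and not has_ties) else "asymptotic"
    res = mannwhitneyu(
        a, b,
        alternative="greater" if alternative == "a_greater" else "less",
        method=method,
    )
    return GroupComparison(
        effector=effector,
        n_a=len(a), n_b=len(b),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        method=method,
    )


def tissue_subset(expr: ExpressionTable, tissues: Sequence[str]) -> ExpressionTable:
    """Column-slice the table to the named tissues (entities unchanged)."""
    all_tissues = list(expr.tissues)
    unknown = [t for t in tissues if t not in all_tissues]
    if unknown:
        raise InputError(f"unknown tissues: {unknown}")
    if len(tissues) == 0:
        raise ParameterError("tissue subset must be non-empty")
    cols = [all_tissues.index(t) for t in tissues]
    return ExpressionTable(
        entities=list(expr.entities),
        tissues=list(tissues),
        values=expr.values[:, cols],
        level=expr.level,
    )


def compare_ppi_scores(
    scores: Mapping[tuple[str, str], float],
    effector: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alternative: str = "a_greater",
) -> GroupComparison:
    """Rank-sum comparison of interaction scores (effector, partner) between
    two partner groups; partners without a score are dropped and logged."""

    def pick(group: Sequence[str]) -> list[float]:
        vals, missing = [], []
        for partner in group:
            key = (effector, partner)
            if key in scores:
                vals.append(scores[key])
            else:
                missing.append(partner)
        if missing:
            logger.warning(
                "effector %s: %d partners without interaction score dropped: %s",
                effector, len(missing), missing,
            )
        return vals

    vals_a, vals_b = pick(group_a), pick(group_b)
    if not vals_a or not vals_b:
        raise ParameterError("both groups empty after dropping unscored pairs")
    return compare_groups(vals_a, vals_b, alternative=alternative, effector=effector)
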