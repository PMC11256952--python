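"""Analysis of trained models: metrics, attention maps and group statistics.

The attention matrix a fitted model applies is itself the object of study:
averaging per-sample maps for one drug gives that drug's gene–gene attention
signature, the strongest off-diagonal pairs nominate gene sets for pathway
analysis, and correlating signatures across drugs tests whether compounds
sharing a mechanism of action (MoA) induce similar interaction patterns.

Also here: differential-expression testing between predicted profiles of
high- vs low-IC50 groups, the zero-shot perturbation-distance analysis, the
responder/non-responder separation test, and a generic hypergeometric
over-representation test for user-supplied gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .network import AttentionMatrix, _as_array


# --------------------------------------------------------------------------
# regression metrics

def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error sqrt(mean((y − ŷ)²))."""
    y, yhat = np.asarray(y, dtype=np.float64), np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pcc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation coefficient between observed and predicted values."""
    y, yhat = np.asarray(y, dtype=np.float64), np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("zero variance input to Pearson correlation")
    return float(stats.pearsonr(y, yhat).statistic)


# --------------------------------------------------------------------------
# attention-map analysis

def mean_attention(maps: Sequence) -> np.ndarray:
    """Element-wise mean of per-sample attention matrices."""
    if len(maps) == 0:
        raise ValueError("empty attention-map list")
    arrays = [_as_array(m) for m in maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("attention maps differ in shape")
    return np.mean(arrays, axis=0)


@dataclass(frozen=True)
class GenePair:
    """An unordered gene pair stored with i < j in the canonical ordering."""

    gene_i: str
    gene_j: str
    score: float


@dataclass
class TopPairs:
    pairs: list[GenePair]
    genes: list[str]  # union of all genes in the pairs, canonical order


def top_gene_pairs(
    A, k: int = 1000, gene_ids: Sequence[str] | None = None
) -> TopPairs:
    """Top-k off-diagonal unordered pairs by attention score, descending.

    Ties break by (i, j) lexicographic order on canonical gene indices, so
    repeated calls are stable.  Returns the pairs plus the union gene set
    (the input for downstream over-representation analysis).
    """
    if gene_ids is None and isinstance(A, AttentionMatrix):
        gene_ids = A.gene_ids
    A = _as_array(A)
    n = A.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    iu, ju = np.triu_indices(n, 1)
    if k > iu.size:
        raise ValueError(f"k={k} exceeds the {iu.size} available pairs")
    scores = A[iu, ju]
    order = np.lexsort((ju, iu, -scores))[:k]
    pairs = [GenePair(gene_ids[iu[o]], gene_ids[ju[o]], float(scores[o])) for o in order]
    member = np.zeros(n, dtype=bool)
    member[iu[order]] = True
    member[ju[order]] = True
    genes = [gene_ids[i] for i in np.flatnonzero(member)]
    return TopPairs(pairs, genes)


def attention_correlation(A1, A2) -> float:
    """Pearson correlation of two maps over strict upper-triangle entries.

    The diagonal is excluded (self-scores would inflate agreement) and the
    lower triangle is redundant for symmetric maps.
    """
    A1, A2 = _as_array(A1), _as_array(A2)
    if A1.shape != A2.shape:
        raise ValueError("shape mismatch")
    iu = np.triu_indices(A1.shape[0], 1)
    return pcc(A1[iu], A2[iu])


@dataclass
class GroupCorrelationResult:
    within_mean: float
    between_mean: float
    median_difference: float
    pair_table: pd.DataFrame
    p_value: float  # one-sided rank-sum, within > between


def group_correlation_contrast(
    maps_by_drug: Mapping[str, np.ndarray],
    group_of: Mapping[str, str],
) -> GroupCorrelationResult:
    """Contrast attention-map correlations within vs between MoA groups.

    All drug pairs are correlated; pairs sharing a group label are "within",
    the rest "between".  Significance of within > between uses a one-sided
    Mann–Whitney rank test (pair correlations are not independent, so a rank
    test is the conservative choice).
    """
    drugs = sorted(maps_by_drug)
    if len(drugs) < 2 or len(set(group_of[d] for d in drugs)) < 2:
        raise ValueError("need at least 2 drugs in at least 2 groups")
    singletons = [
        g for g in set(group_of.values())
        if sum(group_of[d] == g for d in drugs) == 1
    ]
    if singletons:
        warnings.warn(
            f"groups with a single drug contribute no within pairs: {sorted(singletons)}",
            RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for a, b in combinations(drugs, 2):
        rows.append(
            {
                "drug_a": a,
                "drug_b": b,
                "correlation": attention_correlation(maps_by_drug[a], maps_by_drug[b]),
                "same_group": group_of[a] == group_of[b],
            }
        )
    table = pd.DataFrame(rows)
    within = table.loc[table.same_group, "correlation"].to_numpy()
    between = table.loc[~table.same_group, "correlation"].to_numpy()
    if within.size and between.size:
        p = float(stats.mannwhitneyu(within, between, alternative="greater").pvalue)
    else:
        p = float("nan")
    return GroupCorrelationResult(
        within_mean=float(within.mean()) if within.size else float("nan"),
        between_mean=float(between.mean()) if between.size else float("nan"),
        median_difference=(
            float(np.median(within) - np.median(between))
            if within.size and between.size
            else float("nan")
        ),
        pair_table=table,
        p_value=p,
    )


# --------------------------------------------------------------------------
# differential expression on predicted profiles

def deg_analysis(
    group_a: ExpressionMatrix | np.ndarray,
    group_b: ExpressionMatrix | np.ndarray,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t-test between two profile groups, BH-adjusted.

    Returns one row per gene with the mean difference (a − b), t statistic,
    raw and adjusted p, and direction ("up" = higher in group a).  Ranked
    up/down lists for enrichment come from sorting this table.
    """
    if isinstance(group_a, ExpressionMatrix):
        gene_ids = gene_ids or group_a.gene_ids
        group_a = group_a.values
    if isinstance(group_b, ExpressionMatrix):
        group_b = group_b.values
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with a shared gene axis")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(a.shape[1])]
    res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    pvals = np.nan_to_num(res.pvalue, nan=1.0)
    effect = a.mean(axis=0) - b.mean(axis=0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": list(gene_ids),
            "effect": effect,
            "t": np.nan_to_num(res.statistic, nan=0.0),
            "p": pvals,
            "p_adj": padj,
            "direction": np.where(effect > 0, "up", "down"),
        }
    )


def ranked_gene_lists(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(up, down) gene lists ranked by significance within each direction."""
    up = table[table.direction == "up"].sort_values(["p", "gene"])
    down = table[table.direction == "down"].sort_values(["p", "gene"])
    return list(up.gene), list(down.gene)


def split_by_response(
    values: Sequence[float], potent_fraction: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of (low-IC50, high-IC50) groups.

    Default split at the median; with ``potent_fraction`` (e.g. 0.25) the low
    group is the most-sensitive quantile instead.
    """
    v = np.asarray(values, dtype=np.float64)
    cut = (
        np.quantile(v, potent_fraction)
        if potent_fraction is not None
        else np.median(v)
    )
    return np.flatnonzero(v <= cut), np.flatnonzero(v > cut)


# --------------------------------------------------------------------------
# zero-shot perturbation distance and responder separation

def perturbation_distance(g0: np.ndarray, gc_pred: np.ndarray) -> float:
    """Euclidean distance between expression before and after treatment."""
    g0, gc_pred = np.asarray(g0, dtype=np.float64), np.asarray(gc_pred, dtype=np.float64)
    if g0.shape != gc_pred.shape:
        raise ValueError("length mismatch")
    return float(np.linalg.norm(gc_pred - g0))


def perturbation_distance_test(
    sensitive: Sequence[float], resistant: Sequence[float]
) -> tuple[float, float]:
    """One-sided Welch t-test that sensitive samples are perturbed farther."""
    s, r = np.asarray(sensitive, dtype=np.float64), np.asarray(resistant, dtype=np.float64)
    if s.size < 2 or r.size < 2:
        raise ValueError("need at least 2 distances per group")
    res = stats.ttest_ind(s, r, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def responder_separation_test(
    pred_ic50_responders: Sequence[float],
    pred_ic50_nonresponders: Sequence[float],
) -> tuple[float, float]:
    """One-sided Welch t-test that responders have lower predicted log IC50."""
    a = np.asarray(pred_ic50_responders, dtype=np.float64)
    b = np.asarray(pred_ic50_nonresponders, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# over-representation analysis

def hypergeometric_enrichment(
    query: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    P(overlap ≥ observed) given |query| draws from |universe| with
    |set ∩ universe| successes, BH-adjusted across sets.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene list")
    uni = set(universe)
    if not query_set <= uni:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & uni
        if not members:
            raise ValueError(f"gene set {name!r} has no members in the universe")
        overlap = len(query_set & members)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(query_set))
        )
        rows.append(
            {"set": name, "set_size": len(members), "overlap": overlap, "p": min(p, 1.0)}
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
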