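"""Enrichment, differential expression, expression grouping and ΔΔCq.

Functional-category over-representation uses the upper-tail hypergeometric
probability of observing at least k in-category genes among the foreground
draws, flagged at raw p < 0.05 (a BH-adjusted column is provided for
modern use). Differential expression between two pooled libraries (no
biological replicates) uses the exact conditional two-proportion test —
each gene's condition-A count, given the pair's sum, is binomial with
success probability libA/(libA+libB) under the null — with
Benjamini–Hochberg adjustment; a gene is a DEG at adjusted p <= 0.001 and
at least a 4-fold change of library-normalised expression (CPM). DEGs are
grouped by expression pattern (high in both vs high in one) and clustered
by average linkage. Relative qPCR quantification uses the comparative Cq
method: fold = 2^(−ΔΔCq).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # foreground genes carrying the term
    n: int  # foreground size
    K: int  # background genes carrying the term
    N: int  # background size
    p: float
    q: float  # BH-adjusted, informational
    enriched: bool  # raw p < 0.05


def hypergeom_enrich(
    fg: set[str],
    bg: set[str],
    categories: dict[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every term in the background.

    For each term, p = P(X >= k) with X ~ Hypergeom(N, K, n): N background
    genes of which K carry the term, n foreground draws, k observed.
    Terms carried only by foreground genes absent from the background are
    skipped with a warning. Results are sorted by p.
    """
    if not fg or not bg:
        raise ValueError("foreground and background must be nonempty")
    N, n = len(bg), len(fg)
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for gene in bg:
        for t in categories.get(gene, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
    for gene in fg:
        for t in categories.get(gene, ()):
            term_fg[t] = term_fg.get(t, 0) + 1
    skipped = set(term_fg) - set(term_bg)
    for t in sorted(skipped):
        warnings.warn(f"term {t} absent from background; skipped")

    terms = sorted(term_bg)
    pvals = [
        float(stats.hypergeom.sf(term_fg.get(t, 0) - 1, N, term_bg[t], n))
        for t in terms
    ]
    qvals = multipletests(pvals, method="fdr_bh")[1] if terms else []
    results = [
        EnrichmentResult(t, term_fg.get(t, 0), n, term_bg[t], N, p, float(q),
                         p < alpha)
        for t, p, q in zip(terms, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


DEG_GROUPS = ("I", "II-a", "II-b", "none")


def call_degs(
    counts: pd.DataFrame,
    lib_sizes: tuple[float, float] | None = None,
    fdr: float = 0.001,
    min_fold: float = 4.0,
) -> pd.DataFrame:
    """Exact-test differential expression between two pooled libraries.

    ``counts`` has columns ``count_a``/``count_b`` indexed by gene.
    Returns a DataFrame with CPM per condition, ``log2_fold`` (B over A,
    ±inf when one side is zero), raw ``p``, BH-adjusted ``q``, ``is_deg``
    (q <= fdr and |log2 fold| >= log2(min_fold)) and an ``all_zero`` flag
    (such genes get p = 1 and no fold change).
    """
    if (counts[["count_a", "count_b"]].to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    ca = counts["count_a"].to_numpy(dtype=float)
    cb = counts["count_b"].to_numpy(dtype=float)
    if lib_sizes is None:
        lib_sizes = (float(ca.sum()), float(cb.sum()))
    la, lb = lib_sizes
    if la <= 0 or lb <= 0:
        raise ValueError("library sizes must be positive")

    cpm_a = ca / la * 1e6
    cpm_b = cb / lb * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fold = np.log2(cpm_b) - np.log2(cpm_a)

    p0 = la / (la + lb)
    pvals = np.ones(len(ca))
    all_zero = (ca + cb) == 0
    for i in range(len(ca)):
        if all_zero[i]:
            continue
        pvals[i] = stats.binomtest(int(ca[i]), int(ca[i] + cb[i]), p0).pvalue
    q = multipletests(pvals, method="fdr_bh")[1]

    abs_fold = np.abs(log2_fold)
    abs_fold[all_zero] = np.nan
    is_deg = (q <= fdr) & ~all_zero & (abs_fold >= math.log2(min_fold))
    return pd.DataFrame(
        {
            "cpm_a": cpm_a, "cpm_b": cpm_b, "log2_fold": log2_fold,
            "p": pvals, "q": q, "is_deg": is_deg, "all_zero": all_zero,
        },
        index=counts.index,
    )


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    for k, (l, r, h, _) in enumerate(Z):
        heights[n + k] = float(h)

    def rec(i: int) -> str:
        if i < n:
            return labels[i]
        l, r, h, _ = Z[i - n]
        return (f"({rec(int(l))}:{h - heights[int(l)]:.6g},"
                f"{rec(int(r))}:{h - heights[int(r)]:.6g})")

    return rec(n + len(Z) - 1) + ";"


def group_degs(
    degs: pd.DataFrame,
    high_threshold: float = 100.0,
) -> tuple[pd.DataFrame, str]:
    """Pattern grouping and average-linkage clustering of DEGs.

    Group I: CPM above ``high_threshold`` in both conditions (high in both,
    differing in degree). Group II-a: high in condition A only; II-b: high
    in condition B only; DEGs high in neither are ``none``. Clustering runs
    on log2(CPM+1) profiles; the dendrogram is returned as a newick string
    and the leaf order as a ``dendrogram_order`` column.
    """
    deg = degs[degs["is_deg"]].copy()
    if deg.empty:
        raise ValueError("no DEGs to group")
    high_a = deg["cpm_a"] > high_threshold
    high_b = deg["cpm_b"] > high_threshold
    deg["group"] = np.select(
        [high_a & high_b, high_a & ~high_b, ~high_a & high_b],
        ["I", "II-a", "II-b"],
        default="none",
    )
    labels = [str(g) for g in deg.index]
    if len(deg) == 1:
        newick = f"({labels[0]});"
        order = [0]
    else:
        profiles = np.log2(deg[["cpm_a", "cpm_b"]].to_numpy() + 1.0)
        Z = hierarchy.linkage(profiles, method="average")
        newick = _linkage_to_newick(Z, labels)
        order = hierarchy.leaves_list(Z).tolist()
    deg["dendrogram_order"] = pd.Series(
        {labels[i]: rank for rank, i in enumerate(order)}
    ).reindex(labels).to_numpy()
    return deg, newick


def ddcq(measurements: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Comparative Cq (2^−ΔΔCq) relative quantification with a per-gene test.

    ``measurements`` has replicate rows (gene, group, cq_target,
    cq_reference). Per replicate ΔCq = Cq_target − Cq_reference; per gene
    and group, ΔΔCq = mean ΔCq(group) − mean ΔCq(calibrator) and
    fold = 2^(−ΔΔCq), so the calibrator group's fold is 1 by construction.
    For two-group designs a two-sided t statistic compares the ΔCq
    replicates of the non-calibrator group against the calibrator.
    """
    required = {"gene", "group", "cq_target", "cq_reference"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    df = measurements.copy()
    for gene, sub in df.groupby("gene"):
        if sub["cq_reference"].isna().any():
            raise ValueError(f"missing reference Cq for gene {gene}")
        if sub["cq_target"].isna().any():
            raise ValueError(f"missing target Cq for gene {gene}")
        if calibrator not in set(sub["group"]):
            raise ValueError(f"gene {gene} has no calibrator group "
                             f"'{calibrator}' measurements")
    df["dcq"] = df["cq_target"] - df["cq_reference"]

    rows = []
    for (gene, group), sub in df.groupby(["gene", "group"]):
        cal = df[(df["gene"] == gene) & (df["group"] == calibrator)]["dcq"]
        ddcq_val = sub["dcq"].mean() - cal.mean()
        if group == calibrator:
            t_stat, p = math.nan, math.nan
        elif len(sub) > 1 and len(cal) > 1:
            t_stat, p = stats.ttest_ind(sub["dcq"], cal)
        else:
            t_stat, p = math.nan, math.nan
        rows.append({
            "gene": gene, "group": group, "n_replicates": len(sub),
            "mean_dcq": sub["dcq"].mean(), "ddcq": ddcq_val,
            "fold": 2.0 ** (-ddcq_val), "t_stat": t_stat, "p": p,
        })
    return pd.DataFrame(rows)
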