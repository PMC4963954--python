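"""Expression-side statistics linking chromatin and methylation to
transcription.

The paired Wilcoxon signed-rank test compares per-gene expression between
two conditions (e.g. all genes vs. genes near cell-type-specific active
enhancers).  The exact null distribution is computed for small samples by
sign-flip enumeration over the rank sum; larger samples use the normal
approximation with tie and continuity corrections.

Differential expression between two libraries without replicates is tested
per gene with a two-sided exact binomial on the first library's count out of
the pooled count, with the null proportion set to the first library's share
of total depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylation import bh_adjust


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (e.g. all paired
    differences are zero)."""


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    statistic: float
    p_value: float
    test_name: str
    n: int
    summary: dict = field(default_factory=dict)


@dataclass
class ExpressionTable:
    """Genes x conditions expression (FPKM, optionally raw counts)."""

    genes: list[str]
    conditions: list[str]
    fpkm: np.ndarray
    counts: Optional[np.ndarray] = None

    def __post_init__(self):
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.genes), len(self.conditions)):
            raise ValueError("FPKM matrix shape does not match genes x conditions")
        if not np.all(np.isfinite(self.fpkm)) or np.any(self.fpkm < 0):
            raise ValueError("FPKM must be finite and non-negative")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.fpkm.shape:
                raise ValueError("counts shape does not match FPKM")

    def column(self, condition: str, genes: Optional[Sequence[str]] = None,
               counts: bool = False) -> np.ndarray:
        j = self.conditions.index(condition)
        mat = self.counts if counts else self.fpkm
        if genes is None:
            return mat[:, j]
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in genes]
        return mat[rows, j]

    @classmethod
    def read_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        fpkm_cols = [c for c in df.columns if not c.endswith("_count")]
        count_cols = [c + "_count" for c in fpkm_cols
                      if c + "_count" in df.columns]
        counts = df[count_cols].to_numpy() if len(count_cols) == len(fpkm_cols) \
            else None
        return cls(list(df.index), fpkm_cols, df[fpkm_cols].to_numpy(), counts)

    def write_tsv(self, path) -> None:
        data = {c: self.fpkm[:, j] for j, c in enumerate(self.conditions)}
        if self.counts is not None:
            for j, c in enumerate(self.conditions):
                data[c + "_count"] = self.counts[:, j]
        df = pd.DataFrame(data, index=pd.Index(self.genes, name="gene_id"))
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, float]:
    """Average ranks of |d| and the positive rank sum W+."""
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    return ranks, w_plus


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p under the sign-flip null.

    Works on doubled ranks (integers even with midrank ties) and counts the
    probability of a rank sum at least as far from the null mean as
    observed, via dynamic programming over the 2^n sign assignments.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    counts /= 2.0 ** len(r2)
    mu = total / 2.0
    dev = abs(2 * w_plus - mu)
    sums = np.arange(total + 1)
    return float(counts[np.abs(sums - mu) >= dev - 1e-9].sum())


def paired_wilcoxon(
    x: Sequence[float],
    y: Sequence[float],
    exact_threshold: int = 25,
) -> GroupComparison:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (standard Wilcoxon convention).  With at
    most ``exact_threshold`` non-zero pairs the null distribution is exact
    (sign-flip enumeration, midranks for ties); beyond that the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = x - y
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks, w_plus = _signed_ranks(diffs)
    if n <= exact_threshold:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        delta = w_plus - mu
        z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
        method = "normal_approx"
    return GroupComparison(
        group_labels=("x", "y"),
        statistic=w_plus,
        p_value=p,
        test_name=f"wilcoxon_signed_rank_{method}",
        n=n,
    )


def class_expression_comparison(
    expr: ExpressionTable,
    gene_sets: dict[str, Sequence[str]],
    cond_a: str,
    cond_b: str,
) -> list[GroupComparison]:
    """Paired Wilcoxon of per-gene FPKM between two conditions, per gene
    class, with an ``all_genes`` baseline always included.

    Classes with no genes in the table, or with all-zero differences, are
    reported with a nan p-value and a note instead of being dropped.
    """
    sets = {"all_genes": list(expr.genes)}
    for name, genes in gene_sets.items():
        sets[name] = [g for g in genes if g in set(expr.genes)]
    out = []
    for name, genes in sets.items():
        if not genes:
            out.append(GroupComparison(
                (cond_a, cond_b), float("nan"), float("nan"),
                "skipped_empty_class", 0, {"class": name}))
            continue
        a = expr.column(cond_a, genes)
        b = expr.column(cond_b, genes)
        summary = {
            "class": name,
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "q1_a": float(np.percentile(a, 25)),
            "q3_a": float(np.percentile(a, 75)),
            "q1_b": float(np.percentile(b, 25)),
            "q3_b": float(np.percentile(b, 75)),
        }
        try:
            cmp = paired_wilcoxon(a, b)
        except DegenerateTestError:
            out.append(GroupComparison(
                (cond_a, cond_b), float("nan"), float("nan"),
                "degenerate_all_zero_differences", len(genes), summary))
            continue
        cmp.group_labels = (cond_a, cond_b)
        cmp.summary = summary
        out.append(cmp)
    return out


# ---------------------------------------------------------------------------
# Two-library differential expression
# ---------------------------------------------------------------------------

def _binom_two_sided(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Vectorised two-sided exact binomial p (minimum-likelihood rule, as in
    the classical exact binomial test)."""
    out = np.ones(len(k))
    for i, (ki, ni) in enumerate(zip(k, n)):
        if ni == 0:
            continue
        support = np.arange(ni + 1)
        pmf = stats.binom.pmf(support, ni, p0)
        thresh = pmf[ki] * (1 + 1e-7)
        out[i] = float(pmf[pmf <= thresh].sum())
    return np.minimum(out, 1.0)


def two_library_de(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene differential expression between two count libraries.

    For gene *i* with counts ``(a_i, b_i)`` and library depths
    ``(N_a, N_b)``, the two-sided exact binomial tests ``a_i`` out of
    ``a_i + b_i`` against the null proportion ``N_a / (N_a + N_b)``.
    q-values are BH-adjusted; the fold change is depth-normalised with a
    pseudocount, and direction is ``a_up``/``b_up`` by that fold change.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    n_a, n_b = int(a.sum()), int(b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both libraries need positive total counts")
    share = n_a / (n_a + n_b)
    p = _binom_two_sided(a, a + b, share)
    q = bh_adjust(p)
    fold = ((a + pseudocount) / n_a) / ((b + pseudocount) / n_b)
    direction = np.where(fold > 1, "a_up", np.where(fold < 1, "b_up", "none"))
    index = pd.Index(
        genes if genes is not None else range(len(a)), name="gene_id"
    )
    return pd.DataFrame(
        {
            "count_a": a,
            "count_b": b,
            "fold_change": fold,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "significant": p < alpha,
        },
        index=index,
    )
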