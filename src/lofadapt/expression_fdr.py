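"""Differential-expression calling with a replicate half-difference null.

Each mutant-vs-parent contrast contributes two biological-replicate log2
ratios per gene.  Genes are called changed when the replicate average
crosses a fold-change threshold (default 2-fold, i.e. |mean log2| >= 1).

The false-discovery estimate uses the half-difference trick: for iid
replicate noise with sd sigma, (r1 - r2)/2 has mean zero and the same sd
(sigma/sqrt(2)) as the replicate average, so pooling half-differences over
all contrasts yields an empirical null for the averaged statistic.  The
expected false-positive count is the null exceedance rate scaled to the
contrast's gene count; FDR = expected FP / number called.

Overlap between two differentially expressed gene sets is scored with the
upper-tail hypergeometric probability, Bonferroni-adjusted for the number
of comparisons made.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionComparison",
    "DECallSet",
    "call_de",
    "estimate_fdr",
    "overlap_significance",
]


@dataclass
class ExpressionComparison:
    """Per-gene log2 ratios (mutant vs parent) in two biological replicates."""

    log_ratios: pd.DataFrame  # genes x 2 replicate columns
    condition: str = ""

    def __post_init__(self) -> None:
        if self.log_ratios.shape[1] != 2:
            raise ValueError("exactly 2 replicate columns are required")
        if not np.all(np.isfinite(self.log_ratios.to_numpy())):
            raise ValueError("log ratios must be finite")

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str = "") -> "ExpressionComparison":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.iloc[:, :2], condition=condition or Path(path).stem)


@dataclass
class DECallSet:
    """Up/down/unchanged partition of one contrast with its null sample."""

    up: pd.Index
    down: pd.Index
    unchanged: pd.Index
    half_differences: np.ndarray
    log2_threshold: float
    condition: str = ""
    fdr: float | None = None

    @property
    def n_genes(self) -> int:
        return len(self.up) + len(self.down) + len(self.unchanged)

    @property
    def n_called(self) -> int:
        return len(self.up) + len(self.down)


def call_de(expr: ExpressionComparison, fold_threshold: float = 2.0) -> DECallSet:
    """Classify genes by replicate-average fold change.

    ``fold_threshold`` is on the fold scale (>1); a gene is up when its
    average log2 ratio is >= log2(threshold), down when <= -log2(threshold)
    (boundary values count as called).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1 (fold scale)")
    t = float(np.log2(fold_threshold))
    vals = expr.log_ratios.to_numpy()
    avg = vals.mean(axis=1)
    up = avg >= t
    down = avg <= -t
    genes = expr.log_ratios.index
    return DECallSet(
        up=genes[up],
        down=genes[down],
        unchanged=genes[~(up | down)],
        half_differences=(vals[:, 0] - vals[:, 1]) / 2.0,
        log2_threshold=t,
        condition=expr.condition,
    )


def estimate_fdr(callsets: Sequence[DECallSet], pool: bool = True) -> list[DECallSet]:
    """Estimate each callset's FDR from the (pooled) half-difference null.

    The null is the half-differences pooled over all callsets (or per
    callset when ``pool`` is False).  Expected false positives for a
    callset = #{|null| > threshold} x n_genes/n_null; FDR = expected FP /
    #called, capped at 1, and None when nothing was called.
    """
    if not callsets:
        raise ValueError("at least one callset is required")
    pooled = np.concatenate([c.half_differences for c in callsets])
    if pooled.size == 0:
        raise ValueError("empty null sample")
    out = []
    for c in callsets:
        null = pooled if pool else c.half_differences
        exceed = int(np.sum(np.abs(null) > c.log2_threshold))
        expected_fp = exceed * c.n_genes / null.size
        fdr = None if c.n_called == 0 else min(expected_fp / c.n_called, 1.0)
        out.append(
            DECallSet(
                up=c.up,
                down=c.down,
                unchanged=c.unchanged,
                half_differences=c.half_differences,
                log2_threshold=c.log2_threshold,
                condition=c.condition,
                fdr=fdr,
            )
        )
    return out


def overlap_significance(
    set_a: set[str] | Sequence[str],
    set_b: set[str] | Sequence[str],
    universe: int,
    n_comparisons: int = 1,
) -> tuple[float, float]:
    """Upper-tail hypergeometric probability of observing at least the
    given overlap between two gene sets drawn from a common universe,
    with a Bonferroni-adjusted companion value."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe or len(b) > universe:
        raise ValueError("set sizes exceed the universe")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    k = len(a & b)
    # P(overlap >= k) for drawing |a| marked and |b| sampled from universe
    p = float(stats.hypergeom.sf(k - 1, universe, len(a), len(b)))
    return p, min(1.0, p * n_comparisons)
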