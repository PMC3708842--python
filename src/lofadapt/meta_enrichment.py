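"""Meta-analysis of null-mutation fitness calls across many conditions.

Given per-condition sets of genes whose loss-of-function alleles were
significantly beneficial or deleterious, together with coarse functional
class labels (enzyme, regulator, membrane, ...), this module asks whether
particular functional classes contribute more calls than expected.

The enrichment test is a binomial resampling: under the null each tested
gene in a condition is "called" independently with that condition's
overall call rate, the per-class summary statistic is the total number of
calls summed over all conditions, and the one-tailed p-value is the
fraction of simulated draws at or above the observed total.  Benjamini-
Hochberg is applied across classes, separately per direction.

Also provided: a pooled |z| cutoff for calling significance from z-score
screens under a standard-normal null, probe-resampling p-values for
single-replicate probe-level data, recurrence tallies, per-class
condition-fraction summaries, and a first-principles estimate of the rate
at which null alleles arise by nonsense mutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConditionCallTable",
    "ClassEnrichmentResult",
    "call_from_zscores",
    "probe_resampling_pvalue",
    "resample_class_enrichment",
    "class_condition_fractions",
    "recurrent_beneficial_genes",
    "null_allele_rate",
    "stop_gain_probability",
]

UNCLASSIFIED = "unclassified"


@dataclass
class ConditionCallTable:
    """Per-condition significance call sets with functional class labels.

    ``tested``, ``beneficial`` and ``deleterious`` map condition ->
    gene set; beneficial and deleterious are disjoint subsets of tested.
    ``class_labels`` maps gene -> functional class (missing genes are
    treated as "unclassified").
    """

    conditions: list[str]
    tested: dict[str, set[str]]
    beneficial: dict[str, set[str]]
    deleterious: dict[str, set[str]]
    class_labels: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.conditions:
            b, d, t = self.beneficial[c], self.deleterious[c], self.tested[c]
            if b & d:
                raise ValueError(f"beneficial and deleterious overlap in {c!r}")
            if not b <= t or not d <= t:
                raise ValueError(f"call sets must be subsets of tested set in {c!r}")

    def label(self, gene: str) -> str:
        return self.class_labels.get(gene, UNCLASSIFIED)

    @property
    def classes(self) -> list[str]:
        seen = {self.label(g) for t in self.tested.values() for g in t}
        return sorted(seen)

    def calls(self, direction: str) -> dict[str, set[str]]:
        if direction == "beneficial":
            return self.beneficial
        if direction == "deleterious":
            return self.deleterious
        raise ValueError("direction must be 'beneficial' or 'deleterious'")

    def drop_genes(self, gene_ids: Iterable[str]) -> "ConditionCallTable":
        """Remove genes (e.g. essentials) from every set before tallying."""
        drop = set(gene_ids)
        return ConditionCallTable(
            conditions=list(self.conditions),
            tested={c: s - drop for c, s in self.tested.items()},
            beneficial={c: s - drop for c, s in self.beneficial.items()},
            deleterious={c: s - drop for c, s in self.deleterious.items()},
            class_labels={g: l for g, l in self.class_labels.items() if g not in drop},
            provenance=dict(self.provenance),
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for c in self.conditions:
            for g in sorted(self.tested[c]):
                if g in self.beneficial[c]:
                    d = "beneficial"
                elif g in self.deleterious[c]:
                    d = "deleterious"
                else:
                    d = "ns"
                rows.append((c, g, d, self.label(g)))
        pd.DataFrame(rows, columns=["condition", "gene", "direction", "class"]).to_csv(
            path, sep="\t", index=False
        )


def read_call_table(path: str | Path, class_labels: Mapping[str, str] | None = None) -> ConditionCallTable:
    """Read per-condition call lists (columns condition, gene, direction[, class])."""
    df = pd.read_csv(path, sep="\t")
    conditions = list(dict.fromkeys(df["condition"]))
    tested = {c: set() for c in conditions}
    ben = {c: set() for c in conditions}
    dele = {c: set() for c in conditions}
    labels: dict[str, str] = dict(class_labels or {})
    for row in df.itertuples(index=False):
        tested[row.condition].add(row.gene)
        if row.direction == "beneficial":
            ben[row.condition].add(row.gene)
        elif row.direction == "deleterious":
            dele[row.condition].add(row.gene)
        if hasattr(row, "class") and class_labels is None:
            labels[row.gene] = getattr(row, "class")
    return ConditionCallTable(conditions, tested, ben, dele, labels)


@dataclass
class ClassEnrichmentResult:
    """Resampling enrichment outcome for one direction.

    ``table`` is indexed by class with columns ``observed, p, q,
    testable``; p is floored at 1/(n_draws+1).
    """

    direction: str
    table: pd.DataFrame
    n_draws: int
    seed: int

    def significant_classes(self, q_threshold: float = 0.01) -> list[str]:
        t = self.table
        return list(t.index[t["testable"] & (t["q"] < q_threshold)])


# ---------------------------------------------------------------------------
# calling from z-score screens
# ---------------------------------------------------------------------------

def call_from_zscores(
    z: pd.DataFrame,
    target_fdr: float = 0.05,
    class_labels: Mapping[str, str] | None = None,
) -> ConditionCallTable:
    """Call beneficial/deleterious entries from a gene x condition z-score
    matrix under a standard-normal null.

    One |z| cutoff c is chosen over the pooled matrix: the smallest
    observed |z| such that the plug-in estimate
    ``2*(1-Phi(c)) * N_total / #{|z| >= c}`` is at or below target_fdr.
    Entries with z >= c are beneficial, z <= -c deleterious.
    """
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must lie in (0, 1)")
    vals = z.to_numpy(dtype=float)
    present = np.isfinite(vals)
    absz = np.abs(vals[present])
    n_total = absz.size

    order = np.sort(absz)
    # at candidate c = order[i], #{|z| >= c} = n_total - i
    expected_fp = 2.0 * stats.norm.sf(order) * n_total
    counts = n_total - np.arange(n_total)
    est = expected_fp / counts
    ok = np.nonzero(est <= target_fdr)[0]
    if ok.size == 0:
        import warnings

        warnings.warn("no attainable z cutoff at requested FDR; no calls made", stacklevel=2)
        cutoff = np.inf
    else:
        cutoff = float(order[ok[0]])

    conditions = list(z.columns.astype(str))
    tested = {c: set(z.index[np.isfinite(z[c].to_numpy(dtype=float))].astype(str)) for c in z.columns}
    ben = {}
    dele = {}
    for c in z.columns:
        col = z[c].astype(float)
        ben[str(c)] = set(col.index[col >= cutoff].astype(str))
        dele[str(c)] = set(col.index[col <= -cutoff].astype(str))
    tested = {str(c): tested[c] for c in z.columns}
    table = ConditionCallTable(conditions, tested, ben, dele, dict(class_labels or {}))
    table.provenance["z_cutoff"] = f"{cutoff:.6g}"
    return table


def probe_resampling_pvalue(
    gene_probe_scores: Sequence[float],
    all_probe_scores: Sequence[float],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> float:
    """Resampling p-value for a gene's mean probe score against the
    genome-wide probe distribution.

    Same-size probe sets are resampled from the pool; the p-value is the
    fraction of resampled means at least as far from the pool mean as the
    observed mean (two-sided by magnitude), with an add-one floor.
    """
    gene = np.asarray(gene_probe_scores, dtype=float)
    pool = np.asarray(all_probe_scores, dtype=float)
    if gene.size == 0 or pool.size == 0:
        raise ValueError("gene and pool score sets must be nonempty")
    if gene.size > pool.size:
        raise ValueError("gene probe set larger than the pool")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(n_resamples, gene.size), replace=True)
    centre = pool.mean()
    observed = abs(gene.mean() - centre)
    extreme = np.abs(draws.mean(axis=1) - centre) >= observed
    return float((1 + extreme.sum()) / (n_resamples + 1))


# ---------------------------------------------------------------------------
# class enrichment by binomial resampling
# ---------------------------------------------------------------------------

def resample_class_enrichment(
    calls: ConditionCallTable,
    direction: str,
    n_draws: int = 10_000,
    seed: int = 0,
    fdr: float = 0.01,
) -> ClassEnrichmentResult:
    """Binomial-resampling test for per-class excess of calls.

    For each class x condition the null simulates
    ``Binomial(n_class_tested, p_condition)`` where p_condition is the
    condition's average per-gene call probability; per-class totals are
    summed over conditions, and the one-tailed p-value is the fraction of
    draws >= the observed class total.  BH q-values are computed across
    testable classes.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    call_sets = calls.calls(direction)
    classes = calls.classes
    rng = np.random.default_rng(seed)

    observed = {k: 0 for k in classes}
    n_tested = {k: [] for k in classes}  # per condition
    p_cond = []
    for c in calls.conditions:
        tested = calls.tested[c]
        if len(tested) == 0:
            p_cond.append(0.0)
            for k in classes:
                n_tested[k].append(0)
            continue
        p_cond.append(len(call_sets[c]) / len(tested))
        by_class: dict[str, int] = {k: 0 for k in classes}
        for g in tested:
            by_class[calls.label(g)] += 1
        for k in classes:
            n_tested[k].append(by_class[k])
        for g in call_sets[c]:
            observed[calls.label(g)] += 1

    p_cond_arr = np.asarray(p_cond)
    rows = []
    pvals = []
    testable_classes = []
    for k in classes:
        n_arr = np.asarray(n_tested[k])
        testable = bool(n_arr.sum() > 0)
        if testable:
            sims = rng.binomial(n_arr[None, :], p_cond_arr[None, :], size=(n_draws, len(n_arr)))
            totals = sims.sum(axis=1)
            p = max(float((totals >= observed[k]).mean()), 1.0 / (n_draws + 1))
        else:
            p = 1.0
        rows.append((k, observed[k], p, testable))
        if testable:
            pvals.append(p)
            testable_classes.append(k)

    table = pd.DataFrame(rows, columns=["class", "observed", "p", "testable"]).set_index("class")
    table["q"] = np.nan
    if pvals:
        _, q, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        table.loc[testable_classes, "q"] = q
    return ClassEnrichmentResult(direction=direction, table=table, n_draws=n_draws, seed=seed)


def class_condition_fractions(
    calls: ConditionCallTable,
    thresholds: Sequence[float] = (0.05, 0.25, 0.50, 0.75),
    direction: str = "beneficial",
) -> pd.DataFrame:
    """Fraction of each class's members called in at least t*n_conditions
    conditions, for each threshold t."""
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
    call_sets = calls.calls(direction)
    n_cond = len(calls.conditions)
    counts: dict[str, int] = {}
    members: dict[str, set[str]] = {}
    for c in calls.conditions:
        for g in calls.tested[c]:
            members.setdefault(calls.label(g), set()).add(g)
        for g in call_sets[c]:
            counts[g] = counts.get(g, 0) + 1
    out = {}
    for k, genes in sorted(members.items()):
        row = []
        for t in thresholds:
            need = t * n_cond
            row.append(sum(counts.get(g, 0) >= need for g in genes) / len(genes))
        out[k] = row
    return pd.DataFrame.from_dict(out, orient="index", columns=[f">= {t:g}" for t in thresholds])


def recurrent_beneficial_genes(
    calls: ConditionCallTable, min_conditions: int = 10
) -> pd.DataFrame:
    """Genes beneficial in at least ``min_conditions`` conditions, sorted
    by count descending (ties by gene id)."""
    if min_conditions < 1:
        raise ValueError("min_conditions must be >= 1")
    counts: dict[str, int] = {}
    for c in calls.conditions:
        for g in calls.beneficial[c]:
            counts[g] = counts.get(g, 0) + 1
    rows = [
        (g, n, calls.label(g))
        for g, n in counts.items()
        if n >= min_conditions
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene", "n_conditions", "class"]).set_index("gene")


# ---------------------------------------------------------------------------
# null-allele rate
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_STOPS = {"TAA", "TAG", "TGA"}


def _sense_codons() -> list[str]:
    return [
        "".join(c)
        for c in itertools.product(_BASES, repeat=3)
        if "".join(c) not in _STOPS
    ]


def stop_gain_probability(codon_weights: Mapping[str, float] | None = None) -> float:
    """Probability that a random single-nucleotide substitution in a random
    sense codon creates a stop codon, by exhaustive enumeration of all
    codon x position x substitution outcomes.

    ``codon_weights`` optionally re-weights codon usage (default uniform
    over the 61 sense codons).
    """
    codons = _sense_codons()
    if codon_weights is None:
        weights = {c: 1.0 for c in codons}
    else:
        weights = {c: float(w) for c, w in codon_weights.items() if c not in _STOPS}
        if not weights:
            return 0.0
    total_w = sum(weights.values())
    p = 0.0
    for codon, w in weights.items():
        hits = 0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1:]
                if mutant in _STOPS:
                    hits += 1
        p += (w / total_w) * hits / 9.0
    return p


def null_allele_rate(
    per_nt_rate: float = 1e-10,
    orf_length: float = 1000.0,
    considered_fraction: float = 0.5,
    codon_weights: Mapping[str, float] | None = None,
) -> float:
    """Rate of nonsense (premature-stop) null alleles per gene per division.

    Computed as per-nucleotide mutation rate x ORF length x fraction of
    the ORF where a stop is assumed to abolish function x probability that
    a random point mutation in a random sense codon creates a stop (by
    exhaustive enumeration; 23 of the 549 possible single-nucleotide
    substitutions in the 61 sense codons create stops under uniform usage).
    """
    if per_nt_rate < 0 or orf_length < 0 or considered_fraction < 0:
        raise ValueError("rate inputs must be non-negative")
    return per_nt_rate * orf_length * considered_fraction * stop_gain_probability(codon_weights)
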