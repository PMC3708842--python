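"""Significance calling for transposon-footprint fitness selections.

A transposon-footprint experiment compares the abundance of insertion
mutants at each locus before and after competitive growth.  The raw data
are per-gene ratios of transposon signal to genomic-DNA signal on a set of
arrays: several *reference* hybridizations of the unselected library and,
per growth condition, a few *selected* replicate hybridizations.

The pipeline implemented here:

1. :func:`normalize` — sum-normalize each array on the ratio scale, take
   log2, and remove intensity-dependent bias by loess regression of each
   array on the mean of the reference arrays.
2. :func:`summarize_gene` — the sign-concordant minimum: the replicate
   value closest to zero when all replicates agree in sign, else zero.
3. :func:`build_null` — a simulated null of pseudo-genes whose replicate
   values are heavy-tailed (Student t) draws scaled to the replicate
   standard deviation of a randomly chosen real gene and centred on the
   median reference residual of an independently chosen gene.
4. :func:`p_values` — empirical two-sided p-values against the null.
5. :func:`call_significant` — per-condition plug-in FDR thresholding.

Essential genes, for which insertions cannot be recovered, are removed
before testing with :func:`exclude_essentials`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger("lofadapt")

REF_ROLE = "ref"
SEL_ROLE = "sel"

__all__ = [
    "FootprintDataset",
    "NormalizedDataset",
    "NullSummaryModel",
    "SignificanceCalls",
    "read_footprint_tsv",
    "normalize",
    "summarize_gene",
    "summarize_condition",
    "build_null",
    "p_values",
    "null_calibration_ks",
    "call_significant",
    "exclude_essentials",
    "run_footprint_pipeline",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FootprintDataset:
    """Gene x array matrix of transposon/genomic signal ratios.

    ``values`` has one row per gene and a 3-level column MultiIndex
    ``(role, condition, replicate)`` with role ``"ref"`` (pre-selection)
    or ``"sel"`` (post-selection in a named condition).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.nlevels != 3:
            raise ValueError("expected (role, condition, replicate) column index")
        roles = cols.get_level_values(0)
        bad = set(roles) - {REF_ROLE, SEL_ROLE}
        if bad:
            raise ValueError(f"unknown array roles: {sorted(bad)}")
        if (roles == REF_ROLE).sum() < 1:
            raise ValueError("at least one reference array is required")
        if not np.all(self.values.to_numpy() > 0):
            raise ValueError("ratio values must be strictly positive")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_reference(self) -> int:
        return int((self.values.columns.get_level_values(0) == REF_ROLE).sum())

    @property
    def conditions(self) -> list[str]:
        sel = self.values.columns[self.values.columns.get_level_values(0) == SEL_ROLE]
        return list(dict.fromkeys(sel.get_level_values(1)))

    def replicates(self, condition: str) -> int:
        cols = self.values.columns
        mask = (cols.get_level_values(0) == SEL_ROLE) & (
            cols.get_level_values(1) == condition
        )
        return int(mask.sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.columns = [f"{r}:{c}:{k}" for r, c, k in out.columns]
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def read_footprint_tsv(path: str | Path) -> FootprintDataset:
    """Read the tabular footprint format (header ``role:condition:replicate``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    parts = [tuple(c.split(":")) for c in df.columns]
    if any(len(p) != 3 for p in parts):
        raise ValueError("array columns must be named role:condition:replicate")
    df.columns = pd.MultiIndex.from_tuples(parts, names=["role", "condition", "replicate"])
    return FootprintDataset(df)


@dataclass
class NormalizedDataset:
    """Loess-normalized log2 values.

    ``selected`` holds per-gene log2 enrichments for each selected array
    (columns ``(condition, replicate)``); ``reference_residuals`` the
    residuals of each reference array around the loess fit.
    """

    selected: pd.DataFrame
    reference_residuals: pd.DataFrame
    span: float

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        for df in (self.selected, self.reference_residuals):
            if not np.all(np.isfinite(df.to_numpy())):
                raise ValueError("normalized values must be finite")

    def condition_values(self, condition: str) -> pd.DataFrame:
        cols = self.selected.columns
        return self.selected.loc[:, cols.get_level_values(0) == condition]

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.selected.columns.get_level_values(0)))


@dataclass
class NullSummaryModel:
    """Simulated null distribution of pseudo-gene summary statistics."""

    summaries: np.ndarray
    n_pseudo: int
    df: float
    n_replicates: int
    seed: int
    # diagnostics for the scaling contract: each pseudo-gene's draws have sd
    # equal to its sampled real-gene sd, so the pooled draw sd equals the
    # root-mean-square of the sampled sds (and their mean when homoscedastic)
    pooled_draw_sd: float = float("nan")
    mean_target_sd: float = float("nan")
    rms_target_sd: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.summaries) != self.n_pseudo:
            raise ValueError("summary vector length must equal n_pseudo")


@dataclass
class SignificanceCalls:
    """Per-condition significance calls with FDR bookkeeping.

    ``tables`` maps condition -> DataFrame with columns
    ``summary, p, significant, sign`` indexed by gene.
    """

    tables: dict[str, pd.DataFrame]
    cutoffs: dict[str, float]
    fdr_estimates: dict[str, float]
    target_fdr: float
    excluded_essentials: list[str] = field(default_factory=list)

    def significant_genes(self, condition: str) -> pd.Index:
        t = self.tables[condition]
        return t.index[t["significant"]]

    def any_significant(self) -> pd.Index:
        genes: pd.Index | None = None
        for t in self.tables.values():
            sig = t.index[t["significant"]]
            genes = sig if genes is None else genes.union(sig)
        return genes if genes is not None else pd.Index([])

    def write(self, outdir: str | Path, meta: Mapping | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond, t in self.tables.items():
            out = t.copy()
            out.index.name = "gene"
            out.to_csv(outdir / f"calls_{cond}.tsv", sep="\t")
        sidecar = {
            "target_fdr": self.target_fdr,
            "cutoffs": self.cutoffs,
            "fdr_estimates": self.fdr_estimates,
            "excluded_essentials": len(self.excluded_essentials),
        }
        if meta:
            sidecar.update(meta)
        (outdir / "calls_meta.json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _loess_predict(x: np.ndarray, y: np.ndarray, span: float, iters: int = 3) -> np.ndarray:
    """Locally linear loess fit of y on x, evaluated at each x.

    Tricube weights with ``iters`` bisquare robustness iterations;
    prediction by linear interpolation at the fitted abscissae (ties in x
    collapse to one knot).  Robust iterations matter here: genes under
    strong selection are one-sided outliers that would otherwise drag the
    fitted trend away from the unselected majority.
    """
    fit = lowess(y, x, frac=span, it=iters, return_sorted=True)
    return np.interp(x, fit[:, 0], fit[:, 1])


def normalize(dataset: FootprintDataset, span: float = 0.3) -> NormalizedDataset:
    """Sum-normalize, log2-transform, and loess-detrend against the reference mean.

    Each array is scaled so its ratio-scale total equals the mean total
    over arrays, then log2-transformed.  Each array (selected and
    reference alike) is then regressed on the per-gene mean of the
    reference arrays with a loess curve of the given span, and the fitted
    value is subtracted, so genes whose abundance did not respond to
    selection centre near zero.
    """
    if dataset.n_reference < 2:
        raise ValueError("normalization requires at least 2 reference arrays")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")

    vals = dataset.values
    totals = vals.sum(axis=0)
    scaled = vals * (totals.mean() / totals)
    logged = np.log2(scaled)

    roles = logged.columns.get_level_values(0)
    ref = logged.loc[:, roles == REF_ROLE]
    ref_mean = ref.mean(axis=1).to_numpy()

    out = {}
    for col in logged.columns:
        y = logged[col].to_numpy()
        out[col] = y - _loess_predict(ref_mean, y, span)
    norm = pd.DataFrame(out, index=logged.index)
    norm.columns = logged.columns

    sel = norm.loc[:, roles == SEL_ROLE]
    sel.columns = sel.columns.droplevel(0)
    refres = norm.loc[:, roles == REF_ROLE]
    refres.columns = refres.columns.droplevel(0).droplevel(0)
    return NormalizedDataset(selected=sel, reference_residuals=refres, span=span)


# ---------------------------------------------------------------------------
# summary statistic
# ---------------------------------------------------------------------------

def summarize_gene(replicate_values: Sequence[float]) -> float:
    """Sign-concordant minimum: value closest to zero if all replicates
    share a strict sign, zero otherwise (a zero replicate has no sign and
    breaks concordance)."""
    v = np.asarray(replicate_values, dtype=float)
    if v.size == 0:
        raise ValueError("at least one replicate value is required")
    if np.all(v > 0):
        return float(v.min())
    if np.all(v < 0):
        return float(v.max())
    return 0.0


def _summarize_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise sign-concordant minimum (vectorized)."""
    pos = np.all(values > 0, axis=1)
    neg = np.all(values < 0, axis=1)
    out = np.zeros(values.shape[0])
    out[pos] = values[pos].min(axis=1)
    out[neg] = values[neg].max(axis=1)
    return out


def summarize_condition(normalized: NormalizedDataset, condition: str) -> pd.Series:
    """Per-gene summary statistic for one condition's replicates."""
    vals = normalized.condition_values(condition)
    if vals.shape[1] == 0:
        raise ValueError(f"no selected arrays for condition {condition!r}")
    return pd.Series(_summarize_matrix(vals.to_numpy()), index=vals.index, name=condition)


# ---------------------------------------------------------------------------
# simulated null
# ---------------------------------------------------------------------------

def build_null(
    normalized: NormalizedDataset,
    condition: str,
    n_pseudo: int = 500_000,
    df: float = 4.0,
    seed: int = 0,
) -> NullSummaryModel:
    """Simulate a null distribution of pseudo-gene summary statistics.

    Each pseudo-gene receives r replicate draws (r = real replicate count
    for the condition) from a Student t distribution with ``df`` degrees
    of freedom, rescaled so the *distribution's* standard deviation equals
    the replicate standard deviation of a randomly chosen real gene, and
    shifted by the median reference residual of an independently chosen
    (possibly different) gene.  The same summary statistic as for real
    genes is then applied.
    """
    if df <= 2:
        raise ValueError("df must exceed 2 (finite variance required)")
    vals = normalized.condition_values(condition)
    r = vals.shape[1]
    if r < 2:
        raise ValueError("condition needs >=2 replicates for a null model")

    gene_sds = vals.std(axis=1, ddof=1).to_numpy()
    ref_medians = normalized.reference_residuals.median(axis=1).to_numpy()
    n_genes = len(gene_sds)

    rng = np.random.default_rng(seed)
    idx_sd = rng.integers(0, n_genes, size=n_pseudo)
    idx_mu = rng.integers(0, n_genes, size=n_pseudo)
    # t(df) has sd sqrt(df/(df-2)); rescale so draw sd == target sd exactly
    t_sd = np.sqrt(df / (df - 2.0))
    noise = rng.standard_t(df, size=(n_pseudo, r)) / t_sd
    draws = noise * gene_sds[idx_sd, None] + ref_medians[idx_mu, None]

    summaries = _summarize_matrix(draws)
    centred = draws - ref_medians[idx_mu, None]
    return NullSummaryModel(
        summaries=summaries,
        n_pseudo=n_pseudo,
        df=df,
        n_replicates=r,
        seed=seed,
        pooled_draw_sd=float(centred.std()),
        mean_target_sd=float(gene_sds[idx_sd].mean()),
        rms_target_sd=float(np.sqrt(np.mean(gene_sds[idx_sd] ** 2))),
    )


# ---------------------------------------------------------------------------
# p-values and FDR calling
# ---------------------------------------------------------------------------

def p_values(summaries: pd.Series, null: NullSummaryModel) -> pd.Series:
    """Empirical two-sided p-values: fraction of null summaries strictly
    exceeding the observed statistic in magnitude, floored at 1/n_pseudo."""
    if null.n_pseudo == 0:
        raise ValueError("empty null model")
    abs_null = np.sort(np.abs(null.summaries))
    s = np.abs(summaries.to_numpy())
    exceeding = null.n_pseudo - np.searchsorted(abs_null, s, side="right")
    p = np.maximum(exceeding / null.n_pseudo, 1.0 / null.n_pseudo)
    return pd.Series(p, index=summaries.index, name="p")


def null_calibration_ks(summaries: pd.Series, null: NullSummaryModel) -> float:
    """KS check that observed summaries are calibrated against the null.

    The summary statistic has an atom at zero (discordant replicate
    signs), so raw p-values are uniform only on the sign-concordant part:
    for a gene with s != 0, p = q0 * (1 - F(|s|)) where q0 is the null's
    nonzero-summary fraction and F the conditional |summary| CDF.  The
    diagnostic therefore rescales the p-values of nonzero-summary genes by
    q0 and tests them against Uniform(0, 1); returns the KS p-value.
    """
    from scipy import stats

    q0 = float(np.mean(null.summaries != 0))
    if q0 == 0:
        raise ValueError("null model has no nonzero summaries")
    p = p_values(summaries, null)
    nonzero = summaries != 0
    if nonzero.sum() < 10:
        raise ValueError("too few nonzero summaries for a calibration check")
    u = np.clip(p[nonzero].to_numpy() / q0, 0.0, 1.0)
    return float(stats.kstest(u, "uniform").pvalue)


def plugin_fdr_cutoff(p: np.ndarray, n_tested: int, target_fdr: float) -> tuple[float, float]:
    """Largest p threshold alpha with plug-in FDR (alpha*n_tested)/#{p<=alpha}
    at or below target.  Returns (cutoff, estimate); (0, 0) if unattainable."""
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must lie in (0, 1)")
    ps = np.sort(np.unique(p))
    counts = np.searchsorted(np.sort(p), ps, side="right")
    est = ps * n_tested / counts
    ok = est <= target_fdr
    if not ok.any():
        return 0.0, 0.0
    i = np.max(np.nonzero(ok)[0])
    return float(ps[i]), float(est[i])


def call_significant(
    p: pd.Series,
    summaries: pd.Series,
    n_tested: int | None = None,
    target_fdr: float = 0.05,
) -> pd.DataFrame:
    """Flag genes at a plug-in FDR threshold for one condition.

    Returns a DataFrame (gene-indexed) with columns ``summary, p,
    significant, sign`` plus attrs ``cutoff`` and ``fdr_estimate``.
    """
    if n_tested is None:
        n_tested = len(p)
    cutoff, est = plugin_fdr_cutoff(p.to_numpy(), n_tested, target_fdr)
    sig = p.to_numpy() <= cutoff if cutoff > 0 else np.zeros(len(p), bool)
    table = pd.DataFrame(
        {
            "summary": summaries,
            "p": p,
            "significant": sig,
            "sign": np.sign(summaries).astype(int),
        }
    )
    table.attrs["cutoff"] = cutoff
    table.attrs["fdr_estimate"] = est
    return table


def exclude_essentials(
    dataset: FootprintDataset, essential_ids: Iterable[str]
) -> FootprintDataset:
    """Drop essential genes (insertions unrecoverable) before testing."""
    essential = set(essential_ids)
    missing = essential - set(dataset.genes)
    if missing:
        warnings.warn(
            f"{len(missing)} essential ids not present in dataset; ignored",
            stacklevel=2,
        )
    keep = dataset.genes[~dataset.genes.isin(essential)]
    removed = len(dataset.genes) - len(keep)
    logger.info("excluded %d essential genes (%d retained)", removed, len(keep))
    if len(keep) == 0:
        raise ValueError("all genes excluded as essential; nothing to test")
    return FootprintDataset(dataset.values.loc[keep])


def read_essential_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def run_footprint_pipeline(
    dataset: FootprintDataset,
    essential_ids: Iterable[str] = (),
    span: float = 0.3,
    n_pseudo: int = 500_000,
    df: float = 4.0,
    seed: int = 0,
    target_fdr: float = 0.05,
) -> SignificanceCalls:
    """Normalize, summarize, simulate nulls, and call significance for
    every condition in the dataset."""
    essential_ids = list(essential_ids)
    data = exclude_essentials(dataset, essential_ids) if essential_ids else dataset
    norm = normalize(data, span=span)
    tables: dict[str, pd.DataFrame] = {}
    cutoffs: dict[str, float] = {}
    estimates: dict[str, float] = {}
    for i, cond in enumerate(norm.conditions):
        summaries = summarize_condition(norm, cond)
        null = build_null(norm, cond, n_pseudo=n_pseudo, df=df, seed=seed + i)
        p = p_values(summaries, null)
        table = call_significant(p, summaries, target_fdr=target_fdr)
        tables[cond] = table
        cutoffs[cond] = table.attrs["cutoff"]
        estimates[cond] = table.attrs["fdr_estimate"]
    return SignificanceCalls(
        tables=tables,
        cutoffs=cutoffs,
        fdr_estimates=estimates,
        target_fdr=target_fdr,
        excluded_essentials=[g for g in essential_ids if g in set(dataset.genes)],
    )
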