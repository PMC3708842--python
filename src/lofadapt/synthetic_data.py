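"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate, at gene level:

* transposon-footprint ratio arrays — per-gene baseline abundance, a
  slowly varying array-level intensity bias (so loess normalization has
  real work to do), spiked signed log2 fitness effects on the selected
  arrays, and heavy-tailed (Student t, 4 df) replicate noise whose
  *distribution* sd matches a per-gene scale drawn from a configurable
  sampler — mirroring the null model used by the significance pipeline;
* class-labeled per-condition beneficial/deleterious call matrices with
  optional spiked class enrichment, for the meta-analysis tests;
* toy metabolic models with closed-form optima, including a futile cycle
  and a costly bypass, for the flux-analysis oracles;
* paired expression replicates with spiked up/down genes;
* exponential growth curves with blanks, noise, and serial dilutions.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_fdr import ExpressionComparison
from .flux_analysis import MetabolicModel, Reaction
from .footprint_stats import FootprintDataset, REF_ROLE, SEL_ROLE
from .growth_kinetics import GrowthCurve
from .meta_enrichment import ConditionCallTable

__all__ = [
    "FootprintSimConfig",
    "SimTruth",
    "simulate_footprint_dataset",
    "simulate_call_matrix",
    "make_toy_metabolic_model",
    "simulate_expression_pair",
    "simulate_growth_curve",
    "TOY_VARIANTS",
    "DEFAULT_CLASSES",
    "RATIO_FLOOR",
]

RATIO_FLOOR = 1e-6

# coarse functional classes in the style of GenProtEC product types
DEFAULT_CLASSES = (
    "enzyme",
    "regulator",
    "membrane",
    "RNA",
    "structural",
    "carrier",
    "factor",
    "cell process",
)


# ---------------------------------------------------------------------------
# sampler specs
# ---------------------------------------------------------------------------

def make_sampler(spec) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Turn a sampler spec into rng -> values.

    Specs: a number (constant), {"fixed": v}, {"uniform": (lo, hi)},
    {"lognormal": (mean_log, sd_log)}, or a callable (rng, size) -> array.
    """
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        return lambda rng, size: np.full(size, float(spec))
    if isinstance(spec, Mapping) and len(spec) == 1:
        (kind, args), = spec.items()
        if kind == "fixed":
            return lambda rng, size: np.full(size, float(args))
        if kind == "uniform":
            lo, hi = args
            return lambda rng, size: rng.uniform(lo, hi, size)
        if kind == "lognormal":
            mu, sigma = args
            return lambda rng, size: rng.lognormal(mu, sigma, size)
    raise ValueError(f"cannot interpret sampler spec {spec!r}")


# ---------------------------------------------------------------------------
# footprint arrays
# ---------------------------------------------------------------------------

@dataclass
class FootprintSimConfig:
    """Conditions for a simulated footprint selection experiment.

    Defaults mirror the study design the pipeline targets: five reference
    hybridizations of the unselected library; selected conditions with 3
    (and one with 2) biological replicates; heavy-tailed replicate noise
    from a t distribution with 4 degrees of freedom, scaled so its sd
    equals a per-gene value drawn from ``sd_distribution``.
    """

    seed: int = 0
    n_genes: int = 2000
    n_reference_arrays: int = 5
    replicates_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {
            "alanine": 3,
            "aspartate": 3,
            "glutamine": 3,
            "asparagine": 2,
        }
    )
    noise_df: float = 4.0
    sd_distribution: object = field(
        default_factory=lambda: {"lognormal": (np.log(0.3), 0.4)}
    )
    frac_beneficial: float = 0.05
    frac_deleterious: float = 0.05
    effect_size: object = field(default_factory=lambda: {"uniform": (1.0, 4.0)})
    baseline_sd: float = 1.0
    bias_amplitude: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.frac_beneficial <= 1 and 0 <= self.frac_deleterious <= 1):
            raise ValueError("effect fractions must lie in [0, 1]")
        if self.frac_beneficial + self.frac_deleterious > 1:
            raise ValueError("effect fractions must sum to at most 1")
        if self.noise_df <= 2:
            raise ValueError("noise_df must exceed 2 (finite variance required)")
        if self.n_genes < 1 or self.n_reference_arrays < 1:
            raise ValueError("counts must be >= 1")
        for cond, r in self.replicates_per_condition.items():
            if r < 1:
                raise ValueError(f"condition {cond!r} needs >= 1 replicate")


@dataclass
class SimTruth:
    """Recorded ground truth: per gene and condition, the spiked signed
    log2 effect and its label (beneficial / deleterious / null)."""

    effects: pd.DataFrame  # genes x conditions, signed log2
    labels: pd.DataFrame  # genes x conditions, str

    def __post_init__(self) -> None:
        e = self.effects.to_numpy()
        lab = self.labels.to_numpy()
        if e.shape != lab.shape:
            raise ValueError("effects and labels must be congruent")
        if not (
            np.all((lab == "null") == (e == 0))
            and np.all((lab == "beneficial") == (e > 0))
            and np.all((lab == "deleterious") == (e < 0))
        ):
            raise ValueError("labels inconsistent with effect signs")

    def genes_with(self, label: str, condition: str) -> pd.Index:
        col = self.labels[condition]
        return col.index[col == label]


def simulate_footprint_dataset(
    config: FootprintSimConfig,
) -> tuple[FootprintDataset, SimTruth]:
    """Simulate reference and selected ratio arrays with known effects.

    On the log2 scale each value is per-gene baseline + array-level smooth
    intensity bias + spiked effect (selected arrays only) + per-gene-scaled
    heavy-tailed noise; the returned matrix is on the ratio scale, floored
    at a small positive epsilon so logs stay finite.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene")

    baseline = rng.normal(0.0, config.baseline_sd, n)
    gene_sd = make_sampler(config.sd_distribution)(rng, n)
    t_sd = np.sqrt(config.noise_df / (config.noise_df - 2.0))

    # spiked effects: disjoint beneficial/deleterious gene sets, one signed
    # magnitude per gene applied in every selected condition
    n_ben = int(round(config.frac_beneficial * n))
    n_del = int(round(config.frac_deleterious * n))
    perm = rng.permutation(n)
    ben_idx, del_idx = perm[:n_ben], perm[n_ben : n_ben + n_del]
    magnitude = make_sampler(config.effect_size)(rng, n)
    effect = np.zeros(n)
    effect[ben_idx] = np.abs(magnitude[ben_idx])
    effect[del_idx] = -np.abs(magnitude[del_idx])

    # bias length scale: at most ~one period across the intensity spread, so
    # the trend is slowly varying (like real MA-plot dye/intensity trends)
    # and is the kind of curve a loess at span 0.3 is meant to remove
    x_scale = max(config.baseline_sd, 1e-6)

    def array_values(spiked: bool) -> np.ndarray:
        freq = rng.uniform(0.3, 0.8) / x_scale
        phase = rng.uniform(0.0, 2.0 * np.pi)
        bias = config.bias_amplitude * np.sin(freq * baseline + phase)
        noise = rng.standard_t(config.noise_df, n) / t_sd * gene_sd
        log2 = baseline + bias + noise + (effect if spiked else 0.0)
        return np.maximum(np.exp2(log2), RATIO_FLOOR)

    cols: list[tuple[str, str, str]] = []
    mat: list[np.ndarray] = []
    for i in range(config.n_reference_arrays):
        cols.append((REF_ROLE, "pre", f"r{i + 1}"))
        mat.append(array_values(spiked=False))
    for cond, reps in config.replicates_per_condition.items():
        for i in range(reps):
            cols.append((SEL_ROLE, cond, f"r{i + 1}"))
            mat.append(array_values(spiked=True))

    values = pd.DataFrame(
        np.column_stack(mat),
        index=genes,
        columns=pd.MultiIndex.from_tuples(cols, names=["role", "condition", "replicate"]),
    )
    conditions = list(config.replicates_per_condition)
    effects = pd.DataFrame(
        np.tile(effect[:, None], (1, len(conditions))), index=genes, columns=conditions
    )
    labels = effects.map(
        lambda e: "beneficial" if e > 0 else ("deleterious" if e < 0 else "null")
    )
    return FootprintDataset(values), SimTruth(effects=effects, labels=labels)


# ---------------------------------------------------------------------------
# call matrices for the meta-analysis
# ---------------------------------------------------------------------------

def simulate_call_matrix(
    n_genes: int,
    n_conditions: int,
    class_labels: Mapping[str, str] | None = None,
    base_rate: float = 0.02,
    spiked_classes: Mapping[str, float] | None = None,
    seed: int = 0,
    direction: str = "beneficial",
) -> ConditionCallTable:
    """Independent per-gene, per-condition Bernoulli calls with class-
    dependent rates.

    Each gene in ``spiked_classes`` is called at base_rate x multiplier;
    everything else at base_rate.  The spiked class set is recorded in the
    table's provenance as ground truth.
    """
    spiked = dict(spiked_classes or {})
    for cls, mult in spiked.items():
        if not 0 <= base_rate * mult <= 1:
            raise ValueError(f"spiked rate for {cls!r} falls outside [0, 1]")
    if not 0 <= base_rate <= 1:
        raise ValueError("base_rate must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    if class_labels is None:
        assigned = rng.choice(DEFAULT_CLASSES, size=n_genes)
        class_labels = dict(zip(genes, assigned))
    else:
        genes = sorted(class_labels)
        if len(genes) != n_genes:
            raise ValueError("class_labels must cover exactly n_genes genes")

    rates = np.array(
        [base_rate * spiked.get(class_labels[g], 1.0) for g in genes]
    )
    conditions = [f"c{j:03d}" for j in range(n_conditions)]
    calls = rng.random((n_genes, n_conditions)) < rates[:, None]

    tested = {c: set(genes) for c in conditions}
    hit_sets = {
        c: {genes[i] for i in np.nonzero(calls[:, j])[0]}
        for j, c in enumerate(conditions)
    }
    empty = {c: set() for c in conditions}
    ben = hit_sets if direction == "beneficial" else empty
    dele = hit_sets if direction == "deleterious" else empty
    table = ConditionCallTable(
        conditions=conditions,
        tested=tested,
        beneficial=ben,
        deleterious={c: set(s) for c, s in dele.items()},
        class_labels=dict(class_labels),
    )
    table.provenance["spiked_classes"] = ",".join(sorted(spiked))
    table.provenance["base_rate"] = f"{base_rate:g}"
    return table


# ---------------------------------------------------------------------------
# toy metabolic models
# ---------------------------------------------------------------------------

TOY_VARIANTS = ("linear_chain", "futile_cycle", "costly_bypass", "parallel_paths")
_UB = 1000.0


def _toy(reactions: list[Reaction], variant: str, optimum: float, zero_required: Sequence[str]) -> MetabolicModel:
    mets: dict[str, str] = {}
    for r in reactions:
        for m in r.stoichiometry:
            mets.setdefault(m, "e" if m.endswith("_e") else "c")
    model = MetabolicModel(id=f"toy_{variant}", metabolites=mets, reactions=reactions)
    model.notes["optimal_growth"] = repr(optimum)
    model.notes["zero_required"] = ",".join(zero_required)
    return model


def make_toy_metabolic_model(variant: str, uptake: float = 10.0) -> MetabolicModel:
    """Small stoichiometric models with documented closed-form optima.

    * ``linear_chain``: A -> B -> C -> biomass at yield 1; optimum equals
      the uptake bound (10 by default).
    * ``futile_cycle``: biomass synthesis needs energy E made by catabolism
      (A -> 2E); a two-reaction cycle A -> Cf -> A burns one E per turn.
      Optimum 2*uptake/3, attained only with zero cycle flux.
    * ``costly_bypass``: a direct route A -> B and an energy-costing bypass
      A + E -> Cb -> B; optimum equals uptake using the direct route only,
      so catabolism and both bypass steps must be off.
    * ``parallel_paths``: two redundant routes A -> B, one gene-encoded,
      one catalyzed by an isozyme pair (OR rule); optimum equals uptake
      and neither branch is individually required or forbidden.

    Uptake is modeled as the exchange lower bound -uptake on the sole
    carbon source A.
    """
    if variant not in TOY_VARIANTS:
        raise ValueError(f"unknown toy variant {variant!r}; choose from {TOY_VARIANTS}")
    if uptake <= 0:
        raise ValueError("uptake must be positive")
    ex = Reaction("EX_A", {"A": -1.0}, -uptake, _UB)

    if variant == "linear_chain":
        rxns = [
            ex,
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, _UB, gpr="g1"),
            Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, _UB, gpr="g2"),
            Reaction("BIOMASS", {"C": -1.0}, 0.0, _UB, objective=True),
        ]
        return _toy(rxns, variant, uptake, [])

    if variant == "futile_cycle":
        rxns = [
            ex,
            Reaction("CAT", {"A": -1.0, "E": 2.0}, 0.0, _UB, gpr="gcat"),
            Reaction("SYN", {"A": -1.0, "E": -1.0, "B": 1.0}, 0.0, _UB, gpr="gsyn"),
            Reaction("F1", {"A": -1.0, "Cf": 1.0}, 0.0, _UB, gpr="gf1"),
            Reaction("F2", {"Cf": -1.0, "E": -1.0, "A": 1.0}, 0.0, _UB, gpr="gf2"),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, _UB, objective=True),
        ]
        return _toy(rxns, variant, 2.0 * uptake / 3.0, ["F1", "F2"])

    if variant == "costly_bypass":
        rxns = [
            ex,
            Reaction("DIRECT", {"A": -1.0, "B": 1.0}, 0.0, _UB, gpr="gdir"),
            Reaction("CAT", {"A": -1.0, "E": 2.0}, 0.0, _UB, gpr="gcat"),
            Reaction("BY1", {"A": -1.0, "E": -1.0, "Cb": 1.0}, 0.0, _UB, gpr="gb1"),
            Reaction("BY2", {"Cb": -1.0, "B": 1.0}, 0.0, _UB, gpr="gb2"),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, _UB, objective=True),
        ]
        return _toy(rxns, variant, uptake, ["CAT", "BY1", "BY2"])

    # parallel_paths
    rxns = [
        ex,
        Reaction("P1", {"A": -1.0, "B": 1.0}, 0.0, _UB, gpr="g1"),
        Reaction("P2", {"A": -1.0, "B": 1.0}, 0.0, _UB, gpr="g2a or g2b"),
        Reaction("BIOMASS", {"B": -1.0}, 0.0, _UB, objective=True),
    ]
    return _toy(rxns, variant, uptake, [])


# ---------------------------------------------------------------------------
# expression pairs
# ---------------------------------------------------------------------------

def simulate_expression_pair(
    n_genes: int,
    n_up: int = 0,
    n_down: int = 0,
    true_log2_effect: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    condition: str = "synthetic",
) -> tuple[ExpressionComparison, SimTruth]:
    """Two replicate log2-ratio vectors: shared true effect plus
    independent per-replicate Gaussian noise."""
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down must not exceed n_genes")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    effect = np.zeros(n_genes)
    perm = rng.permutation(n_genes)
    effect[perm[:n_up]] = abs(true_log2_effect)
    effect[perm[n_up : n_up + n_down]] = -abs(true_log2_effect)
    reps = effect[:, None] + rng.normal(0.0, noise_sd, (n_genes, 2))
    expr = ExpressionComparison(
        pd.DataFrame(reps, index=genes, columns=["rep1", "rep2"]),
        condition=condition,
    )
    effects = pd.DataFrame({condition: effect}, index=genes)
    labels = effects.map(
        lambda e: "beneficial" if e > 0 else ("deleterious" if e < 0 else "null")
    )
    return expr, SimTruth(effects=effects, labels=labels)


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    doubling_time: float,
    sample_times: Sequence[float],
    dilution_events: Sequence[tuple[float, float]] = (),
    blank: float = 0.04,
    noise_sd: float = 0.0,
    seed: int = 0,
    initial_density: float = 0.002,
) -> GrowthCurve:
    """Exponential growth reset by serial dilutions, plus blank and noise.

    ``dilution_events`` is a list of (time, factor) with factor > 1; the
    measured absorbance after an event is divided by the factor, and the
    cumulative dilution recorded per sample lets fits recover the
    undiluted trajectory.  ``initial_density`` is the blank-free
    absorbance-equivalent at time of the first event-free reading (t=0).
    """
    times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    for t, f in dilution_events:
        if f <= 1:
            raise ValueError("dilution factors must exceed 1")
    rng = np.random.default_rng(seed)
    cumdil = np.array(
        [np.prod([f for t0, f in dilution_events if t0 <= t]) for t in times]
    )
    signal = initial_density * np.exp2(times / doubling_time) / cumdil
    noise = rng.normal(0.0, noise_sd, times.size) if noise_sd > 0 else 0.0
    return GrowthCurve(
        times=times,
        absorbance=signal + blank + noise,
        blank=blank,
        cumulative_dilution=cumdil,
    )
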