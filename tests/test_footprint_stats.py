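"""Unit and property tests for the footprint significance pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lofadapt as la
from lofadapt import footprint_stats as fs

from conftest import flat_dataset


# ---------------------------------------------------------------------------
# summary statistic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [
        ((0.8, 1.2, 2.0), 0.8),
        ((1.2, -0.3, 2.0), 0.0),
        ((-0.5, -0.9), -0.5),
        ((0.0, 1.0, 2.0), 0.0),  # zero has no sign, breaks concordance
        ((3.0,), 3.0),
    ],
)
def test_sign_concordant_minimum(values, expected):
    assert fs.summarize_gene(values) == pytest.approx(expected)


def test_summary_rejects_empty():
    with pytest.raises(ValueError):
        fs.summarize_gene([])


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.floats(min_value=-50, max_value=50, allow_nan=False).filter(lambda x: x != 0),
        min_size=1,
        max_size=6,
    )
)
def test_summary_magnitude_and_sign_invariants(values):
    s = fs.summarize_gene(values)
    assert abs(s) <= min(abs(v) for v in values) + 1e-12
    signs = {np.sign(v) for v in values}
    if len(signs) == 1:
        assert np.sign(s) == signs.pop()
    else:
        assert s == 0.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_flat_dataset_normalizes_to_zero():
    norm = fs.normalize(flat_dataset())
    assert np.abs(norm.selected.to_numpy()).max() < 1e-9
    assert np.abs(norm.reference_residuals.to_numpy()).max() < 1e-9


def test_normalization_idempotent_on_flat_data():
    data = flat_dataset()
    first = fs.normalize(data)
    # rebuild a ratio-scale dataset from the normalized values + baselines
    logged = np.log2(data.values.to_numpy())
    recon = data.values.copy()
    recon.loc[:, :] = np.exp2(logged)  # flat data: normalized residuals are 0
    second = fs.normalize(fs.FootprintDataset(recon))
    delta = np.abs(second.selected.to_numpy() - first.selected.to_numpy())
    assert delta.mean() < 1e-6


def test_single_offset_gene_recovered():
    data = flat_dataset(n_genes=200)
    vals = data.values.copy()
    sel_col = ("sel", "ala", "r0")
    vals.loc["g7", sel_col] *= 2.0**2  # +2 log2 in one selected array
    norm = fs.normalize(fs.FootprintDataset(vals))
    col = norm.selected[("ala", "r0")]
    assert col.loc["g7"] == pytest.approx(2.0, abs=0.15)
    assert np.abs(col.drop("g7")).max() < 0.15


def test_intensity_bias_removed():
    cfg = la.FootprintSimConfig(
        seed=3, n_genes=5000, replicates_per_condition={"ala": 3},
        frac_beneficial=0, frac_deleterious=0, bias_amplitude=0.5,
    )
    data, _ = la.simulate_footprint_dataset(cfg)
    norm = fs.normalize(data, span=0.3)
    ref_mean = np.log2(data.values.loc[:, data.values.columns.get_level_values(0) == "ref"]).mean(axis=1)
    for col in norm.selected.columns:
        r = np.corrcoef(norm.selected[col], ref_mean)[0, 1]
        assert abs(r) < 0.05


def test_normalize_requires_two_reference_arrays():
    data = flat_dataset(n_ref=1)
    with pytest.raises(ValueError, match="reference"):
        fs.normalize(data)


def test_dataset_rejects_nonpositive_ratios():
    data = flat_dataset()
    vals = data.values.copy()
    vals.iloc[0, 0] = 0.0
    with pytest.raises(ValueError, match="positive"):
        fs.FootprintDataset(vals)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def _zero_noise_normalized(n=50, r=3):
    genes = pd.Index([f"g{i}" for i in range(n)], name="gene")
    sel = pd.DataFrame(
        np.ones((n, r)),
        index=genes,
        columns=pd.MultiIndex.from_tuples([("ala", f"r{i}") for i in range(r)]),
    )
    sel.iloc[:, :] = 1.0  # identical replicates: replicate sd 0
    ref = pd.DataFrame(np.zeros((n, 5)), index=genes, columns=[f"r{i}" for i in range(5)])
    return fs.NormalizedDataset(selected=sel, reference_residuals=ref, span=0.3)


def test_null_all_zero_when_sds_and_medians_zero():
    null = fs.build_null(_zero_noise_normalized(), "ala", n_pseudo=500, seed=1)
    assert np.all(null.summaries == 0)


def test_null_reproducible_from_seed(normalized_small):
    a = fs.build_null(normalized_small, "ala", n_pseudo=1000, seed=42)
    b = fs.build_null(normalized_small, "ala", n_pseudo=1000, seed=42)
    assert np.array_equal(a.summaries, b.summaries)


def test_null_rejects_low_df(normalized_small):
    with pytest.raises(ValueError, match="df"):
        fs.build_null(normalized_small, "ala", n_pseudo=100, df=2.0, seed=0)


def test_null_draw_sd_matches_sampled_gene_sds(normalized_small):
    """Scaling contract at default parameters (500,000 pseudo-genes, t with
    4 df): pooled sd of the centred pseudo draws equals the RMS of the
    sampled per-gene sds (law of large numbers, 2%); with homoscedastic
    genes RMS and mean coincide, so the pooled sd also equals the mean."""
    null = fs.build_null(normalized_small, "ala", n_pseudo=500_000, df=4.0, seed=9)
    assert null.pooled_draw_sd == pytest.approx(null.rms_target_sd, rel=0.02)

    homo = _zero_noise_normalized(n=60, r=3)
    sel = homo.selected.to_numpy()
    sel[:, 0] += 0.25  # every gene gets replicate sd exactly 0.25/sqrt(3)
    homo.selected.iloc[:, :] = sel
    null2 = fs.build_null(homo, "ala", n_pseudo=500_000, df=4.0, seed=9)
    assert null2.pooled_draw_sd == pytest.approx(null2.mean_target_sd, rel=0.02)


# ---------------------------------------------------------------------------
# p-values and FDR
# ---------------------------------------------------------------------------

def test_pvalue_direct_count():
    null = fs.NullSummaryModel(
        summaries=np.array([1, -1, 2, -2, 3, -3, 4, -4, 5, -5], dtype=float),
        n_pseudo=10, df=4, n_replicates=3, seed=0,
    )
    s = pd.Series([2.5, 0.0, 10.0], index=["a", "b", "c"])
    p = fs.p_values(s, null)
    assert p["a"] == pytest.approx(6 / 10)
    assert p["b"] == pytest.approx(1.0)  # all null summaries nonzero
    assert p["c"] == pytest.approx(1 / 10)  # floored at 1/n_pseudo


def test_call_significant_all_p_one():
    p = pd.Series(np.ones(100))
    table = fs.call_significant(p, pd.Series(np.zeros(100)), target_fdr=0.05)
    assert not table["significant"].any()
    assert table.attrs["cutoff"] == 0.0


def test_plugin_cutoff_calls_planted_block():
    rng = np.random.default_rng(0)
    p = np.concatenate([np.full(20, 1e-4), rng.uniform(size=980)])
    cutoff, est = fs.plugin_fdr_cutoff(p, len(p), 0.05)
    assert cutoff >= 1e-4
    assert est <= 0.05
    assert (p <= cutoff).sum() >= 20


def test_plugin_cutoff_matches_bruteforce():
    rng = np.random.default_rng(7)
    p = rng.uniform(size=400) ** 2
    n = len(p)
    cutoff, _ = fs.plugin_fdr_cutoff(p, n, 0.05)
    best = 0.0
    for alpha in np.unique(p):
        k = (p <= alpha).sum()
        if alpha * n / k <= 0.05:
            best = max(best, alpha)
    assert cutoff == pytest.approx(best)


def test_detection_power_monotone_in_effect():
    rates = []
    for effect in (1.0, 2.0, 4.0):
        cfg = la.FootprintSimConfig(
            seed=21, n_genes=1000, replicates_per_condition={"ala": 3},
            frac_beneficial=0.05, frac_deleterious=0.0,
            effect_size={"fixed": effect},
        )
        data, truth = la.simulate_footprint_dataset(cfg)
        calls = la.run_footprint_pipeline(data, n_pseudo=20_000, seed=21)
        sig = calls.significant_genes("ala")
        true_ben = truth.genes_with("beneficial", "ala")
        rates.append(len(set(sig) & set(true_ben)) / len(true_ben))
    assert rates[0] <= rates[1] + 0.02 <= rates[2] + 0.04
    assert rates[2] >= 0.9


# ---------------------------------------------------------------------------
# essential exclusion
# ---------------------------------------------------------------------------

def test_exclude_essentials_identity_and_counts(small_footprint):
    data, _ = small_footprint
    same = fs.exclude_essentials(data, [])
    assert same.values.equals(data.values)
    dropped = fs.exclude_essentials(data, list(data.genes[:30]))
    assert len(dropped.genes) == len(data.genes) - 30


def test_exclude_essentials_warns_on_unknown(small_footprint):
    data, _ = small_footprint
    with pytest.warns(UserWarning, match="not present"):
        out = fs.exclude_essentials(data, ["nonexistent_gene"])
    assert len(out.genes) == len(data.genes)


def test_exclude_all_genes_rejected(small_footprint):
    data, _ = small_footprint
    with pytest.raises(ValueError, match="all genes"):
        fs.exclude_essentials(data, list(data.genes))


# ---------------------------------------------------------------------------
# I/O round trip
# ---------------------------------------------------------------------------

def test_footprint_tsv_roundtrip(tmp_path, small_footprint):
    data, _ = small_footprint
    path = tmp_path / "fp.tsv"
    data.to_tsv(path)
    back = fs.read_footprint_tsv(path)
    assert np.allclose(back.values.to_numpy(), data.values.to_numpy())
    assert back.conditions == data.conditions
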