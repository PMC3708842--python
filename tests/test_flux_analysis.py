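"""FBA/FVA tests against a brute-force vertex-enumeration oracle and cobra."""

import numpy as np
import pytest

import lp_oracle
import lofadapt as la
from lofadapt import flux_analysis as fx


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rule,knocked,alive",
    [
        ("g1", set(), True),
        ("g1", {"g1"}, False),
        ("g1 and g2", {"g2"}, False),
        ("g1 or g2", {"g2"}, True),
        ("g1 and (g2 or g3)", {"g2"}, True),
        ("g1 and (g2 or g3)", {"g2", "g3"}, False),
        ("", {"g1"}, True),  # spontaneous reaction survives any deletion
    ],
)
def test_gpr_evaluation(rule, knocked, alive):
    assert fx.eval_gpr(fx.parse_gpr(rule), knocked) is alive


def test_gpr_parse_errors():
    for bad in ("g1 and", "(g1 or g2", "and g1"):
        with pytest.raises(ValueError):
            fx.parse_gpr(bad)


def test_gpr_gene_collection():
    assert fx.gpr_genes(fx.parse_gpr("a and (b or c) and b")) == {"a", "b", "c"}


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant", la.synthetic_data.TOY_VARIANTS)
@pytest.mark.parametrize("dialect", ["table", "sbml"])
def test_model_roundtrip(tmp_path, variant, dialect):
    model = la.make_toy_metabolic_model(variant)
    ext = "tsv" if dialect == "table" else "xml"
    path = tmp_path / f"{variant}.{ext}"
    fx.write_model(model, path, dialect)
    back = fx.read_model(path, dialect)
    assert back.reaction_ids == model.reaction_ids
    for a, b in zip(model.reactions, back.reactions):
        assert a.stoichiometry == b.stoichiometry
        assert a.lower_bound == b.lower_bound and a.upper_bound == b.upper_bound
        assert fx.gpr_genes(fx.parse_gpr(a.gpr)) == fx.gpr_genes(fx.parse_gpr(b.gpr))
        assert a.objective == b.objective
    assert la.fba_max_growth(back).objective_value == pytest.approx(
        la.fba_max_growth(model).objective_value, abs=1e-9
    )


def test_unknown_metabolite_error_names_reaction():
    with pytest.raises(ValueError, match="R_bad"):
        fx.MetabolicModel(
            id="m",
            metabolites={"A": "c"},
            reactions=[
                fx.Reaction("R_bad", {"A": -1.0, "ghost": 1.0}, 0, 10, objective=True)
            ],
        )


def test_bad_equation_rejected_with_location(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("id\tequation\tlb\tub\tgpr\tobjective\nRX\tA + + B\t0\t10\t\t1\n")
    with pytest.raises(ValueError, match="RX"):
        fx.read_model(path, "table")


# ---------------------------------------------------------------------------
# medium setup
# ---------------------------------------------------------------------------

def test_minimal_medium_zero_uptake_zero_growth(toy_models):
    for model in toy_models.values():
        starved = fx.set_minimal_medium(model, "EX_A", uptake=0.0)
        assert la.fba_max_growth(starved).objective_value == pytest.approx(0.0, abs=1e-9)


def test_doubling_uptake_doubles_optimum(toy_models):
    for model in toy_models.values():
        g1 = la.fba_max_growth(fx.set_minimal_medium(model, "EX_A", 10.0)).objective_value
        g2 = la.fba_max_growth(fx.set_minimal_medium(model, "EX_A", 20.0)).objective_value
        assert g2 == pytest.approx(2 * g1, rel=1e-9)


def test_minimal_medium_rejects_non_exchange(toy_models):
    with pytest.raises(ValueError, match="exchange"):
        fx.set_minimal_medium(toy_models["linear_chain"], "R1", 10.0)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def test_all_bounds_zero_gives_zero_optimum(toy_models):
    model = toy_models["linear_chain"]
    closed = model.with_bounds({r.id: (0.0, 0.0) for r in model.reactions})
    sol = la.fba_max_growth(closed)
    assert sol.ok and sol.objective_value == pytest.approx(0.0, abs=1e-12)


def test_useless_bounded_reaction_leaves_optimum(toy_models):
    model = toy_models["linear_chain"]
    mets = dict(model.metabolites)
    mets["junk"] = "c"
    extra = fx.Reaction("USELESS", {"A": -1.0, "junk": 1.0}, 0.0, 0.0, gpr="gx")
    bigger = fx.MetabolicModel(model.id, mets, model.reactions + [extra])
    assert la.fba_max_growth(bigger).objective_value == pytest.approx(10.0, abs=1e-9)


def test_mass_balance_at_optimum(toy_models):
    for model in toy_models.values():
        sol = la.fba_max_growth(model)
        S, _ = model.stoichiometric_matrix()
        assert np.abs(S @ sol.fluxes.to_numpy()).max() <= 1e-6


# ---------------------------------------------------------------------------
# gene deletions
# ---------------------------------------------------------------------------

def test_gene_absent_from_gprs_is_nonessential(toy_models):
    base = toy_models["linear_chain"]
    model = fx.MetabolicModel(
        base.id, dict(base.metabolites), list(base.reactions), genes=["g1", "g2", "bystander"]
    )
    growth, essential = fx.gene_deletion_growth(model, "bystander")
    assert growth == pytest.approx(10.0, abs=1e-9)
    assert not essential


def test_sole_pathway_gene_is_essential(toy_models):
    growth, essential = fx.gene_deletion_growth(toy_models["linear_chain"], "g1")
    assert growth == pytest.approx(0.0, abs=1e-9)
    assert essential


def test_isozyme_deletion_harmless(toy_models):
    model = toy_models["parallel_paths"]
    for g in ("g1", "g2a", "g2b"):
        growth, essential = fx.gene_deletion_growth(model, g)
        assert growth == pytest.approx(10.0, abs=1e-9)
        assert not essential
    with pytest.raises(ValueError, match="unknown gene"):
        fx.gene_deletion_growth(model, "gz")


# ---------------------------------------------------------------------------
# flux scans
# ---------------------------------------------------------------------------

def test_scan_at_optimal_flux_reproduces_optimum(toy_models):
    model = toy_models["futile_cycle"]
    sol = la.fba_max_growth(model)
    v = sol.fluxes["SYN"]
    scan = la.flux_scan(model, "SYN", [v])
    assert scan["growth"].iloc[0] == pytest.approx(sol.objective_value, abs=1e-8)


def test_futile_cycle_scan_shape(toy_models):
    model = toy_models["futile_cycle"]
    values = [0.0, 1.0, 2.0, 4.0, 8.0]
    scan = la.flux_scan(model, "F1", values)
    growth = scan["growth"].to_numpy()
    assert growth[0] == growth.max()
    assert np.all(np.diff(growth) <= 1e-9)  # non-increasing in |flux|


def test_scan_concavity(toy_models):
    model = toy_models["futile_cycle"]
    grid = np.linspace(0.0, 8.0, 5)
    g = la.flux_scan(model, "F1", grid)["growth"].to_numpy()
    mid = (g[:-2] + g[2:]) / 2
    assert np.all(g[1:-1] >= mid - 1e-8)


def test_scan_infeasible_point_flagged(toy_models):
    scan = la.flux_scan(toy_models["linear_chain"], "R1", [50.0])
    assert scan["status"].iloc[0] == "infeasible"
    assert np.isnan(scan["growth"].iloc[0])


def test_scan_oracle_agreement(toy_models):
    model = toy_models["futile_cycle"]
    for v in (0.0, 1.0, 3.0):
        lp = la.flux_scan(model, "F1", [v])["growth"].iloc[0]
        oracle = lp_oracle.oracle_max_growth_at_flux(model, "F1", v)
        assert lp == pytest.approx(oracle, abs=1e-6)


# ---------------------------------------------------------------------------
# FVA and must-be-off genes
# ---------------------------------------------------------------------------

def test_linear_chain_fva_unique_pathway(toy_models):
    res = la.fva(toy_models["linear_chain"])
    for rid in ("R1", "R2", "BIOMASS"):
        assert res.ranges.loc[rid, "min"] == pytest.approx(10.0, abs=1e-6)
        assert res.ranges.loc[rid, "max"] == pytest.approx(10.0, abs=1e-6)
    assert res.zero_required == []


def test_fva_matches_vertex_enumeration(toy_models):
    for variant, model in toy_models.items():
        res = la.fva(model)
        opt, mins, maxs = lp_oracle.oracle_flux_ranges(model)
        assert res.optimum == pytest.approx(opt, abs=1e-6), variant
        assert np.allclose(res.ranges["min"].to_numpy(), mins, atol=1e-6), variant
        assert np.allclose(res.ranges["max"].to_numpy(), maxs, atol=1e-6), variant
        assert set(res.zero_required) == set(lp_oracle.oracle_zero_required(model)), variant


def test_fva_brackets_fba_fluxes(toy_models):
    for model in toy_models.values():
        sol = la.fba_max_growth(model)
        res = la.fva(model)
        assert np.all(res.ranges["min"].to_numpy() - 1e-6 <= sol.fluxes.to_numpy())
        assert np.all(sol.fluxes.to_numpy() <= res.ranges["max"].to_numpy() + 1e-6)


def test_documented_zero_required_sets(toy_models):
    for variant, model in toy_models.items():
        expected = set(filter(None, model.notes["zero_required"].split(",")))
        assert set(la.fva(model).zero_required) == expected, variant


def test_must_off_report_futile_cycle(toy_models):
    model = toy_models["futile_cycle"]
    res = la.fva(model)
    flags = fx.gene_essentiality(model)
    report = la.must_be_off_genes(model, res, flags)
    assert report.final_genes == ["gf1", "gf2"]
    assert "gcat" in [g for g, e in flags.items() if e]


def test_must_off_empty_without_zero_required(toy_models):
    model = toy_models["parallel_paths"]
    report = la.must_be_off_genes(model, la.fva(model), fx.gene_essentiality(model))
    assert report.final_genes == [] and report.implicated_genes == []


def test_gene_in_zero_required_and_active_reaction_still_implicated():
    """Membership rule: a gene catalyzing both a must-off and an active
    reaction is implicated (unless growth-essential)."""
    base = la.make_toy_metabolic_model("futile_cycle")
    reactions = [
        fx.Reaction(r.id, r.stoichiometry, r.lower_bound, r.upper_bound,
                    gpr="gshared" if r.id in ("F1", "SYN") else r.gpr,
                    objective=r.objective)
        for r in base.reactions
    ]
    model = fx.MetabolicModel(base.id, dict(base.metabolites), reactions)
    res = la.fva(model)
    report = la.must_be_off_genes(model, res, fx.gene_essentiality(model))
    # gshared catalyzes zero-required F1 but is essential via SYN: excluded
    assert "gshared" in report.implicated_genes
    assert "gshared" in report.essential_excluded
    assert report.final_genes == ["gf2"]


def test_scale_invariance(toy_models):
    model = toy_models["costly_bypass"]
    scaled = model.with_bounds(
        {r.id: (r.lower_bound * 3, r.upper_bound * 3) for r in model.reactions}
    )
    assert la.fba_max_growth(scaled).objective_value == pytest.approx(
        3 * la.fba_max_growth(model).objective_value, rel=1e-9
    )


# ---------------------------------------------------------------------------
# cobra cross-check (independent implementation)
# ---------------------------------------------------------------------------

def test_fba_and_fva_agree_with_cobra(tmp_path, toy_models):
    import cobra
    from cobra.flux_analysis import flux_variability_analysis

    for variant, model in toy_models.items():
        path = tmp_path / f"{variant}.xml"
        fx.write_model(model, path, "sbml")
        cm = cobra.io.read_sbml_model(str(path))
        sol = cm.optimize()
        ours = la.fba_max_growth(model)
        assert ours.objective_value == pytest.approx(sol.objective_value, abs=1e-6), variant
        theirs = flux_variability_analysis(cm, fraction_of_optimum=1.0)
        res = la.fva(model)
        for rid in model.reaction_ids:
            assert res.ranges.loc[rid, "min"] == pytest.approx(
                theirs.loc[rid, "minimum"], abs=1e-5
            ), (variant, rid)
            assert res.ranges.loc[rid, "max"] == pytest.approx(
                theirs.loc[rid, "maximum"], abs=1e-5
            ), (variant, rid)
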