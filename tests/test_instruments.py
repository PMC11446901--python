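"""Instrument-strength formulas, LD clumping, and the selection cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mrmediate.instruments import (BlockLD, EmptyInstrumentError,
                                   IndependentLD, InstrumentCriteria,
                                   MatrixLD, clump, f_statistic,
                                   select_instruments, variance_explained)
from mrmediate.sumstats import HarmonizedSet, harmonize
from mrmediate.synthdata import SimulationConfig, simulate_summary_stats


def test_variance_explained_matches_direct_formula():
    beta, se, eaf, n = 0.1, 0.02, 0.3, 5959
    num = 2 * beta ** 2 * eaf * (1 - eaf)
    expected = num / (num + se ** 2 * 2 * n * eaf * (1 - eaf))
    assert variance_explained(beta, se, eaf, n) == pytest.approx(expected,
                                                                 rel=1e-12)
    assert expected == pytest.approx(0.0042 / 1.005312, rel=1e-6)


def test_variance_explained_limits_and_domain():
    assert variance_explained(0.0, 0.1, 0.3, 100) == 0.0
    # se -> 0 limit approaches 1
    assert variance_explained(0.1, 1e-9, 0.3, 100) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        variance_explained(0.1, 0.02, 0.0, 100)
    with pytest.raises(ValueError):
        variance_explained(0.1, 0.0, 0.3, 100)


def test_f_statistic_hand_value_and_monotonicity():
    assert f_statistic(0.01, 5959, 1) == pytest.approx(0.01 * 5957 / 0.99)
    assert f_statistic(0.0, 100, 1) == 0.0
    assert f_statistic(0.01, 5959, 2) < f_statistic(0.01, 5959, 1)
    with pytest.raises(ValueError):
        f_statistic(1.0, 100, 1)
    with pytest.raises(ValueError):
        f_statistic(0.5, 3, 2)


def _harmonized(pvals, positions=None, chrom="1", ids=None):
    k = len(pvals)
    ids = ids or [f"rs{i}" for i in range(k)]
    positions = positions if positions is not None else [1000 * (i + 1) for i in range(k)]
    table = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": positions,
        "effect_allele": "A", "other_allele": "C",
        "beta_exposure": 0.1, "se_exposure": 0.01, "eaf_exposure": 0.3,
        "pval_exposure": pvals, "n_exposure": 5959,
        "flipped_exposure": False,
    })
    return HarmonizedSet(traits=["exposure"], table=table)


def test_clump_keeps_most_significant_of_correlated_pair():
    hs = _harmonized([1e-6, 1e-8], ids=["rsA", "rsB"])
    ld = BlockLD({"rsA": 0, "rsB": 0}, 0.5)
    assert clump(hs, ld) == ["rsB"]


def test_clump_keeps_all_independent_variants():
    hs = _harmonized([1e-6, 1e-8, 1e-7])
    assert sorted(clump(hs, IndependentLD())) == ["rs0", "rs1", "rs2"]


def test_clump_block_matches_brute_force_over_orders():
    """Greedy result on a fully-correlated block = unique valid selection."""
    pvals = [3e-6, 1e-8, 5e-7, 2e-6, 9e-6, 1e-6, 4e-8, 7e-7, 8e-6, 6e-7]
    hs = _harmonized(pvals)
    ld = BlockLD({f"rs{i}": 0 for i in range(10)}, 0.9)
    kept = clump(hs, ld)
    # brute force: any maximal subset with pairwise r2 below threshold has
    # size 1; the p-value-greedy rule demands the smallest p
    best = min(range(10), key=lambda i: (pvals[i], f"rs{i}"))
    assert kept == [f"rs{best}"]
    for subset in itertools.combinations(range(10), 2):
        assert not all(ld.r2(f"rs{a}", f"rs{b}") < 0.001
                       for a, b in itertools.combinations(subset, 2))


def test_clump_is_row_order_invariant_with_deterministic_ties():
    pvals = [1e-6, 1e-6, 1e-6]
    hs = _harmonized(pvals, ids=["rsC", "rsA", "rsB"])
    ld = BlockLD({v: 0 for v in ["rsA", "rsB", "rsC"]}, 0.9)
    kept = clump(hs, ld)
    shuffled = HarmonizedSet(
        traits=["exposure"],
        table=hs.table.iloc[[2, 0, 1]].reset_index(drop=True))
    assert clump(shuffled, ld) == kept == ["rsA"]  # lexicographic tie-break


def test_clump_window_limits_ld_comparisons():
    # same block, but 20,000 kb apart: outside the 10,000 kb window
    hs = _harmonized([1e-8, 1e-6], positions=[1_000, 20_000_000 + 1_000])
    ld = BlockLD({"rs0": 0, "rs1": 0}, 0.9)
    assert sorted(clump(hs, ld)) == ["rs0", "rs1"]


def test_matrix_ld_round_trip(tmp_path):
    m = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["rsA", "rsB"],
                     columns=["rsA", "rsB"])
    path = tmp_path / "ld.tsv"
    m.to_csv(path, sep="\t")
    ld = MatrixLD.from_file(path)
    assert ld.r2("rsA", "rsB") == pytest.approx(0.4)
    assert ld.r2("rsA", "rsZ") == 0.0  # missing pair treated as independent


def _selection_setup(seed=1, **cfg_kw):
    cfg = SimulationConfig(theta_xy_direct=0.3, seed=seed, **cfg_kw)
    exposure, _, outcome, truth = simulate_summary_stats(cfg)
    hs = harmonize(exposure, {"outcome": outcome})
    return cfg, hs, truth


def test_select_instruments_enforces_every_criterion():
    cfg, hs, truth = _selection_setup(n_variants=60, instrument_h2=0.25,
                                      ld_block_size=3)
    criteria = InstrumentCriteria()
    ld = BlockLD(truth.block_of, cfg.ld_r2)
    iset = select_instruments(hs, ld, criteria)
    t = iset.table
    assert len(iset) > 0
    assert (t["pval_exposure"] < criteria.pval_threshold).all()
    assert (iset.f > criteria.f_min).all()
    assert ((iset.r2 >= 0) & (iset.r2 <= 1)).all()
    ids = list(t["variant_id"])
    for a, b in itertools.combinations(ids, 2):
        near = (t.set_index("variant_id").loc[a, "chrom"]
                == t.set_index("variant_id").loc[b, "chrom"])
        if near:
            assert ld.r2(a, b) < criteria.clump_r2 or abs(
                int(t.set_index("variant_id").loc[a, "pos"])
                - int(t.set_index("variant_id").loc[b, "pos"])) \
                > criteria.clump_window_kb * 1000
    stages = iset.attrition
    assert stages["input"] >= stages["significant"] >= stages["clumped"] \
        >= stages["strong"] == len(iset)


def test_f_filter_matches_direct_formula_computation():
    """The retained set must equal {j : F_j > 10} computed from the raw draws."""
    cfg, hs, _ = _selection_setup(n_variants=50, instrument_h2=0.2)
    iset = select_instruments(hs, IndependentLD(),
                              InstrumentCriteria(pval_threshold=0.999))
    t = hs.table
    r2 = variance_explained(t["beta_exposure"], t["se_exposure"],
                            t["eaf_exposure"], t["n_exposure"])
    f = f_statistic(np.asarray(r2), t["n_exposure"].to_numpy(dtype=float), 1)
    expected = set(t.loc[np.asarray(f) > 10.0, "variant_id"])
    assert set(iset.variant_ids) == expected
    assert (iset.f > 10).all()
    # the strong-instrument scenario retains a substantial set
    assert len(iset) >= 15


def test_boundary_f_exactly_ten_is_excluded():
    # craft one variant whose F is exactly 10
    n, k = 5959, 1
    # solve r2 from F = 10: r2 = 10k/(n-1-k+10k)
    r2 = 10.0 / (n - 2 + 10.0)
    assert f_statistic(r2, n, 1) == pytest.approx(10.0)
    # beta that realizes this r2 given se, eaf: r2 = b^2/(b^2 + se^2 * n)
    se = 0.02
    beta = np.sqrt(r2 * se ** 2 * n / (1 - r2))
    table = pd.DataFrame({
        "variant_id": ["rs0"], "chrom": ["1"], "pos": [1000],
        "effect_allele": ["A"], "other_allele": ["C"],
        "beta_exposure": [beta], "se_exposure": [se], "eaf_exposure": [0.3],
        "pval_exposure": [1e-8], "n_exposure": [n],
        "flipped_exposure": [False]})
    hs = HarmonizedSet(traits=["exposure"], table=table)
    with pytest.raises(EmptyInstrumentError) as err:
        select_instruments(hs, IndependentLD(), InstrumentCriteria())
    assert err.value.attrition["clumped"] == 1
    assert err.value.attrition["strong"] == 0


def test_pval_threshold_is_strict():
    cfg, hs, _ = _selection_setup(n_variants=30)
    t = hs.table.copy()
    t["pval_exposure"] = 2e-5
    weak = HarmonizedSet(traits=hs.traits, table=t)
    with pytest.raises(EmptyInstrumentError):
        select_instruments(weak, IndependentLD(), InstrumentCriteria())


def test_selection_is_idempotent():
    cfg, hs, truth = _selection_setup(n_variants=60, instrument_h2=0.25)
    ld = BlockLD(truth.block_of, cfg.ld_r2)
    first = select_instruments(hs, ld, InstrumentCriteria())
    again = select_instruments(first.harmonized, ld, InstrumentCriteria())
    assert again.variant_ids == first.variant_ids
    np.testing.assert_allclose(again.f.to_numpy(), first.f.to_numpy())
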