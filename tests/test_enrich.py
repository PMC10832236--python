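"""Ranking index, gene transfer and logistic gene-set analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirmeta as M
from mirmeta.enrich import RankedGeneIndex
from oracles import logistic_irls, transfer_loop


def _meta_table(mu, p):
    return pd.DataFrame(
        {"mu_hat": mu, "p": p, "z": np.sign(mu), "adj_p": p},
        index=pd.Index([f"mir{i}" for i in range(len(mu))], name="mirna_id"),
    )


def test_index_arithmetic_and_sign_symmetry():
    t = _meta_table([2.0, -1.0, 0.5], [0.01, 0.01, 1.0])
    idx = M.mirna_index(t)
    assert idx.iloc[0] == pytest.approx(2.0)   # sign(+) * -log10(0.01)
    assert idx.iloc[1] == pytest.approx(-2.0)  # sign flips, magnitude same
    assert idx.iloc[2] == pytest.approx(0.0)   # p = 1 -> zero index


def test_index_clamps_zero_p_with_warning(caplog):
    t = _meta_table([1.0], [0.0])
    with caplog.at_level("WARNING", logger="mirmeta"):
        idx = M.mirna_index(t)
    assert np.isfinite(idx.iloc[0]) and idx.iloc[0] > 300
    assert any("clamp" in r.message for r in caplog.records)


def test_transfer_mean_of_targeting_mirnas():
    idx = pd.Series({"mir0": 2.0, "mir1": 0.0, "mir2": -3.0})
    targets = {"mir0": {"gA", "gB"}, "mir1": {"gA"}, "mir2": {"gC"}}
    gi = M.transfer_to_genes(idx, targets)
    assert gi.raw["gA"] == pytest.approx(1.0)   # mean of {+2, 0}
    assert gi.raw["gB"] == pytest.approx(2.0)   # single targeting miRNA
    assert gi.raw["gC"] == pytest.approx(-3.0)
    assert gi.n_mirnas["gA"] == 2


def test_transfer_matches_double_loop_oracle_exactly():
    rng = np.random.default_rng(0)
    mirnas = [f"mir{i}" for i in range(50)]
    genes = [f"g{i}" for i in range(500)]
    idx = pd.Series(rng.normal(size=50), index=mirnas)
    targets = {m: set(rng.choice(genes, size=12, replace=False)) for m in mirnas}
    gi = M.transfer_to_genes(idx, targets)
    exp = transfer_loop(idx.to_dict(), targets)
    assert set(gi.raw.index) == set(exp)
    for g, val in exp.items():
        assert gi.raw[g] == pytest.approx(val, abs=1e-12)


def test_transfer_is_linear_in_the_index():
    rng = np.random.default_rng(1)
    idx = pd.Series(rng.normal(size=20), index=[f"mir{i}" for i in range(20)])
    targets = {m: {f"g{rng.integers(0, 30)}"} for m in idx.index}
    a = 3.5
    g1 = M.transfer_to_genes(idx, targets)
    g2 = M.transfer_to_genes(a * idx, targets)
    pd.testing.assert_series_equal(g2.raw, a * g1.raw)


def test_normalized_scores_are_standard_normal_quantiles():
    idx = pd.Series(np.arange(10.0), index=[f"mir{i}" for i in range(10)])
    targets = {m: {f"g{i}"} for i, m in enumerate(idx.index)}
    gi = M.transfer_to_genes(idx, targets)
    assert abs(gi.normalized.mean()) < 1e-9
    expected = stats.norm.ppf((stats.rankdata(gi.raw) - 0.5) / len(gi.raw))
    np.testing.assert_allclose(np.sort(gi.normalized), np.sort(expected))


def test_transfer_empty_overlap_errors():
    with pytest.raises(ValueError, match="no overlap"):
        M.transfer_to_genes(pd.Series({"mirX": 1.0}), {"mirY": {"g1"}})


def _gene_index(n=2000, seed=3):
    rng = np.random.default_rng(seed)
    raw = pd.Series(rng.standard_normal(n), index=[f"G{i:05d}" for i in range(n)])
    ranks = stats.rankdata(raw)
    normalized = pd.Series(stats.norm.ppf((ranks - 0.5) / n), index=raw.index)
    return RankedGeneIndex(raw=raw, normalized=normalized,
                           n_mirnas=pd.Series(1, index=raw.index))


def _annotation(memberships):
    rows = [(g, go, go) for go, genes in memberships.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene_id", "go_id", "go_name"])


def test_planted_top_decile_term_detected_and_matches_irls_oracle():
    gi = _gene_index()
    rng = np.random.default_rng(4)
    top = gi.normalized.sort_values(ascending=False).index[:200]
    planted = set(rng.choice(top, size=100, replace=False))
    random_terms = {
        f"GO:R{i}": set(rng.choice(gi.raw.index, size=100, replace=False))
        for i in range(20)
    }
    res = M.logistic_gsa(gi, _annotation({"GO:PLANT": planted, **random_terms}))
    row = res.loc["GO:PLANT"]
    assert row["lor"] > 0 and row["adj_p"] < 0.05
    y = np.asarray(gi.normalized.index.isin(planted), float)
    lor_ref, p_ref = logistic_irls(gi.normalized.to_numpy(), y)
    assert row["lor"] == pytest.approx(lor_ref, rel=1e-5)
    assert row["p"] == pytest.approx(p_ref, rel=1e-3, abs=1e-12)


def test_sign_flip_of_index_flips_lor_keeps_p():
    gi = _gene_index(n=800, seed=5)
    flipped = RankedGeneIndex(raw=-gi.raw, normalized=-gi.normalized,
                              n_mirnas=gi.n_mirnas)
    rng = np.random.default_rng(6)
    ann = _annotation({
        f"GO:{i}": set(rng.choice(gi.raw.index, size=60, replace=False))
        for i in range(10)
    })
    r1 = M.logistic_gsa(gi, ann).sort_index()
    r2 = M.logistic_gsa(flipped, ann).sort_index()
    np.testing.assert_allclose(r1["lor"], -r2["lor"], rtol=1e-6)
    np.testing.assert_allclose(r1["p"], r2["p"], rtol=1e-6)


def test_terms_outside_size_bounds_are_skipped_and_counted():
    gi = _gene_index(n=300, seed=7)
    rng = np.random.default_rng(8)
    ann = _annotation({
        "GO:small": set(gi.raw.index[:5]),
        "GO:ok": set(rng.choice(gi.raw.index, size=50, replace=False)),
    })
    res = M.logistic_gsa(gi, ann, size_bounds=(10, 100))
    assert list(res.index) == ["GO:ok"]
    assert res.attrs["n_skipped"] == 1


def test_complete_separation_falls_back_to_flagged_score_test():
    gi = _gene_index(n=400, seed=9)
    top = set(gi.normalized.sort_values(ascending=False).index[:40])
    res = M.logistic_gsa(gi, _annotation({"GO:SEP": top}), size_bounds=(10, 100))
    row = res.loc["GO:SEP"]
    assert 0 < row["p"] < 0.05 and row["lor"] > 0
    # perfectly separated membership cannot yield a stable Wald fit
    assert bool(row["flagged"])


def test_target_frequency_counts_match_brute_force():
    rng = np.random.default_rng(10)
    targets = {f"mir{i}": set(rng.choice([f"g{j}" for j in range(40)], size=8,
                                         replace=False)) for i in range(15)}
    sig = {f"mir{i}" for i in range(8)}
    freq = M.target_frequency(sig, targets)
    brute = {}
    for m in sig:
        for g in targets[m]:
            brute[g] = brute.get(g, 0) + 1
    assert dict(zip(freq["gene_id"], freq["n_mirnas"])) == brute
    assert (freq["n_mirnas"].diff().dropna() <= 0).all()  # sorted descending


def test_shared_target_of_eight_mirnas_tops_report():
    targets = {f"mir{i}": {"HUB", f"g{i}"} for i in range(8)}
    freq = M.target_frequency({f"mir{i}" for i in range(8)}, targets)
    assert freq.iloc[0]["gene_id"] == "HUB" and freq.iloc[0]["n_mirnas"] == 8


def test_run_enrichment_without_significant_mirnas_still_tests_full_profile(
    small_meta,
):
    de, meta, truth = small_meta
    # force nothing significant by inflating adj_p
    neutered = {}
    for k, mr in meta.items():
        t = mr.table.copy()
        t["adj_p"] = 1.0
        neutered[k] = M.MetaResult(tissue=mr.tissue, sex=mr.sex, table=t,
                                   inputs=mr.inputs)
    res = M.run_enrichment(neutered, truth.target_map, truth.annotation)
    for r in res.values():
        assert r.freq.empty
        assert len(r.gsa) > 0


def test_end_to_end_recovery_of_planted_go_terms():
    """Planted terms come out enriched (and background mostly not) in at
    least 9 of 10 seeded replicates of the full pipeline."""
    recovered = 0
    for rep in range(10):
        cfg = M.SimulationConfig(
            n_studies=3, platform_per_study=["array", "array", "rnaseq"],
            tissue_per_study=["blood"] * 3, n_mirnas=120,
            frac_shared=0.1, frac_female_only=0.05, frac_male_only=0.05,
            mu_shared=1.5, mu_female_only=1.5, mu_male_only=1.5, seed=42 + rep,
        )
        bundles, truth = M.simulate_multistudy(cfg)
        de = [r for b in bundles for r in M.run_de(b)]
        meta = M.run_meta(de, strata=(("blood", "female"), ("blood", "male")))
        res = M.run_enrichment(meta, truth.target_map, truth.annotation)
        ok = True
        for stratum, r in res.items():
            gsa = r.gsa
            sig = set(gsa.index[gsa["adj_p"] < 0.05])
            planted_ok = truth.enriched_terms <= sig and (
                gsa.loc[sorted(truth.enriched_terms), "lor"] > 0
            ).all()
            n_bg = len(gsa) - len(truth.enriched_terms)
            bg_rate = len(sig - truth.enriched_terms) / n_bg
            ok = ok and planted_ok and bg_rate <= 0.05
        recovered += int(ok)
    assert recovered >= 9
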