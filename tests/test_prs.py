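"""PRS construction: QC, exact HWE, harmonization algebra, pruning, scoring, AUC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from prsgxe.prs import (
    QcThresholds,
    PrsModel,
    build_prs_model,
    choose_threshold,
    concordance_auc,
    harmonize_sumstats,
    hwe_exact_test,
    ld_prune,
    qc_filter_variants,
    score_individuals,
    select_p_threshold,
)

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# exact HWE oracle: full enumeration over heterozygote counts with fixed margins


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return 1.0
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        probs[het] = (
            math.comb(n, het)
            * math.comb(n - het, hom_rare)
            * 2**het
            * math.factorial(rare) * math.factorial(2 * n - rare)
            / math.factorial(2 * n)
        )
    total = sum(probs.values())
    obs = probs[n_ab]
    return min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(25, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 30) == 1.0


def test_hwe_matches_enumeration_oracle():
    assert hwe_exact_test(5, 10, 5) == pytest.approx(hwe_enumeration_oracle(5, 10, 5), abs=1e-12)


def test_hwe_extreme_het_excess():
    p = hwe_exact_test(0, 20, 0)
    assert p == pytest.approx(hwe_enumeration_oracle(0, 20, 0), abs=1e-12)
    assert p < 1e-4


@pytest.mark.parametrize("counts", list(itertools.product([0, 2, 7], repeat=3))[1:])
def test_hwe_oracle_grid(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), abs=1e-10
    )


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# QC


def test_qc_engineered_panel():
    # seven variants, each failing exactly one filter, plus one clean variant
    n = 100
    rng = np.random.default_rng(0)
    hwe_ok = rng.binomial(2, 0.4, size=(n, 8)).astype(float)
    d = hwe_ok.copy()
    d[:, 2][:10] = np.nan                      # call rate 90% -> fails > 0.95
    d[:, 3] = 0.0                              # monomorphic: MAF 0 fails > 0.001
    d[:, 4] = 1.0                              # all hets: extreme HWE failure
    g = make_genotypes(
        d,
        chrom=[1, 1, 1, 1, 1, 23, 1, 1],
        pos=[100, 200, 300, 400, 500, 600, 700, 800],
        ref=["A"] * 8,
        alt=["G", "G", "G", "G", "G", "G", "GT", "G"],
        info=[0.99, 0.99, 0.99, 0.99, 0.99, 0.99, 0.99, 0.80],
    )
    # duplicate id for variant 1
    g.variants.loc[1, "id"] = g.variants.loc[0, "id"]
    kept, drops = qc_filter_variants(g)
    assert kept.n_variants == 1
    assert kept.variants.iloc[0]["pos"] == 100
    assert drops == {
        "duplicate": 1, "non_autosomal": 1, "non_snp": 1,
        "call_rate": 1, "allele_freq": 1, "info": 1, "hwe": 1,
    }


def test_qc_info_bound_is_strict():
    d = np.random.default_rng(1).binomial(2, 0.3, size=(200, 2)).astype(float)
    g = make_genotypes(d, info=[0.80, 0.8000001])
    kept, drops = qc_filter_variants(g)
    assert list(kept.variants["info"]) == [0.8000001]
    assert drops["info"] == 1


def test_qc_fractional_dosages_exempt_from_hwe():
    d = np.full((50, 1), 1.0)
    d[:, 0] += np.linspace(-0.4, 0.4, 50)  # clearly imputed dosages
    g = make_genotypes(d)
    kept, drops = qc_filter_variants(g)
    assert kept.n_variants == 1 and drops["hwe"] == 0


# ---------------------------------------------------------------------------
# harmonization


def _sumstats(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"])


def test_harmonize_direct_and_swapped_match():
    panel = pd.DataFrame(
        {
            "id": ["v0", "v1"], "chrom": [1, 1], "pos": [100, 200],
            "ref": ["G", "A"], "alt": ["A", "G"], "info": [1.0, 1.0],
        }
    )
    ss = _sumstats(
        [
            ("v0", 1, 100, "A", "G", 0.1, 0.01),   # A1 = alt: +0.1
            ("v1", 1, 200, "A", "G", 0.1, 0.01),   # A1 = ref: -0.1 with offset
        ]
    )
    entries, drops = harmonize_sumstats(ss, panel)
    assert len(entries) == 2 and sum(drops.values()) == 0
    assert entries.loc[0, "weight"] == pytest.approx(0.1)
    assert entries.loc[0, "offset"] == 0.0
    assert entries.loc[1, "weight"] == pytest.approx(-0.1)
    assert entries.loc[1, "offset"] == pytest.approx(0.2)


def test_harmonize_ref_allele_effect_score_identity():
    # contribution beta*(2-d) must equal (-beta)*d + 2*beta on a 3-person toy
    d = np.array([[0.0], [1.0], [2.0]])
    g = make_genotypes(d, ref=["A"], alt=["G"])
    ss = _sumstats([("v0", 1, 1000, "A", "G", 0.1, 0.01)])  # effect allele = ref
    entries, _ = harmonize_sumstats(ss, g.variants)
    model = PrsModel(entries=entries, p_threshold=1.0)
    scores = score_individuals(g, model).to_numpy()
    assert scores == pytest.approx(0.1 * (2 - d[:, 0]))


def test_harmonize_palindromic_dropped():
    panel = pd.DataFrame(
        {"id": ["v0"], "chrom": [1], "pos": [100], "ref": ["A"], "alt": ["T"],
         "info": [1.0]}
    )
    ss = _sumstats([("v0", 1, 100, "A", "T", 0.1, 0.01)])
    entries, drops = harmonize_sumstats(ss, panel)
    assert entries.empty and drops["palindromic"] == 1


def test_harmonize_absent_and_mismatch():
    panel = pd.DataFrame(
        {"id": ["v0"], "chrom": [1], "pos": [100], "ref": ["A"], "alt": ["G"],
         "info": [1.0]}
    )
    ss = _sumstats(
        [
            ("x", 2, 100, "A", "G", 0.1, 0.01),   # wrong chromosome
            ("v0", 1, 100, "A", "C", 0.1, 0.01),  # alleles do not match
        ]
    )
    entries, drops = harmonize_sumstats(ss, panel)
    assert entries.empty
    assert drops["absent"] == 1 and drops["mismatch"] == 1


def test_strand_flip_invariance(tiny_genotypes, tiny_sumstats):
    # complementing both alleles of every non-palindromic record: same scores
    ss, _ = tiny_sumstats
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    flipped = ss.copy()
    flipped["A1"] = [comp[a] for a in ss["A1"]]
    flipped["A2"] = [comp[a] for a in ss["A2"]]
    e1, _ = harmonize_sumstats(ss, tiny_genotypes.variants)
    e2, _ = harmonize_sumstats(flipped, tiny_genotypes.variants)
    m1 = PrsModel(entries=e1, p_threshold=1.0)
    m2 = PrsModel(entries=e2, p_threshold=1.0)
    s1 = score_individuals(tiny_genotypes, m1)
    s2 = score_individuals(tiny_genotypes, m2)
    assert np.array_equal(s1.to_numpy(), s2.to_numpy())


def test_allele_swap_shifts_scores_by_constant(tiny_genotypes, tiny_sumstats):
    ss, _ = tiny_sumstats
    swapped = ss.copy()
    swapped["A1"], swapped["A2"] = ss["A2"].copy(), ss["A1"].copy()
    swapped["BETA"] = -ss["BETA"]
    e1, _ = harmonize_sumstats(ss, tiny_genotypes.variants)
    e2, _ = harmonize_sumstats(swapped, tiny_genotypes.variants)
    s1 = score_individuals(tiny_genotypes, PrsModel(entries=e1, p_threshold=1.0))
    s2 = score_individuals(tiny_genotypes, PrsModel(entries=e2, p_threshold=1.0))
    shifts = s2.to_numpy() - s1.to_numpy()
    assert np.allclose(shifts, shifts[0], atol=1e-9)
    labels = (np.arange(len(s1)) % 3 == 0).astype(int)
    a1 = concordance_auc(s1.to_numpy(), labels).auc
    a2 = concordance_auc(s2.to_numpy(), labels).auc
    assert abs(a1 - a2) <= 1e-12


# ---------------------------------------------------------------------------
# LD pruning


def _cands(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "weight",
                                       "offset", "p"])


def test_prune_outside_window_retained():
    rng = np.random.default_rng(2)
    base = rng.binomial(2, 0.5, size=(500, 1)).astype(float)
    d = np.hstack([base, base])  # perfectly correlated pair
    g = make_genotypes(d, pos=[1000, 601_000])
    cands = _cands([("v0", 1, 1000, 0.1, 0, 0.01), ("v1", 1, 601_000, 0.1, 0, 0.02)])
    out = ld_prune(g, cands)
    assert list(out["variant_id"]) == ["v0", "v1"]


def test_prune_greedy_hand_trace():
    # r2(1,2) high with p1 < p2 -> drop 2; variant 3 independent -> kept
    rng = np.random.default_rng(3)
    v1 = rng.binomial(2, 0.5, size=2000).astype(float)
    noise = rng.random(2000) < 0.05
    v2 = np.where(noise, rng.binomial(2, 0.5, size=2000), v1).astype(float)
    v3 = rng.binomial(2, 0.5, size=2000).astype(float)
    g = make_genotypes(np.column_stack([v1, v2, v3]), pos=[1000, 2000, 3000])
    cands = _cands(
        [("v0", 1, 1000, 0.1, 0, 0.001), ("v1", 1, 2000, 0.1, 0, 0.01),
         ("v2", 1, 3000, 0.1, 0, 0.5)]
    )
    out = ld_prune(g, cands)
    assert list(out["variant_id"]) == ["v0", "v2"]


def test_prune_prefers_smaller_p_even_if_earlier_retained():
    # the later variant has the smaller p: the earlier one is displaced
    rng = np.random.default_rng(4)
    v1 = rng.binomial(2, 0.5, size=2000).astype(float)
    g = make_genotypes(np.column_stack([v1, v1]), pos=[1000, 2000])
    cands = _cands([("v0", 1, 1000, 0.1, 0, 0.04), ("v1", 1, 2000, 0.1, 0, 0.0001)])
    out = ld_prune(g, cands)
    assert list(out["variant_id"]) == ["v1"]


def test_prune_vacuous_threshold_keeps_all(tiny_genotypes, tiny_sumstats):
    ss, _ = tiny_sumstats
    entries, _ = harmonize_sumstats(ss, tiny_genotypes.variants)
    out = ld_prune(tiny_genotypes, entries, r2_max=1.0)
    # simulated variants are never perfectly correlated
    assert len(out) == len(entries)


def test_prune_certificate_brute_force(tiny_genotypes, tiny_sumstats):
    # no retained pair within 500 kb may reach r2 >= 0.5 (checked exhaustively)
    ss, _ = tiny_sumstats
    entries, _ = harmonize_sumstats(ss, tiny_genotypes.variants)
    out = ld_prune(tiny_genotypes, entries, r2_max=0.5)
    cols = {v: j for j, v in enumerate(tiny_genotypes.variants["id"])}
    d = tiny_genotypes.dosages
    for i in range(len(out)):
        for j in range(i + 1, len(out)):
            a, b = out.iloc[i], out.iloc[j]
            if a["chrom"] != b["chrom"] or abs(a["pos"] - b["pos"]) > 500_000:
                continue
            x, y = d[:, cols[a["variant_id"]]], d[:, cols[b["variant_id"]]]
            mask = ~(np.isnan(x) | np.isnan(y))
            r = np.corrcoef(x[mask], y[mask])[0, 1]
            assert r * r < 0.5


# ---------------------------------------------------------------------------
# scoring


def test_score_zero_weights():
    g = make_genotypes(np.array([[0.0, 1.0], [2.0, 1.0]]))
    model = PrsModel(
        entries=_cands([("v0", 1, 1000, 0.0, 0, 0.5), ("v1", 1, 2000, 0.0, 0, 0.5)]),
        p_threshold=1.0,
    )
    assert np.all(score_individuals(g, model).to_numpy() == 0.0)


def test_score_arithmetic():
    g = make_genotypes(np.array([[2.0, 1.0]]))
    model = PrsModel(
        entries=_cands([("v0", 1, 1000, 0.1, 0, 0.5), ("v1", 1, 2000, -0.2, 0, 0.5)]),
        p_threshold=1.0,
    )
    assert score_individuals(g, model).to_numpy() == pytest.approx([0.0])


def test_score_mean_imputation():
    g = make_genotypes(np.array([[0.0], [2.0], [np.nan]]))
    model = PrsModel(entries=_cands([("v0", 1, 1000, 0.5, 0, 0.5)]), p_threshold=1.0)
    assert score_individuals(g, model).to_numpy() == pytest.approx([0.0, 1.0, 0.5])


def test_score_linearity_over_partition(tiny_genotypes, tiny_sumstats):
    ss, _ = tiny_sumstats
    entries, _ = harmonize_sumstats(ss, tiny_genotypes.variants)
    full = score_individuals(
        tiny_genotypes, PrsModel(entries=entries, p_threshold=1.0)
    )
    half = len(entries) // 2
    part = sum(
        score_individuals(
            tiny_genotypes,
            PrsModel(entries=entries.iloc[i:j].reset_index(drop=True), p_threshold=1.0),
        ).to_numpy()
        for i, j in [(0, half), (half, len(entries))]
    )
    assert np.allclose(full.to_numpy(), part, atol=1e-9)


# ---------------------------------------------------------------------------
# AUC


def auc_pair_count_oracle(scores, labels):
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = sum((c > controls).sum() + 0.5 * (c == controls).sum() for c in cases)
    return wins / (len(cases) * len(controls))


def test_auc_examples():
    assert concordance_auc(np.array([5.0, 6, 1, 2]), np.array([1, 1, 0, 0])).auc == 1.0
    assert concordance_auc(np.ones(10), np.arange(10) % 2).auc == 0.5
    got = concordance_auc(np.array([1.2, 0.3, 0.5, 0.1]), np.array([1, 1, 0, 0])).auc
    assert got == pytest.approx(0.75)


def test_auc_single_class_error():
    with pytest.raises(ValueError):
        concordance_auc(np.array([1.0, 2.0]), np.array([1, 1]))


def test_auc_matches_oracle_and_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(8)
    for _ in range(20):
        n = int(rng.integers(10, 400))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = (rng.random(n) < 0.3).astype(int)
        if labels.sum() in (0, n):
            continue
        got = concordance_auc(scores, labels).auc
        assert got == pytest.approx(auc_pair_count_oracle(scores, labels), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# threshold selection


def test_choose_threshold_printed_map():
    # reference AUC profile: less strict cutoffs predict better; argmax is 0.05
    auc_map = {0.05: 0.677, 0.005: 0.648, 0.0005: 0.612, 0.00005: 0.586}
    assert choose_threshold(auc_map) == 0.05


def test_choose_threshold_tie_goes_less_strict():
    assert choose_threshold({0.05: 0.6, 0.005: 0.6, 0.0005: None}) == 0.05


def test_select_single_candidate(tiny_genotypes, tiny_sumstats, tiny_cohort):
    ss, _ = tiny_sumstats
    entries, _ = harmonize_sumstats(ss, tiny_genotypes.variants)
    labels = tiny_cohort["scz_status"].to_numpy()
    chosen, auc_map = select_p_threshold(
        entries, tiny_genotypes, labels, candidates=(0.5,)
    )
    assert chosen == 0.5 and set(auc_map) == {0.5}
    assert auc_map[0.5] is not None


def test_build_model_records_provenance(tiny_genotypes, tiny_sumstats):
    ss, _ = tiny_sumstats
    entries, _ = harmonize_sumstats(ss, tiny_genotypes.variants)
    model = build_prs_model(entries, tiny_genotypes, 0.5)
    assert model.provenance["after_prune"] <= model.provenance["after_threshold"]
    assert (model.entries["p"] < 0.5).all()
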