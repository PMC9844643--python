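import itertools

import numpy as np
import pandas as pd
import pytest

from gipm import prs


def _variants(rows):
    base = {
        "variant_id": "v", "chr": "1", "pos": 1000, "effect_allele": "A",
        "other_allele": "G", "beta": 0.1, "p": 1e-10, "maf_gwas": 0.2,
        "maf_ref": 0.2, "site": "CRC", "qc_status": "pass",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


# ---------------------------------------------------------------------------
# Significance / MAF filter
# ---------------------------------------------------------------------------

def test_summary_stat_filters():
    df = _variants([
        {"variant_id": "a", "p": 1e-7, "maf_gwas": 0.2},
        {"variant_id": "b", "p": 1e-9, "maf_gwas": 0.005},
        {"variant_id": "c", "p": 4.9e-8, "maf_gwas": 0.01},
        {"variant_id": "d", "p": np.nan, "maf_gwas": 0.3},
    ])
    out = prs.filter_summary_stats(df)
    status = dict(zip(out["variant_id"], out["qc_status"]))
    assert status == {"a": "fail:p_threshold", "b": "fail:maf", "c": "pass",
                      "d": "fail:missing_stats"}


# ---------------------------------------------------------------------------
# Proxy substitution
# ---------------------------------------------------------------------------

def _ld_frame(pairs):
    return pd.DataFrame(pairs, columns=["id_a", "id_b", "r2"])


def test_proxy_identity_when_available():
    v = _variants([{"variant_id": "a"}]).iloc[0]
    out = prs.proxy_substitute(v, {"a"}, _ld_frame([]))
    assert out["variant_id"] == "a" and out["qc_status"] == "pass"


def test_proxy_substituted_above_threshold():
    v = _variants([{"variant_id": "a"}]).iloc[0]
    ld = _ld_frame([("a", "b", 0.85), ("a", "c", 0.7)])
    out = prs.proxy_substitute(v, {"b", "c"}, ld, positions={"b": 500, "c": 800})
    assert out["variant_id"] == "b"
    assert out["qc_status"] == "proxy:a"


def test_proxy_threshold_is_strict():
    v = _variants([{"variant_id": "a"}]).iloc[0]
    out = prs.proxy_substitute(v, {"b"}, _ld_frame([("a", "b", 0.8)]))
    assert out["qc_status"] == "fail:no_proxy"


def test_proxy_tie_broken_by_position():
    v = _variants([{"variant_id": "a"}]).iloc[0]
    ld = _ld_frame([("a", "b", 0.9), ("a", "c", 0.9)])
    out = prs.proxy_substitute(v, {"b", "c"}, ld, positions={"b": 900, "c": 400})
    assert out["variant_id"] == "c"


# ---------------------------------------------------------------------------
# Reference QC
# ---------------------------------------------------------------------------

def _ref(**overrides):
    base = {"variant_id": "v", "pos": 1000, "effect_allele": "A",
            "other_allele": "G", "maf_ref": 0.2}
    base.update(overrides)
    return pd.Series(base)


def test_maf_discordance():
    v = _variants([{"maf_gwas": 0.30}]).iloc[0]
    out = prs.qc_against_reference(v, _ref(maf_ref=0.42))
    assert out["qc_status"] == "fail:maf_discordant"


def test_palindromic_rejected_at_high_maf():
    v = _variants([{"effect_allele": "A", "other_allele": "T", "maf_gwas": 0.46}]).iloc[0]
    out = prs.qc_against_reference(v, _ref(effect_allele="A", other_allele="T", maf_ref=0.46))
    assert out["qc_status"] == "fail:palindromic"


def test_palindromic_kept_at_low_maf():
    v = _variants([{"effect_allele": "A", "other_allele": "T", "maf_gwas": 0.30}]).iloc[0]
    out = prs.qc_against_reference(v, _ref(effect_allele="A", other_allele="T", maf_ref=0.30))
    assert out["qc_status"] == "pass"


def test_allele_swap_negates_beta():
    v = _variants([{"effect_allele": "A", "other_allele": "G", "beta": 0.25,
                    "maf_gwas": 0.2}]).iloc[0]
    out = prs.qc_against_reference(v, _ref(effect_allele="G", other_allele="A", maf_ref=0.8))
    assert out["qc_status"] == "pass"
    assert out["beta"] == pytest.approx(-0.25)
    assert out["effect_allele"] == "G"
    assert out["maf_gwas"] == pytest.approx(0.8)


def test_strand_flip_reconciles():
    v = _variants([{"effect_allele": "A", "other_allele": "G", "beta": 0.25}]).iloc[0]
    out = prs.qc_against_reference(v, _ref(effect_allele="T", other_allele="C"))
    assert out["qc_status"] == "pass"
    assert out["beta"] == pytest.approx(0.25)


def test_allele_mismatch_and_absent_reference():
    v = _variants([{"effect_allele": "A", "other_allele": "G"}]).iloc[0]
    out = prs.qc_against_reference(v, _ref(effect_allele="A", other_allele="C"))
    assert out["qc_status"] == "fail:allele_mismatch"
    out2 = prs.qc_against_reference(v, None)
    assert out2["qc_status"] == "fail:not_in_reference"


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def greedy_clump_oracle(ids, p, pos, r2, threshold=0.2):
    """Independent reference: explicit loop over candidates sorted by
    (p, position), keeping a variant iff no already-kept variant is linked."""
    order = sorted(range(len(ids)), key=lambda i: (p[i], pos[i]))
    kept = []
    for i in order:
        if all(r2.get(frozenset((ids[i], ids[j])), 0.0) < threshold for j in kept):
            kept.append(i)
    return {ids[i] for i in kept}


def test_clump_unlinked_pair_kept():
    df = _variants([
        {"variant_id": "a", "p": 1e-10, "pos": 1},
        {"variant_id": "b", "p": 1e-9, "pos": 2},
    ])
    out = prs.ld_clump(df, {("a", "b"): 0.1})
    assert (out["qc_status"] == "pass").all()


def test_clump_fully_linked_trio_keeps_smallest_p():
    df = _variants([
        {"variant_id": "a", "p": 1e-12, "pos": 1},
        {"variant_id": "b", "p": 1e-10, "pos": 2},
        {"variant_id": "c", "p": 1e-9, "pos": 3},
    ])
    ld = {("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.5}
    out = prs.ld_clump(df, ld)
    status = dict(zip(out["variant_id"], out["qc_status"]))
    assert status["a"] == "pass"
    assert status["b"].startswith("fail:clumped") and status["c"].startswith("fail:clumped")


def test_clump_chain_keeps_ends():
    df = _variants([
        {"variant_id": "a", "p": 1e-12, "pos": 1},
        {"variant_id": "b", "p": 1e-10, "pos": 2},
        {"variant_id": "c", "p": 1e-9, "pos": 3},
    ])
    ld = {("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.05}
    out = prs.ld_clump(df, ld)
    kept = set(out.loc[out["qc_status"] == "pass", "variant_id"])
    assert kept == {"a", "c"}


def test_clump_matches_oracle_on_random_panels():
    rng = np.random.default_rng(2024)
    for trial in range(25):
        m = int(rng.integers(2, 13))
        ids = [f"v{i}" for i in range(m)]
        p = 10.0 ** -rng.uniform(8, 20, m)
        pos = rng.choice(10_000, size=m, replace=False)
        r2 = {}
        for i, j in itertools.combinations(range(m), 2):
            if rng.random() < 0.5:
                r2[frozenset((ids[i], ids[j]))] = float(rng.random())
        df = _variants([
            {"variant_id": ids[i], "p": p[i], "pos": int(pos[i])} for i in range(m)
        ])
        out = prs.ld_clump(df, {tuple(sorted(k)): v for k, v in r2.items()})
        kept = set(out.loc[out["qc_status"] == "pass", "variant_id"])
        assert kept == greedy_clump_oracle(ids, p, pos, r2), f"trial {trial}"


def test_clump_strict_mode_requires_ld_entries():
    df = _variants([
        {"variant_id": "a", "p": 1e-12, "pos": 1},
        {"variant_id": "b", "p": 1e-10, "pos": 2},
    ])
    with pytest.raises(KeyError):
        prs.ld_clump(df, {}, strict=True)
    out = prs.ld_clump(df, {})  # lenient: unlinked
    assert (out["qc_status"] == "pass").all()


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def test_site_score_weighted_sum():
    variants = _variants([
        {"variant_id": "a", "beta": 0.1}, {"variant_id": "b", "beta": 0.2},
        {"variant_id": "c", "beta": 0.3},
    ])
    dosages = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [2.0]})
    assert prs.score_site_prs(dosages, variants)[0] == pytest.approx(0.8)
    zeros = pd.DataFrame({"a": [0.0], "b": [0.0], "c": [0.0]})
    assert prs.score_site_prs(zeros, variants)[0] == 0.0


def test_dosage_range_enforced():
    variants = _variants([{"variant_id": "a", "beta": 0.1}])
    with pytest.raises(prs.DosageError):
        prs.score_site_prs(pd.DataFrame({"a": [2.5]}), variants)


def test_allele_flip_shifts_scores_by_constant():
    """Swapping alleles (dosage -> 2-d, beta -> -beta) adds the same offset
    to every participant; ranks are untouched."""
    rng = np.random.default_rng(3)
    variants = _variants([
        {"variant_id": f"v{i}", "beta": float(b)}
        for i, b in enumerate(rng.normal(0, 0.2, 6))
    ])
    dosages = pd.DataFrame(rng.integers(0, 3, size=(50, 6)).astype(float),
                           columns=[f"v{i}" for i in range(6)])
    s1 = prs.score_site_prs(dosages, variants)
    flipped = variants.copy()
    flipped.loc[0, "beta"] = -variants.loc[0, "beta"]
    d2 = dosages.copy()
    d2["v0"] = 2.0 - d2["v0"]
    s2 = prs.score_site_prs(d2, flipped)
    offsets = s2 - s1
    assert np.allclose(offsets, offsets[0])
    assert np.array_equal(np.argsort(s1), np.argsort(s2))


# ---------------------------------------------------------------------------
# Composite score
# ---------------------------------------------------------------------------

def _site_scores(n=1000, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "ESC": rng.normal(0.5, 0.1, n),
        "GC": rng.normal(0.2, 0.05, n),
        "CRC": rng.normal(1.0, 0.3, n),
    })


def test_unit_weights_sum_sites():
    scores = pd.DataFrame({"ESC": [0.2], "GC": [0.3], "CRC": [0.5]})
    w = prs.IncidenceWeights(rates={"ESC": 1.0, "GC": 1.0, "CRC": 1.0})
    # a single participant cannot be standardized/quintiled; use 6 copies
    # with tiny jitter
    many = pd.concat([scores] * 6, ignore_index=True) + np.arange(6)[:, None] * 1e-6
    out = prs.combine_gi_prs(many, w)
    assert out["gi_prs"].iloc[0] == pytest.approx(1.0, abs=1e-5)


def test_weight_scaling_leaves_z_and_categories_invariant():
    scores = _site_scores()
    w1 = prs.IncidenceWeights(rates={"ESC": 14, "GC": 11, "CRC": 70})
    w2 = prs.IncidenceWeights(rates={"ESC": 28, "GC": 22, "CRC": 140})
    o1, o2 = prs.combine_gi_prs(scores, w1), prs.combine_gi_prs(scores, w2)
    np.testing.assert_allclose(o1["gi_prs_z"], o2["gi_prs_z"], atol=1e-12)
    assert (o1["quintile"] == o2["quintile"]).all()


def test_mean_standardized_mode_gives_unit_means():
    out = prs.combine_gi_prs(_site_scores(),
                             prs.IncidenceWeights(mode="mean_standardized"))
    for site in ("ESC", "GC", "CRC"):
        assert abs(out[f"{site}_rescaled"].mean() - 1.0) < 1e-12


def test_mean_standardized_zero_mean_rejected():
    scores = _site_scores()
    scores["GC"] = np.tile([-1.0, 1.0], len(scores) // 2)  # exactly zero mean
    with pytest.raises(ZeroDivisionError):
        prs.combine_gi_prs(scores, prs.IncidenceWeights(mode="mean_standardized"))


def test_constant_shift_leaves_categories_and_z_unchanged():
    scores = _site_scores()
    o1 = prs.combine_gi_prs(scores)
    o2 = prs.combine_gi_prs(scores + 5.0)
    np.testing.assert_allclose(o1["gi_prs_z"], o2["gi_prs_z"], atol=1e-9)
    assert (o1["genetic_category"] == o2["genetic_category"]).all()


# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------

def test_continuous_scores_split_20_60_20():
    rng = np.random.default_rng(8)
    out = prs.assign_genetic_category(rng.normal(size=100_000))
    counts = out["genetic_category"].value_counts()
    assert counts["low"] == 20_000
    assert counts["intermediate"] == 60_000
    assert counts["high"] == 20_000


def test_boundary_value_goes_to_lower_quintile():
    v = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    out = prs.assign_genetic_category(v)
    # 2 equals the 20th-percentile cut: assigned to quintile 1 (lower side)
    cuts = np.quantile(v, [0.2, 0.4, 0.6, 0.8])
    assert v[1] == cuts[0]
    assert out["quintile"].iloc[1] == 1


def test_degenerate_scores_rejected():
    with pytest.raises(ValueError):
        prs.assign_genetic_category(np.ones(100))


# ---------------------------------------------------------------------------
# Full harmonization cascade
# ---------------------------------------------------------------------------

def _cascade_inputs():
    variants = _variants([
        {"variant_id": "keep", "p": 1e-10, "pos": 100},
        {"variant_id": "weak", "p": 1e-6, "pos": 200},
        {"variant_id": "rare", "p": 1e-10, "maf_gwas": 0.002, "pos": 300},
        {"variant_id": "absent", "p": 1e-10, "pos": 400},
        {"variant_id": "pal", "p": 1e-10, "pos": 500,
         "effect_allele": "A", "other_allele": "T", "maf_gwas": 0.47},
        {"variant_id": "linked", "p": 1e-9, "pos": 110},
    ])
    reference = pd.DataFrame([
        {"variant_id": "keep", "pos": 100, "effect_allele": "A", "other_allele": "G", "maf_ref": 0.2},
        {"variant_id": "proxyid", "pos": 405, "effect_allele": "A", "other_allele": "G", "maf_ref": 0.2},
        {"variant_id": "pal", "pos": 500, "effect_allele": "A", "other_allele": "T", "maf_ref": 0.47},
        {"variant_id": "linked", "pos": 110, "effect_allele": "A", "other_allele": "G", "maf_ref": 0.2},
    ])
    ld = pd.DataFrame([
        ("absent", "proxyid", 0.9),
        ("keep", "linked", 0.6),
    ], columns=["id_a", "id_b", "r2"])
    return variants, reference, ld


def test_cascade_statuses_partition_input():
    variants, reference, ld = _cascade_inputs()
    out = prs.harmonize(variants, reference, ld)
    assert len(out) == len(variants)
    report = prs.harmonization_report(out)
    assert report["n"].sum() == len(variants)
    status = dict(zip(out["variant_id"], out["qc_status"]))
    assert status["keep"] == "pass"
    assert status["weak"] == "fail:p_threshold"
    assert status["rare"] == "fail:maf"
    assert status["proxyid"] == "proxy:absent"
    assert status["pal"] == "fail:palindromic"
    assert status["linked"].startswith("fail:clumped")
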