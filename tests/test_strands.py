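"""Mutation-table analyses: profiles, strand asymmetry, methylation,
MMR regions, de novo filter, statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perseq.strands import (
    annotate_replication_strand,
    filter_de_novo,
    is_cpg_tpg,
    methylation_binned_frequency,
    mmr_region_ratio,
    mutational_profile,
    pyrimidine_context_occurrences,
    rank_and_mean_tests,
    sign_test,
    strand_asymmetry,
)


def _muts(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# mutational profile
# ---------------------------------------------------------------------------

def test_purine_reference_maps_to_reverse_complement_channel():
    # G>A in a CGT plus-strand context == C>T in ACG (pyrimidine-centric)
    genome = {"chr1": "ACGTA"}
    muts = _muts([("s1", "chr1", 3, "G", "A")])  # 1-based: the G of ACG
    occ = {"ACG": 100}
    prof = mutational_profile(muts, occ, genome=genome)
    assert prof["ACG>T"] == pytest.approx(0.01)
    assert prof.drop("ACG>T").sum() == 0


def test_empty_table_gives_zero_profile():
    prof = mutational_profile(_muts([]), {"ACG": 10}, genome={"chr1": "ACGTA"})
    assert prof.sum() == 0


def test_ref_genome_disagreement_excluded():
    genome = {"chr1": "ACGTA"}
    muts = _muts([("s1", "chr1", 2, "T", "A")])  # genome has C at pos 2
    prof = mutational_profile(muts, {"ACG": 10}, genome=genome)
    assert prof.sum() == 0
    assert prof.attrs["excluded"] == 1


def test_profile_union_is_weighted_combination():
    rng = np.random.default_rng(0)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 4000))}
    occ = pyrimidine_context_occurrences(genome)
    pos = rng.integers(2, 3999, 60)
    rows = []
    for i, p in enumerate(pos):
        ref = genome["chr1"][p - 1]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        rows.append(("s1" if i < 30 else "s2", "chr1", int(p), ref, alt))
    muts = _muts(rows)
    whole = mutational_profile(muts, occ, genome=genome)
    a = mutational_profile(muts.iloc[:30], occ, genome=genome)
    b = mutational_profile(muts.iloc[30:], occ, genome=genome)
    assert np.allclose(whole.to_numpy(), a.to_numpy() + b.to_numpy())


def test_simulated_pdf_recovered_with_high_cosine():
    from perseq.decompose import cosine_similarity
    from perseq.simulate import MutationSimConfig, simulate_mutation_dataset

    cfg = MutationSimConfig(
        n_samples=1, mutations_per_sample=10_000, seed=31,
        n_chromosomes=4, chrom_length=500_000,
    )
    data = simulate_mutation_dataset(cfg)
    occ = pyrimidine_context_occurrences(data.genome)
    prof = mutational_profile(data.mutations, occ, genome=data.genome)
    pdf = data.truth["signature_pdf"]
    from perseq._channels import CHANNELS_96

    occ_vec = np.array([occ.get(t, 0) for t, _ in CHANNELS_96])
    expected = np.where(occ_vec > 0, pdf / np.maximum(occ_vec, 1), 0.0)
    assert cosine_similarity(prof.to_numpy() + 1e-300, expected + 1e-300) >= 0.98


# ---------------------------------------------------------------------------
# replication strand
# ---------------------------------------------------------------------------

DOMAINS = pd.DataFrame(
    {
        "chrom": ["chr1", "chr1"],
        "start": [0, 1000],
        "end": [1000, 2000],
        "direction": ["left", "right"],
        "timing": [0.2, 0.8],
    }
)


def test_strand_rule_left_right_and_unannotated():
    muts = _muts(
        [
            ("s1", "chr1", 500, "C", "T"),  # left domain, C on plus
            ("s1", "chr1", 1500, "C", "T"),  # right domain
            ("s1", "chr1", 5000, "C", "T"),  # outside
            ("s1", "chr1", 600, "G", "A"),  # left domain, pyrimidine on minus
        ]
    )
    labels = annotate_replication_strand(muts, DOMAINS)
    assert list(labels) == [
        "leading_template", "lagging_template", "unannotated", "lagging_template",
    ]


def test_strand_labels_partition_annotated_mutations():
    rng = np.random.default_rng(7)
    muts = _muts(
        [("s1", "chr1", int(p), rng.choice(list("ACGT")), "T")
         for p in rng.integers(1, 2000, 50)]
    )
    muts = muts[muts["ref"] != "T"]
    labels = annotate_replication_strand(muts, DOMAINS)
    assert set(labels) <= {"leading_template", "lagging_template"}


def test_strand_asymmetry_sign_flips_with_direction_swap():
    rng = np.random.default_rng(8)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), p=[.2,.3,.3,.2], size=2000))}
    # all CpG>TpG mutations on the plus strand: leading in left domains
    seq = genome["chr1"]
    cpg_c = [i + 1 for i in range(1, 1998) if seq[i] == "C" and seq[i + 1] == "G"]
    muts = _muts([("s1", "chr1", p, "C", "T") for p in cpg_c[:40]])
    asym = strand_asymmetry(muts, DOMAINS, genome)
    flipped = DOMAINS.assign(
        direction=DOMAINS["direction"].map({"left": "right", "right": "left"})
    )
    asym_flip = strand_asymmetry(muts, flipped, genome)
    assert asym["log2_ratio"].iloc[0] == pytest.approx(
        -asym_flip["log2_ratio"].iloc[0]
    )


def test_strand_asymmetry_equal_frequencies_zero():
    genome = {"chr1": "ACGACG" * 400}
    seq = genome["chr1"]
    cpg_c = [i + 1 for i in range(1, 1800) if seq[i] == "C" and seq[i + 1] == "G"]
    muts_rows = []
    # same count of plus-strand C hits in left and right domains
    left = [p for p in cpg_c if p <= 1000][:10]
    right = [p for p in cpg_c if p > 1000][:10]
    for p in left + right:
        muts_rows.append(("s1", "chr1", p, "C", "T"))
    asym = strand_asymmetry(_muts(muts_rows), DOMAINS, genome)
    assert asym["log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# methylation binning
# ---------------------------------------------------------------------------

def test_methylation_single_bin_frequency():
    meth = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 1001) * 10, "beta": 0.95,
         "coverage": 30}
    )
    muts = _muts([("s1", "chr1", int(p) * 10, "C", "T") for p in range(1, 6)])
    res = methylation_binned_frequency(muts, meth, bins=[0.9, 1.0])
    assert res["frequency"].iloc[0] == pytest.approx(5 / 1000)


def test_methylation_g_to_a_counts_toward_preceding_cpg():
    meth = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "beta": [0.95],
                         "coverage": [30]})
    muts = _muts([("s1", "chr1", 101, "G", "A")])
    res = methylation_binned_frequency(muts, meth, bins=[0.0, 1.0])
    assert res["n_mutations"].iloc[0] == 1


def test_methylation_no_mutations_all_zero():
    meth = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "beta": [0.5],
                         "coverage": [10]})
    res = methylation_binned_frequency(_muts([]), meth, bins=[0.0, 1.0])
    assert res["n_mutations"].sum() == 0


# ---------------------------------------------------------------------------
# MMR regions
# ---------------------------------------------------------------------------

def _meth_uniform(n=200, beta=0.95):
    return pd.DataFrame(
        {"chrom": "chr1", "pos": (np.arange(n) + 1) * 10, "beta": beta,
         "coverage": 30}
    )


def test_mmr_identical_frequencies_give_zero_ratio():
    meth = _meth_uniform(200)
    inside = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
    # 2 mutated CpGs inside (100 sites), 2 outside (100 sites)
    muts = _muts(
        [("s1", "chr1", 10, "C", "T"), ("s1", "chr1", 20, "C", "T"),
         ("s1", "chr1", 1010, "C", "T"), ("s1", "chr1", 1020, "C", "T")]
    )
    res = mmr_region_ratio(muts, inside, meth)
    assert res["log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_mmr_label_swap_negates_ratio():
    meth = _meth_uniform(200)
    inside = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
    outside = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2001]})
    muts = _muts(
        [("s1", "chr1", 10, "C", "T"),
         ("s1", "chr1", 1010, "C", "T"), ("s1", "chr1", 1020, "C", "T")]
    )
    a = mmr_region_ratio(muts, inside, meth)
    b = mmr_region_ratio(muts, outside, meth)
    assert a["log2_ratio"].iloc[0] == pytest.approx(-b["log2_ratio"].iloc[0])


def test_mmr_unmethylated_sites_ignored():
    meth = _meth_uniform(100, beta=0.5)
    inside = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
    muts = _muts([("s1", "chr1", 10, "C", "T")])
    res = mmr_region_ratio(muts, inside, meth)
    assert len(res) == 0


def test_mmr_simulated_early_depletion_detected():
    """MMRp-like depletion in early-replicating regions produces negative
    log2 ratios with a significant sign test."""
    from perseq.simulate import MutationSimConfig, simulate_mutation_dataset

    cfg = MutationSimConfig(
        n_samples=30, mutations_per_sample=600, seed=41,
        n_chromosomes=4, chrom_length=500_000,
        early_depletion=0.4,
    )
    data = simulate_mutation_dataset(cfg)
    q1 = data.domains["timing"].quantile(0.25)
    early = data.domains[data.domains["timing"] <= q1][["chrom", "start", "end"]]
    res = mmr_region_ratio(data.mutations, early, data.methylation)
    assert res["log2_ratio"].median() < -0.5
    assert sign_test(res["log2_ratio"]) < 1e-4


# ---------------------------------------------------------------------------
# de novo filter
# ---------------------------------------------------------------------------

def _dn_rows(pos, depths, alts, called, ref="C", alt="T"):
    return [
        {"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt, "sample": f"s{i}",
         "depth": d, "alt_reads": a, "called": c}
        for i, (d, a, c) in enumerate(zip(depths, alts, called))
    ]


def test_de_novo_filter_four_clauses():
    rows = []
    # retained: single-sample call, depths in window, VAF 0.5, clean elsewhere
    rows += _dn_rows(100, [20, 25, 30], [10, 0, 0], [True, False, False])
    # rejected: coverage 45 out of window in one sample
    rows += _dn_rows(200, [20, 45, 30], [10, 0, 0], [True, False, False])
    # rejected: VAF 0.2 below the window
    rows += _dn_rows(300, [20, 25, 30], [4, 0, 0], [True, False, False])
    # rejected: alt evidence in another sample
    rows += _dn_rows(400, [20, 25, 30], [10, 1, 0], [True, False, False])
    # rejected: called in two samples
    rows += _dn_rows(500, [20, 25, 30], [10, 12, 0], [True, True, False])
    # rejected: coverage 8 below window
    rows += _dn_rows(600, [8, 25, 30], [4, 0, 0], [True, False, False])
    # retained: VAF exactly at the boundaries is inclusive
    rows += _dn_rows(700, [40, 25, 30], [10, 0, 0], [True, False, False])
    kept = filter_de_novo(pd.DataFrame(rows))
    assert sorted(kept["pos"]) == [100, 700]
    assert (kept["sample"] == "s0").all()


def test_de_novo_missing_depth_excludes_site():
    rows = _dn_rows(100, [20, np.nan, 30], [10, 0, 0], [True, False, False])
    kept = filter_de_novo(pd.DataFrame(rows))
    assert len(kept) == 0


def test_de_novo_max_other_alt_flag():
    rows = _dn_rows(100, [20, 25, 30], [10, 1, 0], [True, False, False])
    assert len(filter_de_novo(pd.DataFrame(rows))) == 0
    assert len(filter_de_novo(pd.DataFrame(rows), max_other_alt=1)) == 1


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_sign_test_closed_forms():
    assert sign_test([1] * 8) == pytest.approx(2 * 0.5**8)
    assert sign_test([1] * 5 + [-1] * 5) == pytest.approx(1.0)
    assert sign_test([1]) == pytest.approx(1.0)
    assert sign_test([1, -1, 0, 2]) == sign_test([1, -1, 2])  # zeros dropped
    with pytest.raises(ValueError):
        sign_test([0, 0])


def oracle_two_sided_binomial(k, n):
    """Sum of all binomial(n, 1/2) outcomes no more likely than k."""
    from scipy.stats import binom

    pk = binom.pmf(k, n, 0.5)
    return float(
        sum(binom.pmf(j, n, 0.5) for j in range(n + 1)
            if binom.pmf(j, n, 0.5) <= pk * (1 + 1e-9))
    )


@settings(deadline=None, derandomize=True, max_examples=120)
@given(st.integers(min_value=1, max_value=30), st.data())
def test_sign_test_matches_binomial_enumeration(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    values = [1] * k + [-1] * (n - k)
    assert sign_test(values) == pytest.approx(
        min(oracle_two_sided_binomial(k, n), 1.0), rel=1e-9
    )


def test_welch_t_matches_hand_computation():
    # A={1,2,3}, B={11,12,13}: equal variances 1, pooled se = sqrt(2/3),
    # t = -10/sqrt(2/3), df = 4 by Welch-Satterthwaite
    p = rank_and_mean_tests([1, 2, 3], [11, 12, 13], mode="welch_t")
    import scipy.stats

    t = -10 / np.sqrt(2 / 3)
    expected = 2 * scipy.stats.t.sf(abs(t), df=4)
    assert p == pytest.approx(expected, rel=1e-12)


def test_mann_whitney_identical_groups_near_one():
    p = rank_and_mean_tests([1, 2, 3, 4], [1, 2, 3, 4], mode="mann_whitney")
    assert p > 0.8


def test_paired_identical_vectors_degenerate():
    with pytest.raises(ValueError, match="degenerate|equal"):
        rank_and_mean_tests([1, 2, 3], [1, 2, 3], mode="paired_t")
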