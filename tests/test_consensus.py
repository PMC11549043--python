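"""Consensus calling: threshold rules, oracle agreement, tabulation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perseq._channels import BASES, N_CODE, decode
from perseq.consensus import (
    ConsensusConfig,
    call_all_molecules,
    call_linear_copy,
    call_molecule,
    consensus_copies,
    group_linear_copies,
    tabulate_errors,
)
from perseq.readprep import ReadBatch
from perseq.roi import annotate_roi

REF = annotate_roi("ACGTACGTAC")  # 10 bp toy reference


def reads_at(pos, bases, ref=REF):
    """Build read call rows equal to the reference except `bases` at pos."""
    rows = []
    for b in bases:
        row = ref.codes.copy()
        row[pos] = "ACGTN".index(b)
        rows.append(row)
    return np.array(rows)


# ---------------------------------------------------------------------------
# copy-level rules
# ---------------------------------------------------------------------------

def test_unanimous_alt_is_a_copy_variant():
    cons = call_linear_copy(reads_at(1, "TTT"), REF)  # ref C at pos 1
    assert (1, "T") in cons.variant_positions
    assert cons.read_support == 3


def test_two_thirds_below_threshold_gives_n():
    # 2/3 = 0.667 < 0.70 for T, 1/3 for ref C: nothing reaches 70% -> N
    cons = call_linear_copy(reads_at(1, "TTC"), REF)
    assert cons.variant_positions == set()
    assert cons.consensus[1] == N_CODE


def test_minority_alt_keeps_reference():
    cons = call_linear_copy(reads_at(1, "TTTCCCCCCC"), REF)
    assert cons.variant_positions == set()
    assert cons.consensus[1] == 1  # C


def test_ns_do_not_vote():
    # 2 T + 2 N: informative n=2, T at 100% -> variant
    cons = call_linear_copy(reads_at(1, "TTNN"), REF)
    assert (1, "T") in cons.variant_positions


def test_empty_group_is_an_error():
    with pytest.raises(ValueError):
        call_linear_copy(np.empty((0, 10), dtype=np.uint8), REF)


# ---------------------------------------------------------------------------
# molecule-level rules
# ---------------------------------------------------------------------------

def _copies(variant_lists, umi="U1"):
    out = []
    for i, variants in enumerate(variant_lists):
        cons = REF.codes.copy()
        for pos, b in variants:
            cons[pos] = "ACGTN".index(b)
        out.append(
            call_linear_copy(cons[None, :], REF, umi=umi, ulci=f"L{i}")
        )
    return out


def test_variant_in_all_three_copies_is_called():
    mol = call_molecule(_copies([[(7, "C")], [(7, "C")], [(7, "C")]]), REF)
    assert mol is not None
    assert (7, "T", "C") in mol.variants


def test_single_copy_artifact_not_called():
    mol = call_molecule(_copies([[(7, "C")], [], []]), REF)
    assert mol is not None
    assert mol.variants == set()


def test_two_copies_discards_molecule():
    assert call_molecule(_copies([[(7, "C")], [(7, "C")]]), REF) is None


def test_mixed_umis_raise():
    copies = _copies([[], []], umi="U1") + _copies([[]], umi="U2")
    with pytest.raises(ValueError, match="mixed"):
        call_molecule(copies, REF)


def test_positions_with_too_few_informative_copies_excluded():
    # position 3 is N in two of three copies -> informative=1 < 3
    copies = _copies([[(3, "N")], [(3, "N")], [(3, "C")]])
    mol = call_molecule(copies, REF)
    assert mol is not None
    assert not mol.covered_positions[3]
    assert all(pos != 3 for pos, _, _ in mol.variants)


def test_group_linear_copies_structure():
    rows = [
        ("U1", "L1", REF.codes), ("U1", "L1", REF.codes), ("U1", "L2", REF.codes),
        ("U2", "L1", REF.codes),
    ]
    groups = group_linear_copies(rows)
    assert set(groups) == {("U1", "L1"), ("U1", "L2"), ("U2", "L1")}
    assert groups[("U1", "L1")].shape[0] == 2


# ---------------------------------------------------------------------------
# brute-force oracle: independent exhaustive reimplementation
# ---------------------------------------------------------------------------

def oracle_copy_consensus(read_rows, agreement=0.70):
    """Dict/loop reimplementation of the copy consensus rule."""
    n_pos = len(read_rows[0])
    cons = []
    for p in range(n_pos):
        obs = [r[p] for r in read_rows if r[p] != 4]
        if not obs:
            cons.append(4)
            continue
        counts = {b: obs.count(b) for b in set(obs)}
        best = min([b for b, c in counts.items()
                    if c == max(counts.values())])
        if counts[best] / len(obs) >= agreement - 1e-12:
            cons.append(best)
        else:
            cons.append(4)
    return cons


def oracle_molecule_call(copy_rows, ref_codes, agreement=0.70, min_copies=3):
    if len(copy_rows) < min_copies:
        return None
    variants = set()
    covered = []
    for p in range(len(ref_codes)):
        obs = [r[p] for r in copy_rows if r[p] != 4]
        covered.append(len(obs) >= min_copies)
        if not covered[-1]:
            continue
        counts = {b: obs.count(b) for b in set(obs)}
        best = min([b for b, c in counts.items() if c == max(counts.values())])
        if best != ref_codes[p] and counts[best] / len(obs) >= agreement - 1e-12:
            variants.add((p, best))
    return variants, covered


base_or_n = st.integers(min_value=0, max_value=4)
read_row = st.lists(base_or_n, min_size=6, max_size=6)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.lists(read_row, min_size=1, max_size=5))
def test_copy_consensus_matches_exhaustive_oracle(rows):
    ref = annotate_roi("ACGTAC")
    mat = np.array(rows, dtype=np.uint8)
    cons = call_linear_copy(mat, ref)
    expected = oracle_copy_consensus(rows)
    # the oracle breaks count ties by smallest base; ties cannot pass the
    # >0.5 agreement threshold, so tie-breaking never matters
    assert list(cons.consensus) == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.lists(read_row, min_size=1, max_size=5))
def test_molecule_call_matches_exhaustive_oracle(rows):
    ref = annotate_roi("ACGTAC")
    copies = [
        call_linear_copy(np.array([r], dtype=np.uint8), ref, umi="U", ulci=f"L{i}")
        for i, r in enumerate(rows)
    ]
    mol = call_molecule(copies, ref)
    expected = oracle_molecule_call([c.consensus for c in copies], ref.codes)
    if expected is None:
        assert mol is None
    else:
        variants, covered = expected
        assert {(p, BASES.index(a)) for p, _, a in mol.variants} == variants
        assert list(mol.covered_positions) == covered


# ---------------------------------------------------------------------------
# vectorized engine equals the per-object path
# ---------------------------------------------------------------------------

@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_vectorized_engine_matches_object_api(seed):
    rng = np.random.default_rng(seed)
    ref = annotate_roi(decode(rng.integers(0, 4, 30).astype(np.uint8)))
    umis, ulcis, rows = [], [], []
    for m in range(rng.integers(3, 12)):
        umi = f"U{m:03d}"
        for c in range(rng.integers(1, 6)):
            ulci = f"L{c}"
            for _ in range(rng.integers(1, 4)):
                row = ref.codes.copy()
                # sprinkle random substitutions and Ns
                k = rng.integers(0, 4)
                pos = rng.integers(0, 30, size=k)
                row[pos] = rng.integers(0, 5, size=k)
                umis.append(umi)
                ulcis.append(ulci)
                rows.append(row)
    batch = ReadBatch(
        umis=np.array(umis, dtype=object),
        ulcis=np.array(ulcis, dtype=object),
        calls=np.array(rows, dtype=np.uint8),
    )
    mcs = call_all_molecules(batch, ref)

    # object-level reference path
    groups = group_linear_copies(batch)
    by_umi = {}
    for (umi, ulci), mat in groups.items():
        by_umi.setdefault(umi, []).append(
            call_linear_copy(mat, ref, umi=umi, ulci=ulci)
        )
    expected = {}
    for umi, copies in by_umi.items():
        mol = call_molecule(copies, ref)
        if mol is not None:
            expected[umi] = mol

    assert set(mcs.umis) == set(expected)
    got_variants = {
        (mcs.umis[r.mol], r.pos, r.alt)
        for r in mcs.variants.itertuples()
    }
    want_variants = {
        (umi, p, a) for umi, mol in expected.items() for p, _, a in mol.variants
    }
    assert got_variants == want_variants
    want_cov = np.zeros(30, dtype=np.int64)
    for mol in expected.values():
        want_cov += mol.covered_positions
    assert np.array_equal(mcs.coverage, want_cov)


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def _batch_one_molecule_variant():
    """Three copies of one molecule, all carrying C>T in the ACG at pos 1."""
    rows, umis, ulcis = [], [], []
    for c in range(3):
        row = REF.codes.copy()
        row[1] = 3  # T
        rows.append(row)
        umis.append("U1")
        ulcis.append(f"L{c}")
    return ReadBatch(np.array(umis, object), np.array(ulcis, object),
                     np.array(rows, dtype=np.uint8))


def test_tabulate_single_variant_hits_its_channel():
    mcs = call_all_molecules(_batch_one_molecule_variant(), REF)
    tab = tabulate_errors(mcs, REF)
    hit = tab[(tab["context"] == "ACG") & (tab["alt"] == "T")]
    assert hit["count"].iloc[0] == 1
    assert tab["count"].sum() == 1
    # opportunities: one molecule fully covered over 8 internal positions
    assert tab.groupby("context")["opportunity"].first().sum() == 8


def test_tabulate_empty_input_is_all_zero():
    empty = ReadBatch(np.empty(0, object), np.empty(0, object),
                      np.empty((0, 10), np.uint8))
    mcs = call_all_molecules(empty, REF)
    tab = tabulate_errors(mcs, REF)
    assert tab["count"].sum() == 0
    assert tab["opportunity"].sum() == 0


def test_injected_channel_rate_recovered_within_poisson(small_noisy_calls):
    """A uniform 1e-3 true error rate should be recovered by the pipeline
    within Poisson sampling error of the aggregate count."""
    lib, _batch, mcs, _report = small_noisy_calls
    tab = tabulate_errors(mcs, lib.annotation)
    total = tab["count"].sum()
    opp = tab.groupby("context")["opportunity"].first().sum()
    expected = 1e-3 * opp
    assert abs(total - expected) <= 3 * np.sqrt(expected)
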