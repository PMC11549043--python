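"""Signature algebra: frequencies, background subtraction, strand collapse,
PDF scaling, context-class rates."""
import numpy as np
import pandas as pd
import pytest

from perseq._channels import CHANNEL_192_INDEX, CHANNELS_192
from perseq.roi import annotate_roi
from perseq.signatures import (
    BackgroundEstimate,
    ErrorSignature,
    MissingClassError,
    collapse_strand,
    compute_signature,
    context_class_rate,
    scale_pdf,
    subtract_background,
    total_error_frequency,
)


def _table(counts=None, opportunities=None):
    df = pd.DataFrame(
        {
            "context": [t for t, _ in CHANNELS_192],
            "alt": [a for _, a in CHANNELS_192],
            "count": counts if counts is not None else np.zeros(192, int),
            "opportunity": (opportunities if opportunities is not None
                            else np.full(192, 1000)),
        }
    )
    return df


def test_frequency_is_count_over_opportunity():
    counts = np.zeros(192, int)
    counts[0] = 2
    sig = compute_signature(_table(counts))
    assert sig.frequencies[0] == pytest.approx(2e-3)
    assert sig.frequencies[1:].sum() == 0


def test_zero_opportunity_channels_flagged():
    opp = np.full(192, 1000)
    opp[5] = 0
    sig = compute_signature(_table(opportunities=opp))
    assert sig.frequencies[5] == 0
    assert sig.zero_opportunity[5]
    assert not sig.zero_opportunity[0]


def test_negative_counts_rejected():
    counts = np.zeros(192, int)
    counts[0] = -1
    with pytest.raises(ValueError):
        compute_signature(_table(counts))


def test_background_subtraction_arithmetic_and_clamp():
    filled = ErrorSignature(np.full(192, 5e-5))
    bg = BackgroundEstimate(np.full(192, 1e-5), np.full(192, 1e-5))
    out = subtract_background(filled, bg)
    assert np.allclose(out.frequencies, 3e-5)
    # background exceeding the signal clamps at zero
    big = BackgroundEstimate(np.full(192, 1e-3), np.zeros(192))
    assert np.all(subtract_background(filled, big).frequencies == 0)
    # zero background is the identity
    ident = subtract_background(filled, BackgroundEstimate.zero())
    assert np.array_equal(ident.frequencies, filled.frequencies)
    # counts are invalidated after subtraction
    assert ident.counts is None


def test_collapse_strand_pairing_example():
    freqs = np.zeros(192)
    freqs[CHANNEL_192_INDEX[("ACG", "T")]] = 4e-5
    freqs[CHANNEL_192_INDEX[("CGT", "A")]] = 2e-5
    sig96 = collapse_strand(ErrorSignature(freqs))
    df = sig96.to_frame()
    row = df[(df["context"] == "ACG") & (df["alt"] == "T")]
    assert row["frequency"].iloc[0] == pytest.approx(3e-5)


def test_collapse_strand_symmetric_input_is_fixed_point():
    rng = np.random.default_rng(0)
    half = rng.random(96)
    freqs = np.zeros(192)
    from perseq._channels import COLLAPSE_PAIRS

    freqs[COLLAPSE_PAIRS[:, 0]] = half
    freqs[COLLAPSE_PAIRS[:, 1]] = half
    sig96 = collapse_strand(ErrorSignature(freqs))
    assert np.allclose(sig96.frequencies, half)


def test_collapse_conserves_mean():
    rng = np.random.default_rng(1)
    sig = ErrorSignature(rng.random(192))
    sig96 = collapse_strand(sig)
    assert sig96.frequencies.mean() == pytest.approx(sig.frequencies.mean())


def test_double_collapse_is_an_error():
    sig96 = collapse_strand(ErrorSignature(np.ones(192)))
    with pytest.raises(ValueError):
        collapse_strand(sig96)


def test_total_error_frequency_examples():
    assert total_error_frequency(ErrorSignature(np.full(192, 3e-6))) == pytest.approx(3e-6)
    one = np.zeros(192)
    one[7] = 192e-6
    assert total_error_frequency(ErrorSignature(one)) == pytest.approx(1e-6)
    rng = np.random.default_rng(2)
    v = rng.random(192)
    assert total_error_frequency(ErrorSignature(v)) == pytest.approx(
        sum(v) / 192
    )
    with pytest.raises(ValueError):
        total_error_frequency(ErrorSignature(np.full(192, 1 / 192), scale="pdf"))


def test_scale_pdf():
    sig = ErrorSignature(np.array([1.0, 1.0, 2.0] + [0.0] * 189))
    pdf = scale_pdf(sig)
    assert pdf.frequencies[:3] == pytest.approx([0.25, 0.25, 0.5])
    assert pdf.frequencies.sum() == pytest.approx(1.0, abs=1e-12)
    # idempotent
    again = scale_pdf(pdf)
    assert np.allclose(again.frequencies, pdf.frequencies)
    with pytest.raises(ValueError):
        scale_pdf(ErrorSignature(np.zeros(192)))


def test_tsv_roundtrip_bit_exact(tmp_path):
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 50, 192)
    opp = rng.integers(100, 10_000, 192)
    sig = compute_signature(_table(counts, opp))
    p = tmp_path / "sig.tsv"
    sig.to_tsv(p)
    back = ErrorSignature.from_tsv(p)
    assert np.array_equal(back.counts, sig.counts)
    assert np.array_equal(back.opportunities, sig.opportunities)
    assert np.array_equal(back.frequencies, sig.frequencies)
    # a reordered file is rejected
    df = pd.read_csv(p, sep="\t").iloc[::-1]
    df.to_csv(p, sep="\t", index=False)
    with pytest.raises(ValueError, match="ordering"):
        ErrorSignature.from_tsv(p)


# ---------------------------------------------------------------------------
# context-class rates
# ---------------------------------------------------------------------------

# a template with CpG (ACGT), dcm (CCAGG) and CpH (TCTT) contexts, padded
# so classes map to distinct trinucleotides
ROI_CLASSY = annotate_roi("AACGTTCCAGGTTCTTAA", "m_sssi")


def test_class_rate_single_channel():
    freqs = np.zeros(192)
    # the CpG at position 2 sits in trinucleotide ACG
    freqs[CHANNEL_192_INDEX[("ACG", "T")]] = 7e-5
    sig = ErrorSignature(freqs)
    assert context_class_rate(sig, ROI_CLASSY, "CpG", "T") == pytest.approx(7e-5)


def test_class_rate_uniform_c_channels():
    freqs = np.zeros(192)
    for (t, a), i in CHANNEL_192_INDEX.items():
        if t[1] == "C" and a == "T":
            freqs[i] = 5e-5
    sig = ErrorSignature(freqs)
    for cls in ("CpG", "dcm", "CpH"):
        assert context_class_rate(sig, ROI_CLASSY, cls, "T") == pytest.approx(5e-5)


def test_class_rate_missing_class_flagged():
    ann = annotate_roi("AACGTT")  # no dcm context
    sig = ErrorSignature(np.zeros(192))
    with pytest.raises(MissingClassError):
        context_class_rate(sig, ann, "dcm", "T")


def test_methylated_cpg_rate_ratio_recovered(tmp_path):
    """Simulated 2.6-fold methylated/unmethylated CpG C>T rate ratio is
    recovered from the full pipeline within sampling error."""
    from perseq.consensus import call_all_molecules, tabulate_errors
    from perseq.readprep import process_paired_fastq
    from perseq.simulate import ErrorModel, LibrarySimConfig, simulate_library

    rng = np.random.default_rng(21)
    rates = np.zeros((64, 3))
    for (t, a), i in CHANNEL_192_INDEX.items():
        if t[1] == "C" and a == "T":
            rates[i // 3, i % 3] = 5e-4
    results = {}
    for mode in ("m_sssi", "mock"):
        cfg = LibrarySimConfig(
            n_molecules=15_000, seed=22, roi_length=250,
            methylation_mode=mode,
            error_model=ErrorModel(rates, methylated_multiplier=2.6),
            artifact_rate=0.0, seq_error_rate=0.0,
        )
        lib = simulate_library(cfg, tmp_path / mode)
        batches, _ = process_paired_fastq(
            lib.fastq1, lib.fastq2, cfg.layout, lib.sample_sheet, lib.annotation
        )
        mcs = call_all_molecules(batches[lib.sample_id], lib.annotation)
        sig = compute_signature(tabulate_errors(mcs, lib.annotation))
        results[mode] = context_class_rate(sig, lib.annotation, "CpG", "T")
    ratio = results["m_sssi"] / results["mock"]
    assert 2.0 < ratio < 3.3
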