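"""Read preparation: barcode layout parsing, demultiplexing, ROI alignment.

The sequencing library has a fixed structure: read 1 carries
``[sample_bc_part1][19-bp UMI][ROI 5' portion]`` and read 2 carries
``[sample_bc_part2][4-bp ULCI][reverse-complemented ROI 3' portion]``.
Because the amplicon is a known fixed sequence, alignment is gapless and
anchored: read 1 maps to the template 5' end, reverse-complemented read 2
to the 3' end.  Reads with too many substitutions (apparent indels shift
the frame and blow past the mismatch ceiling) or too many Ns are excluded
from substitution analysis.  Where the pair overlaps and disagrees the
position is masked to N — the consensus layers absorb Ns.

Bases below the Phred quality threshold are masked to N before any
consensus is taken.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from ._channels import ASCII_TO_CODE, COMP, N_CODE
from .roi import ROIAnnotation


@dataclass(frozen=True)
class BarcodeLayout:
    """Fixed prefix layout of the paired reads.

    The sample barcode is split across the two reads (usually 3+3 bp);
    the 19-bp UMI follows on read 1 and the 4-bp ULCI on read 2.
    """

    sample_bc_read1_len: int = 3
    sample_bc_read2_len: int = 3
    umi_len: int = 19
    ulci_len: int = 4

    def __post_init__(self):
        if min(self.sample_bc_read1_len, self.sample_bc_read2_len) < 0:
            raise ValueError("barcode lengths must be >= 0")
        if self.umi_len < 0 or self.ulci_len < 0:
            raise ValueError("UMI/ULCI lengths must be >= 0")
        if self.umi_len + self.ulci_len == 0:
            raise ValueError("umi_len + ulci_len must be > 0")

    @property
    def prefix1_len(self) -> int:
        return self.sample_bc_read1_len + self.umi_len

    @property
    def prefix2_len(self) -> int:
        return self.sample_bc_read2_len + self.ulci_len

    @property
    def sample_bc_len(self) -> int:
        return self.sample_bc_read1_len + self.sample_bc_read2_len


@dataclass
class ParseFailure:
    reason: str


@dataclass
class ParsedPair:
    sample_bc: str
    umi: str
    ulci: str
    roi_seq1: str
    roi_seq2: str
    qual1: str = ""
    qual2: str = ""


def parse_read_pair(read1, read2, layout: BarcodeLayout):
    """Split a read pair into barcodes and ROI portions.

    `read1`/`read2` are ``(id, sequence, quality)`` tuples.  Returns a
    :class:`ParsedPair`, or a :class:`ParseFailure` when a read is shorter
    than its barcode prefix.  Mismatched pair identifiers raise.
    """
    id1, seq1, q1 = read1
    id2, seq2, q2 = read2
    if _pair_key(id1) != _pair_key(id2):
        raise ValueError(f"read pair identifiers do not match: {id1!r} vs {id2!r}")
    if len(seq1) < layout.prefix1_len or len(seq2) < layout.prefix2_len:
        return ParseFailure("short_read")
    b1 = layout.sample_bc_read1_len
    b2 = layout.sample_bc_read2_len
    return ParsedPair(
        sample_bc=seq1[:b1] + seq2[:b2],
        umi=seq1[b1 : b1 + layout.umi_len],
        ulci=seq2[b2 : b2 + layout.ulci_len],
        roi_seq1=seq1[layout.prefix1_len :],
        roi_seq2=seq2[layout.prefix2_len :],
        qual1=q1[layout.prefix1_len :],
        qual2=q2[layout.prefix2_len :],
    )


def _pair_key(read_id: str) -> str:
    # strip trailing /1 or /2 and anything after the first whitespace
    key = read_id.split()[0]
    if key.endswith("/1") or key.endswith("/2"):
        key = key[:-2]
    return key


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_sample_sheet(sample_sheet: Dict[str, str], layout: BarcodeLayout,
                          max_mismatch: int) -> None:
    """Check barcode lengths and pairwise separation of the sample sheet."""
    for bc in sample_sheet:
        if len(bc) != layout.sample_bc_len:
            raise ValueError(
                f"barcode {bc!r} length {len(bc)} != layout sample barcode "
                f"length {layout.sample_bc_len}"
            )
    bcs = list(sample_sheet)
    for i in range(len(bcs)):
        for j in range(i + 1, len(bcs)):
            d = _hamming(bcs[i], bcs[j])
            if d <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {bcs[i]!r} and {bcs[j]!r} are Hamming distance "
                    f"{d} apart; need > {2 * max_mismatch} for "
                    f"max_mismatch={max_mismatch}"
                )


def assign_barcode(bc: str, sample_sheet: Dict[str, str], max_mismatch: int
                   ) -> Optional[str]:
    """Assign an observed sample barcode to a sample, or None (unassigned)."""
    if bc in sample_sheet:
        return sample_sheet[bc]
    if max_mismatch == 0:
        return None
    best, best_d = None, max_mismatch + 1
    for sheet_bc, sample in sample_sheet.items():
        d = _hamming(bc, sheet_bc)
        if d < best_d:
            best, best_d = sample, d
        elif d == best_d:
            best = None  # ambiguous at this distance
    return best if best_d <= max_mismatch else None


def demultiplex(
    pairs: Iterable,
    sample_sheet: Dict[str, str],
    layout: BarcodeLayout,
    max_mismatch: int = 0,
) -> Tuple[Dict[str, List[ParsedPair]], int]:
    """Partition parsed pairs by sample barcode.

    Returns ``(per_sample_lists, unassigned_count)``.  The partition is
    exact: every pair lands in exactly one sample or in the unassigned
    count.
    """
    validate_sample_sheet(sample_sheet, layout, max_mismatch)
    out: Dict[str, List[ParsedPair]] = {s: [] for s in sample_sheet.values()}
    unassigned = 0
    cache: Dict[str, Optional[str]] = {}
    for p in pairs:
        if isinstance(p, ParseFailure):
            unassigned += 1
            continue
        if p.sample_bc in cache:
            sample = cache[p.sample_bc]
        else:
            sample = assign_barcode(p.sample_bc, sample_sheet, max_mismatch)
            cache[p.sample_bc] = sample
        if sample is None:
            unassigned += 1
        else:
            out[sample].append(p)
    return out, unassigned


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _codes_block(seqs: List[str], length: int) -> np.ndarray:
    """Stack equal-length sequences into an (n, length) code matrix."""
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return ASCII_TO_CODE[buf].reshape(len(seqs), length)


def _qual_block(quals: List[str], length: int) -> np.ndarray:
    buf = np.frombuffer("".join(quals).encode("ascii"), dtype=np.uint8)
    return buf.reshape(len(quals), length)


def align_block(
    seqs1: List[str],
    seqs2: List[str],
    reference: ROIAnnotation,
    quals1: Optional[List[str]] = None,
    quals2: Optional[List[str]] = None,
    max_mismatch_frac: float = 0.10,
    max_n_frac: float = 0.50,
    min_phred: int = 20,
    phred_offset: int = 33,
) -> Tuple[np.ndarray, np.ndarray]:
    """Gapless anchored alignment of a block of equal-length read pairs.

    Read 1 ROI portions anchor at the template 5' end; reverse-complemented
    read 2 portions anchor at the 3' end.  Returns ``(calls, pass_mask)``
    where `calls` is an (n, L) uint8 matrix over {A,C,G,T,N} codes.
    """
    L = len(reference)
    ref = reference.codes
    n = len(seqs1)
    l1 = len(seqs1[0]) if n else 0
    l2 = len(seqs2[0]) if n else 0
    calls = np.full((n, L), N_CODE, dtype=np.uint8)
    if n == 0:
        return calls, np.zeros(0, dtype=bool)

    c1 = _codes_block(seqs1, l1)
    c2 = _codes_block(seqs2, l2)
    if quals1 is not None:
        q1 = _qual_block(quals1, l1)
        c1 = np.where(q1 < min_phred + phred_offset, N_CODE, c1)
    if quals2 is not None:
        q2 = _qual_block(quals2, l2)
        c2 = np.where(q2 < min_phred + phred_offset, N_CODE, c2)

    w1 = min(l1, L)
    w2 = min(l2, L)
    calls[:, :w1] = c1[:, :w1]
    # reverse-complement read2, anchored to the 3' end
    r2 = COMP[c2[:, :w2][:, ::-1]]
    start2 = L - w2
    if w1 <= start2:
        calls[:, start2:] = r2
    else:
        # overlap region [start2, w1): merge with N on disagreement
        calls[:, w1:] = r2[:, w1 - start2 :]
        a = calls[:, start2:w1]
        b = r2[:, : w1 - start2]
        merged = np.where(a == N_CODE, b, np.where((b == N_CODE) | (a == b), a, N_CODE))
        calls[:, start2:w1] = merged

    span = min(L, w1 + w2)  # number of positions the pair covers
    non_n = calls != N_CODE
    n_non_n = non_n.sum(axis=1)
    mismatches = (non_n & (calls != ref[None, :])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mis_frac = np.where(n_non_n > 0, mismatches / np.maximum(n_non_n, 1), 1.0)
    n_frac = (span - n_non_n) / max(span, 1)
    pass_mask = (mis_frac <= max_mismatch_frac) & (n_frac <= max_n_frac)
    return calls, pass_mask


def align_to_roi(
    roi_seq1: str,
    roi_seq2: str,
    reference: ROIAnnotation,
    max_mismatch_frac: float = 0.10,
    max_n_frac: float = 0.50,
    qual1: Optional[str] = None,
    qual2: Optional[str] = None,
    min_phred: int = 20,
):
    """Align one read pair's ROI portions to the reference.

    Returns ``(aligned_calls, passed)``; `aligned_calls` is a length-L
    uint8 code vector with N at uncovered/masked positions.
    """
    if reference is None:
        raise ValueError("reference ROI annotation is required")
    calls, ok = align_block(
        [roi_seq1],
        [roi_seq2],
        reference,
        [qual1] if qual1 is not None else None,
        [qual2] if qual2 is not None else None,
        max_mismatch_frac=max_mismatch_frac,
        max_n_frac=max_n_frac,
        min_phred=min_phred,
    )
    return calls[0], bool(ok[0])


# ---------------------------------------------------------------------------
# FASTQ streaming and the batch demux+align pipeline stage
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def stream_read_pairs(fastq1, fastq2) -> Iterator[Tuple[tuple, tuple]]:
    """Yield synchronized ``(read1, read2)`` record tuples from paired FASTQ."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(fastq1) as f1, _open_text(fastq2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for r1 in it1:
            try:
                r2 = next(it2)
            except StopIteration:
                raise ValueError("read 2 file ended before read 1 file")
            yield r1, r2


@dataclass
class ReadBatch:
    """Aligned reads for one sample: parallel arrays over reads."""

    umis: np.ndarray  # str array
    ulcis: np.ndarray  # str array
    calls: np.ndarray  # (n_reads, L) uint8

    def __len__(self) -> int:
        return len(self.umis)


@dataclass
class DemuxReport:
    total_pairs: int = 0
    short_read: int = 0
    unassigned: int = 0
    assigned: Dict[str, int] = field(default_factory=dict)
    failed_alignment: Dict[str, int] = field(default_factory=dict)
    passed: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "short_read": self.short_read,
            "unassigned": self.unassigned,
            "assigned": dict(self.assigned),
            "failed_alignment": dict(self.failed_alignment),
            "passed": dict(self.passed),
        }


def process_paired_fastq(
    fastq1,
    fastq2,
    layout: BarcodeLayout,
    sample_sheet: Dict[str, str],
    reference: ROIAnnotation,
    max_mismatch: int = 0,
    max_mismatch_frac: float = 0.10,
    max_n_frac: float = 0.50,
    min_phred: int = 20,
    chunk_size: int = 200_000,
) -> Tuple[Dict[str, ReadBatch], DemuxReport]:
    """Demultiplex and align a paired FASTQ library.

    Streams the files in chunks, demultiplexes on the split sample barcode
    and aligns ROI portions with the gapless anchored aligner.  Returns
    per-sample :class:`ReadBatch` objects plus an attrition report
    satisfying ``total = short_read + unassigned + failed + passed``.
    """
    validate_sample_sheet(sample_sheet, layout, max_mismatch)
    report = DemuxReport()
    samples = sorted(set(sample_sheet.values()))
    for s in samples:
        report.assigned[s] = 0
        report.failed_alignment[s] = 0
        report.passed[s] = 0

    acc: Dict[str, dict] = {
        s: {"umi": [], "ulci": [], "calls": []} for s in samples
    }
    bc_cache: Dict[str, Optional[str]] = {}
    b1 = layout.sample_bc_read1_len
    b2 = layout.sample_bc_read2_len
    p1 = layout.prefix1_len
    p2 = layout.prefix2_len

    # chunk buffers keyed by (sample, len1, len2) so blocks are rectangular
    def flush(buf):
        for (sample, _l1, _l2), d in buf.items():
            calls, ok = align_block(
                d["s1"], d["s2"], reference, d["q1"], d["q2"],
                max_mismatch_frac=max_mismatch_frac,
                max_n_frac=max_n_frac, min_phred=min_phred,
            )
            n_ok = int(ok.sum())
            report.failed_alignment[sample] += len(ok) - n_ok
            report.passed[sample] += n_ok
            if n_ok:
                acc[sample]["umi"].append(np.asarray(d["umi"], dtype=object)[ok])
                acc[sample]["ulci"].append(np.asarray(d["ulci"], dtype=object)[ok])
                acc[sample]["calls"].append(calls[ok])

    buf: Dict[tuple, dict] = {}
    in_buf = 0
    for (id1, seq1, q1), (id2, seq2, q2) in stream_read_pairs(fastq1, fastq2):
        report.total_pairs += 1
        if len(seq1) < p1 or len(seq2) < p2:
            report.short_read += 1
            continue
        bc = seq1[:b1] + seq2[:b2]
        sample = bc_cache.get(bc, "?")
        if sample == "?":
            sample = assign_barcode(bc, sample_sheet, max_mismatch)
            bc_cache[bc] = sample
        if sample is None:
            report.unassigned += 1
            continue
        report.assigned[sample] += 1
        key = (sample, len(seq1), len(seq2))
        d = buf.get(key)
        if d is None:
            d = buf[key] = {"umi": [], "ulci": [], "s1": [], "s2": [],
                            "q1": [], "q2": []}
        d["umi"].append(seq1[b1:p1])
        d["ulci"].append(seq2[b2:p2])
        d["s1"].append(seq1[p1:])
        d["s2"].append(seq2[p2:])
        d["q1"].append(q1[p1:])
        d["q2"].append(q2[p2:])
        in_buf += 1
        if in_buf >= chunk_size:
            flush(buf)
            buf, in_buf = {}, 0
    flush(buf)

    L = len(reference)
    batches: Dict[str, ReadBatch] = {}
    for s in samples:
        if acc[s]["calls"]:
            batches[s] = ReadBatch(
                umis=np.concatenate(acc[s]["umi"]),
                ulcis=np.concatenate(acc[s]["ulci"]),
                calls=np.concatenate(acc[s]["calls"], axis=0),
            )
        else:
            batches[s] = ReadBatch(
                umis=np.empty(0, dtype=object),
                ulcis=np.empty(0, dtype=object),
                calls=np.empty((0, L), dtype=np.uint8),
            )
    return batches, report


def read_sample_sheet(path) -> Dict[str, str]:
    """Read a two-column (sample_id, barcode) TSV into barcode->sample."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" in cols and "barcode" in cols:
        pairs = zip(df[cols["barcode"]], df[cols["sample_id"]])
    else:  # headerless fallback
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        pairs = zip(df[1], df[0])
    return {bc: s for bc, s in pairs}
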