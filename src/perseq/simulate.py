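"""Synthetic data generation: sequencing libraries and mutation datasets.

Two generators live here.

:func:`simulate_library` emulates the barcoded linear-amplification
library structure: each template molecule receives a unique 19-bp UMI and
carries true polymerase errors drawn per daughter-strand position; the
molecule is linearly amplified into 7-10 copies (uniform by default),
each with a distinct 4-bp ULCI and independent damage/amplification
artifacts (transition-biased, deamination-like); every copy is sequenced
into one or more read pairs with independent per-base sequencing errors.
Paired FASTQ files in the barcode-layout dialect are written together
with ground-truth tables, so every called variant downstream can be
classified as true/spike/artifact/sequencing by joining on truth.

:func:`simulate_mutation_dataset` builds a synthetic genome with
alternating 20-kb left/right replication domains, a per-CpG methylation
map and peak regions, and draws per-sample mutation tables from a
96-channel signature PDF with configurable leading-strand enrichment,
methylation dependence and replication-timing depletion — the structure
the strand/methylation analyses assume.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._channels import (
    BASES,
    CHANNELS_96,
    CODE_TO_ASCII,
    COMP,
    TRINUC_INDEX,
    TRINUCS,
    encode,
    revcomp,
    trinuc_codes,
)
from .readprep import BarcodeLayout
from .roi import CLASS_CPG, CLASS_DCM, ROIAnnotation, annotate_roi

# transitions in code space: A<->G, C<->T
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion partners of each base
_TRANSVERSIONS = np.array(
    [[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8
)


# ---------------------------------------------------------------------------
# error model
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """Per-replication misincorporation rates on the daughter strand.

    ``channel_rates[t, r]`` is the per-position probability that the
    template trinucleotide with code t is copied with alt rank r (alts
    ordered alphabetically among the three non-template bases).  Optional
    class multipliers scale all alt rates at CpG/dcm/CpH positions, and
    ``methylated_multiplier`` additionally scales methylated cytosines —
    emulating the elevated C:dA rate at (methylated) CpGs.
    """

    channel_rates: np.ndarray  # (64, 3)
    class_multipliers: Dict[str, float] = field(default_factory=dict)
    methylated_multiplier: float = 1.0

    def __post_init__(self):
        self.channel_rates = np.asarray(self.channel_rates, dtype=float)
        if self.channel_rates.shape != (64, 3):
            raise ValueError("channel_rates must be (64, 3)")
        if np.any(self.channel_rates < 0) or np.any(self.channel_rates > 1):
            raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def uniform(cls, per_position_rate: float) -> "ErrorModel":
        """Same total error rate at every position, uniform over alts."""
        return cls(np.full((64, 3), per_position_rate / 3.0))

    @classmethod
    def single_channel(cls, trinuc: str, alt: str, rate: float) -> "ErrorModel":
        rates = np.zeros((64, 3))
        t = TRINUC_INDEX[trinuc]
        alts = [b for b in BASES if b != trinuc[1]]
        rates[t, alts.index(alt)] = rate
        return cls(rates)

    def positional_rates(self, annotation: ROIAnnotation) -> np.ndarray:
        """(L, 3) per-position alt-rank rates (zero at the terminal
        positions, which have no trinucleotide context)."""
        L = len(annotation)
        out = np.zeros((L, 3))
        tri = annotation.trinuc
        ok = tri >= 0
        out[ok] = self.channel_rates[tri[ok]]
        if self.class_multipliers:
            mult = np.ones(L)
            for cls_name, f in self.class_multipliers.items():
                pos = annotation.class_positions(cls_name)
                mult[pos] = f
            out *= mult[:, None]
        if self.methylated_multiplier != 1.0:
            out[annotation.is_methylated] *= self.methylated_multiplier
        return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass
class LibrarySimConfig:
    """Study conditions for a simulated library.

    Defaults mirror the assay: 7-10 linear copies per molecule (uniform),
    19-bp UMI / 4-bp ULCI / split 6-bp sample barcode, 150-bp paired-end
    reads, one read pair per linear copy at desk scale, deamination-like
    (transition-biased) per-copy artifacts.
    """

    n_molecules: int
    seed: int
    roi_sequence: Optional[str] = None
    roi_length: int = 250
    methylation_mode: str = "m_sssi"
    copy_number_choices: Tuple[int, ...] = (7, 8, 9, 10)
    copy_number_probs: Optional[Tuple[float, ...]] = None  # uniform if None
    reads_per_copy: int = 1
    error_model: ErrorModel = field(
        default_factory=lambda: ErrorModel.uniform(1e-5)
    )
    artifact_rate: float = 1e-3
    artifact_transition_fraction: float = 0.9
    seq_error_rate: float = 1e-3
    layout: BarcodeLayout = field(default_factory=BarcodeLayout)
    sample_barcode: str = "ACGTGA"
    read_length: int = 150

    def __post_init__(self):
        for r in (self.artifact_rate, self.seq_error_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if not (0.0 <= self.artifact_transition_fraction <= 1.0):
            raise ValueError("artifact_transition_fraction must lie in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_molecules > 4**19 // 100:
            raise ValueError(
                "n_molecules too large for the 19-bp UMI space "
                "(collision risk no longer negligible)"
            )
        if len(self.sample_barcode) != self.layout.sample_bc_len:
            raise ValueError("sample_barcode length must match the layout")
        if min(self.copy_number_choices) < 1 or max(self.copy_number_choices) > 15:
            raise ValueError("linear copy numbers must lie in 1..15")
        if self.reads_per_copy < 1:
            raise ValueError("reads_per_copy must be >= 1")


@dataclass
class SpikeInConfig:
    """Mutant templates spiked at fixed dilutions.

    Each mutant carries six substitutions, three near each end of the
    ROI.  ``mutants[i]`` is a list of (0-based pos, alt base) pairs; if
    None, mutants are generated to match the dilution list.
    """

    dilutions: Tuple[float, ...] = (1e-1, 1e-3, 1e-5)
    mutants: Optional[List[List[Tuple[int, str]]]] = None
    end_window: int = 40

    EXTENDED_DILUTIONS = (1e-1, 1e-2, 1e-3, 1e-4, 2e-5, 1e-6)

    def __post_init__(self):
        for d in self.dilutions:
            if not (0.0 < d < 1.0):
                raise ValueError("dilutions must lie in (0, 1)")
        if sum(self.dilutions) >= 1.0:
            raise ValueError("total spike fraction must be < 1")


@dataclass
class SimulatedLibrary:
    """A simulated library: file paths plus in-memory ground truth."""

    fastq1: Path
    fastq2: Path
    annotation: ROIAnnotation
    config: LibrarySimConfig
    truth_molecules: pd.DataFrame  # mol, umi, n_copies
    truth_variants: pd.DataFrame  # mol, pos (0-based), ref, alt, origin
    truth_artifacts: pd.DataFrame  # copy, mol, pos (0-based), ref, alt
    expected_spikes: Optional[pd.DataFrame] = None  # mutant, pos, ref, alt, expected_frequency
    sample_id: str = "sim"

    def write_truth(self, outdir) -> None:
        outdir = Path(outdir)
        self.truth_molecules.to_csv(outdir / "truth_molecules.tsv", sep="\t", index=False)
        self.truth_variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
        self.truth_artifacts.to_csv(outdir / "truth_artifacts.tsv", sep="\t", index=False)
        if self.expected_spikes is not None:
            self.expected_spikes.to_csv(outdir / "expected_spikes.tsv", sep="\t", index=False)

    @property
    def sample_sheet(self) -> Dict[str, str]:
        return {self.config.sample_barcode: self.sample_id}


def _random_roi(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    return CODE_TO_ASCII[codes].tobytes().decode("ascii")


def _decode_rows(mat: np.ndarray) -> List[str]:
    width = mat.shape[1]
    blob = CODE_TO_ASCII[mat].tobytes().decode("ascii")
    return [blob[i * width : (i + 1) * width] for i in range(mat.shape[0])]


def _draw_alts(rng, refs: np.ndarray, transition_fraction: float) -> np.ndarray:
    """Draw alt bases with a transition bias (deamination-like artifacts
    are C->T/G->A-heavy; transitions generalize this to all bases)."""
    n = len(refs)
    u = rng.random(n)
    is_transition = u < transition_fraction
    tv_pick = rng.integers(0, 2, size=n)
    alts = np.where(
        is_transition,
        _TRANSITION[refs],
        _TRANSVERSIONS[refs, tv_pick],
    ).astype(np.uint8)
    return alts


def _distinct_ulcis(rng, mol_of_copy: np.ndarray, n_copies_total: int) -> np.ndarray:
    """Draw 4-bp ULCIs, re-drawing until distinct within each molecule."""
    ulci = rng.integers(0, 256, size=n_copies_total).astype(np.int64)
    for _ in range(64):
        order = np.lexsort((ulci, mol_of_copy))
        dup = np.zeros(n_copies_total, dtype=bool)
        same = (np.diff(mol_of_copy[order]) == 0) & (np.diff(ulci[order]) == 0)
        dup[order[1:]] = same
        if not dup.any():
            break
        ulci[dup] = rng.integers(0, 256, size=int(dup.sum()))
    else:
        raise RuntimeError("could not draw distinct ULCIs")
    # expand to 4 base codes
    out = np.empty((n_copies_total, 4), dtype=np.uint8)
    v = ulci.copy()
    for i in range(3, -1, -1):
        out[:, i] = v % 4
        v //= 4
    return out


def _write_fastq(path, names: np.ndarray, prefix: bytes, barcode_mat: np.ndarray,
                 roi_mat: np.ndarray, chunk: int = 400_000) -> None:
    """Write fixed-width FASTQ records assembled from numpy byte blocks."""
    n = roi_mat.shape[0]
    pre = np.frombuffer(prefix, dtype=np.uint8)
    bc_w = len(pre)
    tag_w = barcode_mat.shape[1]
    seq_w = bc_w + tag_w + roi_mat.shape[1]
    name_w = names.shape[1]
    rec_w = name_w + 1 + seq_w + 3 + seq_w + 1
    with open(path, "wb") as f:
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            m = hi - lo
            rec = np.empty((m, rec_w), dtype=np.uint8)
            c = 0
            rec[:, c : c + name_w] = names[lo:hi]
            c += name_w
            rec[:, c] = ord("\n")
            c += 1
            rec[:, c : c + bc_w] = pre[None, :]
            c += bc_w
            rec[:, c : c + tag_w] = CODE_TO_ASCII[barcode_mat[lo:hi]]
            c += tag_w
            rec[:, c : c + roi_mat.shape[1]] = CODE_TO_ASCII[roi_mat[lo:hi]]
            c += roi_mat.shape[1]
            rec[:, c] = ord("\n")
            rec[:, c + 1] = ord("+")
            rec[:, c + 2] = ord("\n")
            c += 3
            rec[:, c : c + seq_w] = ord("I")  # flat Phred 40
            c += seq_w
            rec[:, c] = ord("\n")
            rec.tofile(f)


def _read_names(n: int) -> np.ndarray:
    """(n, 11) byte matrix of '@R'+9-digit read indices."""
    names = np.empty((n, 11), dtype=np.uint8)
    names[:, 0] = ord("@")
    names[:, 1] = ord("R")
    v = np.arange(n, dtype=np.int64)
    for col in range(10, 1, -1):
        names[:, col] = ord("0") + (v % 10)
        v //= 10
    return names


def simulate_library(
    cfg: LibrarySimConfig,
    outdir,
    spike: Optional[SpikeInConfig] = None,
) -> SimulatedLibrary:
    """Simulate a library and write paired FASTQ plus ground truth.

    With a :class:`SpikeInConfig`, mutant template molecules are mixed in
    at the configured dilutions and the expected per-variant frequencies
    are returned for observed-vs-expected validation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    roi = cfg.roi_sequence or _random_roi(rng, cfg.roi_length)
    ann = annotate_roi(roi, cfg.methylation_mode)
    L = len(ann)
    n_mol = cfg.n_molecules
    layout = cfg.layout
    l1roi = cfg.read_length - layout.prefix1_len
    l2roi = cfg.read_length - layout.prefix2_len
    if l1roi <= 0 or l2roi <= 0:
        raise ValueError("read_length shorter than the barcode prefixes")
    if l1roi + l2roi < L:
        raise ValueError("read pair does not span the ROI")
    l1roi = min(l1roi, L)
    l2roi = min(l2roi, L)

    # --- molecules ---------------------------------------------------------
    umi_mat = rng.integers(0, 4, size=(n_mol, layout.umi_len)).astype(np.uint8)
    probs = cfg.copy_number_probs
    copies = rng.choice(np.asarray(cfg.copy_number_choices), size=n_mol, p=probs)

    # spike-in template assignment
    expected_spikes = None
    spike_variants: List[Tuple[np.ndarray, int, int]] = []
    mutant_of_mol = np.full(n_mol, -1, dtype=np.int64)
    if spike is not None:
        mutants = spike.mutants
        if mutants is None:
            mutants = _default_mutants(rng, ann, len(spike.dilutions), spike.end_window)
        if len(mutants) != len(spike.dilutions):
            raise ValueError("need one mutant template per dilution")
        seen_pos: set = set()
        for m in mutants:
            for p, a in m:
                if not (0 < p < L - 1):
                    raise ValueError(f"spike position {p} outside internal ROI")
                if p in seen_pos:
                    raise ValueError(f"overlapping mutant definitions at position {p}")
                if a == roi[p]:
                    raise ValueError(f"spike alt equals reference at position {p}")
                seen_pos.add(p)
        fractions = np.array(list(spike.dilutions) + [1.0 - sum(spike.dilutions)])
        mutant_of_mol = rng.choice(len(fractions), size=n_mol, p=fractions)
        mutant_of_mol[mutant_of_mol == len(spike.dilutions)] = -1
        rows = []
        for mi, (m, dil) in enumerate(zip(mutants, spike.dilutions)):
            for p, a in m:
                rows.append(
                    {"mutant": mi, "pos": p, "ref": roi[p], "alt": a,
                     "expected_frequency": dil}
                )
        expected_spikes = pd.DataFrame(rows)

    # --- true errors -------------------------------------------------------
    pos_rates = cfg.error_model.positional_rates(ann)  # (L, 3)
    flat = np.nonzero(pos_rates > 0)
    err_mol, err_pos, err_alt = [], [], []
    if len(flat[0]):
        ks = rng.binomial(n_mol, pos_rates[flat])
        total = int(ks.sum())
        if total:
            rep = np.repeat(np.arange(len(ks)), ks)
            pos = flat[0][rep]
            rank = flat[1][rep]
            mols = rng.integers(0, n_mol, size=total)
            # alt rank -> base code given the reference base
            refc = ann.codes[pos]
            alt_code = _alt_from_rank(refc, rank)
            err_mol, err_pos, err_alt = [mols], [pos], [alt_code]

    truth_rows = []
    daughter = np.tile(ann.codes, (n_mol, 1))
    if err_mol:
        mols = np.concatenate(err_mol)
        pos = np.concatenate(err_pos)
        alt = np.concatenate(err_alt)
        # dedupe colliding (mol, pos) draws, keep the first
        _, keep = np.unique(mols * L + pos, return_index=True)
        mols, pos, alt = mols[keep], pos[keep], alt[keep]
        daughter[mols, pos] = alt
        truth_rows.append(
            pd.DataFrame(
                {"mol": mols, "pos": pos,
                 "ref": [roi[p] for p in pos],
                 "alt": [BASES[a] for a in alt],
                 "origin": "error"}
            )
        )
    if spike is not None:
        for mi, m in enumerate(mutants):
            mol_ids = np.nonzero(mutant_of_mol == mi)[0]
            if len(mol_ids) == 0:
                continue
            for p, a in m:
                daughter[mol_ids, p] = BASES.index(a)
            truth_rows.append(
                pd.DataFrame(
                    {
                        "mol": np.repeat(mol_ids, len(m)),
                        "pos": np.tile([p for p, _ in m], len(mol_ids)),
                        "ref": np.tile([roi[p] for p, _ in m], len(mol_ids)),
                        "alt": np.tile([a for _, a in m], len(mol_ids)),
                        "origin": "spike",
                    }
                )
            )
    truth_variants = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["mol", "pos", "ref", "alt", "origin"])
    )

    # --- linear copies with independent artifacts --------------------------
    n_copies_total = int(copies.sum())
    mol_of_copy = np.repeat(np.arange(n_mol), copies)
    copy_seqs = daughter[mol_of_copy]
    del daughter

    n_art = rng.binomial(n_copies_total * L, cfg.artifact_rate)
    if n_art:
        a_copy = rng.integers(0, n_copies_total, size=n_art)
        a_pos = rng.integers(0, L, size=n_art)
        refs = copy_seqs[a_copy, a_pos]
        alts = _draw_alts(rng, refs, cfg.artifact_transition_fraction)
        copy_seqs[a_copy, a_pos] = alts
        truth_artifacts = pd.DataFrame(
            {
                "copy": a_copy,
                "mol": mol_of_copy[a_copy],
                "pos": a_pos,
                "ref": [BASES[r] for r in refs],
                "alt": [BASES[a] for a in alts],
            }
        )
    else:
        truth_artifacts = pd.DataFrame(columns=["copy", "mol", "pos", "ref", "alt"])

    ulci_mat = _distinct_ulcis(rng, mol_of_copy, n_copies_total)

    # --- reads --------------------------------------------------------------
    rpc = cfg.reads_per_copy
    copy_of_read = np.repeat(np.arange(n_copies_total), rpc)
    n_reads = len(copy_of_read)
    r1 = copy_seqs[copy_of_read][:, :l1roi].copy()
    r2 = COMP[copy_seqs[copy_of_read][:, L - l2roi :]][:, ::-1].copy()
    for mat in (r1, r2):
        n_se = rng.binomial(mat.size, cfg.seq_error_rate)
        if n_se:
            rr = rng.integers(0, mat.shape[0], size=n_se)
            cc = rng.integers(0, mat.shape[1], size=n_se)
            mat[rr, cc] = (mat[rr, cc] + 1 + rng.integers(0, 3, size=n_se)) % 4

    names = _read_names(n_reads)
    bc1 = cfg.sample_barcode[: layout.sample_bc_read1_len].encode()
    bc2 = cfg.sample_barcode[layout.sample_bc_read1_len :].encode()
    fq1 = outdir / "reads_R1.fastq"
    fq2 = outdir / "reads_R2.fastq"
    _write_fastq(fq1, names, bc1, umi_mat[mol_of_copy[copy_of_read]], r1)
    _write_fastq(fq2, names, bc2, ulci_mat[copy_of_read], r2)

    truth_molecules = pd.DataFrame(
        {"mol": np.arange(n_mol), "umi": _decode_rows(umi_mat), "n_copies": copies}
    )
    if spike is not None:
        truth_molecules["mutant"] = mutant_of_mol

    return SimulatedLibrary(
        fastq1=fq1,
        fastq2=fq2,
        annotation=ann,
        config=cfg,
        truth_molecules=truth_molecules,
        truth_variants=truth_variants,
        truth_artifacts=truth_artifacts,
        expected_spikes=expected_spikes,
    )


def _alt_from_rank(ref_codes: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Map (reference base, alt rank) to the alt base code."""
    alts_table = np.empty((4, 3), dtype=np.uint8)
    for c in range(4):
        alts_table[c] = [BASES.index(b) for b in BASES if b != BASES[c]]
    return alts_table[ref_codes, ranks]


def _default_mutants(
    rng, ann: ROIAnnotation, n_mutants: int, end_window: int
) -> List[List[Tuple[int, str]]]:
    """Generate mutant templates: three substitutions near each ROI end,
    six in total, mutually non-overlapping positions across mutants."""
    L = len(ann)
    left = np.arange(1, 1 + end_window)
    right = np.arange(L - 1 - end_window, L - 1)
    need = 3 * n_mutants
    if len(left) < need or len(right) < need:
        raise ValueError("end windows too small for the requested mutants")
    lpos = rng.choice(left, size=need, replace=False)
    rpos = rng.choice(right, size=need, replace=False)
    mutants = []
    for i in range(n_mutants):
        pos = np.concatenate([lpos[3 * i : 3 * i + 3], rpos[3 * i : 3 * i + 3]])
        muts = []
        for p in sorted(pos):
            ref = ann.sequence[p]
            alt = BASES[(BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
            muts.append((int(p), alt))
        mutants.append(muts)
    return mutants


def simulate_spikein_pool(
    cfg: LibrarySimConfig, spike: SpikeInConfig, outdir
) -> SimulatedLibrary:
    """Simulate a library with mutant templates spiked at fixed dilutions."""
    return simulate_library(cfg, outdir, spike=spike)


# ---------------------------------------------------------------------------
# mutation-dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class MutationSimConfig:
    """Study conditions for a synthetic cancer/mouse-style mutation set.

    The synthetic genome has `n_chromosomes` chromosomes of
    `chrom_length` bp, tiled with alternating left/right-replicating
    20-kb domains carrying a sawtooth replication-timing value.  CpG
    sites get bisulfite-style beta values from a high/low mixture.
    Mutations are drawn per sample from `signature_pdf` (96 COSMIC-order
    channels); CpG>TpG mutations are placed with leading-strand
    enrichment `leading_enrichment` (rho), methylation multiplier
    `methylation_multiplier` for beta >= beta_high versus beta <=
    beta_low, and an `early_depletion` factor (<1 depletes
    early-replicating, MMR-active regions; rho and factors of 1 give the
    null).
    """

    n_samples: int
    mutations_per_sample: int
    seed: int
    n_chromosomes: int = 10
    chrom_length: int = 2_000_000
    domain_width: int = 20_000
    signature_pdf: Optional[np.ndarray] = None  # default: CpG>TpG-heavy
    leading_enrichment: float = 1.0
    methylation_multiplier: float = 1.0
    beta_low: float = 0.2
    beta_high: float = 0.8
    fraction_high_meth: float = 0.7
    early_depletion: float = 1.0
    peak_depletion: float = 1.0
    peak_fraction: float = 0.3

    def __post_init__(self):
        if self.leading_enrichment <= 0:
            raise ValueError("leading_enrichment must be > 0")
        if self.signature_pdf is not None:
            p = np.asarray(self.signature_pdf, dtype=float)
            if p.shape != (96,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError("signature_pdf must be a 96-channel PDF")
            self.signature_pdf = p


def default_signature_pdf(cpg_tpg_weight: float = 0.6) -> np.ndarray:
    """A CpG>TpG-heavy 96-channel PDF: `cpg_tpg_weight` on the four NCG
    C>T channels, the rest uniform over all other channels."""
    pdf = np.zeros(96)
    ncg = [i for i, (t, a) in enumerate(CHANNELS_96)
           if t[1] == "C" and t[2] == "G" and a == "T"]
    pdf[ncg] = cpg_tpg_weight / len(ncg)
    rest = [i for i in range(96) if i not in ncg]
    pdf[rest] = (1.0 - cpg_tpg_weight) / len(rest)
    return pdf


@dataclass
class SimulatedMutationData:
    mutations: pd.DataFrame  # sample, chrom, pos (1-based), ref, alt
    domains: pd.DataFrame  # chrom, start, end (0-based half-open), direction, timing
    methylation: pd.DataFrame  # chrom, pos (1-based C), beta, coverage
    peaks: pd.DataFrame  # chrom, start, end
    genome: Dict[str, str]
    config: MutationSimConfig
    truth: dict

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["mutations"] = outdir / "mutations.tsv"
        self.mutations.to_csv(paths["mutations"], sep="\t", index=False)
        paths["domains"] = outdir / "domains.bed"
        self.domains.to_csv(paths["domains"], sep="\t", index=False, header=False)
        paths["methylation"] = outdir / "methylation.tsv"
        self.methylation.to_csv(paths["methylation"], sep="\t", index=False)
        paths["peaks"] = outdir / "peaks.bed"
        self.peaks.to_csv(paths["peaks"], sep="\t", index=False, header=False)
        paths["genome"] = outdir / "genome.fa"
        with open(paths["genome"], "w") as f:
            for name, seq in self.genome.items():
                f.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    f.write(seq[i : i + 80] + "\n")
        return paths


def simulate_mutation_dataset(cfg: MutationSimConfig) -> SimulatedMutationData:
    """Generate a synthetic genome, tracks and per-sample mutation tables."""
    rng = np.random.default_rng(cfg.seed)
    pdf = cfg.signature_pdf if cfg.signature_pdf is not None else default_signature_pdf()

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome_codes: Dict[str, np.ndarray] = {}
    for c in chroms:
        genome_codes[c] = rng.integers(0, 4, size=cfg.chrom_length).astype(np.uint8)

    # --- domains: alternating left/right, sawtooth timing -------------------
    dom_rows = []
    n_dom = cfg.chrom_length // cfg.domain_width
    for c in chroms:
        for i in range(n_dom):
            direction = "right" if i % 2 == 0 else "left"
            dom_rows.append((c, i * cfg.domain_width, (i + 1) * cfg.domain_width,
                             direction, 0.0))
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end",
                                              "direction", "timing"])
    # timing: sawtooth over groups of 4 domains (0 early .. 1 late)
    k = np.arange(len(domains)) % 4
    domains["timing"] = np.where(k < 2, k / 2.0 + 0.25 * rng.random(len(domains)),
                                 (4 - k) / 2.0 - 0.25 * rng.random(len(domains)))
    domains["timing"] = domains["timing"].clip(0.0, 1.0)

    # --- per-site indexes ----------------------------------------------------
    # trinucleotide codes per chromosome (plus strand)
    tri: Dict[str, np.ndarray] = {c: trinuc_codes(genome_codes[c]) for c in chroms}

    # CpG sites: plus-strand C followed by G (internal)
    cpg_chrom, cpg_pos, cpg_flank = [], [], []
    for c in chroms:
        g = genome_codes[c]
        p = np.nonzero((g[:-1] == 1) & (g[1:] == 2))[0]
        p = p[(p > 0) & (p < len(g) - 2)]
        cpg_chrom.append(np.full(len(p), chroms.index(c)))
        cpg_pos.append(p)
        cpg_flank.append(g[p - 1])
    cpg_chrom = np.concatenate(cpg_chrom)
    cpg_pos = np.concatenate(cpg_pos)
    cpg_flank = np.concatenate(cpg_flank)
    n_cpg = len(cpg_pos)

    beta = np.where(
        rng.random(n_cpg) < cfg.fraction_high_meth,
        rng.beta(20, 2, size=n_cpg),
        rng.beta(2, 20, size=n_cpg),
    )
    coverage = rng.poisson(30, size=n_cpg) + 5

    # domain annotation per CpG
    dom_idx_of = lambda pos: np.minimum(pos // cfg.domain_width, n_dom - 1)
    cpg_dom = cpg_chrom * n_dom + dom_idx_of(cpg_pos)
    dom_dir_right = (domains["direction"] == "right").to_numpy()
    dom_timing = domains["timing"].to_numpy()
    cpg_right = dom_dir_right[cpg_dom]
    cpg_timing = dom_timing[cpg_dom]

    # peaks: random subset of domains
    peak_mask_dom = rng.random(len(domains)) < cfg.peak_fraction
    peaks = domains.loc[peak_mask_dom, ["chrom", "start", "end"]].reset_index(drop=True)
    cpg_in_peak = peak_mask_dom[cpg_dom]

    # timing quartiles for depletion
    q1, q3 = np.quantile(dom_timing, [0.25, 0.75])
    cpg_early = cpg_timing <= q1

    # CpG>TpG site weights
    w = np.ones(n_cpg)
    w[beta >= cfg.beta_high] *= cfg.methylation_multiplier
    w[cpg_early] *= cfg.early_depletion
    w[cpg_in_peak] *= cfg.peak_depletion

    # non-CpG>TpG channels: site lists per plus-strand trinucleotide code
    sites_by_tri: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for t in range(64):
        cc, pp = [], []
        for ci, c in enumerate(chroms):
            p = np.nonzero(tri[c] == t)[0]
            cc.append(np.full(len(p), ci))
            pp.append(p)
        sites_by_tri[t] = (np.concatenate(cc), np.concatenate(pp))

    ncg_channels = {i for i, (t, a) in enumerate(CHANNELS_96)
                    if t[1] == "C" and t[2] == "G" and a == "T"}
    rho = cfg.leading_enrichment
    p_leading = rho / (1.0 + rho)

    mut_rows = []
    for s in range(cfg.n_samples):
        counts = rng.multinomial(cfg.mutations_per_sample, pdf)
        for ch, k in enumerate(counts):
            if k == 0:
                continue
            t, alt = CHANNELS_96[ch]
            if ch in ncg_channels:
                # weighted CpG site with the channel's 5' flank, then the
                # strand of the mutated C
                flank_code = BASES.index(t[0])
                subset = np.nonzero(cpg_flank == flank_code)[0]
                if len(subset) == 0:
                    continue
                ws = w[subset]
                sites = subset[
                    rng.choice(len(subset), size=k, p=ws / ws.sum())
                ]
                lead = rng.random(k) < p_leading
                # plus-strand C is the leading template in right... no:
                # leading template = plus strand in LEFT-replicating
                # domains, minus strand in right-replicating domains
                site_right = cpg_right[sites]
                on_plus = np.where(site_right, ~lead, lead)
                ci = cpg_chrom[sites]
                p0 = cpg_pos[sites]
                for j in range(k):
                    c = chroms[ci[j]]
                    if on_plus[j]:
                        # mutate the plus-strand C: also honor the flank
                        mut_rows.append((s, c, int(p0[j]) + 1, "C", "T"))
                    else:
                        # minus-strand C == plus-strand G at pos+1
                        mut_rows.append((s, c, int(p0[j]) + 2, "G", "A"))
            else:
                tcode = TRINUC_INDEX[t]
                rc_code = TRINUC_INDEX[revcomp(t)]
                plus_sites = sites_by_tri[tcode]
                minus_sites = sites_by_tri[rc_code]
                npl, nmi = len(plus_sites[1]), len(minus_sites[1])
                if npl + nmi == 0:
                    continue
                take_plus = rng.random(k) < npl / (npl + nmi)
                for j in range(k):
                    if take_plus[j] and npl:
                        idx = rng.integers(0, npl)
                        c = chroms[plus_sites[0][idx]]
                        p0 = int(plus_sites[1][idx])
                        mut_rows.append((s, c, p0 + 1, t[1], alt))
                    elif nmi:
                        idx = rng.integers(0, nmi)
                        c = chroms[minus_sites[0][idx]]
                        p0 = int(minus_sites[1][idx])
                        mut_rows.append(
                            (s, c, p0 + 1, revcomp(t)[1], revcomp(alt))
                        )

    mutations = pd.DataFrame(
        mut_rows, columns=["sample", "chrom", "pos", "ref", "alt"]
    )
    mutations["sample"] = "S" + mutations["sample"].astype(str).str.zfill(3)
    mutations = mutations.drop_duplicates(
        subset=["sample", "chrom", "pos"]
    ).reset_index(drop=True)

    methylation = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in cpg_chrom],
            "pos": cpg_pos + 1,
            "beta": beta,
            "coverage": coverage,
        }
    )
    genome = {c: CODE_TO_ASCII[genome_codes[c]].tobytes().decode("ascii")
              for c in chroms}
    truth = {
        "leading_enrichment": rho,
        "methylation_multiplier": cfg.methylation_multiplier,
        "early_depletion": cfg.early_depletion,
        "peak_depletion": cfg.peak_depletion,
        "signature_pdf": pdf,
    }
    return SimulatedMutationData(
        mutations=mutations,
        domains=domains,
        methylation=methylation,
        peaks=peaks,
        genome=genome,
        config=cfg,
        truth=truth,
    )
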