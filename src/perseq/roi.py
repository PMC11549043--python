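"""Region-of-interest (ROI) template annotation.

The ROI is the 200-300 bp template whose replication errors are measured.
Every position is annotated with its template-strand trinucleotide context,
cytosine class and methylation state.  Cytosine classes partition the
internal cytosines:

* ``CpG`` — C followed by G (methylated only when the template was treated
  with M.SssI, which methylates all CpG cytosines);
* ``dcm`` — the second C of CCAGG/CCTGG, the cytosine methylated by the
  E. coli Dcm methyltransferase; these sites are methylated in every ROI
  regardless of M.SssI treatment because templates are prepared in E. coli;
* ``CpH`` — any other cytosine context (never methylated here).

A cytosine that is simultaneously CpG and inside CCWGG is classed CpG (the
classes are treated as mutually exclusive, and M.SssI acts on all CpGs).
The first and last positions have no full trinucleotide and are excluded
from context counts and from every frequency denominator downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Literal

import numpy as np
import pandas as pd

from ._channels import BASES, TRINUCS, encode, revcomp, trinuc_codes

MethylationMode = Literal["mock", "m_sssi"]

CLASS_NOT_C = 0
CLASS_CPG = 1
CLASS_DCM = 2
CLASS_CPH = 3
CLASS_NAMES = np.array(["not_C", "CpG", "dcm", "CpH"])


@dataclass
class ROIAnnotation:
    """Annotated ROI template.

    Attributes
    ----------
    name : str
        Record identifier.
    sequence : str
        Template-strand sequence (A/C/G/T only).
    methylation_mode : {"mock", "m_sssi"}
        Whether CpG cytosines were methylated by M.SssI.
    codes : np.ndarray
        Per-position base codes (A=0..T=3).
    trinuc : np.ndarray
        Per-position trinucleotide code (0..63), -1 at the two ends.
    cclass : np.ndarray
        Per-position cytosine class code (0 not_C, 1 CpG, 2 dcm, 3 CpH).
    is_methylated : np.ndarray of bool
        True where the template cytosine carries 5mC.
    trinuc_counts : dict
        Template-strand trinucleotide occurrence counts over internal
        positions (sums to len-2).
    """

    name: str
    sequence: str
    methylation_mode: MethylationMode
    codes: np.ndarray = field(repr=False)
    trinuc: np.ndarray = field(repr=False)
    cclass: np.ndarray = field(repr=False)
    is_methylated: np.ndarray = field(repr=False)
    trinuc_counts: Dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def internal(self) -> slice:
        """Positions with a defined trinucleotide context."""
        return slice(1, len(self.sequence) - 1)

    def class_positions(self, cls: str) -> np.ndarray:
        """Internal 0-based positions whose cytosine class is `cls`."""
        code = {"CpG": CLASS_CPG, "dcm": CLASS_DCM, "CpH": CLASS_CPH}[cls]
        pos = np.nonzero(self.cclass == code)[0]
        return pos[(pos > 0) & (pos < len(self.sequence) - 1)]

    def to_frame(self) -> pd.DataFrame:
        """Per-position annotation table (1-based positions for reporting)."""
        n = len(self.sequence)
        trinuc_str = [TRINUCS[t] if t >= 0 else "." for t in self.trinuc]
        return pd.DataFrame(
            {
                "pos": np.arange(1, n + 1),
                "base": list(self.sequence),
                "trinuc": trinuc_str,
                "class": CLASS_NAMES[self.cclass],
                "methylated": self.is_methylated,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def annotate_roi(
    sequence: str, methylation_mode: MethylationMode = "mock", name: str = "roi"
) -> ROIAnnotation:
    """Annotate an ROI template sequence.

    Raises
    ------
    ValueError
        If the sequence is shorter than 3 bases, contains a non-ACGT
        character (the offending position is reported), or the methylation
        mode is unknown.
    """
    if methylation_mode not in ("mock", "m_sssi"):
        raise ValueError(f"unknown methylation_mode {methylation_mode!r}")
    if len(sequence) < 3:
        raise ValueError("ROI sequence must be at least 3 bases long")
    sequence = sequence.upper()
    for i, b in enumerate(sequence):
        if b not in BASES:
            raise ValueError(f"non-ACGT character {b!r} at position {i} (0-based)")

    codes = encode(sequence)
    n = len(codes)
    tri = trinuc_codes(codes)

    is_c = codes == 1
    cclass = np.full(n, CLASS_NOT_C, dtype=np.int8)
    # CpG: C followed by G
    cpg = is_c.copy()
    cpg[:-1] &= codes[1:] == 2
    cpg[-1] = False
    # dcm: second C of CCAGG/CCTGG (CCWGG), i.e. seq[i-1:i+4] == CC[AT]GG
    dcm = np.zeros(n, dtype=bool)
    for i in range(1, n - 3):
        if (
            codes[i] == 1
            and codes[i - 1] == 1
            and codes[i + 1] in (0, 3)
            and codes[i + 2] == 2
            and codes[i + 3] == 2
        ):
            dcm[i] = True
    cclass[is_c] = CLASS_CPH
    cclass[dcm & is_c] = CLASS_DCM
    cclass[cpg] = CLASS_CPG  # CpG takes precedence over dcm

    meth = (cclass == CLASS_DCM) | (
        (cclass == CLASS_CPG) & (methylation_mode == "m_sssi")
    )

    internal = tri[1:-1] if n >= 3 else np.empty(0, dtype=np.int32)
    counts = np.bincount(internal[internal >= 0], minlength=64)
    trinuc_counts = {TRINUCS[i]: int(c) for i, c in enumerate(counts) if c > 0}

    return ROIAnnotation(
        name=name,
        sequence=sequence,
        methylation_mode=methylation_mode,
        codes=codes,
        trinuc=tri,
        cclass=cclass,
        is_methylated=meth,
        trinuc_counts=trinuc_counts,
    )


def count_trinucleotides(
    annotation: ROIAnnotation, strand: Literal["template", "both"] = "template"
) -> Dict[str, int]:
    """Trinucleotide occurrence counts over internal ROI positions.

    ``strand="both"`` adds the reverse-complement counts of the template
    strand, for strand-unspecific denominators.
    """
    counts = dict(annotation.trinuc_counts)
    if strand == "template":
        return counts
    if strand != "both":
        raise ValueError(f"unknown strand {strand!r}")
    for t, c in annotation.trinuc_counts.items():
        rc = revcomp(t)
        counts[rc] = counts.get(rc, 0) + c
    return counts


def read_roi_fasta(
    path, methylation_mode: MethylationMode = "mock"
) -> Dict[str, ROIAnnotation]:
    """Read one or more ROI records from a FASTA file and annotate them."""
    from Bio import SeqIO

    out: Dict[str, ROIAnnotation] = {}
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        out[rec.id] = annotate_roi(str(rec.seq), methylation_mode, name=rec.id)
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out
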