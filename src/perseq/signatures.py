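"""Error-signature construction and algebra.

An error signature is the per-trinucleotide-context misincorporation
frequency vector: 192 strand-specific channels (template trinucleotide x
3 alt bases) or 96 strand-collapsed pyrimidine-centric channels in COSMIC
SBS order.  Frequency = errors / context opportunities, so signatures are
normalized for the trinucleotide composition of the ROI.

The assay background (template damage and preparation artifacts measured
in parental samples, plus the gapping background supplied as a table) is
subtracted channel-wise in frequency space and clamped at zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from ._channels import (
    BASES,
    CHANNELS_192,
    CHANNELS_96,
    COLLAPSE_PAIRS,
    TRINUC_INDEX,
)
from .roi import ROIAnnotation

Scale = Literal["frequency", "pdf"]


@dataclass
class ErrorSignature:
    """A 192- or 96-channel error signature.

    ``frequencies`` is ordered by the canonical channel order (192:
    trinucleotide-lexicographic x alt; 96: COSMIC SBS).  ``counts`` and
    ``opportunities`` are retained when the signature came straight from
    tabulated errors and are dropped (None) after background subtraction.
    """

    frequencies: np.ndarray
    n_channels: int = 192
    scale: Scale = "frequency"
    counts: Optional[np.ndarray] = None
    opportunities: Optional[np.ndarray] = None
    zero_opportunity: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (self.n_channels,):
            raise ValueError(
                f"expected {self.n_channels} channels, got "
                f"{self.frequencies.shape}"
            )
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be nonnegative")

    @property
    def channels(self):
        return CHANNELS_192 if self.n_channels == 192 else CHANNELS_96

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "context": [t for t, _ in self.channels],
                "alt": [a for _, a in self.channels],
                "frequency": self.frequencies,
            }
        )
        if self.counts is not None:
            df.insert(2, "count", self.counts)
        if self.opportunities is not None:
            df.insert(3, "opportunity", self.opportunities)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, scale: Scale = "frequency") -> "ErrorSignature":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        n = len(df)
        if n not in (192, 96):
            raise ValueError(f"expected 192 or 96 rows, got {n}")
        expected = CHANNELS_192 if n == 192 else CHANNELS_96
        got = list(zip(df["context"], df["alt"]))
        if got != expected:
            raise ValueError("channel ordering does not match the canonical order")
        return cls(
            frequencies=df["frequency"].to_numpy(),
            n_channels=n,
            scale=scale,
            counts=df["count"].to_numpy() if "count" in df else None,
            opportunities=df["opportunity"].to_numpy() if "opportunity" in df else None,
        )


def compute_signature(channel_table: pd.DataFrame) -> ErrorSignature:
    """Build a 192-channel frequency signature from a tabulated
    count/opportunity table (as produced by
    :func:`perseq.consensus.tabulate_errors`).

    Channels with zero opportunity get frequency 0 and are flagged in
    ``zero_opportunity``.
    """
    if len(channel_table) != 192:
        raise ValueError("channel table must have 192 rows")
    counts = channel_table["count"].to_numpy(dtype=np.int64)
    opp = channel_table["opportunity"].to_numpy(dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if np.any(opp < 0):
        raise ValueError("negative opportunities")
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(opp > 0, counts / np.maximum(opp, 1), 0.0)
    return ErrorSignature(
        frequencies=freq,
        n_channels=192,
        scale="frequency",
        counts=counts,
        opportunities=opp,
        zero_opportunity=opp == 0,
    )


@dataclass
class BackgroundEstimate:
    """Assay backgrounds: parental (template damage, measured by running
    the identical pipeline on parental-sample FASTQs) and gapping
    (user-supplied table; zero by default)."""

    parental: np.ndarray
    gapping: np.ndarray

    def __post_init__(self):
        self.parental = np.asarray(self.parental, dtype=float)
        self.gapping = np.asarray(self.gapping, dtype=float)
        for v in (self.parental, self.gapping):
            if v.shape != (192,):
                raise ValueError("backgrounds must be 192-channel vectors")

    @classmethod
    def zero(cls) -> "BackgroundEstimate":
        return cls(np.zeros(192), np.zeros(192))


def subtract_background(
    filled: ErrorSignature, bg: BackgroundEstimate
) -> ErrorSignature:
    """Channel-wise ``max(0, filled - parental - gapping)``.

    Operates in frequency space; counts/opportunities are invalidated on
    the result because the subtracted frequencies no longer correspond to
    integer counts.
    """
    if filled.n_channels != 192:
        raise ValueError("background subtraction operates on 192-channel signatures")
    if filled.scale != "frequency":
        raise ValueError("background subtraction requires frequency scale")
    freq = np.maximum(0.0, filled.frequencies - bg.parental - bg.gapping)
    return ErrorSignature(
        frequencies=freq, n_channels=192, scale="frequency",
        counts=None, opportunities=None,
        zero_opportunity=filled.zero_opportunity,
    )


def collapse_strand(sig192: ErrorSignature) -> ErrorSignature:
    """Collapse a 192-channel strand-specific signature to 96 channels.

    Each pyrimidine-centric channel is the mean of itself and its
    reverse-complement purine channel (e.g. C>T in ACG with G>A in CGT),
    in COSMIC SBS row order.
    """
    if sig192.n_channels != 192:
        raise ValueError("collapse_strand requires a 192-channel signature")
    pyr = sig192.frequencies[COLLAPSE_PAIRS[:, 0]]
    pur = sig192.frequencies[COLLAPSE_PAIRS[:, 1]]
    return ErrorSignature(
        frequencies=(pyr + pur) / 2.0, n_channels=96, scale=sig192.scale,
    )


def total_error_frequency(sig192: ErrorSignature) -> float:
    """Overall error frequency: the unweighted mean of the 192 channel
    frequencies (trinucleotide-normalized by construction)."""
    if sig192.n_channels != 192:
        raise ValueError("total_error_frequency requires a 192-channel signature")
    if sig192.scale != "frequency":
        raise ValueError("total_error_frequency requires frequency scale")
    return float(sig192.frequencies.mean())


def scale_pdf(sig: ErrorSignature) -> ErrorSignature:
    """Scale a signature to a probability density (channels sum to 1)."""
    total = sig.frequencies.sum()
    if total <= 0:
        raise ValueError("cannot PDF-scale an all-zero signature")
    return ErrorSignature(
        frequencies=sig.frequencies / total, n_channels=sig.n_channels,
        scale="pdf",
    )


class MissingClassError(ValueError):
    """The requested cytosine class does not occur in the ROI."""


def context_class_rate(
    sig192: ErrorSignature,
    annotation: ROIAnnotation,
    ref_class: Literal["CpG", "dcm", "CpH"],
    alt: str = "T",
    weighted: bool = True,
) -> float:
    """Error rate of template-C channels restricted to a cytosine class.

    Averages the (template C trinucleotide, alt) channel frequencies over
    the ROI positions whose cytosine falls in `ref_class` (dcm only over
    CCWGG positions), weighting each position by its channel opportunity
    share.  With ``weighted=False`` an unweighted mean over the class's
    distinct trinucleotides is returned.

    Note: a channel frequency is a per-trinucleotide aggregate; if the
    same trinucleotide occurs in two classes within one ROI (possible for
    dcm CCA/CCT contexts) the channel mixes both classes.
    """
    if alt not in BASES or alt == "C":
        raise ValueError(f"invalid alt base {alt!r} for a template C")
    positions = annotation.class_positions(ref_class)
    if len(positions) == 0:
        raise MissingClassError(f"class {ref_class} absent from ROI {annotation.name}")
    tri = annotation.trinuc[positions]
    from ._channels import CHANNEL_LOOKUP

    chan = CHANNEL_LOOKUP[tri, BASES.index(alt)]
    freqs = sig192.frequencies[chan]
    if not weighted:
        uniq = pd.unique(chan)
        return float(sig192.frequencies[uniq].mean())
    if sig192.opportunities is not None:
        # per-position opportunity = channel opportunity / occurrences of
        # that trinucleotide, i.e. molecules covering the position class
        w = sig192.opportunities[chan].astype(float)
        occ = np.array([annotation.trinuc_counts[CHANNELS_192[c][0]] for c in chan])
        w = np.where(occ > 0, w / occ, 0.0)
        if w.sum() == 0:
            w = np.ones_like(w)
    else:
        w = np.ones(len(chan))
    return float(np.average(freqs, weights=w))
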