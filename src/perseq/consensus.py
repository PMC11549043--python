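"""Two-level consensus calling: reads -> linear copies -> molecules.

A *linear copy* is the set of reads sharing a (UMI, ULCI) dual barcode; a
*molecule* is the set of linear copies sharing a UMI.  Variants must be
present in at least 70% of the informative (non-N) reads of a copy, and in
at least 70% of the informative copies of a molecule; only molecules with
at least three distinct ULCIs are retained.  Requiring several independent
linear copies is what separates true polymerase errors (present in every
copy of the daughter strand) from amplification/damage/sequencing
artifacts (independent per copy).

Thresholds are computed over informative reads/copies (Ns do not vote).
When no base reaches the copy-level agreement the position is set to N, so
ambiguous copies do not vote at the molecule level.  If two different alt
bases each pass the molecule threshold (impossible with agreement > 0.5)
the position would be uninformative; with the default 0.7 agreement at
most one base can pass.

Two evaluation modes exist for the frequency-versus-copy-number analysis:
the production rule above, and :func:`copy_support_curve`, which asks for
a variant to be *supported by at least k linear copies* — the quantity
that isolates how many independent observations are needed before
artifact coincidences stop inflating the error frequency.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._channels import BASES, CHANNEL_LOOKUP, CHANNELS_192, N_CODE
from .readprep import ReadBatch
from .roi import ROIAnnotation

_EPS = 1e-9


@dataclass(frozen=True)
class ConsensusConfig:
    """Consensus thresholds (defaults are the assay's published rules)."""

    copy_read_agreement: float = 0.70
    molecule_copy_agreement: float = 0.70
    min_linear_copies: int = 3
    min_reads_per_copy: int = 1

    def __post_init__(self):
        for f in (self.copy_read_agreement, self.molecule_copy_agreement):
            if not (0.5 < f <= 1.0):
                raise ValueError("agreement fractions must be in (0.5, 1.0]")
        if self.min_linear_copies < 1:
            raise ValueError("min_linear_copies must be >= 1")
        if self.min_reads_per_copy < 1:
            raise ValueError("min_reads_per_copy must be >= 1")


@dataclass
class LinearCopyConsensus:
    umi: str
    ulci: str
    consensus: np.ndarray  # (L,) uint8 codes, N where uninformative
    read_support: int
    variant_positions: Set[Tuple[int, str]] = field(default_factory=set)


@dataclass
class MoleculeCall:
    umi: str
    n_linear_copies: int
    variants: Set[Tuple[int, str, str]]  # (pos, ref, alt)
    covered_positions: np.ndarray  # bool (L,)


def group_linear_copies(reads) -> Dict[Tuple[str, str], np.ndarray]:
    """Group aligned reads by their (UMI, ULCI) dual barcode.

    Accepts a :class:`~perseq.readprep.ReadBatch` or an iterable of
    ``(umi, ulci, calls)`` tuples; returns a dict mapping the dual barcode
    to an (n_reads, L) call matrix.
    """
    if isinstance(reads, ReadBatch):
        items = zip(reads.umis, reads.ulcis, reads.calls)
    else:
        items = reads
    groups: Dict[Tuple[str, str], List[np.ndarray]] = {}
    for umi, ulci, calls in items:
        groups.setdefault((umi, ulci), []).append(np.asarray(calls, dtype=np.uint8))
    return {k: np.vstack(v) for k, v in groups.items()}


def _consensus_from_counts(counts: np.ndarray, agreement: float) -> np.ndarray:
    """Base-call a (L, 5) count matrix: the unique base reaching the
    agreement fraction of informative observations, else N."""
    informative = counts[:, :4].sum(axis=1)
    best = counts[:, :4].argmax(axis=1)
    best_count = counts[np.arange(len(counts)), best]
    ok = (informative > 0) & (best_count >= agreement * informative - _EPS)
    return np.where(ok, best, N_CODE).astype(np.uint8)


def call_linear_copy(
    group,
    reference: ROIAnnotation,
    cfg: ConsensusConfig = ConsensusConfig(),
    umi: str = "",
    ulci: str = "",
) -> LinearCopyConsensus:
    """Collapse the reads of one dual-barcode group into a copy consensus."""
    mat = np.atleast_2d(np.asarray(group, dtype=np.uint8))
    if mat.shape[0] == 0:
        raise ValueError("empty read group")
    if mat.shape[0] < cfg.min_reads_per_copy:
        raise ValueError(
            f"group of {mat.shape[0]} reads below min_reads_per_copy="
            f"{cfg.min_reads_per_copy}"
        )
    L = mat.shape[1]
    counts = np.stack([(mat == b).sum(axis=0) for b in range(5)], axis=1)
    cons = _consensus_from_counts(counts, cfg.copy_read_agreement)
    ref = reference.codes
    var_pos = np.nonzero((cons != N_CODE) & (cons != ref))[0]
    variants = {(int(p), BASES[cons[p]]) for p in var_pos}
    return LinearCopyConsensus(
        umi=umi, ulci=ulci, consensus=cons, read_support=int(mat.shape[0]),
        variant_positions=variants,
    )


def call_molecule(
    copies: Sequence[LinearCopyConsensus],
    reference: ROIAnnotation,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> Optional[MoleculeCall]:
    """Collapse the linear copies of one UMI into a molecule call.

    Returns None when the molecule is discarded (fewer distinct ULCIs than
    ``min_linear_copies``).  Positions informative in fewer than
    ``min_linear_copies`` copies are excluded from ``covered_positions``
    and cannot host variants.
    """
    umis = {c.umi for c in copies}
    if len(umis) > 1:
        raise ValueError(f"copies carry mixed UMIs: {sorted(umis)}")
    n_copies = len({c.ulci for c in copies})
    if n_copies < cfg.min_linear_copies:
        return None
    mat = np.vstack([c.consensus for c in copies])
    counts = np.stack([(mat == b).sum(axis=0) for b in range(5)], axis=1)
    informative = counts[:, :4].sum(axis=1)
    covered = informative >= cfg.min_linear_copies
    cons = _consensus_from_counts(counts, cfg.molecule_copy_agreement)
    ref = reference.codes
    var_pos = np.nonzero(covered & (cons != N_CODE) & (cons != ref))[0]
    variants = {(int(p), BASES[ref[p]], BASES[cons[p]]) for p in var_pos}
    return MoleculeCall(
        umi=copies[0].umi,
        n_linear_copies=n_copies,
        variants=variants,
        covered_positions=covered,
    )


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------

@dataclass
class MoleculeCallSet:
    """Molecule-level calls for one sample, in array form.

    ``variants`` has columns ``mol`` (index into the retained-molecule
    arrays), ``pos`` (0-based), ``ref``, ``alt`` (base characters).
    ``coverage[p]`` is the number of retained molecules informative at
    position p in >= min_linear_copies copies — the per-position
    opportunity denominator.
    """

    umis: np.ndarray
    n_copies: np.ndarray
    variants: pd.DataFrame
    coverage: np.ndarray
    n_molecules_total: int
    n_discarded: int

    @property
    def n_retained(self) -> int:
        return len(self.umis)

    def variant_frequency(self, pos: int, alt: str) -> float:
        """Fraction of covering molecules that carry (pos, alt)."""
        if self.coverage[pos] == 0:
            return float("nan")
        k = int(((self.variants["pos"] == pos) & (self.variants["alt"] == alt)).sum())
        return k / int(self.coverage[pos])

    def to_frame(self) -> pd.DataFrame:
        """Molecules TSV layout: umi, n_copies, variants 'pos:ref>alt;...'
        (1-based positions)."""
        var_strs = ["" for _ in range(self.n_retained)]
        for mol, grp in self.variants.groupby("mol"):
            var_strs[int(mol)] = ";".join(
                f"{int(p) + 1}:{r}>{a}"
                for p, r, a in zip(grp["pos"], grp["ref"], grp["alt"])
            )
        return pd.DataFrame(
            {"umi": self.umis, "n_copies": self.n_copies, "variants": var_strs}
        )


def consensus_copies(
    batch: ReadBatch, cfg: ConsensusConfig = ConsensusConfig()
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized copy-level consensus.

    Returns ``(copy_umis, copy_ulcis, copy_calls)`` where `copy_calls` is
    an (n_copies, L) uint8 consensus matrix.
    """
    n, L = batch.calls.shape
    if n == 0:
        return (np.empty(0, object), np.empty(0, object),
                np.empty((0, L), np.uint8))
    # "|" cannot occur in sequence-derived barcodes
    keys = pd.Series([u + "|" + c for u, c in zip(batch.umis, batch.ulcis)])
    codes, uniques = pd.factorize(keys, sort=False)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(len(uniques)))
    sizes = np.diff(np.append(starts, n))

    cons = np.empty((len(uniques), L), dtype=np.uint8)
    R = batch.calls[order]
    n_groups = len(uniques)
    chunk = max(1, 50_000_000 // (L * 5))
    for g_lo in range(0, n_groups, chunk):
        g_hi = min(g_lo + chunk, n_groups)
        row_lo = starts[g_lo]
        row_hi = starts[g_hi] if g_hi < n_groups else n
        sub = R[row_lo:row_hi]
        if sizes[g_lo:g_hi].max() == 1:
            # one read per copy: the read is its own consensus
            cons[g_lo:g_hi] = sub
            continue
        rel_starts = (starts[g_lo:g_hi] - row_lo).astype(np.int64)
        counts = np.empty((g_hi - g_lo, 5, L), dtype=np.int32)
        for b in range(5):
            counts[:, b, :] = np.add.reduceat(
                (sub == b).astype(np.int32), rel_starts, axis=0
            )
        informative = counts[:, :4, :].sum(axis=1)
        best = counts[:, :4, :].argmax(axis=1)
        best_count = np.take_along_axis(
            counts[:, :4, :], best[:, None, :], axis=1
        )[:, 0, :]
        ok = (informative > 0) & (
            best_count >= cfg.copy_read_agreement * informative - _EPS
        )
        cons[g_lo:g_hi] = np.where(ok, best, N_CODE).astype(np.uint8)

    if cfg.min_reads_per_copy > 1:
        keep = sizes >= cfg.min_reads_per_copy
    else:
        keep = np.ones(len(uniques), dtype=bool)
    copy_umis = np.asarray(
        [k.split("|", 1)[0] for k in uniques], dtype=object
    )
    copy_ulcis = np.asarray(
        [k.split("|", 1)[1] for k in uniques], dtype=object
    )
    return copy_umis[keep], copy_ulcis[keep], cons[keep]


def _molecule_counts_chunks(copy_calls, mol_idx, chunk_mols=20_000):
    """Yield (mol_lo, counts) with counts of shape (n_chunk, 5, L), for
    copies sorted by molecule index."""
    n_mols = int(mol_idx[-1]) + 1 if len(mol_idx) else 0
    L = copy_calls.shape[1]
    starts = np.searchsorted(mol_idx, np.arange(n_mols))
    bounds = np.append(starts, len(mol_idx))
    for lo in range(0, n_mols, chunk_mols):
        hi = min(lo + chunk_mols, n_mols)
        row_lo, row_hi = bounds[lo], bounds[hi]
        sub = copy_calls[row_lo:row_hi]
        rel = (starts[lo:hi] - row_lo).astype(np.int64)
        counts = np.empty((hi - lo, 5, L), dtype=np.int32)
        for b in range(5):
            counts[:, b, :] = np.add.reduceat(
                (sub == b).astype(np.int32), rel, axis=0
            )
        yield lo, counts


def call_all_molecules(
    batch: ReadBatch,
    reference: ROIAnnotation,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> MoleculeCallSet:
    """Full vectorized reads -> copies -> molecules consensus for a sample."""
    copy_umis, _copy_ulcis, copy_calls = consensus_copies(batch, cfg)
    L = len(reference)
    if len(copy_umis) == 0:
        return MoleculeCallSet(
            umis=np.empty(0, object), n_copies=np.empty(0, np.int64),
            variants=_empty_variants(), coverage=np.zeros(L, np.int64),
            n_molecules_total=0, n_discarded=0,
        )
    mol_codes, mol_umis = pd.factorize(pd.Series(copy_umis), sort=False)
    order = np.argsort(mol_codes, kind="stable")
    mol_idx = mol_codes[order]
    copy_calls = copy_calls[order]
    n_mols = len(mol_umis)
    n_copies = np.bincount(mol_idx, minlength=n_mols)

    retained_mask = n_copies >= cfg.min_linear_copies
    ref = reference.codes.astype(np.int64)
    coverage = np.zeros(L, dtype=np.int64)
    var_mol, var_pos, var_alt = [], [], []
    # map original molecule index -> retained index
    retained_new = np.cumsum(retained_mask) - 1

    for lo, counts in _molecule_counts_chunks(copy_calls, mol_idx):
        hi = lo + counts.shape[0]
        rmask = retained_mask[lo:hi]
        if not rmask.any():
            continue
        counts = counts[rmask]
        informative = counts[:, :4, :].sum(axis=1)
        covered = informative >= cfg.min_linear_copies
        coverage += covered.sum(axis=0)
        best = counts[:, :4, :].argmax(axis=1)
        best_count = np.take_along_axis(
            counts[:, :4, :], best[:, None, :], axis=1
        )[:, 0, :]
        is_var = (
            covered
            & (best != ref[None, :])
            & (best_count >= cfg.molecule_copy_agreement * informative - _EPS)
            & (informative > 0)
        )
        mm, pp = np.nonzero(is_var)
        if len(mm):
            orig = np.nonzero(rmask)[0][mm] + lo
            var_mol.append(retained_new[orig])
            var_pos.append(pp)
            var_alt.append(best[mm, pp])

    if var_mol:
        vm = np.concatenate(var_mol)
        vp = np.concatenate(var_pos)
        va = np.concatenate(var_alt)
        variants = pd.DataFrame(
            {
                "mol": vm.astype(np.int64),
                "pos": vp.astype(np.int64),
                "ref": [BASES[ref[p]] for p in vp],
                "alt": [BASES[a] for a in va],
            }
        )
    else:
        variants = _empty_variants()

    return MoleculeCallSet(
        umis=np.asarray(mol_umis, dtype=object)[retained_mask],
        n_copies=n_copies[retained_mask],
        variants=variants,
        coverage=coverage,
        n_molecules_total=n_mols,
        n_discarded=int((~retained_mask).sum()),
    )


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        {"mol": pd.Series(dtype=np.int64), "pos": pd.Series(dtype=np.int64),
         "ref": pd.Series(dtype=object), "alt": pd.Series(dtype=object)}
    )


def copy_support_curve(
    batch: ReadBatch,
    reference: ROIAnnotation,
    min_copies_values: Sequence[int],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> pd.DataFrame:
    """Called error frequency as a function of the required number of
    supporting linear copies.

    For each threshold k, molecules with at least k linear copies are
    considered, a position counts as covered when informative in at least
    k copies, and a variant is called when at least k copies agree on the
    same alt base.  At k=1 every per-copy artifact is admitted; artifact
    coincidences decay geometrically with k while true errors (present in
    every copy) survive, so the curve plateaus at the true error rate once
    k reaches ~3.  Internal ROI positions only.

    Returns a DataFrame with columns ``min_copies, n_variants,
    opportunities, frequency``.
    """
    copy_umis, _ulcis, copy_calls = consensus_copies(batch, cfg)
    L = len(reference)
    ks = sorted(set(int(k) for k in min_copies_values))
    if len(copy_umis) == 0:
        return pd.DataFrame(
            {"min_copies": ks, "n_variants": 0, "opportunities": 0,
             "frequency": np.nan}
        )
    mol_codes, _ = pd.factorize(pd.Series(copy_umis), sort=False)
    order = np.argsort(mol_codes, kind="stable")
    mol_idx = mol_codes[order]
    copy_calls = copy_calls[order]
    n_copies = np.bincount(mol_idx)
    ref = reference.codes.astype(np.int64)
    internal = np.zeros(L, dtype=bool)
    internal[1:-1] = True

    n_var = {k: 0 for k in ks}
    opp = {k: 0 for k in ks}
    for lo, counts in _molecule_counts_chunks(copy_calls, mol_idx):
        hi = lo + counts.shape[0]
        informative = counts[:, :4, :].sum(axis=1)
        alt_counts = counts[:, :4, :].copy()
        # zero out the reference base so the max is over alts only
        alt_counts[:, ref, np.arange(L)] = 0
        max_alt = alt_counts.max(axis=1)
        for k in ks:
            rmask = n_copies[lo:hi] >= k
            if not rmask.any():
                continue
            covered = (informative[rmask] >= k) & internal[None, :]
            opp[k] += int(covered.sum())
            n_var[k] += int((covered & (max_alt[rmask] >= k)).sum())

    rows = []
    for k in ks:
        freq = n_var[k] / opp[k] if opp[k] else float("nan")
        rows.append(
            {"min_copies": k, "n_variants": n_var[k], "opportunities": opp[k],
             "frequency": freq}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# error tabulation
# ---------------------------------------------------------------------------

def tabulate_errors(
    molecules: MoleculeCallSet, annotation: ROIAnnotation
) -> pd.DataFrame:
    """Aggregate molecule variants into 192-channel counts + opportunities.

    Each called variant increments its (template trinucleotide, alt)
    channel; opportunities are per-molecule covered internal positions
    summed per trinucleotide (with full coverage this equals
    n_molecules x ROI context counts).  Variants at the terminal positions
    (no trinucleotide context) are excluded.
    """
    L = len(annotation)
    counts = np.zeros(192, dtype=np.int64)
    excluded = 0
    if len(molecules.variants):
        pos = molecules.variants["pos"].to_numpy()
        alt = np.array([BASES.index(a) for a in molecules.variants["alt"]])
        tri = annotation.trinuc[pos]
        valid = tri >= 0
        excluded = int((~valid).sum())
        chan = CHANNEL_LOOKUP[tri[valid], alt[valid]]
        counts += np.bincount(chan, minlength=192)
    if excluded:
        import logging

        logging.getLogger(__name__).info(
            "%d variant(s) at terminal ROI positions excluded from "
            "tabulation", excluded,
        )
    tri_opp = np.zeros(64, dtype=np.int64)
    internal_pos = np.arange(1, L - 1)
    tri_codes = annotation.trinuc[internal_pos]
    np.add.at(tri_opp, tri_codes[tri_codes >= 0],
              molecules.coverage[internal_pos][tri_codes >= 0])
    opp = np.repeat(tri_opp, 3)
    return pd.DataFrame(
        {
            "context": [t for t, _ in CHANNELS_192],
            "alt": [a for _, a in CHANNELS_192],
            "count": counts,
            "opportunity": opp,
        }
    )
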