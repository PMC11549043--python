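"""Mutation-table analyses: spectra, replication-strand asymmetry,
methylation dependence, MMR-active-region depletion, de novo filtering.

Inputs are plain tables: single-base substitutions as (sample, chrom,
1-based pos, ref, alt) with everything reported on the plus strand;
replication domains as fixed-width 20-kb BED intervals annotated with the
direction of fork movement (left/right) and replication timing; per-CpG
methylation beta values from bisulfite sequencing; and H3K36me3-style
peak intervals.  Intervals are half-open 0-based on disk (BED) and
converted to 1-based points where they meet mutations.

Strand convention: the leading-strand template is the plus strand in
left-replicating domains and the minus strand in right-replicating
domains (and vice versa for the lagging template).  A mutation is
assigned the strand class of the strand carrying its mutated pyrimidine
(for CpG>TpG, the C).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats

from ._channels import BASES, CHANNEL_96_INDEX, CHANNELS_96, encode, revcomp

PYRIMIDINES = {"C", "T"}
PURINES = {"G", "A"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt"]


def read_mutation_table(path) -> pd.DataFrame:
    """Read a (sample, chrom, pos, ref, alt) TSV of SNVs."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns {missing}")
    return validate_mutations(df)


def validate_mutations(df: pd.DataFrame) -> pd.DataFrame:
    bad = df[(df["ref"] == df["alt"])
             | ~df["ref"].isin(list(BASES)) | ~df["alt"].isin(list(BASES))]
    if len(bad):
        raise ValueError(f"{len(bad)} records are not valid single-base substitutions")
    return df


def read_mutation_vcf(path, sample_id: str) -> pd.DataFrame:
    """Read SNVs from a minimal single-sample VCF."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        if not v.is_snp:
            continue
        rows.append((sample_id, v.CHROM, v.POS, v.REF, v.ALT[0]))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def read_domains_bed(path) -> pd.DataFrame:
    """BED with extra columns: chrom, start, end, direction, timing."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "direction", "timing"],
                     dtype={0: str})
    if not set(df["direction"]) <= {"left", "right"}:
        raise ValueError("domain direction must be 'left' or 'right'")
    return df


def read_methylation_map(path, min_coverage: int = 5) -> pd.DataFrame:
    """bedGraph-like TSV (chrom, pos, beta, coverage); sites below the
    coverage floor are dropped."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos", "beta"} <= set(df.columns):
        raise ValueError("methylation map needs chrom, pos, beta columns")
    if (df["beta"].min() < 0) or (df["beta"].max() > 1):
        raise ValueError("beta values must lie in [0, 1]")
    if "coverage" in df.columns:
        df = df[df["coverage"] >= min_coverage]
    return df.reset_index(drop=True)


def read_regions_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={0: str})
    return df


# ---------------------------------------------------------------------------
# genome context helpers
# ---------------------------------------------------------------------------

class GenomeContexts:
    """Trinucleotide context lookup over a genome (dict of sequences or a
    FASTA path opened with pyfaidx)."""

    def __init__(self, genome: Union[Dict[str, str], str]):
        if isinstance(genome, dict):
            self._seqs = {c: s.upper() for c, s in genome.items()}
            self._fa = None
        else:
            from pyfaidx import Fasta

            self._fa = Fasta(str(genome), sequence_always_upper=True)
            self._seqs = None

    def chrom_names(self):
        return list(self._seqs) if self._seqs is not None else list(self._fa.keys())

    def sequence(self, chrom: str) -> str:
        if self._seqs is not None:
            return self._seqs[chrom]
        return str(self._fa[chrom][:])

    def trinuc(self, chrom: str, pos1: int) -> Optional[str]:
        """Plus-strand trinucleotide around a 1-based position."""
        if self._seqs is not None:
            s = self._seqs[chrom]
            if pos1 < 2 or pos1 > len(s) - 1:
                return None
            return s[pos1 - 2 : pos1 + 1]
        if pos1 < 2:
            return None
        tri = str(self._fa[chrom][pos1 - 2 : pos1 + 1])
        return tri if len(tri) == 3 else None


def pyrimidine_context_occurrences(
    genome: Union[GenomeContexts, Dict[str, str], str],
    chroms: Optional[Sequence[str]] = None,
) -> Dict[str, int]:
    """Occurrences of the 32 pyrimidine-centric trinucleotide contexts,
    counting both strands (a plus-strand purine context counts toward its
    reverse complement)."""
    gc = genome if isinstance(genome, GenomeContexts) else GenomeContexts(genome)
    counts: Dict[str, int] = {}
    for chrom in chroms or gc.chrom_names():
        seq = gc.sequence(chrom)
        codes = encode(seq)
        tri = 16 * codes[:-2].astype(np.int64) + 4 * codes[1:-1] + codes[2:]
        valid = (codes[:-2] < 4) & (codes[1:-1] < 4) & (codes[2:] < 4)
        binc = np.bincount(tri[valid], minlength=64)
        from ._channels import TRINUCS

        for t, c in zip(TRINUCS, binc):
            if c == 0:
                continue
            key = t if t[1] in PYRIMIDINES else revcomp(t)
            counts[key] = counts.get(key, 0) + int(c)
    return counts


def mutational_profile(
    muts: pd.DataFrame,
    occurrences: Dict[str, int],
    genome: Union[GenomeContexts, Dict[str, str], str, None] = None,
    context_col: str = "context",
    per_sample: bool = False,
) -> Union[pd.Series, pd.DataFrame]:
    """96-channel mutational profile(s): counts per (context, alt) divided
    by the occurrences of the context.

    Context is taken from a precomputed `context_col` (plus-strand
    trinucleotide) if present, otherwise looked up in `genome`.
    Purine-reference mutations are mapped to the reverse-complement
    pyrimidine channel.  Mutations whose stated ref disagrees with the
    genome base are excluded (their count is reported via the
    ``excluded`` attribute of the result).
    """
    validate_mutations(muts)
    if context_col in muts.columns:
        contexts = muts[context_col].astype(str)
    elif genome is not None:
        gc = genome if isinstance(genome, GenomeContexts) else GenomeContexts(genome)
        contexts = pd.Series(
            [gc.trinuc(c, int(p)) for c, p in zip(muts["chrom"], muts["pos"])],
            index=muts.index,
        )
    else:
        raise ValueError("need either a context column or a genome")

    channels = np.full(len(muts), -1, dtype=np.int64)
    excluded = 0
    for i, (ctx, ref, alt) in enumerate(zip(contexts, muts["ref"], muts["alt"])):
        if ctx is None or not isinstance(ctx, str) or len(ctx) != 3:
            excluded += 1
            continue
        if ctx[1] != ref:
            excluded += 1
            continue
        if ref in PURINES:
            ctx, alt = revcomp(ctx), _COMP[alt]
        key = (ctx, alt)
        if key not in CHANNEL_96_INDEX:
            excluded += 1
            continue
        channels[i] = CHANNEL_96_INDEX[key]

    occ = np.array([occurrences.get(t, 0) for t, _ in CHANNELS_96], dtype=float)
    labels = [f"{t}>{a}" for t, a in CHANNELS_96]

    def _one(chan_subset) -> pd.Series:
        counts = np.bincount(chan_subset[chan_subset >= 0], minlength=96)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(occ > 0, counts / np.maximum(occ, 1.0), 0.0)
        return pd.Series(freq, index=labels)

    if per_sample:
        out = {}
        for s, idx in muts.groupby("sample").indices.items():
            out[s] = _one(channels[idx])
        result = pd.DataFrame(out).T
    else:
        result = _one(channels)
    result.attrs["excluded"] = excluded
    return result


# ---------------------------------------------------------------------------
# replication strand
# ---------------------------------------------------------------------------

def _domain_trees(domains: pd.DataFrame):
    from intervaltree import IntervalTree

    trees: Dict[str, "IntervalTree"] = {}
    for chrom, grp in domains.groupby("chrom"):
        t = IntervalTree()
        for _, r in grp.iterrows():
            if r["end"] > r["start"]:
                t[int(r["start"]) : int(r["end"])] = str(r["direction"])
        trees[chrom] = t
    return trees


def annotate_replication_strand(
    muts: pd.DataFrame, domains: pd.DataFrame
) -> pd.Series:
    """Label each mutation leading_template / lagging_template /
    unannotated based on the strand carrying its mutated pyrimidine and
    the replication direction of the containing 20-kb domain."""
    trees = _domain_trees(domains)
    known_chroms = set(domains["chrom"])
    mut_chroms = set(muts["chrom"])
    if mut_chroms and not (mut_chroms & known_chroms):
        import warnings

        warnings.warn(
            "no mutation chromosome matches any domain chromosome — "
            "assembly or naming mismatch?", stacklevel=2,
        )
    labels = []
    for chrom, pos, ref in zip(muts["chrom"], muts["pos"], muts["ref"]):
        tree = trees.get(chrom)
        hits = tree[int(pos) - 1] if tree is not None else set()
        if not hits:
            labels.append("unannotated")
            continue
        direction = next(iter(hits)).data
        pyr_on_plus = ref in PYRIMIDINES
        # leading template: plus strand in left-replicating domains
        if (pyr_on_plus and direction == "left") or (
            not pyr_on_plus and direction == "right"
        ):
            labels.append("leading_template")
        else:
            labels.append("lagging_template")
    return pd.Series(labels, index=muts.index, name="strand")


def is_cpg_tpg(muts: pd.DataFrame, genome) -> pd.Series:
    """CpG>TpG mask: C>T with a 3' G, or G>A with a 5' C (plus strand)."""
    gc = genome if isinstance(genome, GenomeContexts) else GenomeContexts(genome)
    mask = []
    for chrom, pos, ref, alt in zip(muts["chrom"], muts["pos"], muts["ref"], muts["alt"]):
        tri = gc.trinuc(chrom, int(pos))
        if tri is None:
            mask.append(False)
        elif ref == "C" and alt == "T":
            mask.append(tri[2] == "G")
        elif ref == "G" and alt == "A":
            mask.append(tri[0] == "C")
        else:
            mask.append(False)
    return pd.Series(mask, index=muts.index)


def cpg_strand_opportunities(genome, domains: pd.DataFrame) -> Dict[str, int]:
    """CpG cytosine counts on the leading and lagging template strands
    within domains.  A CpG site carries one C per strand, so both classes
    see every in-domain CpG site once."""
    gc = genome if isinstance(genome, GenomeContexts) else GenomeContexts(genome)
    n = 0
    for chrom, grp in domains.groupby("chrom"):
        try:
            seq = gc.sequence(chrom)
        except KeyError:
            continue
        codes = encode(seq)
        cpg = (codes[:-1] == 1) & (codes[1:] == 2)
        pos = np.nonzero(cpg)[0]
        for _, r in grp.iterrows():
            n += int(((pos >= r["start"]) & (pos < r["end"])).sum())
    return {"leading_template": n, "lagging_template": n}


def strand_asymmetry(
    muts: pd.DataFrame,
    domains: pd.DataFrame,
    genome,
    context_filter: Optional[str] = "CpG>TpG",
    opportunities: Optional[Dict[str, int]] = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-sample log2(leading/lagging) mutation frequency ratio.

    Frequencies are normalized by per-strand context opportunities.
    Samples with zero mutations on both strands are excluded; when
    exactly one strand has zero mutations, `pseudocount` is added to both
    strands' counts so the sample is kept without an infinite ratio.
    """
    if context_filter == "CpG>TpG":
        muts = muts[is_cpg_tpg(muts, genome)]
        if opportunities is None:
            opportunities = cpg_strand_opportunities(genome, domains)
    elif context_filter is not None:
        raise ValueError(f"unsupported context filter {context_filter!r}")
    if opportunities is None:
        raise ValueError("opportunities are required without a context filter")
    if opportunities["leading_template"] == 0 or opportunities["lagging_template"] == 0:
        raise ValueError("zero strand opportunities")

    strand = annotate_replication_strand(muts, domains)
    rows = []
    for sample, grp in muts.groupby("sample"):
        s = strand.loc[grp.index]
        n_lead = int((s == "leading_template").sum())
        n_lag = int((s == "lagging_template").sum())
        if n_lead + n_lag == 0:
            continue
        lead, lag = float(n_lead), float(n_lag)
        if n_lead == 0 or n_lag == 0:
            lead += pseudocount
            lag += pseudocount
        f_lead = lead / opportunities["leading_template"]
        f_lag = lag / opportunities["lagging_template"]
        rows.append(
            {
                "sample": sample,
                "n_leading": n_lead,
                "n_lagging": n_lag,
                "leading_freq": f_lead,
                "lagging_freq": f_lag,
                "log2_ratio": float(np.log2(f_lead / f_lag)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylation binning
# ---------------------------------------------------------------------------

def methylation_binned_frequency(
    muts: pd.DataFrame,
    methmap: pd.DataFrame,
    bins: Union[int, Sequence[float]] = 10,
    per_sample: bool = False,
) -> pd.DataFrame:
    """CpG>TpG mutation frequency in CpGs binned by methylation beta.

    The CpG universe is the methylation map (1-based position of the
    plus-strand C).  A site counts as mutated in a sample when the sample
    has a C>T at the site or a G>A at site+1.  The pooled frequency is
    mutated-site events per (site x sample).  Empty bins get NaN.
    """
    if isinstance(bins, int):
        edges = np.linspace(0.0, 1.0, bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    site_key = methmap["chrom"].astype(str) + ":" + methmap["pos"].astype(str)
    site_bin = np.clip(np.searchsorted(edges, methmap["beta"], side="right") - 1,
                       0, len(edges) - 2)
    bin_of_site = dict(zip(site_key, site_bin))
    sites_per_bin = np.bincount(site_bin, minlength=len(edges) - 1)

    c_hits = muts[(muts["ref"] == "C") & (muts["alt"] == "T")]
    g_hits = muts[(muts["ref"] == "G") & (muts["alt"] == "A")]
    keys = pd.concat(
        [
            pd.DataFrame(
                {"sample": c_hits["sample"],
                 "key": c_hits["chrom"].astype(str) + ":" + c_hits["pos"].astype(str)}
            ),
            pd.DataFrame(
                {"sample": g_hits["sample"],
                 "key": g_hits["chrom"].astype(str) + ":" + (g_hits["pos"] - 1).astype(str)}
            ),
        ],
        ignore_index=True,
    )
    keys = keys[keys["key"].isin(bin_of_site)]
    keys["bin"] = keys["key"].map(bin_of_site)

    samples = sorted(muts["sample"].unique())
    n_samples = max(len(samples), 1)
    records = []
    if per_sample:
        for s in samples:
            kb = keys[keys["sample"] == s]
            counts = np.bincount(kb["bin"], minlength=len(edges) - 1)
            for b in range(len(edges) - 1):
                freq = counts[b] / sites_per_bin[b] if sites_per_bin[b] else np.nan
                records.append(
                    {"sample": s, "bin_low": edges[b], "bin_high": edges[b + 1],
                     "n_sites": int(sites_per_bin[b]), "n_mutations": int(counts[b]),
                     "frequency": freq}
                )
    else:
        counts = np.bincount(keys["bin"], minlength=len(edges) - 1)
        for b in range(len(edges) - 1):
            denom = sites_per_bin[b] * n_samples
            freq = counts[b] / denom if denom else np.nan
            records.append(
                {"bin_low": edges[b], "bin_high": edges[b + 1],
                 "n_sites": int(sites_per_bin[b]), "n_mutations": int(counts[b]),
                 "frequency": freq}
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# MMR-active regions
# ---------------------------------------------------------------------------

def _region_trees(regions: pd.DataFrame):
    from intervaltree import IntervalTree

    trees: Dict[str, "IntervalTree"] = {}
    for chrom, grp in regions.groupby("chrom"):
        t = IntervalTree()
        for _, r in grp.iterrows():
            if r["end"] > r["start"]:
                t[int(r["start"]) : int(r["end"])] = True
        trees[chrom] = t
    return trees


def mmr_region_ratio(
    muts: pd.DataFrame,
    regions_inside: pd.DataFrame,
    methmap: pd.DataFrame,
    beta_min: float = 0.9,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-sample log2 ratio of CpG>TpG frequency inside/outside regions.

    Restricted to methylated CpGs (beta >= `beta_min`) so the comparison
    is not confounded by 5mC levels.  ``regions_inside`` marks the
    MMR-active class (early-replicating or H3K36me3 peaks); frequency is
    mutated CpGs per eligible CpG in each class.  Samples with a class
    lacking eligible CpGs are excluded; a pseudocount keeps samples with
    zero mutations on one side finite.
    """
    eligible = methmap[methmap["beta"] >= beta_min]
    if len(eligible) == 0:
        return pd.DataFrame(
            columns=["sample", "n_inside", "n_outside", "freq_inside",
                     "freq_outside", "log2_ratio"]
        )
    trees = _region_trees(regions_inside)
    inside_mask = np.array(
        [
            bool(trees.get(c) and trees[c][int(p) - 1])
            for c, p in zip(eligible["chrom"], eligible["pos"])
        ]
    )
    n_in = int(inside_mask.sum())
    n_out = int((~inside_mask).sum())
    if n_in == 0 or n_out == 0:
        return pd.DataFrame(
            columns=["sample", "n_inside", "n_outside", "freq_inside",
                     "freq_outside", "log2_ratio"]
        )
    site_class = dict(
        zip(
            eligible["chrom"].astype(str) + ":" + eligible["pos"].astype(str),
            inside_mask,
        )
    )
    rows = []
    for sample, grp in muts.groupby("sample"):
        c_hits = grp[(grp["ref"] == "C") & (grp["alt"] == "T")]
        g_hits = grp[(grp["ref"] == "G") & (grp["alt"] == "A")]
        hit_keys = pd.concat(
            [
                c_hits["chrom"].astype(str) + ":" + c_hits["pos"].astype(str),
                g_hits["chrom"].astype(str) + ":" + (g_hits["pos"] - 1).astype(str),
            ]
        )
        k_in = k_out = 0
        for key in hit_keys:
            cls = site_class.get(key)
            if cls is None:
                continue
            if cls:
                k_in += 1
            else:
                k_out += 1
        if k_in == 0 and k_out == 0:
            continue
        a, b = float(k_in), float(k_out)
        if k_in == 0 or k_out == 0:
            a += pseudocount
            b += pseudocount
        f_in = a / n_in
        f_out = b / n_out
        rows.append(
            {"sample": sample, "n_inside": k_in, "n_outside": k_out,
             "freq_inside": f_in, "freq_outside": f_out,
             "log2_ratio": float(np.log2(f_in / f_out))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# de novo filter
# ---------------------------------------------------------------------------

def filter_de_novo(
    variants: pd.DataFrame,
    cov_min: int = 10,
    cov_max: int = 40,
    vaf_min: float = 0.25,
    vaf_max: float = 0.75,
    max_other_alt: int = 0,
) -> pd.DataFrame:
    """Retain de novo candidate variants.

    `variants` is a long table with columns (chrom, pos, ref, alt,
    sample, depth, alt_reads, called).  A variant (chrom, pos, ref, alt)
    survives when: it is called in exactly one sample; depth lies in
    [cov_min, cov_max] in ALL samples (a sample with missing depth
    excludes the site); no other sample shows more than `max_other_alt`
    alt-supporting reads; and the called sample's variant allele
    frequency lies in [vaf_min, vaf_max].  Returns the surviving
    (chrom, pos, ref, alt, sample) records.
    """
    required = {"chrom", "pos", "ref", "alt", "sample", "depth", "alt_reads", "called"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    out = []
    n_samples = variants["sample"].nunique()
    for (chrom, pos, ref, alt), grp in variants.groupby(
        ["chrom", "pos", "ref", "alt"], sort=True
    ):
        if len(grp) < n_samples or grp["depth"].isna().any():
            continue  # insufficiently characterized site
        called = grp[grp["called"].astype(bool)]
        if len(called) != 1:
            continue
        depths = grp["depth"].to_numpy(dtype=float)
        if (depths < cov_min).any() or (depths > cov_max).any():
            continue
        others = grp[~grp["called"].astype(bool)]
        if (others["alt_reads"] > max_other_alt).any():
            continue
        row = called.iloc[0]
        vaf = row["alt_reads"] / row["depth"]
        if not (vaf_min <= vaf <= vaf_max):
            continue
        out.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
             "sample": row["sample"], "vaf": float(vaf)}
        )
    return pd.DataFrame(out, columns=["chrom", "pos", "ref", "alt", "sample", "vaf"])


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def sign_test(values: Iterable[float]) -> float:
    """Exact two-sided sign test that the median of the differences is 0.

    Zeros are dropped; the p value is the two-sided binomial(n, 1/2) tail
    probability of the observed positive/negative split, capped at 1.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[v != 0]
    if len(v) == 0:
        raise ValueError("sign test undefined: all differences are zero")
    n_pos = int((v > 0).sum())
    return float(scipy.stats.binomtest(n_pos, len(v), 0.5).pvalue)


def rank_and_mean_tests(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: Literal["mann_whitney", "welch_t", "paired_t"] = "mann_whitney",
) -> float:
    """Two-sided two-sample tests: Mann-Whitney U (exact below n=20
    without ties, normal approximation with tie correction otherwise),
    Welch's t (unequal variances), or paired t."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if mode == "paired_t":
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired test needs >= 2 pairs of equal length")
        d = a - b
        if np.allclose(d.std(ddof=1), 0):
            raise ValueError("degenerate variance: all paired differences equal")
        return float(scipy.stats.ttest_rel(a, b).pvalue)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("group sizes must be >= 2")
    if mode == "welch_t":
        if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
            raise ValueError("degenerate variance in both groups")
        return float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)
    if mode == "mann_whitney":
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
        return float(
            scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    raise ValueError(f"unknown mode {mode!r}")
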