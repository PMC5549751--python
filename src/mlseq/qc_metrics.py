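"""Quantitative quality control for multi-level RNA-seq designs.

Beyond the usual per-sample summaries (strand bias, nucleotide composition,
depth), the discriminating metrics here operate at gene level: per-gene
complexity (NR/R of the incident reads), the Jaccard similarity of the top-N
most abundant genes, and the point-to-point Pearson correlation (p2pPCC)
between per-position coverage vectors — which detects coverage-shape
discordance that whole-gene abundance correlations hide.  These feed replicate
outlier detection and the empirical estimation of the abundance noise floor
("offset") used downstream by the differential-expression call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import AlignmentSet, AnnotationIndex, GeneCoverageModel, ReadSet

_CORR_METHODS = {"PCC": "pearson", "SCC": "spearman", "KCC": "kendall"}


# ---------------------------------------------------------------------------
# Sample-level metrics
# ---------------------------------------------------------------------------


def strand_bias(al: AlignmentSet, ann: AnnotationIndex) -> float:
    """Strand bias |P - 0.5| + |N - 0.5| over CDS-incident redundant reads.

    P and N are the proportions of CDS-incident redundant read placements on
    the + and - strand.  0 means perfectly balanced, 1 fully stranded.
    Returns NaN (with a warning) when no read is CDS-incident.
    """
    if al.records.empty:
        warnings.warn("strand_bias: no CDS-incident reads", stacklevel=2)
        return float("nan")
    rec = al.records
    mask = [
        ann.overlaps_class("CDS", c, s, e)
        for c, s, e in zip(rec["chrom"], rec["start"], rec["end"])
    ]
    sub = rec[np.asarray(mask, dtype=bool)]
    if sub.empty:
        warnings.warn("strand_bias: no CDS-incident reads", stacklevel=2)
        return float("nan")
    plus = float(sub.loc[sub["strand"] == "+", "count"].sum())
    minus = float(sub.loc[sub["strand"] == "-", "count"].sum())
    total = plus + minus
    p, n = plus / total, minus / total
    return abs(p - 0.5) + abs(n - 0.5)


def nucleotide_composition(rs: ReadSet) -> pd.DataFrame:
    """Per-position base frequencies over redundant reads (rows sum to 1)."""
    bases = ["A", "C", "G", "T", "N"]
    if rs.R == 0:
        return pd.DataFrame(columns=bases)
    counts = np.zeros((rs.read_length, len(bases)))
    idx = {b: i for i, b in enumerate(bases)}
    for seq, c in rs.counts.items():
        for pos, base in enumerate(seq):
            counts[pos, idx.get(base, idx["N"])] += c
    freq = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freq, columns=bases)


def sample_complexity(rs: ReadSet) -> float:
    """NR/R ratio; ~0 when all reads identical, 1 when all distinct."""
    return rs.complexity()


def gene_complexity(al: AlignmentSet, ann: AnnotationIndex) -> pd.DataFrame:
    """Per-gene R, NR and complexity C = NR/R of the incident unique reads."""
    from collections import defaultdict

    per_gene: Dict[str, set] = defaultdict(set)
    for seq, chrom, start, end in zip(
        al.records["seq"], al.records["chrom"], al.records["start"], al.records["end"]
    ):
        for gid in ann.genes_overlapping(chrom, start, end):
            per_gene[gid].add(seq)
    rows = []
    for gid in ann.gene_ids():
        seqs = per_gene.get(gid, set())
        r = sum(al.counts[s] for s in seqs)
        nr = len(seqs)
        rows.append((gid, r, nr, nr / r if r else np.nan))
    return pd.DataFrame(rows, columns=["gene", "R", "NR", "C"]).set_index("gene")


# ---------------------------------------------------------------------------
# Complexity-difference profiles
# ---------------------------------------------------------------------------


def _log2_bin(abundance: np.ndarray) -> np.ndarray:
    """Width-1 log2 abundance bin, lower-edge inclusive (bin b = [2^b, 2^(b+1)))."""
    return np.floor(np.log2(abundance)).astype(int)


@dataclass
class ComplexityDiffProfile:
    """Binned per-gene absolute complexity differences between two samples.

    ``per_gene`` holds one row per gene expressed in both samples: its mean
    incident abundance, abundance bin and |C_A - C_B| (all in [0, 1]).
    Reference lines at 0.05 and 0.1 flag replicate discordance.
    """

    per_gene: pd.DataFrame
    n_exclusive: int = 0
    reference_lines: Tuple[float, float] = (0.05, 0.1)

    def bin_medians(self) -> pd.Series:
        if self.per_gene.empty:
            return pd.Series(dtype=float)
        return self.per_gene.groupby("bin")["dC"].median()

    def hump_bins(self, line: float = 0.05, min_run: int = 3) -> List[int]:
        """Bins inside the longest run of >= min_run consecutive bins whose
        median |dC| exceeds ``line`` (a replicate-discordance 'hump')."""
        med = self.bin_medians()
        if med.empty:
            return []
        bins = sorted(med.index)
        best: List[int] = []
        run: List[int] = []
        prev = None
        for b in bins:
            if med[b] > line and (prev is None or b == prev + 1 or not run):
                if run and b != prev + 1:
                    run = []
                run.append(b)
            else:
                run = []
            prev = b
            if len(run) > len(best):
                best = list(run)
        return best if len(best) >= min_run else []


def complexity_diff_profile(
    alA: AlignmentSet, alB: AlignmentSet, ann: AnnotationIndex
) -> ComplexityDiffProfile:
    """Per-gene |C_A - C_B| binned by log2 mean incident abundance.

    Genes expressed in only one of the samples are excluded from the profile
    and counted in ``n_exclusive``.
    """
    ga = gene_complexity(alA, ann)
    gb = gene_complexity(alB, ann)
    both = (ga["R"] > 0) & (gb["R"] > 0)
    either = (ga["R"] > 0) | (gb["R"] > 0)
    n_exclusive = int(either.sum() - both.sum())
    if not both.any():
        warnings.warn("complexity_diff_profile: no genes expressed in both samples",
                      stacklevel=2)
        return ComplexityDiffProfile(
            pd.DataFrame(columns=["abundance", "bin", "dC"]), n_exclusive
        )
    mean_ab = (ga.loc[both, "R"] + gb.loc[both, "R"]) / 2.0
    dC = (ga.loc[both, "C"] - gb.loc[both, "C"]).abs()
    per_gene = pd.DataFrame(
        {"abundance": mean_ab, "bin": _log2_bin(mean_ab.values), "dC": dC}
    )
    return ComplexityDiffProfile(per_gene, n_exclusive)


# ---------------------------------------------------------------------------
# Similarity and correlation
# ---------------------------------------------------------------------------


def _top_n_set(expr: pd.Series, n: int) -> set:
    expressed = expr[expr > 0]
    if len(expressed) == 0:
        return set()
    if len(expressed) < n:
        warnings.warn(
            f"jaccard_topN: only {len(expressed)} expressed genes (< {n}); using all",
            stacklevel=3,
        )
        return set(expressed.index)
    ordered = expressed.sort_values(ascending=False)
    threshold = ordered.iloc[n - 1]
    # include all genes tied with the N-th abundance: deterministic, order-free
    return set(expressed[expressed >= threshold].index)


def jaccard_topN(exprA: pd.Series, exprB: pd.Series, n: int = 1000) -> float:
    """Jaccard similarity of the top-N most abundant gene sets.

    J = |topN(A) & topN(B)| / |topN(A) | topN(B)|; ties at rank N are all
    included.  1.0 for a sample against itself; NaN when both sets are empty.
    """
    a, b = _top_n_set(exprA, n), _top_n_set(exprB, n)
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


def jaccard_matrix(expr: pd.DataFrame, n: int = 1000) -> pd.DataFrame:
    """Symmetric sample-by-sample Jaccard top-N similarity matrix."""
    samples = list(expr.columns)
    sets = {s: _top_n_set(expr[s], n) for s in samples}
    mat = pd.DataFrame(index=samples, columns=samples, dtype=float)
    for i, s in enumerate(samples):
        for t in samples[i:]:
            union = sets[s] | sets[t]
            val = len(sets[s] & sets[t]) / len(union) if union else np.nan
            mat.loc[s, t] = mat.loc[t, s] = val
    return mat


def correlation_matrix(expr: pd.DataFrame, method: str = "PCC") -> pd.DataFrame:
    """Sample-by-sample correlation of gene-expression vectors.

    ``method`` is one of PCC (Pearson), SCC (Spearman) or KCC (Kendall
    tau-b).  Constant columns yield NaN off-diagonal entries.
    """
    if method not in _CORR_METHODS:
        raise ValueError(f"method must be one of {sorted(_CORR_METHODS)}")
    if len(expr) < 2:
        raise ValueError("correlation requires >= 2 genes")
    mat = expr.corr(method=_CORR_METHODS[method])
    np.fill_diagonal(mat.values, 1.0)
    return mat


# ---------------------------------------------------------------------------
# Point-to-point PCC
# ---------------------------------------------------------------------------


def p2p_pcc(covA: np.ndarray, covB: np.ndarray) -> float:
    """Pearson correlation between two per-position coverage vectors.

    NaN when either vector is constant (zero variance), which includes the
    all-zero case.  The vectors must be the same length.
    """
    a = np.asarray(covA, dtype=float)
    b = np.asarray(covB, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coverage length mismatch: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class P2PProfile:
    """Per-gene p2pPCC against log2 mean abundance, with per-bin medians."""

    per_gene: pd.DataFrame  # columns: abundance, bin, p2ppcc
    pair: Tuple[str, str] = ("A", "B")

    def bin_medians(self) -> pd.Series:
        defined = self.per_gene.dropna(subset=["p2ppcc"])
        if defined.empty:
            return pd.Series(dtype=float)
        return defined.groupby("bin")["p2ppcc"].median()


def p2p_profile(
    alA: AlignmentSet,
    alB: AlignmentSet,
    ann: AnnotationIndex,
    genes: Optional[Sequence[str]] = None,
) -> P2PProfile:
    """Per-gene point-to-point PCC between two samples' coverage vectors.

    Computed for genes with incident reads in both samples; genes with
    constant coverage in either sample have undefined (NaN) p2pPCC and are
    excluded from the bin medians.
    """
    modelA = GeneCoverageModel(alA, ann, genes)
    modelB = GeneCoverageModel(alB, ann, genes)
    rows = []
    for g in modelA.lengths:
        ya = modelA.coverage(g, alA.counts)
        yb = modelB.coverage(g, alB.counts)
        ra = modelA.abundance(g, alA.counts)
        rb = modelB.abundance(g, alB.counts)
        if ra == 0 or rb == 0:
            continue
        mean_ab = (ra + rb) / 2.0
        rows.append((g, mean_ab, int(np.floor(np.log2(mean_ab))), p2p_pcc(ya, yb)))
    per_gene = pd.DataFrame(rows, columns=["gene", "abundance", "bin", "p2ppcc"])
    if not per_gene.empty:
        per_gene = per_gene.set_index("gene")
    name_a = alA.name or "A"
    name_b = alB.name or "B"
    return P2PProfile(per_gene, (name_a, name_b))


def estimate_offset(
    profiles: Sequence[P2PProfile], threshold: float = 0.7
) -> float:
    """Empirical abundance noise floor from replicate p2pPCC profiles.

    Returns the smallest bin lower edge (on the linear abundance scale,
    2**bin) such that, for *every* replicate-pair profile, the median p2pPCC
    of that bin and all higher bins exceeds ``threshold`` (worst-pair rule,
    the most conservative choice).  NaN when no bin qualifies.
    """
    medians = [p.bin_medians() for p in profiles]
    medians = [m for m in medians if not m.empty]
    if not medians:
        return float("nan")
    candidate_bins = sorted(set().union(*[set(m.index) for m in medians]))
    for b in candidate_bins:
        ok = True
        for m in medians:
            upper = m[m.index >= b]
            if upper.empty or (upper <= threshold).any():
                ok = False
                break
        if ok:
            return float(2.0 ** b)
    return float("nan")


# ---------------------------------------------------------------------------
# Outlier flagging and QC report
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Aggregated QC outputs for a set of samples."""

    sample_stats: pd.DataFrame
    jaccard: pd.DataFrame
    correlations: Dict[str, pd.DataFrame]
    offset: float = float("nan")
    outliers: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dir(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.sample_stats.to_csv(out / "sample_stats.tsv", sep="\t")
        self.jaccard.to_csv(out / "jaccard.tsv", sep="\t")
        for meth, mat in self.correlations.items():
            mat.to_csv(out / f"{meth.lower()}.tsv", sep="\t")
        (out / "offset.txt").write_text(f"{self.offset}\n")
        self.outliers.to_csv(out / "outliers.tsv", sep="\t", index=False)


def flag_outlier_replicates(
    design: pd.DataFrame,
    profiles: Mapping[Tuple[str, str], ComplexityDiffProfile],
    jaccard: pd.DataFrame,
    p2p_similarity: Optional[pd.DataFrame] = None,
    condition_cols: Optional[Sequence[str]] = None,
    line: float = 0.05,
    min_run: int = 3,
) -> pd.DataFrame:
    """Flag replicates that disagree with their siblings.

    A replicate is flagged when both hold:

    (a) its complexity-difference profile against *every* sibling replicate
        shows a contiguous hump of >= ``min_run`` bins with median |dC|
        above ``line``;
    (b) by Jaccard top-N or pairwise p2pPCC similarity, its median
        similarity to its siblings is lower than the reference similarity —
        the similarity of the remaining siblings to each other when the
        condition has >= 3 replicates, otherwise the replicate's similarity
        to other-condition samples.  Equidistant replicates therefore never
        trigger (b).

    ``profiles`` maps unordered sample pairs to complexity-difference
    profiles; ``p2p_similarity`` is an optional sample-by-sample matrix of
    median per-gene p2pPCC, which is sensitive to coverage-shape distortions
    that leave abundances (and hence the Jaccard index) unchanged.
    """
    if condition_cols is None:
        condition_cols = [c for c in design.columns if c != "replicate"]
    cond = design[list(condition_cols)].astype(str).agg("|".join, axis=1)
    sources = {"jaccard": jaccard}
    if p2p_similarity is not None:
        sources["p2ppcc"] = p2p_similarity
    rows = []
    for sample in design.index:
        siblings = [s for s in design.index if s != sample and cond[s] == cond[sample]]
        others = [s for s in design.index if cond[s] != cond[sample]]
        if not siblings:
            warnings.warn(f"flag_outlier_replicates: {sample} has no siblings",
                          stacklevel=2)
            continue
        humps = []
        for sib in siblings:
            prof = profiles.get((sample, sib)) or profiles.get((sib, sample))
            humps.append([] if prof is None else prof.hump_bins(line=line, min_run=min_run))
        hump_vs_all = all(len(h) > 0 for h in humps)
        triggers = []
        for label, mat in sources.items():
            if mat is None or sample not in mat.index:
                continue
            sib_vals = [mat.loc[sample, s] for s in siblings if s in mat.columns]
            if not sib_vals or np.all(np.isnan(sib_vals)):
                continue
            med_sib = float(np.nanmedian(sib_vals))
            sib_pairs = [
                mat.loc[a, b]
                for i, a in enumerate(siblings)
                for b in siblings[i + 1 :]
                if a in mat.index and b in mat.columns
            ]
            if sib_pairs:
                ref = float(np.nanmedian(sib_pairs))
                ref_desc = "sibling-to-sibling"
            elif others:
                ref = float(np.nanmedian([mat.loc[sample, s] for s in others]))
                ref_desc = "other-condition"
            else:
                continue
            if not np.isnan(ref) and med_sib < ref:
                triggers.append(
                    f"{label} to siblings {med_sib:.3f} < {ref_desc} reference {ref:.3f}"
                )
        less_similar = bool(triggers)
        flagged = hump_vs_all and less_similar
        reasons = []
        if hump_vs_all:
            reasons.append(
                "complexity hump vs all siblings (bins "
                + "; ".join(str(h) for h in humps)
                + ")"
            )
        reasons.extend(triggers)
        rows.append(
            {
                "sample": sample,
                "condition": cond[sample],
                "flagged": flagged,
                "hump": hump_vs_all,
                "less_similar_than_siblings_reference": less_similar,
                "reason": "; ".join(reasons) if flagged else "",
            }
        )
    return pd.DataFrame(rows)
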