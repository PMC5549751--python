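"""Subsampling-based normalization with consistency and bootstrap checks.

The primary normalization subsamples each library's redundant reads, without
replacement, down to a fixed total (the minimum depth of the accepted
samples): every selected read instance leaves the pool, so subsampled counts
follow the multivariate hypergeometric distribution over unique reads and can
never exceed the originals.  The with-replacement variant (multinomial) is
provided for comparison; it can over-amplify abundant reads and drop rare
ones.  Two protocol checks precede the fixed-total step: an incremental
subsampling exercise (95% down to 45% in steps of 5%) verifying that the
genome-matching proportion stays constant and the mean point-to-point PCC to
the original stays above 0.95, and a bootstrap representativeness check at
the fixed total.  Quantile and RPM scaling are included as baselines and as
the optional post-subsampling correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AlignmentSet,
    AnnotationIndex,
    GeneCoverageModel,
    ReadSet,
    _class_membership,
)
from .qc_metrics import p2p_pcc

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.95, 0.449, -0.05), 2))  # 0.95 .. 0.45


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _sorted_items(rs: ReadSet):
    seqs = sorted(rs.counts)
    counts = np.array([rs.counts[s] for s in seqs], dtype=np.int64)
    return seqs, counts


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------


def subsample_without_replacement(rs: ReadSet, target: int, seed=None) -> ReadSet:
    """Draw ``target`` read instances without replacement.

    Counts follow the multivariate hypergeometric distribution over unique
    reads; every subsampled count is <= the original and the totals sum to
    ``target`` exactly.  Upsampling is impossible: target must be <= R.
    """
    if not 1 <= target <= rs.R:
        raise ValueError(f"target must be in [1, R={rs.R}], got {target}")
    seqs, counts = _sorted_items(rs)
    drawn = _rng(seed).multivariate_hypergeometric(counts, target, method="marginals")
    new = {s: int(c) for s, c in zip(seqs, drawn) if c > 0}
    return ReadSet(new, rs.read_length, name=rs.name)


def subsample_with_replacement(rs: ReadSet, target: int, seed=None) -> ReadSet:
    """Draw ``target`` read instances with replacement (multinomial).

    Selection probabilities stay fixed at c_i/R throughout, so counts may
    exceed the originals (over-amplification) and rare reads may vanish.
    """
    if rs.R == 0:
        raise ValueError("cannot subsample an empty ReadSet")
    if target < 1:
        raise ValueError(f"target must be >= 1, got {target}")
    seqs, counts = _sorted_items(rs)
    drawn = _rng(seed).multinomial(target, counts / counts.sum())
    new = {s: int(c) for s, c in zip(seqs, drawn) if c > 0}
    return ReadSet(new, rs.read_length, name=rs.name)


def remove_ncrna_reads(
    rs: ReadSet,
    al: AlignmentSet,
    ann: AnnotationIndex,
    classes: Sequence[str] = ("ncRNA",),
) -> ReadSet:
    """Drop reads incident with ncRNA (t/rRNA etc.) features.

    Applied to the redundant read set before subsampling, so contaminant
    classes cannot distort the normalized distributions.
    """
    membership = _class_membership(al, ann)
    remove = set()
    for cls in classes:
        remove |= membership.get(cls, set())
    kept = {s: c for s, c in rs.counts.items() if s not in remove}
    return ReadSet(kept, rs.read_length, name=rs.name)


# ---------------------------------------------------------------------------
# Incremental consistency check
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyReport:
    """Outcome of the incremental subsampling exercise for one sample.

    One row per fraction: redundant/non-redundant totals, complexity,
    redundant genome-matching percentage and mean p2pPCC of the subsample
    against the original.  The sample passes when the genome-matching
    percentage stays within tolerance of the original at every fraction and
    the mean p2pPCC exceeds the criterion throughout.
    """

    table: pd.DataFrame
    original_pct_matching: float
    tolerance: float
    p2p_criterion: float

    @property
    def passed(self) -> bool:
        t = self.table
        within = (t["pct_genome_matching"] - self.original_pct_matching).abs() <= (
            100.0 * self.tolerance
        )
        p2p_ok = t["mean_p2ppcc"] > self.p2p_criterion
        return bool(within.all() and p2p_ok.all())


def incremental_consistency_check(
    rs: ReadSet,
    al: AlignmentSet,
    ann: AnnotationIndex,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed=None,
    tolerance: float = 0.005,
    p2p_criterion: float = 0.95,
) -> ConsistencyReport:
    """Subsample at each fraction and test structural stability.

    ``tolerance`` is the allowed absolute drift of the redundant
    genome-matching proportion (default +/-0.5 percentage points);
    ``p2p_criterion`` the minimum mean per-gene p2pPCC between subsample and
    original coverage (default 0.95).
    """
    rng = _rng(seed)
    matched = al.matched_sequences()
    model = GeneCoverageModel(al, ann)
    orig_cov = {g: model.coverage(g, al.counts) for g in model.lengths}
    expressed = [g for g, y in orig_cov.items() if y.sum() > 0]
    orig_pct = 100.0 * al.genome_matching_R / rs.R if rs.R else np.nan
    rows = []
    for f in fractions:
        target = max(1, int(round(f * rs.R)))
        sub = subsample_without_replacement(rs, target, rng)
        sub_match_R = sum(c for s, c in sub.counts.items() if s in matched)
        pccs = []
        for g in expressed:
            v = p2p_pcc(orig_cov[g], model.coverage(g, sub.counts))
            if not np.isnan(v):
                pccs.append(v)
        rows.append(
            {
                "fraction": f,
                "R": sub.R,
                "NR": sub.NR,
                "complexity": sub.complexity(),
                "pct_genome_matching": 100.0 * sub_match_R / sub.R,
                "mean_p2ppcc": float(np.mean(pccs)) if pccs else np.nan,
            }
        )
    return ConsistencyReport(pd.DataFrame(rows), orig_pct, tolerance, p2p_criterion)


# ---------------------------------------------------------------------------
# Fixed-total subsampling with bootstrap representativeness
# ---------------------------------------------------------------------------


@dataclass
class SubsampleResult:
    """A fixed-total subsample with its bootstrap diagnostics."""

    readset: ReadSet
    seed: int
    target: int
    bootstrap_pcc: np.ndarray
    chosen_index: int
    passed: bool
    requires_review: bool = False


def bootstrap_fixed_total(
    rs: ReadSet,
    al: AlignmentSet,
    ann: AnnotationIndex,
    target: int,
    n_boot: int = 10,
    seed: int = 0,
    pcc_criterion: float = 0.95,
    min_fraction: float = 0.55,
) -> SubsampleResult:
    """Subsample to a fixed total, checking representativeness by bootstrap.

    ``n_boot`` independent without-replacement subsamples are drawn; each is
    judged by the gene-level expression PCC against the original sample.  If
    all exceed ``pcc_criterion`` the draw is accepted and one subsample is
    selected at random.  Subsampling below ``min_fraction`` of the original
    depth (default 55%) is allowed but flagged ``requires_review`` for
    case-by-case assessment.
    """
    if target > rs.R:
        raise ValueError(f"target {target} exceeds R={rs.R}")
    requires_review = target / rs.R < min_fraction
    if requires_review:
        warnings.warn(
            f"{rs.name or 'sample'}: subsampling to {target / rs.R:.0%} of depth "
            f"(< {min_fraction:.0%}); flagged for case-by-case review",
            stacklevel=2,
        )
    model = GeneCoverageModel(al, ann)
    genes = list(model.lengths)
    orig_expr = np.array([model.abundance(g, al.counts) for g in genes])
    master = np.random.default_rng(seed)
    draw_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_boot)]
    subsamples, pccs = [], []
    for s in draw_seeds:
        sub = subsample_without_replacement(rs, target, s)
        subsamples.append(sub)
        expr = np.array([model.abundance(g, sub.counts) for g in genes])
        if np.ptp(orig_expr) == 0 or np.ptp(expr) == 0:
            pccs.append(np.nan)
        else:
            pccs.append(float(np.corrcoef(orig_expr, expr)[0, 1]))
    pccs = np.array(pccs)
    passed = bool(np.all(pccs > pcc_criterion))
    chosen = int(master.integers(0, n_boot))
    return SubsampleResult(
        subsamples[chosen], draw_seeds[chosen], target, pccs, chosen, passed,
        requires_review,
    )


# ---------------------------------------------------------------------------
# Matrix-level baselines
# ---------------------------------------------------------------------------


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common (mean-of-sorted) distribution.

    Each column's values are replaced by the across-sample mean of the sorted
    columns at the matching rank; ties receive the average of the reference
    values they span, so the transform is idempotent and rank-preserving.
    """
    if expr.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    values = expr.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(len(reference), dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def rpm_scale(expr: pd.DataFrame, depths: Mapping[str, float]) -> pd.DataFrame:
    """Scale each sample by (mean depth / sample depth).

    The scaling total is the mean of the sequencing depths of the compared
    samples, so equal depths leave the matrix unchanged.
    """
    d = pd.Series({s: float(depths[s]) for s in expr.columns})
    if (d <= 0).any():
        raise ValueError("sequencing depths must be positive")
    return expr * (d.mean() / d)


def needs_quantile_correction(expr: pd.DataFrame, ks_threshold: float = 0.01) -> bool:
    """True when any two samples' abundance distributions differ (KS > threshold).

    If the distributions are already aligned after subsampling, the quantile
    correction is unnecessary.
    """
    cols = list(expr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if stats.ks_2samp(expr[a], expr[b]).statistic > ks_threshold:
                return True
    return False
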