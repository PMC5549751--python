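"""Hierarchical differential expression with offset fold change.

With few replicates, per-gene variance estimates are unreliable; the
conservative alternative used here is the *maximal confidence interval* — the
[min, max] envelope of the replicate normalized expressions.  Differential
expression between two classes is called on the *proximal ends* of their
maximal CIs (the closest pair of endpoints), so a call requires the replicate
ranges to be disjoint, and its amplitude is measured as an offset fold
change, OFC = log2((a + offset)/(b + offset)).  The offset (default 20, the
empirically determined abundance noise floor) damps fold changes of
low-abundance genes.

For nested designs the call proceeds level by level in descending order of
DE amplitude (e.g. body part before treatment).  Genes are first categorized
by which top-level classes express them; the treatment test then runs only
within a gene's native categories, so tissue-specific transcripts detected at
trace level in the other tissue ("leaky" genes, dissection carry-over)
cannot masquerade as treatment DE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

DEFAULT_OFFSET = 20.0
DEFAULT_FOLD = 1.5


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaximalCI:
    """[min, max] of replicate normalized expressions for one gene/class."""

    lo: float
    hi: float
    n: int = 2

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"lo {self.lo} > hi {self.hi}")
        if self.lo < 0:
            raise ValueError("expression levels must be non-negative")

    @property
    def degenerate(self) -> bool:
        return self.n < 2


def maximal_ci(values: Sequence[float]) -> MaximalCI:
    """Maximal confidence interval of replicate values: [min, max].

    A single value yields a degenerate interval (lo == hi, flagged via
    ``degenerate``); an empty sequence is an error.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("maximal_ci requires at least one value")
    return MaximalCI(float(vals.min()), float(vals.max()), n=int(vals.size))


def ofc(a, b, offset: float = DEFAULT_OFFSET):
    """Offset fold change log2((a + offset)/(b + offset)).

    Antisymmetric in its arguments; the offset damps ratios of low-abundance
    values toward 0.  With offset 0 and b == 0 the result is infinite
    (reported as +/-inf with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if offset < 0:
        raise ValueError("offset must be >= 0")
    num, den = a + offset, b + offset
    if np.any(den == 0) or np.any(num == 0):
        warnings.warn("ofc: zero term with offset 0 yields infinite fold change",
                      stacklevel=2)
        with np.errstate(divide="ignore"):
            out = np.log2(num) - np.log2(den)
        return out if out.shape else float(out)
    out = np.log2(num / den)
    return out if out.shape else float(out)


@dataclass
class DECall:
    flag: bool
    amplitude: float  # |log2 OFC| between proximal ends; 0 when overlapping
    direction: Optional[str]  # 'A>B', 'B>A' or None


def de_call(
    ciA: MaximalCI,
    ciB: MaximalCI,
    offset: float = DEFAULT_OFFSET,
    fold: float = DEFAULT_FOLD,
) -> DECall:
    """Call DE between two classes from the proximal ends of their maximal CIs.

    The proximal ends are the closest pair of endpoints: hi of the lower
    interval and lo of the higher.  A gene is DE iff the intervals are
    strictly disjoint (touching intervals are not DE) and the OFC between the
    proximal ends reaches ``fold`` (>= log2(fold), i.e. >= 1.5-fold by
    default).  Overlapping intervals yield amplitude 0 by convention.
    """
    if ciA.hi < ciB.lo:
        amplitude = float(ofc(ciB.lo, ciA.hi, offset))
        direction = "B>A"
    elif ciB.hi < ciA.lo:
        amplitude = float(ofc(ciA.lo, ciB.hi, offset))
        direction = "A>B"
    else:
        return DECall(False, 0.0, None)
    flag = amplitude >= np.log2(fold)
    return DECall(bool(flag), amplitude, direction)


# ---------------------------------------------------------------------------
# Level ordering
# ---------------------------------------------------------------------------


def _check_design(expr: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = [s for s in expr.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")


def de_distribution(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    level: str,
    offset: float = DEFAULT_OFFSET,
) -> Dict[str, object]:
    """Distribution of per-gene between-class |OFC| for one hierarchy level.

    Class expression is the mean over that class's samples; with more than
    two classes the maximum pairwise amplitude is used.  The same statistic
    computed between replicate pairs within identical class combinations
    gives the replicate-noise distribution used as a comparison baseline.
    """
    _check_design(expr, design)
    classes = sorted(design[level].astype(str).unique())
    if len(classes) < 2:
        raise ValueError(f"level {level!r} needs >= 2 classes")
    class_means = {
        c: expr[[s for s in expr.columns if str(design.loc[s, level]) == c]].mean(axis=1)
        for c in classes
    }
    amp = None
    for a, b in combinations(classes, 2):
        pair = np.abs(ofc(class_means[a].values, class_means[b].values, offset))
        amp = pair if amp is None else np.maximum(amp, pair)
    amplitudes = pd.Series(amp, index=expr.index, name=f"|OFC| {level}")

    # replicate-to-replicate baseline: pairs within identical full conditions
    other = [c for c in design.columns if c != "replicate"]
    cond = design[other].astype(str).agg("|".join, axis=1)
    rep_vals: List[float] = []
    for _, samples in expr.columns.to_series().groupby(cond[expr.columns]):
        for a, b in combinations(list(samples), 2):
            rep_vals.extend(np.abs(ofc(expr[a].values, expr[b].values, offset)))
    replicate = pd.Series(rep_vals, name="|OFC| replicates")

    def summary(s: pd.Series) -> Dict[str, float]:
        if s.empty:
            return {k: np.nan for k in ("mean", "median", "iqr", "min", "max")}
        return {
            "mean": float(s.mean()),
            "median": float(s.median()),
            "iqr": float(s.quantile(0.75) - s.quantile(0.25)),
            "min": float(s.min()),
            "max": float(s.max()),
        }

    return {
        "level": level,
        "amplitudes": amplitudes,
        "replicate_amplitudes": replicate,
        "summary": summary(amplitudes),
        "replicate_summary": summary(replicate),
    }


def order_levels(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    levels: Sequence[str],
    offset: float = DEFAULT_OFFSET,
) -> pd.DataFrame:
    """Order candidate hierarchy levels by descending DE amplitude.

    Sorted by median per-gene |OFC| (ties broken by IQR, then declared
    order).  The ``overlap_with_replicates`` column is the fraction of
    between-class amplitudes not exceeding the 95th percentile of the
    replicate-noise amplitudes: values near 1 mean the level's DE is subtle
    (its distribution overlaps replicate noise).
    """
    rows = []
    for i, level in enumerate(levels):
        dist = de_distribution(expr, design, level, offset)
        rep = dist["replicate_amplitudes"]
        q95 = rep.quantile(0.95) if not rep.empty else np.nan
        amp = dist["amplitudes"]
        overlap = float((amp <= q95).mean()) if not np.isnan(q95) else np.nan
        rows.append(
            {
                "level": level,
                "declared_order": i,
                **dist["summary"],
                "overlap_with_replicates": overlap,
            }
        )
    out = pd.DataFrame(rows)
    out["tie"] = out.duplicated("median", keep=False)
    out = out.sort_values(
        ["median", "iqr", "declared_order"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Two-step hierarchical DE
# ---------------------------------------------------------------------------


def hierarchical_de(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    levels: Optional[Sequence[str]] = None,
    offset: float = DEFAULT_OFFSET,
    fold: float = DEFAULT_FOLD,
    expressed_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Two-step DE call for a nested two-level design.

    Step (i): per gene, expression is summed over the lower-level classes
    within each top-level class, and genes are categorized by the top-level
    classes that express them (summed abundance > ``expressed_threshold``,
    default the offset, treated as the noise floor).  With two classes this
    yields the three categories {class1-only, class2-only, both}.

    Step (ii): within each top-level class in a gene's category, DE between
    the lower-level classes is called from maximal CIs over the replicates.
    Genes whose category excludes a top class are never tested there, which
    removes leaky genes from the foreign class's treatment test.

    ``levels`` defaults to the data-driven ordering of every non-replicate
    design column (see :func:`order_levels`).
    """
    _check_design(expr, design)
    if levels is None:
        candidates = [c for c in design.columns if c != "replicate"]
        levels = list(order_levels(expr, design, candidates, offset)["level"])
    if len(levels) < 2:
        raise ValueError("hierarchical DE needs >= 2 levels")
    top, second = levels[0], levels[1]
    if expressed_threshold is None:
        expressed_threshold = offset
    top_classes = sorted(design[top].astype(str).unique())
    sec_classes = sorted(design[second].astype(str).unique())

    samples_of = {
        (tc, sc): [
            s
            for s in expr.columns
            if str(design.loc[s, top]) == tc and str(design.loc[s, second]) == sc
        ]
        for tc in top_classes
        for sc in sec_classes
    }
    for (tc, sc), ss in samples_of.items():
        if len(ss) == 1:
            warnings.warn(
                f"single replicate for {top}={tc}, {second}={sc}: degenerate CIs",
                stacklevel=2,
            )

    rows = []
    for gene in expr.index:
        vals = expr.loc[gene]
        # step (i): summed expression across second-level classes per top class
        summed = {
            tc: float(
                sum(vals[s] for sc in sec_classes for s in samples_of[(tc, sc)])
            )
            for tc in top_classes
        }
        expressed = [tc for tc in top_classes if summed[tc] > expressed_threshold]
        if not expressed:
            category = "none"
        elif len(expressed) == len(top_classes):
            category = "both" if len(top_classes) == 2 else "all"
        else:
            category = "+".join(expressed) + "-only"
        row: Dict[str, object] = {"gene": gene, "category": category}
        any_de = False
        low_conf = False
        for tc in top_classes:
            prefix = f"{tc}"
            if tc not in expressed:
                row[f"{prefix}_flag"] = False
                row[f"{prefix}_amplitude"] = np.nan
                row[f"{prefix}_direction"] = None
                continue
            cis = {}
            for sc in sec_classes:
                ss = samples_of[(tc, sc)]
                if not ss:
                    cis[sc] = None
                    continue
                ci = maximal_ci([vals[s] for s in ss])
                cis[sc] = ci
                row[f"{prefix}_{sc}_lo"] = ci.lo
                row[f"{prefix}_{sc}_hi"] = ci.hi
                if ci.degenerate:
                    low_conf = True
            best = DECall(False, 0.0, None)
            for a, b in combinations([c for c in sec_classes if cis.get(c)], 2):
                call = de_call(cis[a], cis[b], offset, fold)
                if call.amplitude > best.amplitude or (call.flag and not best.flag):
                    direction = None
                    if call.direction == "A>B":
                        direction = f"{a}>{b}"
                    elif call.direction == "B>A":
                        direction = f"{b}>{a}"
                    best = DECall(call.flag, call.amplitude, direction)
            row[f"{prefix}_flag"] = best.flag
            row[f"{prefix}_amplitude"] = best.amplitude
            row[f"{prefix}_direction"] = best.direction
            any_de = any_de or best.flag
        row["de"] = any_de
        row["low_confidence"] = low_conf
        row["offset"] = offset
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def cv_profile(
    expr: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    reference_lines: Tuple[float, float] = (0.25, 0.5),
) -> pd.DataFrame:
    """Per-gene coefficient of variation per replicate group, abundance-binned.

    CV = sample standard deviation (ddof=1) / mean over the group's
    replicates; NaN where the mean is 0.  The abundance bin is
    floor(log2(group mean)).  Reference lines at 0.25 and 0.5 mark the
    replicate-variability levels that compromise a variance-based DE call.
    """
    rows = []
    for group, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {group!r} needs >= 2 replicates")
        sub = expr[list(samples)]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.nan)
            bins = np.where(mean > 0, np.floor(np.log2(mean.where(mean > 0))), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "gene": expr.index,
                    "group": group,
                    "mean": mean.values,
                    "cv": cv,
                    "bin": bins,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["reference_lines"] = reference_lines
    return out


def ma_table(
    exprA: pd.Series,
    exprB: pd.Series,
    offset: float = DEFAULT_OFFSET,
) -> pd.DataFrame:
    """Per-gene (log2 mean abundance, OFC) table for MA-style inspection.

    Reference lines at 0 and +/-0.5 log2 delimit the band below the usual
    low-throughput validation threshold.  Genes with zero mean abundance get
    NaN on the abundance axis.
    """
    genes = exprA.index.intersection(exprB.index)
    a, b = exprA[genes].astype(float), exprB[genes].astype(float)
    mean = (a + b) / 2.0
    with np.errstate(divide="ignore"):
        log_mean = np.where(mean > 0, np.log2(mean.where(mean > 0)), np.nan)
    out = pd.DataFrame(
        {"abundance_log2": log_mean, "ofc": ofc(a.values, b.values, offset)},
        index=genes,
    )
    out.attrs["reference_lines"] = (0.0, 0.5, -0.5)
    return out
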