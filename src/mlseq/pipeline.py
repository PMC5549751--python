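"""End-to-end orchestration: QC -> normalization -> hierarchical DE.

A run takes FASTQ read files, a FASTA genome, a GFF3 annotation and a sample
design table, and produces a versioned run directory with QC matrices,
consistency reports, normalized expression and the DE call, plus a manifest
(parameters, seeds, input checksums) sufficient to reproduce the run.
Replicates flagged as outliers are excluded only when ``auto_exclude`` is
set — exclusion is a judgment call and never silent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import core_io, hierarchical_de as hde, normalization as norm, qc_metrics as qc

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


class ValidationError(ValueError):
    """Fatal problem with pipeline inputs."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    Every parameter defaults to the protocol's stated value: top_n=1000
    genes for the Jaccard similarity, p2pPCC offset threshold 0.7, DE offset
    'auto' (estimated, falling back to 20), 1.5-fold DE threshold,
    incremental-check fractions 0.95..0.45, 10 bootstrap draws, and a 55%
    minimum subsampling fraction before case-by-case review.
    """

    design: str = ""
    genome: str = ""
    annotation: str = ""
    reads_dir: str = ""
    out: str = "mlseq_run"
    top_n: int = 1000
    p2p_threshold: float = 0.7
    offset: object = "auto"          # 'auto' or a number
    fold: float = 1.5
    target_total: object = "auto"    # 'auto' (min accepted depth) or an int
    fractions: Sequence[float] = tuple(norm.DEFAULT_FRACTIONS)
    n_boot: int = 10
    min_fraction: float = 0.55
    matching_tolerance: float = 0.005
    ks_threshold: float = 0.01
    seed: int = 0
    steps: Sequence[str] = ("qc", "normalize", "de")
    auto_exclude: bool = False
    run_consistency_check: bool = True
    remove_ncrna: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        d["steps"] = list(self.steps)
        return d


@dataclass
class Diagnostic:
    severity: str  # 'fatal' | 'warning'
    message: str


def validate_inputs(cfg: PipelineConfig) -> List[Diagnostic]:
    """Check that the declared inputs exist and are mutually consistent.

    Fatal findings: missing files, design samples without FASTQ, GFF
    chromosomes absent from the FASTA.  Single-replicate classes produce a
    warning (degenerate maximal CIs downstream).
    """
    diags: List[Diagnostic] = []
    for label in ("design", "genome", "annotation"):
        p = getattr(cfg, label)
        if not p or not Path(p).exists():
            diags.append(Diagnostic("fatal", f"{label} file not found: {p!r}"))
    if diags:
        return diags
    design = pd.read_csv(cfg.design, sep="\t", index_col=0)
    if "replicate" not in design.columns or design.shape[1] < 2:
        diags.append(
            Diagnostic("fatal", "design needs a 'replicate' column plus >=1 level column")
        )
        return diags
    reads_dir = Path(cfg.reads_dir or Path(cfg.design).parent)
    for sample in design.index:
        if not (reads_dir / f"{sample}.fastq").exists():
            diags.append(Diagnostic("fatal", f"no FASTQ for design sample {sample!r}"))
    genome = core_io.read_fasta(cfg.genome)
    gff_chroms = set()
    with open(cfg.annotation) as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            gff_chroms.add(ln.split("\t", 1)[0])
    missing = gff_chroms - set(genome)
    if missing:
        diags.append(
            Diagnostic("fatal", f"GFF chromosomes absent from FASTA: {sorted(missing)}")
        )
    level_cols = [c for c in design.columns if c != "replicate"]
    for cond, grp in design.groupby(level_cols):
        if len(grp) < 2:
            diags.append(
                Diagnostic("warning", f"single replicate for condition {cond}: "
                                      "maximal CIs will be degenerate")
        )
    return diags


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _replicate_pairs(design: pd.DataFrame) -> List[Tuple[str, str]]:
    cols = [c for c in design.columns if c != "replicate"]
    cond = design[cols].astype(str).agg("|".join, axis=1)
    pairs = []
    for _, grp in design.groupby(cond):
        pairs.extend(combinations(list(grp.index), 2))
    return pairs


@dataclass
class PipelineResult:
    outdir: Path
    qc_report: Optional[qc.QCReport] = None
    consistency: Dict[str, norm.ConsistencyReport] = field(default_factory=dict)
    normalized_expr: Optional[pd.DataFrame] = None
    de_table: Optional[pd.DataFrame] = None
    level_order: Optional[pd.DataFrame] = None
    excluded: List[str] = field(default_factory=list)
    offset: float = float("nan")
    manifest: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write the run directory.

    Stages: input validation, alignment, QC (with optional outlier
    exclusion), subsampling normalization with consistency and bootstrap
    checks plus optional quantile correction, post-normalization QC, and the
    hierarchical DE call.  Identical config + seed give identical outputs.
    """
    diags = validate_inputs(cfg)
    fatal = [d for d in diags if d.severity == "fatal"]
    for d in diags:
        (logger.error if d.severity == "fatal" else logger.warning)(d.message)
    if fatal:
        raise ValidationError("; ".join(d.message for d in fatal))

    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(outdir=out)
    manifest: dict = {
        "config": cfg.to_dict(),
        "inputs": {
            k: {"path": getattr(cfg, k), "sha256": _sha256(getattr(cfg, k))}
            for k in ("design", "genome", "annotation")
        },
        "stages": [],
    }
    design = pd.read_csv(cfg.design, sep="\t", index_col=0)
    genome = core_io.read_fasta(cfg.genome)
    sizes = {c: len(s) for c, s in genome.items()}
    ann = core_io.load_annotation(cfg.annotation, chrom_sizes=sizes)
    reads_dir = Path(cfg.reads_dir or Path(cfg.design).parent)

    try:
        readsets = {
            s: core_io.read_fastq(reads_dir / f"{s}.fastq", name=s) for s in design.index
        }
        alignments = {
            s: core_io.exact_match(rs, genome, name=s) for s, rs in readsets.items()
        }
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"[alignment] {exc}") from exc
    manifest["stages"].append("alignment")

    expr_raw = core_io.gene_expression(alignments, ann)
    core_io.write_expression_tsv(expr_raw, out / "expression_raw.tsv")

    profiles_p2p = []
    cdp: Dict[Tuple[str, str], qc.ComplexityDiffProfile] = {}
    if "qc" in cfg.steps:
        try:
            stats_rows = []
            for s in design.index:
                rs, al = readsets[s], alignments[s]
                stats_rows.append(
                    {
                        "sample": s,
                        "R": rs.R,
                        "NR": rs.NR,
                        "complexity": rs.complexity(),
                        "pct_genome_matching": 100.0 * al.genome_matching_R / rs.R
                        if rs.R
                        else np.nan,
                        "strand_bias": qc.strand_bias(al, ann),
                    }
                )
            sample_stats = pd.DataFrame(stats_rows).set_index("sample")
            jac = qc.jaccard_matrix(expr_raw, cfg.top_n)
            corrs = {m: qc.correlation_matrix(expr_raw, m) for m in ("PCC", "SCC", "KCC")}
            p2p_sim = pd.DataFrame(
                np.nan, index=design.index, columns=design.index, dtype=float
            )
            np.fill_diagonal(p2p_sim.values, 1.0)
            for a, b in _replicate_pairs(design):
                cdp[(a, b)] = qc.complexity_diff_profile(alignments[a], alignments[b], ann)
                prof = qc.p2p_profile(alignments[a], alignments[b], ann)
                profiles_p2p.append(prof)
                defined = prof.per_gene["p2ppcc"].dropna()
                sim = float(defined.median()) if not defined.empty else np.nan
                p2p_sim.loc[a, b] = p2p_sim.loc[b, a] = sim
            offset_est = qc.estimate_offset(profiles_p2p, cfg.p2p_threshold)
            outliers = qc.flag_outlier_replicates(design, cdp, jac, p2p_sim)
            report = qc.QCReport(sample_stats, jac, corrs, offset_est, outliers)
            report.to_dir(out / "qc")
            pd.concat(
                {f"{a}|{b}": p.per_gene for (a, b), p in cdp.items()}, names=["pair"]
            ).to_csv(out / "qc" / "complexity_profiles.tsv", sep="\t")
            result.qc_report = report
        except Exception as exc:
            raise StageError(f"[qc] {exc}") from exc
        manifest["stages"].append("qc")

        flagged = list(report.outliers.loc[report.outliers["flagged"], "sample"])
        if flagged and cfg.auto_exclude:
            result.excluded = flagged
            design = design.drop(index=flagged)
            logger.info("excluded outlier replicates: %s", flagged)
            # outlier pairs depress the p2pPCC medians; re-estimate the noise
            # floor from the retained replicate pairs only
            kept = [
                p
                for p in profiles_p2p
                if p.pair[0] in design.index and p.pair[1] in design.index
            ]
            report.offset = qc.estimate_offset(kept, cfg.p2p_threshold)
        elif flagged:
            warnings.warn(
                f"outlier replicates flagged but kept (no auto_exclude): {flagged}",
                stacklevel=2,
            )

    normalized = expr_raw
    if "normalize" in cfg.steps:
        try:
            rng = np.random.default_rng(cfg.seed)
            working = {s: readsets[s] for s in design.index}
            if cfg.remove_ncrna:
                working = {
                    s: norm.remove_ncrna_reads(rs, alignments[s], ann)
                    for s, rs in working.items()
                }
            if cfg.run_consistency_check:
                for s, rs in working.items():
                    rep = norm.incremental_consistency_check(
                        rs,
                        alignments[s].restrict(rs.counts),
                        ann,
                        fractions=cfg.fractions,
                        seed=int(rng.integers(2**31 - 1)),
                        tolerance=cfg.matching_tolerance,
                    )
                    result.consistency[s] = rep
                    rep.table.to_csv(out / f"consistency_{s}.tsv", sep="\t", index=False)
            target = (
                min(rs.R for rs in working.values())
                if cfg.target_total == "auto"
                else int(cfg.target_total)
            )
            norm_aligns = {}
            sub_meta = {}
            for s, rs in working.items():
                res = norm.bootstrap_fixed_total(
                    rs,
                    alignments[s].restrict(rs.counts),
                    ann,
                    target,
                    n_boot=cfg.n_boot,
                    seed=int(rng.integers(2**31 - 1)),
                    min_fraction=cfg.min_fraction,
                )
                norm_aligns[s] = alignments[s].restrict(res.readset.counts)
                sub_meta[s] = {
                    "target": res.target,
                    "seed": res.seed,
                    "chosen_index": res.chosen_index,
                    "bootstrap_pcc": [float(x) for x in res.bootstrap_pcc],
                    "passed": res.passed,
                    "requires_review": res.requires_review,
                }
            (out / "subsample_meta.json").write_text(json.dumps(sub_meta, indent=2))
            normalized = core_io.gene_expression(norm_aligns, ann)
            if norm.needs_quantile_correction(normalized, cfg.ks_threshold):
                normalized = norm.quantile_normalize(normalized)
            core_io.write_expression_tsv(normalized, out / "expression_normalized.tsv")
            result.normalized_expr = normalized
        except Exception as exc:
            raise StageError(f"[normalize] {exc}") from exc
        manifest["stages"].append("normalize")

    if "de" in cfg.steps:
        try:
            if cfg.offset == "auto":
                offset = result.qc_report.offset if result.qc_report else float("nan")
                if np.isnan(offset):
                    warnings.warn("offset estimation failed; falling back to 20",
                                  stacklevel=2)
                    offset = hde.DEFAULT_OFFSET
            else:
                offset = float(cfg.offset)
            result.offset = offset
            levels = [c for c in design.columns if c != "replicate"]
            order = hde.order_levels(normalized, design, levels, offset)
            order.to_csv(out / "level_order.tsv", sep="\t", index=False)
            de = hde.hierarchical_de(
                normalized, design, list(order["level"]), offset=offset, fold=cfg.fold
            )
            de.to_csv(out / "de_results.tsv", sep="\t")
            result.de_table = de
            result.level_order = order
        except Exception as exc:
            raise StageError(f"[de] {exc}") from exc
        manifest["stages"].append("de")

    result.manifest = manifest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    write_report(result)
    return result


def write_report(result: PipelineResult) -> Path:
    """Write a human-readable markdown summary of a (possibly partial) run."""
    out = result.outdir
    lines = ["# mlseq run report", ""]
    if result.qc_report is not None:
        lines += ["## Quality control", "",
                  result.qc_report.sample_stats.to_string(), "",
                  f"Estimated offset (abundance noise floor): {result.qc_report.offset}",
                  ""]
        flagged = result.qc_report.outliers
        if not flagged.empty and flagged["flagged"].any():
            names = list(flagged.loc[flagged["flagged"], "sample"])
            lines.append(f"Outlier replicates flagged: {names}")
        else:
            lines.append("No outlier replicates flagged.")
        if result.excluded:
            lines.append(f"Excluded from downstream analysis: {result.excluded}")
        lines.append("")
    if result.consistency:
        lines += ["## Incremental consistency checks", ""]
        for s, rep in result.consistency.items():
            verdict = "pass" if rep.passed else "FAIL"
            lines.append(
                f"- {s}: {len(rep.table)} fractions "
                f"({rep.table['fraction'].max():.2f}-{rep.table['fraction'].min():.2f}), "
                f"{verdict}"
            )
        lines.append("")
    if result.de_table is not None:
        lines += ["## Differential expression", ""]
        counts = result.de_table["category"].value_counts()
        lines.append("Genes per category: " + json.dumps(counts.to_dict()))
        n_de = int(result.de_table["de"].sum())
        lines.append(f"DE calls: {n_de}" if n_de else "DE calls: zero genes called DE")
        lines.append(f"Offset used: {result.offset}")
        lines.append("")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
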