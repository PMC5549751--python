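"""Synthetic multi-level RNA-seq studies with known ground truth.

The generator emulates the structure of a nested behavioural-transcriptomics
experiment: two body parts x two treatments x replicated libraries, sequenced
single-end at a fixed read length.  It produces a random genome with
non-overlapping gene models (UTRs, optional introns, ncRNA loci for the
contaminant-removal filter), per-sample read sets drawn gene-by-gene with
log-normal replicate noise, planted treatment effects, body-part-specific and
"leaky" genes (trace carry-over into the foreign body part), variable depths,
and optionally one outlier replicate whose duplicate structure is perturbed
by concentrating a fraction of its reads onto a few positions per gene —
which raises the duplicate rate (lowers per-gene complexity) without
changing totals.

Everything is reproducible from the seed; the ground truth (per-gene
category, leaky flag and planted effect; per-replicate outlier flag) is
exported alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import ReadSet, write_fastq

_BASES = np.array(list("ACGT"))


@dataclass
class OutlierSpec:
    """Perturbation of one replicate's duplicate structure."""

    sample: Optional[str] = None  # default: replicate 3 of the first condition
    fraction: float = 0.5         # fraction of reads re-drawn at anchor positions
    n_positions: int = 3          # anchor positions per gene


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a fly-style nested design scaled to desk size: 2 body
    parts x 2 treatments x 3 replicates, ~10% extra ncRNA loci, log-normal
    per-gene base abundances (median ~200 units), 40% body-part-specific
    genes of which a fraction leak at ~1% into the other body part, a 20%
    subset of genes carrying a 1 log2 treatment effect, and multiplicative
    log-normal replicate noise of sigma 0.05 (CV ~5%).
    """

    n_genes: int = 40
    gene_length: Tuple[int, int] = (240, 400)
    intergenic_gap: Tuple[int, int] = (60, 120)
    utr_length: int = 20
    intron_fraction: float = 0.3
    intron_length: int = 40
    ncrna_fraction: float = 0.1
    ncrna_weight: float = 0.05
    ncrna_length: Tuple[int, int] = (100, 200)
    levels: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"body_part": ["HT", "A"], "treatment": ["plus", "minus"]}
    )
    n_replicates: int = 3
    depth: int = 20000
    depth_jitter: float = 0.0      # relative spread of per-sample depths
    read_length: int = 36
    base_abundance_median: float = 200.0
    base_abundance_sigma: float = 0.8   # ln-scale
    specific_fraction: float = 0.4
    body_part_sigma_log2: float = 1.5   # spread of body-part effects on shared genes
    leaky_fraction: float = 0.1         # of all genes; leaky genes are specific
    leak_ratio: float = 0.01
    treatment_de_fraction: float = 0.2
    treatment_effect_log2: float = 1.0
    replicate_sigma: float = 0.05       # ln-scale multiplicative noise
    strand_plus_prob: float = 0.5
    outlier: Optional[OutlierSpec] = None
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted per-gene and per-replicate truth for a simulated study."""

    genes: pd.DataFrame      # gene, biotype, native, leaky, treatment_effect_log2, base
    replicates: pd.DataFrame  # sample, outlier flag


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: Dict[str, str]
    gff: str
    design: pd.DataFrame
    truth: GroundTruth
    readsets: Dict[str, ReadSet] = field(default_factory=dict)
    gene_layout: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Design and truth
# ---------------------------------------------------------------------------


def design_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample design: one row per sample with its class at every level."""
    levels = {k: list(v) for k, v in cfg.levels.items()}
    names = list(levels)
    combos = [[]]
    for lv in names:
        combos = [c + [cls] for c in combos for cls in levels[lv]]
    rows = []
    for combo in combos:
        for r in range(1, cfg.n_replicates + 1):
            sample = "_".join(combo + [f"r{r}"])
            rows.append({"sample": sample, **dict(zip(names, combo)), "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def make_truth(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> GroundTruth:
    """Draw the planted truth: categories, leaky flags, effects, base levels."""
    rng = rng or np.random.default_rng(cfg.seed)
    top_level = next(iter(cfg.levels))
    top_classes = list(cfg.levels[top_level])
    n = cfg.n_genes
    base = cfg.base_abundance_median * np.exp(
        rng.normal(0.0, cfg.base_abundance_sigma, size=n)
    )
    n_leaky = round(cfg.leaky_fraction * n)
    n_specific = max(round(cfg.specific_fraction * n), n_leaky)
    order = rng.permutation(n)
    specific_idx = order[:n_specific]
    leaky_idx = set(specific_idx[:n_leaky])
    native = np.array(["both"] * n, dtype=object)
    for j, gi in enumerate(specific_idx):
        native[gi] = top_classes[j % len(top_classes)]
    leaky = np.array([i in leaky_idx for i in range(n)])
    # treatment effects planted on non-leaky genes only, so leak trajectories
    # are flat across treatments by construction
    eligible = np.array([i for i in range(n) if i not in leaky_idx])
    n_de = round(cfg.treatment_de_fraction * n)
    de_idx = rng.choice(eligible, size=min(n_de, len(eligible)), replace=False)
    effect = np.zeros(n)
    for j, gi in enumerate(de_idx):
        effect[gi] = cfg.treatment_effect_log2 * (1 if j % 2 == 0 else -1)
    # shared genes still differ between body parts (as most genes do between
    # tissues); specific genes are absent from the foreign part instead
    bp_effect = rng.normal(0.0, cfg.body_part_sigma_log2, size=n)
    bp_effect[native != "both"] = 0.0
    genes = pd.DataFrame(
        {
            "gene": [f"g{i:03d}" for i in range(n)],
            "biotype": "protein_coding",
            "native": native,
            "leaky": leaky,
            "treatment_effect_log2": effect,
            "body_part_effect_log2": bp_effect,
            "base_abundance": base,
        }
    ).set_index("gene")
    design = design_table(cfg)
    outlier_sample = None
    if cfg.outlier is not None:
        outlier_sample = cfg.outlier.sample or design.index[cfg.n_replicates - 1]
    reps = pd.DataFrame(
        {"sample": design.index, "outlier": [s == outlier_sample for s in design.index]}
    ).set_index("sample")
    return GroundTruth(genes, reps)


def expected_weights(cfg: SimulationConfig, truth: GroundTruth,
                     design: pd.DataFrame) -> pd.DataFrame:
    """Noise-free expected abundance weight of each gene in each sample."""
    top_level = next(iter(cfg.levels))
    second_level = list(cfg.levels)[1] if len(cfg.levels) > 1 else None
    up_class = cfg.levels[second_level][0] if second_level else None
    w = pd.DataFrame(index=truth.genes.index, columns=design.index, dtype=float)
    for sample in design.index:
        tc = str(design.loc[sample, top_level])
        sc = str(design.loc[sample, second_level]) if second_level else None
        col = truth.genes["base_abundance"].copy()
        foreign = (truth.genes["native"] != "both") & (truth.genes["native"] != tc)
        col[foreign & truth.genes["leaky"]] *= cfg.leak_ratio
        col[foreign & ~truth.genes["leaky"]] = 0.0
        if tc == str(cfg.levels[top_level][0]):
            col = col * np.power(2.0, truth.genes["body_part_effect_log2"])
        if sc == up_class:
            col = col * np.power(2.0, truth.genes["treatment_effect_log2"])
        w[sample] = col
    return w


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------


def make_reference(cfg: SimulationConfig,
                   rng: Optional[np.random.Generator] = None):
    """Random genome and GFF3 with non-overlapping gene models.

    Returns (genome dict, gff string, layout DataFrame).  Each protein-coding
    gene carries UTR/exon (and optionally intron) children; additional ncRNA
    loci (round(ncrna_fraction * n_genes)) are interspersed for the
    contaminant filter.  Deterministic under the config seed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_nc = round(cfg.ncrna_fraction * cfg.n_genes)
    loci: List[dict] = []
    pos = int(rng.integers(*cfg.intergenic_gap))
    gff_lines = ["##gff-version 3"]
    nc_slots = set(
        rng.choice(cfg.n_genes + n_nc, size=n_nc, replace=False)
    ) if n_nc else set()
    gi = ni = 0
    for slot in range(cfg.n_genes + n_nc):
        if slot in nc_slots:
            length = int(rng.integers(*cfg.ncrna_length))
            gid = f"nc{ni:03d}"
            loci.append(
                {"id": gid, "type": "ncRNA", "start": pos, "end": pos + length,
                 "strand": "+", "intron": None}
            )
            ni += 1
        else:
            length = int(rng.integers(*cfg.gene_length))
            gid = f"g{gi:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            has_intron = (
                rng.random() < cfg.intron_fraction
                and length > 2 * cfg.utr_length + cfg.intron_length + 2 * cfg.read_length
            )
            loci.append(
                {"id": gid, "type": "gene", "start": pos, "end": pos + length,
                 "strand": strand, "intron": has_intron}
            )
            gi += 1
        pos = loci[-1]["end"] + int(rng.integers(*cfg.intergenic_gap))
    genome_len = pos
    genome_seq = "".join(rng.choice(_BASES, size=genome_len))
    genome = {"chr1": genome_seq}

    def line(ftype, start, end, strand, attrs):
        # internal 0-based half-open -> GFF 1-based closed
        return f"chr1\tmlseq_sim\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"

    layout_rows = []
    for locus in loci:
        s, e, st, gid = locus["start"], locus["end"], locus["strand"], locus["id"]
        layout_rows.append(
            {"id": gid, "type": locus["type"], "start": s, "end": e, "strand": st}
        )
        if locus["type"] == "ncRNA":
            gff_lines.append(line("ncRNA", s, e, st, f"ID={gid}"))
            continue
        gff_lines.append(line("gene", s, e, st, f"ID={gid};Name={gid}"))
        u = cfg.utr_length
        utr5, utr3 = ("5UTR", "3UTR") if st == "+" else ("3UTR", "5UTR")
        utr_type = {"5UTR": "five_prime_UTR", "3UTR": "three_prime_UTR"}
        gff_lines.append(line(utr_type[utr5], s, s + u, st, f"ID={gid}.u5;Parent={gid}"))
        gff_lines.append(line(utr_type[utr3], e - u, e, st, f"ID={gid}.u3;Parent={gid}"))
        if locus["intron"]:
            mid = (s + e) // 2
            i_lo, i_hi = mid - cfg.intron_length // 2, mid + cfg.intron_length // 2
            gff_lines.append(line("exon", s, i_lo, st, f"ID={gid}.e1;Parent={gid}"))
            gff_lines.append(line("intron", i_lo, i_hi, st, f"ID={gid}.i1;Parent={gid}"))
            gff_lines.append(line("exon", i_hi, e, st, f"ID={gid}.e2;Parent={gid}"))
            gff_lines.append(line("CDS", s + u, i_lo, st, f"ID={gid}.c1;Parent={gid}"))
            gff_lines.append(line("CDS", i_hi, e - u, st, f"ID={gid}.c2;Parent={gid}"))
        else:
            gff_lines.append(line("exon", s, e, st, f"ID={gid}.e1;Parent={gid}"))
            gff_lines.append(line("CDS", s + u, e - u, st, f"ID={gid}.c1;Parent={gid}"))
    gff = "\n".join(gff_lines) + "\n"
    return genome, gff, pd.DataFrame(layout_rows).set_index("id")


# ---------------------------------------------------------------------------
# Count- and read-level simulation
# ---------------------------------------------------------------------------


def simulate_counts(cfg: SimulationConfig,
                    truth: Optional[GroundTruth] = None) -> Tuple[pd.DataFrame, GroundTruth]:
    """Matrix-level simulation: normalized expression with replicate noise.

    Expression(g, s) = expected weight x log-normal(sigma) noise, scaled so
    each sample's total equals the configured depth.  Use this when read
    placement is irrelevant (e.g. DE truth-recovery studies); it gives direct
    control of the replicate CV (~sigma for small sigma).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = truth or make_truth(cfg, rng)
    design = design_table(cfg)
    w = expected_weights(cfg, truth, design)
    noise = rng.lognormal(0.0, cfg.replicate_sigma, size=w.shape)
    expr = w * noise
    expr = expr * (cfg.depth / expr.sum(axis=0))
    return expr, truth


def simulate_reads(cfg: SimulationConfig,
                   truth: Optional[GroundTruth] = None) -> SimulatedStudy:
    """Read-level simulation: genome, annotation and per-sample ReadSets.

    Per sample, reads are allocated to loci by a multinomial over expected
    weights (with log-normal replicate noise), placed uniformly within the
    locus span on either strand, and cut verbatim from the genome (reverse
    complemented on the minus strand).  ncRNA loci receive ~``ncrna_weight``
    of each library.  The outlier replicate, when configured, has a fraction
    of its reads re-drawn at a few anchor positions per locus.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = truth or make_truth(cfg, rng)
    genome, gff, layout = make_reference(cfg, rng)
    design = design_table(cfg)
    w = expected_weights(cfg, truth, design)
    k = cfg.read_length

    # ncRNA loci weights: constant contaminant share of the library
    nc_ids = [i for i in layout.index if layout.loc[i, "type"] == "ncRNA"]
    gene_ids = list(truth.genes.index)
    total_base = float(truth.genes["base_abundance"].sum())
    nc_w = (
        cfg.ncrna_weight * total_base / ((1.0 - cfg.ncrna_weight) * len(nc_ids))
        if nc_ids
        else 0.0
    )

    outlier_sample = None
    spec = cfg.outlier
    if spec is not None:
        outlier_sample = spec.sample or design.index[cfg.n_replicates - 1]

    anchors: Dict[str, np.ndarray] = {}
    if spec is not None:
        for lid in list(gene_ids) + nc_ids:
            lo, hi = int(layout.loc[lid, "start"]), int(layout.loc[lid, "end"])
            n_pos = min(spec.n_positions, hi - lo - k + 1)
            anchors[lid] = rng.choice(hi - lo - k + 1, size=max(n_pos, 1), replace=False)

    chrom_seq = genome["chr1"]
    readsets: Dict[str, ReadSet] = {}
    for sample in design.index:
        weights = np.concatenate(
            [w[sample].to_numpy(dtype=float), np.full(len(nc_ids), nc_w)]
        )
        noise = rng.lognormal(0.0, cfg.replicate_sigma, size=weights.size)
        weights = weights * noise
        depth = cfg.depth
        if cfg.depth_jitter:
            depth = max(1, int(round(depth * rng.lognormal(0.0, cfg.depth_jitter))))
        p = weights / weights.sum()
        per_locus = rng.multinomial(depth, p)
        counts: Counter = Counter()
        is_outlier = sample == outlier_sample
        for lid, n_reads in zip(gene_ids + nc_ids, per_locus):
            if n_reads == 0:
                continue
            lo, hi = int(layout.loc[lid, "start"]), int(layout.loc[lid, "end"])
            span = hi - lo - k + 1
            starts = rng.integers(0, span, size=n_reads)
            if is_outlier and lid in anchors:
                concentrated = rng.random(n_reads) < spec.fraction
                starts[concentrated] = rng.choice(
                    anchors[lid], size=int(concentrated.sum())
                )
            minus = rng.random(n_reads) >= cfg.strand_plus_prob
            for s0, m in zip(starts, minus):
                seq = chrom_seq[lo + s0 : lo + s0 + k]
                if m:
                    seq = _revcomp(seq)
                counts[seq] += 1
        readsets[sample] = ReadSet(dict(counts), k, name=sample)
    return SimulatedStudy(cfg, genome, gff, design, truth, readsets, layout)


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_truth(truth: GroundTruth, outdir: str | Path) -> pd.DataFrame:
    """Write the per-gene and per-replicate truth tables as TSV; returns the
    gene table.  Idempotent: re-export overwrites identical content."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    truth.replicates.to_csv(out / "truth_replicates.tsv", sep="\t")
    return truth.genes


def write_study(study: SimulatedStudy, outdir: str | Path) -> Path:
    """Write FASTA, GFF3, per-sample FASTQ, design and truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fasta", "w") as fh:
        for chrom, seq in study.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    (out / "annotation.gff3").write_text(study.gff)
    study.design.to_csv(out / "design.tsv", sep="\t")
    for sample, rs in study.readsets.items():
        write_fastq(rs, out / f"{sample}.fastq")
    export_truth(study.truth, out)
    return out
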