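"""Core containers and I/O for read-level RNA-seq analysis.

The unit of work is the *redundant* read set: every sequenced read instance,
aggregated per unique sequence.  Reads are placed on the genome by exact,
full-length, gap-free matching (both strands), and gene expression is the
algebraic sum of the abundances of the reads incident with each gene.

Coordinates are 0-based half-open internally; GFF3 input (1-based closed)
is converted on load.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: annotation classes recognised by the index; GFF feature types are mapped
#: onto these (see :func:`load_annotation`).
ANNOTATION_CLASSES = ("CDS", "exon", "intron", "5UTR", "3UTR", "ncRNA", "intergenic")

_GFF_CLASS_MAP = {
    "CDS": "CDS",
    "mRNA": "CDS",
    "exon": "exon",
    "intron": "intron",
    "five_prime_UTR": "5UTR",
    "5UTR": "5UTR",
    "three_prime_UTR": "3UTR",
    "3UTR": "3UTR",
    "ncRNA": "ncRNA",
    "tRNA": "ncRNA",
    "rRNA": "ncRNA",
    "miRNA": "ncRNA",
    "snoRNA": "ncRNA",
    "snRNA": "ncRNA",
}


class FastqParseError(ValueError):
    """Raised when a FASTQ record cannot be parsed; carries the line number."""


# ---------------------------------------------------------------------------
# ReadSet
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """A redundant read collection with per-unique-sequence counts.

    ``R`` (redundant) is the total number of read instances, ``NR``
    (non-redundant) the number of distinct sequences; the ratio NR/R is the
    sample *complexity* (1 when every read differs, ~0 when all identical).
    """

    counts: Dict[str, int]
    read_length: int
    name: str = ""

    @property
    def R(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def NR(self) -> int:
        return len(self.counts)

    def __post_init__(self) -> None:
        for seq, c in self.counts.items():
            if c < 1:
                raise ValueError(f"read count must be >= 1 (got {c} for {seq!r})")
            if self.read_length and len(seq) != self.read_length:
                raise ValueError(
                    f"read {seq!r} has length {len(seq)}, expected {self.read_length}"
                )

    def complexity(self) -> float:
        """NR/R; NaN for an empty set."""
        r = self.R
        return self.NR / r if r else float("nan")


def read_fastq(path: str | Path, name: str = "") -> ReadSet:
    """Load a single-end FASTQ file into a :class:`ReadSet`.

    All reads must share one length (trim first if they do not).  An empty
    file yields an empty ReadSet with a warning.
    """
    path = Path(path)
    counts: Counter = Counter()
    lengths = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            seq = str(rec.seq).upper()
            counts[seq] += 1
            lengths.add(len(seq))
    except ValueError as exc:  # malformed record
        raise FastqParseError(
            f"{path}: malformed FASTQ near line {4 * len(counts) + 1}: {exc}"
        ) from exc
    if not counts:
        warnings.warn(f"{path}: empty FASTQ file", stacklevel=2)
        return ReadSet({}, 0, name=name or path.stem)
    if len(lengths) > 1:
        raise ValueError(
            f"{path}: reads of mixed lengths {sorted(lengths)}; trim to a common "
            "length (trim_reads) before analysis"
        )
    return ReadSet(dict(counts), lengths.pop(), name=name or path.stem)


def write_fastq(rs: ReadSet, path: str | Path) -> None:
    """Write a ReadSet as plain FASTQ (one record per read instance)."""
    with open(path, "w") as fh:
        i = 0
        for seq in sorted(rs.counts):
            for _ in range(rs.counts[seq]):
                fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                i += 1


def trim_reads(rs: ReadSet, length: int) -> ReadSet:
    """Truncate every read to its first ``length`` bases, merging duplicates.

    R is preserved; NR may decrease as distinct reads collapse onto a shared
    prefix.  Used to make libraries of different read lengths comparable.
    """
    if length > rs.read_length:
        raise ValueError(
            f"cannot trim to {length} nt: reads are {rs.read_length} nt"
        )
    if length == rs.read_length:
        return ReadSet(dict(rs.counts), rs.read_length, name=rs.name)
    merged: Counter = Counter()
    for seq, c in rs.counts.items():
        merged[seq[:length]] += c
    return ReadSet(dict(merged), length, name=rs.name)


# ---------------------------------------------------------------------------
# Genome + exact matching
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Load a FASTA file as a chrom -> uppercase-sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class AlignmentSet:
    """Exact full-length read placements on a genome.

    ``records`` has one row per (unique read, hit): columns
    ``seq, chrom, start, end, strand, count, n_hits``.  ``counts`` maps each
    unique sequence (matched or not) to its redundant abundance.
    """

    records: pd.DataFrame
    counts: Dict[str, int]
    read_length: int
    name: str = ""
    unmatched: Dict[str, int] = field(default_factory=dict)

    @property
    def genome_matching_R(self) -> int:
        if self.records.empty:
            return 0
        per_seq = self.records.drop_duplicates("seq")
        return int(per_seq["count"].sum())

    @property
    def genome_matching_NR(self) -> int:
        return int(self.records["seq"].nunique()) if not self.records.empty else 0

    def matched_sequences(self) -> set:
        return set(self.records["seq"]) if not self.records.empty else set()

    def restrict(self, counts: Mapping[str, int]) -> "AlignmentSet":
        """Alignments re-weighted to a (sub)sampled count mapping.

        Reads absent from ``counts`` (count 0) are dropped; hit positions are
        re-used, which is valid because a subsample is a subset of the
        original unique reads.
        """
        keep = {s: c for s, c in counts.items() if c > 0}
        if self.records.empty:
            rec = self.records
        else:
            rec = self.records[self.records["seq"].isin(keep)].copy()
            rec["count"] = rec["seq"].map(keep)
        unmatched = {s: c for s, c in keep.items() if s in self.unmatched}
        return AlignmentSet(rec, dict(keep), self.read_length, self.name, unmatched)


_RECORD_COLUMNS = ["seq", "chrom", "start", "end", "strand", "count", "n_hits"]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=_RECORD_COLUMNS)


def exact_match(rs: ReadSet, genome: Mapping[str, str], name: str = "") -> AlignmentSet:
    """Place reads by exact, full-length, gap-free matching on both strands.

    Every position where the read (+) or its reverse complement (-) equals
    the genomic substring is reported.  Reads containing ambiguity codes (N)
    never match.  Equivalent to a brute-force scan of all substrings of the
    read length.
    """
    k = rs.read_length
    if k == 0:
        return AlignmentSet(_empty_records(), {}, 0, name=name or rs.name)
    index: Dict[str, List] = defaultdict(list)
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((chrom, i))
    rows = []
    unmatched: Dict[str, int] = {}
    for seq, count in rs.counts.items():
        hits = []
        if "N" not in seq:
            for chrom, pos in index.get(seq, ()):
                hits.append((chrom, pos, "+"))
            rc = reverse_complement(seq)
            for chrom, pos in index.get(rc, ()):
                hits.append((chrom, pos, "-"))
        if hits:
            for chrom, pos, strand in hits:
                rows.append((seq, chrom, pos, pos + k, strand, count, len(hits)))
        else:
            unmatched[seq] = count
    records = (
        pd.DataFrame(rows, columns=_RECORD_COLUMNS) if rows else _empty_records()
    )
    return AlignmentSet(records, dict(rs.counts), k, name=name or rs.name, unmatched=unmatched)


def read_sam(path: str | Path, name: str = "") -> AlignmentSet:
    """Ingest alignments from a SAM file, keeping only exact full-length hits.

    Records must be ungapped, unclipped (CIGAR ``<k>M``) and have ``NM == 0``
    to mirror the exact-match criterion; anything else is dropped with a log
    message.  The original read sequence is recovered from reverse-strand
    records by reverse complementing the stored SEQ.
    """
    import pysam

    rows = []
    counts: Counter = Counter()
    seen_pairs = set()
    dropped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            k = len(aln.query_sequence)
            if aln.cigarstring != f"{k}M" or aln.get_tag("NM") != 0:
                dropped += 1
                continue
            seq = aln.query_sequence.upper()
            strand = "-" if aln.is_reverse else "+"
            if aln.is_reverse:
                seq = reverse_complement(seq)
            key = (aln.query_name, aln.reference_name, aln.reference_start, strand)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            rows.append((seq, aln.reference_name, aln.reference_start, strand))
    if dropped:
        logger.info("read_sam: dropped %d non-exact alignment records", dropped)
    if not rows:
        return AlignmentSet(_empty_records(), {}, 0, name=name)
    k = len(rows[0][0])
    # redundant count per sequence = number of read instances (query names)
    per_read: Dict[str, set] = defaultdict(set)
    hit_rows: Dict[str, set] = defaultdict(set)
    for i, (seq, chrom, start, strand) in enumerate(rows):
        hit_rows[seq].add((chrom, start, strand))
    # count instances: each row was one (read, placement); instances per seq =
    # rows per seq / hits per seq is fragile, so count query names per seq
    counts = Counter()
    name_sets: Dict[str, set] = defaultdict(set)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            kk = len(aln.query_sequence)
            if aln.cigarstring != f"{kk}M" or aln.get_tag("NM") != 0:
                continue
            seq = aln.query_sequence.upper()
            if aln.is_reverse:
                seq = reverse_complement(seq)
            name_sets[seq].add(aln.query_name)
    counts = {seq: len(names) for seq, names in name_sets.items()}
    out = []
    for seq, hits in hit_rows.items():
        for chrom, start, strand in sorted(hits):
            out.append((seq, chrom, start, start + k, strand, counts[seq], len(hits)))
    records = pd.DataFrame(out, columns=_RECORD_COLUMNS)
    return AlignmentSet(records, dict(counts), k, name=name)


def write_alignment_tsv(al: AlignmentSet, path: str | Path) -> None:
    """Dump alignments as TSV: read_id, seq, chrom, start0, strand, count."""
    df = al.records.copy()
    if df.empty:
        df = pd.DataFrame(columns=["read_id", "seq", "chrom", "start0", "strand", "count"])
    else:
        ids = {s: f"r{i}" for i, s in enumerate(sorted(al.counts))}
        df = df.assign(read_id=df["seq"].map(ids))[
            ["read_id", "seq", "chrom", "start", "strand", "count"]
        ].rename(columns={"start": "start0"})
    df.to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path: str | Path, read_length: Optional[int] = None,
                       name: str = "") -> AlignmentSet:
    """Load the TSV alignment dump written by :func:`write_alignment_tsv`."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return AlignmentSet(_empty_records(), {}, read_length or 0, name=name)
    k = read_length or len(df["seq"].iloc[0])
    counts = df.drop_duplicates("seq").set_index("seq")["count"].to_dict()
    n_hits = df.groupby("seq")["seq"].transform("size")
    records = pd.DataFrame(
        {
            "seq": df["seq"],
            "chrom": df["chrom"],
            "start": df["start0"],
            "end": df["start0"] + k,
            "strand": df["strand"],
            "count": df["count"],
            "n_hits": n_hits,
        }
    )
    return AlignmentSet(records, {s: int(c) for s, c in counts.items()}, k, name=name)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationIndex:
    """Class-indexed interval store over the genome annotation.

    ``features`` maps each annotation class to a DataFrame with columns
    ``chrom, start, end, strand, gene_id`` (0-based half-open).  ``genes``
    holds one row per gene (its genomic span); ``gene_exons`` the exon model.
    """

    features: Dict[str, pd.DataFrame]
    genes: pd.DataFrame
    gene_exons: Dict[str, List[tuple]]
    chrom_sizes: Dict[str, int] = field(default_factory=dict)
    _trees: Dict[tuple, IntervalTree] = field(default_factory=dict, repr=False)
    _gene_trees: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for cls, df in self.features.items():
            for chrom, sub in df.groupby("chrom", observed=True):
                tree = IntervalTree()
                for start, end in zip(sub["start"], sub["end"]):
                    if end > start:
                        tree.addi(int(start), int(end))
                self._trees[(cls, str(chrom))] = tree
        for chrom, sub in self.genes.groupby("chrom", observed=True):
            tree = IntervalTree()
            for gid, start, end in zip(sub["gene_id"], sub["start"], sub["end"]):
                tree.addi(int(start), int(end), gid)
            self._gene_trees[str(chrom)] = tree

    def classes(self) -> List[str]:
        return [c for c in ANNOTATION_CLASSES if c in self.features]

    def overlaps_class(self, cls: str, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get((cls, chrom))
        return bool(tree is not None and tree.overlap(start, end))

    def genes_overlapping(self, chrom: str, start: int, end: int) -> List[str]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def gene_span(self, gene_id: str) -> tuple:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"gene {gene_id!r} not in annotation")
        r = row.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["strand"])

    def gene_ids(self) -> List[str]:
        return list(self.genes["gene_id"])


def load_annotation(gff_path: str | Path,
                    chrom_sizes: Optional[Mapping[str, int]] = None) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GFF3 file.

    Feature types are mapped onto the canonical classes (mRNA/CDS -> CDS,
    five_prime_UTR -> 5UTR, t/rRNA/miRNA/... -> ncRNA); unknown types are
    ignored with a log message.  When ``chrom_sizes`` is given, the
    ``intergenic`` class is computed as the complement of all annotated
    features.
    """
    import pyranges as pr

    df = pr.read_gff3(str(gff_path)).df
    if (df["End"] < df["Start"]).any():
        bad = df[df["End"] < df["Start"]].iloc[0]
        raise ValueError(
            f"{gff_path}: feature end < start at {bad['Chromosome']}:{bad['Start']}"
        )
    df = df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end", "Strand": "strand"}
    )
    df["chrom"] = df["chrom"].astype(str)
    df["strand"] = df["strand"].astype(str)

    genes = df[df["Feature"] == "gene"].reset_index(drop=True)
    gene_rows = pd.DataFrame(
        {
            "gene_id": genes["ID"] if "ID" in genes else pd.Series(dtype=str),
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "strand": genes["strand"],
            "biotype": genes["biotype"]
            if "biotype" in genes
            else ["protein_coding"] * len(genes),
        }
    )

    # resolve Parent one level (exon -> mRNA -> gene) if transcripts are used
    parent_of = {}
    if "ID" in df.columns and "Parent" in df.columns:
        with_id = df.dropna(subset=["ID"])
        parent_of = dict(zip(with_id["ID"], with_id.get("Parent", np.nan)))
    gene_ids = set(gene_rows["gene_id"])

    def to_gene(parent):
        if parent in gene_ids:
            return parent
        grand = parent_of.get(parent)
        return grand if grand in gene_ids else None

    features: Dict[str, list] = defaultdict(list)
    unknown = Counter()
    for _, row in df.iterrows():
        ftype = str(row["Feature"])
        if ftype == "gene":
            continue
        cls = _GFF_CLASS_MAP.get(ftype)
        if cls is None:
            unknown[ftype] += 1
            continue
        gid = to_gene(row.get("Parent")) if pd.notna(row.get("Parent", np.nan)) else None
        if gid is None and pd.notna(row.get("ID", np.nan)):
            gid = row["ID"] if row["ID"] in gene_ids else row["ID"]
        features[cls].append(
            (row["chrom"], int(row["start"]), int(row["end"]), row["strand"], gid)
        )
    if unknown:
        logger.info("load_annotation: ignored feature types %s", dict(unknown))

    feat_frames = {
        cls: pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])
        for cls, rows in features.items()
    }
    for cls in ANNOTATION_CLASSES:
        if cls not in feat_frames and cls != "intergenic":
            feat_frames[cls] = pd.DataFrame(
                columns=["chrom", "start", "end", "strand", "gene_id"]
            )

    gene_exons: Dict[str, List[tuple]] = defaultdict(list)
    for _, row in feat_frames["exon"].iterrows():
        if row["gene_id"] is not None:
            gene_exons[row["gene_id"]].append((int(row["start"]), int(row["end"])))
    for gid in gene_exons:
        gene_exons[gid].sort()

    sizes = dict(chrom_sizes or {})
    if sizes:
        inter_rows = []
        for chrom, size in sizes.items():
            covered = IntervalTree()
            for cls, fdf in feat_frames.items():
                sub = fdf[fdf["chrom"] == chrom]
                for s, e in zip(sub["start"], sub["end"]):
                    covered.addi(int(s), int(e))
            sub = gene_rows[gene_rows["chrom"] == chrom]
            for s, e in zip(sub["start"], sub["end"]):
                covered.addi(int(s), int(e))
            covered.merge_overlaps()
            pos = 0
            for iv in sorted(covered):
                if iv.begin > pos:
                    inter_rows.append((chrom, pos, iv.begin, ".", None))
                pos = max(pos, iv.end)
            if pos < size:
                inter_rows.append((chrom, pos, size, ".", None))
        feat_frames["intergenic"] = pd.DataFrame(
            inter_rows, columns=["chrom", "start", "end", "strand", "gene_id"]
        )

    return AnnotationIndex(feat_frames, gene_rows, dict(gene_exons), sizes)


# ---------------------------------------------------------------------------
# Read classification and intersection analysis
# ---------------------------------------------------------------------------


def classify_reads(al: AlignmentSet, ann: AnnotationIndex) -> pd.DataFrame:
    """Per-annotation-class R/NR counts and proportions of matched reads.

    A unique read belongs to a class when any of its placements overlaps at
    least one feature of that class; classes are therefore *not* mutually
    exclusive.  Proportions are relative to the genome-matching totals.
    """
    total_R = al.genome_matching_R
    total_NR = al.genome_matching_NR
    classes = ann.classes()
    if total_R == 0:
        warnings.warn("classify_reads: no genome-matching reads", stacklevel=2)
        return pd.DataFrame(
            {"class": classes, "R": 0, "NR": 0, "pct_R": 0.0, "pct_NR": 0.0}
        ).set_index("class")
    membership = _class_membership(al, ann)
    rows = []
    for cls in classes:
        seqs = membership[cls]
        r = sum(al.counts[s] for s in seqs)
        nr = len(seqs)
        rows.append((cls, r, nr, 100.0 * r / total_R, 100.0 * nr / total_NR))
    return pd.DataFrame(rows, columns=["class", "R", "NR", "pct_R", "pct_NR"]).set_index(
        "class"
    )


def _class_membership(al: AlignmentSet, ann: AnnotationIndex) -> Dict[str, set]:
    membership: Dict[str, set] = {cls: set() for cls in ann.classes()}
    if al.records.empty:
        return membership
    for seq, chrom, start, end in zip(
        al.records["seq"], al.records["chrom"], al.records["start"], al.records["end"]
    ):
        for cls in membership:
            if seq not in membership[cls] and ann.overlaps_class(cls, chrom, start, end):
                membership[cls].add(seq)
    return membership


def intersection_matrix(al: AlignmentSet, ann: AnnotationIndex) -> pd.DataFrame:
    """Class-by-class intersection proportions (asymmetric).

    Entry (row r, column c) is the redundant abundance of reads belonging to
    both classes divided by that of reads in the *column* class; the
    diagonal is 1.00 and an empty column class yields NA.
    """
    membership = _class_membership(al, ann)
    classes = ann.classes()
    mat = pd.DataFrame(index=classes, columns=classes, dtype=float)
    col_totals = {
        c: sum(al.counts[s] for s in membership[c]) for c in classes
    }
    for c in classes:
        for r in classes:
            if col_totals[c] == 0:
                mat.loc[r, c] = np.nan
            else:
                both = membership[r] & membership[c]
                mat.loc[r, c] = sum(al.counts[s] for s in both) / col_totals[c]
    return mat


# ---------------------------------------------------------------------------
# Expression and coverage
# ---------------------------------------------------------------------------


def multi_gene_reads(al: AlignmentSet, ann: AnnotationIndex) -> set:
    """Unique reads whose placements overlap more than one gene."""
    hit: Dict[str, set] = defaultdict(set)
    for seq, chrom, start, end in zip(
        al.records["seq"], al.records["chrom"], al.records["start"], al.records["end"]
    ):
        hit[seq].update(ann.genes_overlapping(chrom, start, end))
    return {s for s, genes in hit.items() if len(genes) > 1}


def gene_expression(
    alignments: Mapping[str, AlignmentSet],
    ann: AnnotationIndex,
    exclude_multi_gene: bool = False,
) -> pd.DataFrame:
    """Genes x samples matrix of raw abundances.

    A gene's abundance is the sum of the counts of the unique reads incident
    with it (each unique read counted once per gene, however many placements
    it has inside that gene).  Reads hitting several genes contribute their
    full count to each unless ``exclude_multi_gene`` is set.
    """
    genes = ann.gene_ids()
    data = {}
    for sample, al in alignments.items():
        excluded = multi_gene_reads(al, ann) if exclude_multi_gene else set()
        per_gene: Dict[str, set] = defaultdict(set)
        for seq, chrom, start, end in zip(
            al.records["seq"], al.records["chrom"], al.records["start"], al.records["end"]
        ):
            if seq in excluded:
                continue
            for gid in ann.genes_overlapping(chrom, start, end):
                per_gene[gid].add(seq)
        data[sample] = [
            float(sum(al.counts[s] for s in per_gene.get(g, ()))) for g in genes
        ]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def coverage_vector(
    al: AlignmentSet, ann: AnnotationIndex, gene: str, spliced: bool = False
) -> np.ndarray:
    """Per-position summed read abundance y[i] over a gene.

    y[i] is the sum of the counts of reads overlapping position i, in
    ascending genomic coordinates over the gene's genomic span (introns
    included); with ``spliced=True`` positions are the concatenated exons.
    """
    chrom, g_start, g_end, _ = ann.gene_span(gene)
    if g_end <= g_start:
        raise ValueError(f"gene {gene!r} has zero length")
    span = np.zeros(g_end - g_start)
    sub = al.records
    if not sub.empty:
        sub = sub[(sub["chrom"] == chrom) & (sub["start"] < g_end) & (sub["end"] > g_start)]
        for start, end, count in zip(sub["start"], sub["end"], sub["count"]):
            lo = max(int(start), g_start) - g_start
            hi = min(int(end), g_end) - g_start
            span[lo:hi] += count
    if not spliced:
        return span
    exons = ann.gene_exons.get(gene)
    if not exons:
        return span
    parts = [span[s - g_start : e - g_start] for s, e in exons]
    return np.concatenate(parts)


class GeneCoverageModel:
    """Precomputed read-to-gene overlap segments for fast re-weighting.

    Subsampling changes read *counts* but not placements; this caches, per
    gene, the (seq, lo, hi) overlap segments so coverage vectors under any
    count mapping can be rebuilt cheaply.
    """

    def __init__(self, al: AlignmentSet, ann: AnnotationIndex,
                 genes: Optional[Sequence[str]] = None):
        self.lengths: Dict[str, int] = {}
        self.segments: Dict[str, List[tuple]] = {}
        gene_list = list(genes) if genes is not None else ann.gene_ids()
        spans = {g: ann.gene_span(g) for g in gene_list}
        for g, (chrom, s, e, _) in spans.items():
            self.lengths[g] = e - s
            self.segments[g] = []
        if al.records.empty:
            return
        for seq, chrom, start, end in zip(
            al.records["seq"], al.records["chrom"], al.records["start"], al.records["end"]
        ):
            for gid in ann.genes_overlapping(chrom, start, end):
                if gid not in self.segments:
                    continue
                _, g_start, g_end, _ = spans[gid]
                lo = max(int(start), g_start) - g_start
                hi = min(int(end), g_end) - g_start
                self.segments[gid].append((seq, lo, hi))

    def coverage(self, gene: str, counts: Mapping[str, int]) -> np.ndarray:
        y = np.zeros(self.lengths[gene])
        for seq, lo, hi in self.segments[gene]:
            c = counts.get(seq, 0)
            if c:
                y[lo:hi] += c
        return y

    def abundance(self, gene: str, counts: Mapping[str, int]) -> float:
        seqs = {seq for seq, _, _ in self.segments[gene]}
        return float(sum(counts.get(s, 0) for s in seqs))


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV expression matrix (header row, gene index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
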