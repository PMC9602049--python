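"""Candidate piRNA discovery from small-RNA reads.

The protocol collapses reads into unique-sequence tags, maps tags to the
genome, subtracts known non-coding classes (rRNA, tRNA, snRNA, snoRNA, scRNA)
by annotation overlap, removes miRNAs by exact sequence or locus match, and
finally retains tags of 24-33 nt that align to exactly one genomic position.
Surviving tags are the candidate piRNAs; helpers summarise their first-base
bias, length distribution, and group sharing.

Every subtraction stage returns a removal ledger so that tag accounting is
conserved end to end.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import FastqParseError, as_dna, iter_fastq, read_fasta, revcomp

KNOWN_NCRNA_CLASSES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA", "scRNA"})
PIRNA_LENGTH_RANGE = (24, 33)

__all__ = [
    "SmallRNATag",
    "AlignmentHit",
    "PiRNACandidate",
    "collapse_reads",
    "map_tags",
    "ingest_sam",
    "subtract_ncrna",
    "subtract_mirna",
    "call_pirnas",
    "first_base_bias",
    "group_set_partition",
    "length_distribution",
    "discover_pipeline",
    "DiscoveryResult",
    "EmptyGroupError",
]


class EmptyGroupError(ValueError):
    """A per-group summary was requested for a group with no candidates."""


@dataclass
class SmallRNATag:
    """A collapsed unique read sequence with per-replicate counts."""

    sequence: str
    counts: dict[str, int]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def pooled(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class AlignmentHit:
    """One genomic placement of a tag (0-based half-open, forward coords)."""

    tag: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int = 0


@dataclass
class PiRNACandidate:
    """A tag that survived all identification filters."""

    pirna_id: str
    sequence: str
    locus: AlignmentHit
    counts: dict[str, int]
    group_presence: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def first_base(self) -> str:
        """5'-terminal base, reported in RNA letters (T -> U)."""
        return "U" if self.sequence[0] == "T" else self.sequence[0]

    @property
    def pooled(self) -> int:
        return sum(self.counts.values())


def pirna_id(sequence: str) -> str:
    """Stable sequence-derived identifier."""
    return "piR-syn-" + hashlib.sha1(sequence.encode()).hexdigest()[:10]


def collapse_reads(fastq_by_replicate: Mapping[str, str | Path]):
    """Collapse FASTQ reads into unique-sequence tags with per-replicate counts.

    Returns (tags sorted by sequence, library sizes {replicate: total reads}).
    The result is independent of read order within files.
    """
    if len(set(fastq_by_replicate)) != len(fastq_by_replicate):
        raise ValueError("replicate labels must be unique")
    per_rep: dict[str, Counter] = {}
    library_sizes: dict[str, int] = {}
    for rep, path in fastq_by_replicate.items():
        ctr: Counter = Counter()
        n = 0
        for _title, seq in iter_fastq(path):
            seq = as_dna(seq)
            if set(seq) - set("ACGT"):
                raise FastqParseError(f"{path}: non-ACGT characters in read {_title!r}")
            ctr[seq] += 1
            n += 1
        per_rep[rep] = ctr
        library_sizes[rep] = n
    all_seqs = sorted(set().union(*[set(c) for c in per_rep.values()]) if per_rep else set())
    tags = [
        SmallRNATag(seq, {rep: per_rep[rep][seq] for rep in per_rep if per_rep[rep][seq]})
        for seq in all_seqs
    ]
    return tags, library_sizes


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _scan_mismatched(genome_codes: np.ndarray, tag: str, max_mm: int) -> list[tuple[int, int]]:
    """All (start, mismatches) placements with <= max_mm substitutions."""
    L = len(tag)
    if L > len(genome_codes):
        return []
    tag_codes = np.frombuffer(tag.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(genome_codes, L)
    mm = (windows != tag_codes).sum(axis=1)
    starts = np.nonzero(mm <= max_mm)[0]
    return [(int(s), int(mm[s])) for s in starts]


_SEED_K = 18  # shortest tag the exact-match index serves directly


def _build_seed_index(genome: Mapping[str, str], k: int = _SEED_K):
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((chrom, i))
    return index


def _exact_hits(genome, index, seq: str) -> list[tuple[str, int]]:
    """All exact forward-strand placements of seq, via the seed index."""
    if len(seq) < _SEED_K:  # rare short tag: fall back to direct search
        return [(c, s) for c, g in genome.items() for s in _find_all(g, seq)]
    out = []
    for chrom, pos in index.get(seq[:_SEED_K], ()):
        if genome[chrom][pos : pos + len(seq)] == seq:
            out.append((chrom, pos))
    return out


def map_tags(
    tags: Sequence[SmallRNATag] | Sequence[str],
    genome: Mapping[str, str] | str | Path,
    max_mismatches: int = 0,
) -> dict[str, list[AlignmentHit]]:
    """Map tag sequences to the genome on both strands.

    Exact matching (the default) goes through a seed k-mer index with full
    verification; with max_mismatches > 0 a numpy sliding-window scan is used
    (adequate for desk-scale genomes). Only hits at the best mismatch stratum
    are reported, and every hit is re-verified by direct sequence comparison.
    """
    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    seqs = [t.sequence if isinstance(t, SmallRNATag) else as_dna(t) for t in tags]
    codes = (
        {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in genome.items()}
        if max_mismatches > 0
        else {}
    )
    index = _build_seed_index(genome) if max_mismatches == 0 else {}
    hits_by_tag: dict[str, list[AlignmentHit]] = {}
    for seq in seqs:
        rc = revcomp(seq)
        found: list[AlignmentHit] = []
        if max_mismatches == 0:
            for chrom, s in _exact_hits(genome, index, seq):
                found.append(AlignmentHit(seq, chrom, s, s + len(seq), "+", 0))
            for chrom, s in _exact_hits(genome, index, rc):
                found.append(AlignmentHit(seq, chrom, s, s + len(seq), "-", 0))
        else:
            for chrom in genome:
                for s, mm in _scan_mismatched(codes[chrom], seq, max_mismatches):
                    found.append(AlignmentHit(seq, chrom, s, s + len(seq), "+", mm))
                for s, mm in _scan_mismatched(codes[chrom], rc, max_mismatches):
                    found.append(AlignmentHit(seq, chrom, s, s + len(seq), "-", mm))
        if found:
            best = min(h.mismatches for h in found)
            found = [h for h in found if h.mismatches == best]
            # verification: the placed genome substring must reproduce the tag
            for h in found:
                sub = genome[h.chrom][h.start : h.end]
                obs = sub if h.strand == "+" else revcomp(sub)
                n_mm = sum(a != b for a, b in zip(obs, seq))
                assert n_mm == h.mismatches, "mapper self-check failed"
            hits_by_tag[seq] = sorted(found, key=lambda h: (h.chrom, h.start, h.strand))
    return hits_by_tag


def ingest_sam(
    sam_path: str | Path, genome: Mapping[str, str] | str | Path
) -> dict[str, list[AlignmentHit]]:
    """Ingest externally produced SAM/BAM alignments, re-verifying coordinates.

    Keeps, per tag sequence, all alignments at the best reported mismatch
    stratum (recomputed by direct comparison against the FASTA).
    """
    import pysam

    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    raw: dict[str, list[AlignmentHit]] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            chrom = aln.reference_name
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} in SAM absent from FASTA")
            seq = as_dna(aln.get_forward_sequence() or aln.query_sequence)
            start, end = aln.reference_start, aln.reference_start + len(seq)
            sub = genome[chrom][start:end]
            if len(sub) != len(seq):
                continue
            strand = "-" if aln.is_reverse else "+"
            obs = sub if strand == "+" else revcomp(sub)
            mm = sum(a != b for a, b in zip(obs, seq))
            raw.setdefault(seq, []).append(AlignmentHit(seq, chrom, start, end, strand, mm))
    out = {}
    for seq, hits in raw.items():
        best = min(h.mismatches for h in hits)
        out[seq] = sorted(
            (h for h in hits if h.mismatches == best),
            key=lambda h: (h.chrom, h.start, h.strand),
        )
    return out


def _build_trees(features: pd.DataFrame, classes: Iterable[str]) -> dict[str, IntervalTree]:
    classes = set(classes)
    trees: dict[str, IntervalTree] = {}
    sel = features[features["type"].isin(classes)]
    for row in sel.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.type)
    return trees


def subtract_ncrna(
    tags: Sequence[SmallRNATag],
    hits_by_tag: Mapping[str, list[AlignmentHit]],
    features: pd.DataFrame,
    classes: Iterable[str] = KNOWN_NCRNA_CLASSES,
    min_overlap_frac: float = 0.5,
):
    """Remove tags whose alignments overlap annotated ncRNA features.

    A tag is removed if any of its hits overlaps a listed-class feature by at
    least min_overlap_frac of the tag length, on either strand. Returns
    (surviving tags, ledger DataFrame with columns tag/stage/reason).
    """
    classes = list(classes)
    unknown = set(classes) - KNOWN_NCRNA_CLASSES
    if unknown:
        raise ValueError(f"unknown ncRNA classes in filter list: {sorted(unknown)}")
    trees = _build_trees(features, classes)
    survivors, ledger = [], []
    for tag in tags:
        removed_class = None
        for h in hits_by_tag.get(tag.sequence, []):
            tree = trees.get(h.chrom)
            if tree is None:
                continue
            best_ov, best_cls = 0, None
            for iv in tree.overlap(h.start, h.end):
                ov = min(h.end, iv.end) - max(h.start, iv.begin)
                if ov > best_ov:
                    best_ov, best_cls = ov, iv.data
            if best_ov >= min_overlap_frac * tag.length:
                removed_class = best_cls
                break
        if removed_class is None:
            survivors.append(tag)
        else:
            ledger.append((tag.sequence, "ncRNA_subtraction", removed_class))
    return survivors, pd.DataFrame(ledger, columns=["tag", "stage", "reason"])


def subtract_mirna(
    tags: Sequence[SmallRNATag],
    mirna_sequences: Iterable[str] | None = None,
    mirna_loci: pd.DataFrame | None = None,
    hits_by_tag: Mapping[str, list[AlignmentHit]] | None = None,
    min_overlap_frac: float = 0.5,
):
    """Remove known miRNA tags, by exact sequence match and/or locus overlap."""
    if mirna_sequences is None and mirna_loci is None:
        raise ValueError("provide miRNA sequences and/or miRNA loci")
    mir_set = {as_dna(s) for s in mirna_sequences} if mirna_sequences is not None else set()
    trees = (
        _build_trees(mirna_loci.assign(type="miRNA"), {"miRNA"})
        if mirna_loci is not None
        else {}
    )
    survivors, ledger = [], []
    for tag in tags:
        reason = None
        if tag.sequence in mir_set:
            reason = "miRNA_sequence"
        elif trees and hits_by_tag is not None:
            for h in hits_by_tag.get(tag.sequence, []):
                tree = trees.get(h.chrom)
                if tree is None:
                    continue
                for iv in tree.overlap(h.start, h.end):
                    ov = min(h.end, iv.end) - max(h.start, iv.begin)
                    if ov >= min_overlap_frac * tag.length:
                        reason = "miRNA_locus"
                        break
                if reason:
                    break
        if reason is None:
            survivors.append(tag)
        else:
            ledger.append((tag.sequence, "miRNA_subtraction", reason))
    return survivors, pd.DataFrame(ledger, columns=["tag", "stage", "reason"])


def call_pirnas(
    tags: Sequence[SmallRNATag],
    hits_by_tag: Mapping[str, list[AlignmentHit]],
    length_range: tuple[int, int] = PIRNA_LENGTH_RANGE,
    rep_to_group: Mapping[str, str] | None = None,
    min_count: int = 1,
):
    """Apply the length window and unique-position filters.

    A tag becomes a candidate piRNA iff its length lies in the inclusive
    window and it has exactly one best-stratum alignment. Output is sorted by
    descending pooled count, then sequence. Returns (candidates, ledger).
    """
    lo, hi = length_range
    candidates, ledger = [], []
    for tag in tags:
        hits = hits_by_tag.get(tag.sequence, [])
        if not lo <= tag.length <= hi:
            ledger.append((tag.sequence, "length_filter", f"length={tag.length}"))
            continue
        if len(hits) != 1:
            ledger.append((tag.sequence, "unique_position_filter", f"n_hits={len(hits)}"))
            continue
        cand = PiRNACandidate(pirna_id(tag.sequence), tag.sequence, hits[0], dict(tag.counts))
        if rep_to_group is not None:
            groups = sorted(set(rep_to_group.values()))
            pooled = {g: 0 for g in groups}
            for rep, c in cand.counts.items():
                pooled[rep_to_group[rep]] += c
            cand.group_presence = {g: pooled[g] >= min_count for g in groups}
        candidates.append(cand)
    candidates.sort(key=lambda c: (-c.pooled, c.sequence))
    return candidates, pd.DataFrame(ledger, columns=["tag", "stage", "reason"])


def _present(candidates: Sequence[PiRNACandidate], group: str | None):
    if group is None:
        return list(candidates)
    return [c for c in candidates if c.group_presence.get(group, False)]


def first_base_bias(
    candidates: Sequence[PiRNACandidate], group: str | None = None, weighted: bool = False
) -> dict[str, float]:
    """Fractions of 5'-first bases over {A, C, G, U}.

    By default each distinct candidate counts once; with weighted=True
    candidates are weighted by their pooled read counts.
    """
    present = _present(candidates, group)
    if not present:
        raise EmptyGroupError(f"no candidates present in group {group!r}")
    weights = Counter()
    for c in present:
        weights[c.first_base] += c.pooled if weighted else 1
    total = sum(weights.values())
    return {b: weights[b] / total for b in "ACGU"}


def length_distribution(
    candidates: Sequence[PiRNACandidate],
    group: str | None = None,
    length_range: tuple[int, int] = PIRNA_LENGTH_RANGE,
) -> dict[int, int]:
    """Histogram of candidate lengths over the inclusive piRNA window."""
    lo, hi = length_range
    hist = {length: 0 for length in range(lo, hi + 1)}
    for c in _present(candidates, group):
        hist[c.length] += 1
    return hist


@dataclass
class PartitionResult:
    """Venn-style partition of candidates by group presence."""

    cells: dict[tuple[str, ...], set[str]]
    groups: tuple[str, ...]

    @property
    def shared(self) -> set[str]:
        return self.cells.get(self.groups, set())

    def unique(self, group: str) -> set[str]:
        return self.cells.get((group,), set())

    def sizes(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.cells.items()}


def group_set_partition(
    candidates: Sequence[PiRNACandidate], groups: Sequence[str] | None = None
) -> PartitionResult:
    """Exhaustive, disjoint partition of candidates by their presence pattern.

    Presence follows each candidate's group_presence flags (pooled group count
    >= min_count, as set in call_pirnas).
    """
    if groups is None:
        groups = sorted({g for c in candidates for g in c.group_presence})
    groups = tuple(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a set partition")
    cells: dict[tuple[str, ...], set[str]] = {}
    for c in candidates:
        key = tuple(g for g in groups if c.group_presence.get(g, False))
        if key:
            cells.setdefault(key, set()).add(c.pirna_id)
    return PartitionResult(cells=cells, groups=groups)


@dataclass
class DiscoveryResult:
    """Everything the discovery stage produces."""

    candidates: list[PiRNACandidate]
    ledger: pd.DataFrame
    library_sizes: dict[str, int]
    n_tags_in: int

    def counts_frame(self) -> pd.DataFrame:
        reps = sorted(self.library_sizes)
        data = {
            c.pirna_id: [c.counts.get(r, 0) for r in reps] for c in self.candidates
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=reps)

    def catalog_frame(self) -> pd.DataFrame:
        reps = sorted(self.library_sizes)
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "pirna_id": c.pirna_id,
                    "sequence": c.sequence,
                    "length": c.length,
                    "first_base": c.first_base,
                    "chrom": c.locus.chrom,
                    "start": c.locus.start,
                    "end": c.locus.end,
                    "strand": c.locus.strand,
                    **{f"count_{r}": c.counts.get(r, 0) for r in reps},
                    "pooled": c.pooled,
                }
            )
        cols = [
            "pirna_id", "sequence", "length", "first_base", "chrom", "start",
            "end", "strand", *[f"count_{r}" for r in reps], "pooled",
        ]
        return pd.DataFrame(rows, columns=cols)


def discover_pipeline(
    fastq_by_replicate: Mapping[str, str | Path],
    genome: Mapping[str, str] | str | Path,
    annotations: pd.DataFrame,
    mirna_sequences: Iterable[str] | None = None,
    rep_to_group: Mapping[str, str] | None = None,
    ncrna_classes: Iterable[str] = KNOWN_NCRNA_CLASSES,
    min_overlap_frac: float = 0.5,
    length_range: tuple[int, int] = PIRNA_LENGTH_RANGE,
    max_mismatches: int = 0,
) -> DiscoveryResult:
    """Run the full identification protocol on per-replicate FASTQ files."""
    tags, library_sizes = collapse_reads(fastq_by_replicate)
    n_in = len(tags)
    hits = map_tags(tags, genome, max_mismatches=max_mismatches)
    tags1, led1 = subtract_ncrna(tags, hits, annotations, classes=ncrna_classes,
                                 min_overlap_frac=min_overlap_frac)
    mirna_loci = annotations[annotations["type"] == "miRNA"]
    tags2, led2 = subtract_mirna(
        tags1,
        mirna_sequences=mirna_sequences,
        mirna_loci=mirna_loci if len(mirna_loci) else None,
        hits_by_tag=hits,
        min_overlap_frac=min_overlap_frac,
    )
    candidates, led3 = call_pirnas(
        tags2, hits, length_range=length_range, rep_to_group=rep_to_group
    )
    ledger = pd.concat([led1, led2, led3], ignore_index=True)
    return DiscoveryResult(candidates, ledger, library_sizes, n_in)
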