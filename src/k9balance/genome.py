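"""Annotation data model, interval arithmetic, and GFF3/BED I/O.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)``.  GFF3 files
are read and written 1-based inclusive; BED files 0-based half-open.  All
conversions happen at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "TERecord",
    "ChromosomePartition",
    "AnnotationSet",
    "FeatureConfig",
    "SUPERFAMILIES",
    "merge_intervals",
    "interval_overlap_bp",
    "te_bp_in_window",
    "nearest_te_distance",
    "classify_compartment",
    "read_gff3",
    "write_gff3",
    "read_partition_bed",
    "write_partition_bed",
    "read_te_bed",
    "write_te_bed",
]

SUPERFAMILIES = frozenset({"Gypsy", "Copia", "LINE", "DNA", "other"})

STRANDS = frozenset({"+", "-", "."})


class GenomeModelError(ValueError):
    """Raised on validation failures in the annotation model."""


class GFF3ParseError(GenomeModelError):
    """Raised when a GFF3 line cannot be parsed; carries the line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise GenomeModelError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise GenomeModelError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise GenomeModelError(f"strand must be one of {sorted(STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    id: str
    interval: GenomicInterval
    is_nlr: bool = False
    is_focal: bool = False
    categories: frozenset = frozenset()


@dataclass(frozen=True)
class TERecord:
    id: str
    interval: GenomicInterval
    superfamily: str = "other"

    def __post_init__(self):
        if self.superfamily not in SUPERFAMILIES:
            raise GenomeModelError(
                f"superfamily {self.superfamily!r} not in {sorted(SUPERFAMILIES)}"
            )


COMPARTMENTS = ("arm", "pericentromere")


@dataclass(frozen=True)
class ChromosomePartition:
    """Ordered, non-overlapping labelled segments per chromosome.

    ``segments`` maps chromosome -> list of (interval, label) with label in
    {"arm", "pericentromere"}; segments must be sorted and non-overlapping.
    """

    segments: Mapping[str, Tuple[Tuple[GenomicInterval, str], ...]]

    def __post_init__(self):
        for chrom, segs in self.segments.items():
            prev_end = -1
            for iv, label in segs:
                if label not in COMPARTMENTS:
                    raise GenomeModelError(f"unknown compartment label {label!r}")
                if iv.chrom != chrom:
                    raise GenomeModelError(
                        f"partition segment chrom {iv.chrom} filed under {chrom}"
                    )
                if iv.start < prev_end:
                    raise GenomeModelError(
                        f"overlapping partition segments on {chrom}"
                    )
                prev_end = iv.end

    def label_at(self, chrom: str, pos: int) -> str:
        segs = self.segments.get(chrom)
        if segs is None:
            raise GenomeModelError(f"no partition for chromosome {chrom}")
        for iv, label in segs:
            if iv.start <= pos < iv.end:
                return label
        raise GenomeModelError(
            f"position {chrom}:{pos} outside partitioned extent"
        )


@dataclass
class AnnotationSet:
    genes: List[GeneRecord] = field(default_factory=list)
    tes: List[TERecord] = field(default_factory=list)
    partition: Optional[ChromosomePartition] = None
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        seen_g = set()
        for g in self.genes:
            if g.id in seen_g:
                raise GenomeModelError(f"duplicate gene id {g.id}")
            seen_g.add(g.id)
        seen_t = set()
        for t in self.tes:
            if t.id in seen_t:
                raise GenomeModelError(f"duplicate TE id {t.id}")
            seen_t.add(t.id)
        if self.chrom_lengths:
            for rec in list(self.genes) + list(self.tes):
                L = self.chrom_lengths.get(rec.interval.chrom)
                if L is not None and rec.interval.end > L:
                    raise GenomeModelError(
                        f"{rec.id} extends past end of {rec.interval.chrom}"
                    )

    def tes_by_chrom(self) -> Dict[str, List[TERecord]]:
        out: Dict[str, List[TERecord]] = {}
        for t in self.tes:
            out.setdefault(t.interval.chrom, []).append(t)
        for lst in out.values():
            lst.sort(key=lambda t: (t.interval.start, t.interval.end, t.id))
        return out


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union-merge intervals into disjoint sorted intervals.

    Touching intervals ([0,5), [5,9)) merge.  All inputs must share one
    chromosome.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise GenomeModelError(f"mixed chromosomes in merge: {sorted(chroms)}")
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: List[GenomicInterval] = []
    cur_start, cur_end = ordered[0].start, ordered[0].end
    chrom = ordered[0].chrom
    for iv in ordered[1:]:
        if iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
            cur_start, cur_end = iv.start, iv.end
    merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def interval_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals (0 when chromosomes differ)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def te_bp_in_window(
    gene: GeneRecord | GenomicInterval,
    tes: Iterable[TERecord],
    flank_d: int,
    chrom_length: Optional[int] = None,
) -> int:
    """Union TE base pairs inside the gene span extended by ``flank_d``.

    The window is clamped to [0, chrom_length); overlapping TE annotations
    are merged before counting so no base is counted twice.  Monotone
    non-decreasing in ``flank_d``.
    """
    if flank_d < 0:
        raise GenomeModelError("flank_d must be >= 0")
    iv = gene.interval if isinstance(gene, GeneRecord) else gene
    w_start = max(0, iv.start - flank_d)
    w_end = iv.end + flank_d
    if chrom_length is not None:
        w_end = min(w_end, chrom_length)
    if w_end <= w_start:
        return 0
    window = GenomicInterval(iv.chrom, w_start, w_end)
    clipped = []
    for te in tes:
        ov = interval_overlap_bp(window, te.interval)
        if ov > 0:
            clipped.append(
                GenomicInterval(
                    iv.chrom,
                    max(te.interval.start, w_start),
                    min(te.interval.end, w_end),
                )
            )
    return sum(m.length for m in merge_intervals(clipped))


def nearest_te_distance(
    gene: GeneRecord | GenomicInterval, tes: Iterable[TERecord]
) -> Optional[int]:
    """Gap in bp to the closest TE on the same chromosome.

    Returns 0 when a TE overlaps the gene and ``None`` when no TE shares the
    chromosome (callers exclude such genes from group means).
    """
    iv = gene.interval if isinstance(gene, GeneRecord) else gene
    best: Optional[int] = None
    for te in tes:
        t = te.interval
        if t.chrom != iv.chrom:
            continue
        if t.start < iv.end and iv.start < t.end:
            return 0
        gap = t.start - iv.end if t.start >= iv.end else iv.start - t.end
        if best is None or gap < best:
            best = gap
    return best


def classify_compartment(
    interval: GenomicInterval, partition: ChromosomePartition
) -> str:
    """Compartment label of the segment containing the interval midpoint."""
    return partition.label_at(interval.chrom, interval.midpoint)


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureConfig:
    """Maps GFF3 feature types and attributes onto the annotation model.

    ``gene_types``/``te_types`` select which GFF3 ``type`` column values
    become genes and TEs.  Flags and labels are read from the attribute keys
    named here; the NLR/focal attributes are truthy when equal to "1",
    "true" or "yes" (case-insensitive).
    """

    gene_types: frozenset = frozenset({"gene"})
    te_types: frozenset = frozenset({"transposable_element"})
    nlr_attribute: str = "is_nlr"
    focal_attribute: str = "is_focal"
    superfamily_attribute: str = "superfamily"
    category_attribute: str = "categories"


_TRUTHY = {"1", "true", "yes"}


def _parse_attributes(text: str, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GFF3ParseError(lineno, f"malformed attribute {part!r}")
        key, _, val = part.partition("=")
        attrs[key.strip()] = val.strip()
    return attrs


def read_gff3(path, feature_config: FeatureConfig | None = None) -> AnnotationSet:
    """Read an AnnotationSet from GFF3 (1-based inclusive coordinates).

    Unrecognized feature types are ignored.  ``##sequence-region`` directives
    populate ``chrom_lengths``.
    """
    cfg = feature_config or FeatureConfig()
    genes: List[GeneRecord] = []
    tes: List[TERecord] = []
    chrom_lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    try:
                        chrom_lengths[parts[1]] = int(parts[3])
                    except ValueError as exc:
                        raise GFF3ParseError(lineno, str(exc)) from exc
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    lineno, f"expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(lineno, f"non-integer coordinate: {exc}") from exc
            if end1 < start1:
                raise GFF3ParseError(lineno, f"end {end1} < start {start1}")
            attrs = _parse_attributes(attr_s, lineno)
            fid = attrs.get("ID")
            if fid is None:
                raise GFF3ParseError(lineno, "missing ID attribute")
            if strand not in STRANDS:
                strand = "."
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if ftype in cfg.gene_types:
                cats = attrs.get(cfg.category_attribute, "")
                genes.append(
                    GeneRecord(
                        id=fid,
                        interval=iv,
                        is_nlr=attrs.get(cfg.nlr_attribute, "").lower() in _TRUTHY,
                        is_focal=attrs.get(cfg.focal_attribute, "").lower() in _TRUTHY,
                        categories=frozenset(c for c in cats.split(",") if c),
                    )
                )
            elif ftype in cfg.te_types:
                fam = attrs.get(cfg.superfamily_attribute, "other")
                if fam not in SUPERFAMILIES:
                    fam = "other"
                tes.append(TERecord(id=fid, interval=iv, superfamily=fam))
    key = lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.id)
    genes.sort(key=key)
    tes.sort(key=key)
    return AnnotationSet(genes=genes, tes=tes, chrom_lengths=chrom_lengths)


def write_gff3(
    annotation: AnnotationSet, path, feature_config: FeatureConfig | None = None
) -> None:
    """Write genes and TEs as deterministic, sorted GFF3."""
    cfg = feature_config or FeatureConfig()
    gene_type = sorted(cfg.gene_types)[0]
    te_type = sorted(cfg.te_types)[0]
    key = lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.id)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(
                f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}\n"
            )
        for g in sorted(annotation.genes, key=key):
            iv = g.interval
            attrs = [f"ID={g.id}"]
            if g.is_nlr:
                attrs.append(f"{cfg.nlr_attribute}=1")
            if g.is_focal:
                attrs.append(f"{cfg.focal_attribute}=1")
            if g.categories:
                attrs.append(
                    f"{cfg.category_attribute}={','.join(sorted(g.categories))}"
                )
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "k9balance",
                        gene_type,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand != "." else ".",
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
        for t in sorted(annotation.tes, key=key):
            iv = t.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "k9balance",
                        te_type,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand != "." else ".",
                        ".",
                        f"ID={t.id};{cfg.superfamily_attribute}={t.superfamily}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open)
# ---------------------------------------------------------------------------


def write_partition_bed(partition: ChromosomePartition, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(partition.segments):
            for iv, label in partition.segments[chrom]:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def read_partition_bed(path) -> ChromosomePartition:
    segs: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GFF3ParseError(lineno, "partition BED needs 4 columns")
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            segs.setdefault(chrom, []).append((GenomicInterval(chrom, start, end), label))
    for lst in segs.values():
        lst.sort(key=lambda p: p[0].start)
    return ChromosomePartition({c: tuple(v) for c, v in segs.items()})


def write_te_bed(tes: Sequence[TERecord], path) -> None:
    key = lambda t: (t.interval.chrom, t.interval.start, t.interval.end, t.id)
    with open(path, "w") as fh:
        for t in sorted(tes, key=key):
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.id}\t0\t{iv.strand}\t{t.superfamily}\n"
            )


def read_te_bed(path) -> List[TERecord]:
    tes: List[TERecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GFF3ParseError(lineno, "TE BED needs >= 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            fam = parts[6] if len(parts) > 6 and parts[6] in SUPERFAMILIES else "other"
            tes.append(
                TERecord(id=name, interval=GenomicInterval(chrom, start, end, strand), superfamily=fam)
            )
    return tes
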