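"""Proximal polyadenylation analysis on per-base coverage tracks.

Coverage normalization and replicate/background arithmetic, read counting
in the segments between ordered polyA sites, genotype contrasts of segment
usage, and detection of the site where mutant read-through drops.

Segment convention
------------------
PolyA sites are numbered 1..n in transcript order; genomically their 1-based
coordinates ascend on the + strand and descend on the - strand.  The segment
between sites k and k+1 runs from just after site k's base to site k+1's
base inclusive (in transcript direction); the first segment additionally
covers site 1's base.  Segments therefore tile the closed genomic span
between the first and last site, each site base counted exactly once, with
an interior site base belonging to the segment upstream of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .differential import bh_adjust, nb_wald_test

__all__ = [
    "CoverageTrack",
    "PolyASiteSet",
    "coverage_cpm",
    "combine_and_subtract",
    "segment_intervals",
    "segment_counts",
    "differential_segment_usage",
    "detect_drop_site",
    "read_bedgraph",
    "write_bedgraph",
    "read_polya_sites",
    "write_polya_sites",
]


class ApaError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Per-base coverage over one contiguous interval of a chromosome."""

    chrom: str
    start: int                 # 0-based genomic offset of values[0]
    values: np.ndarray
    total_reads: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ApaError("coverage values must be >= 0")
        if self.start < 0:
            raise ApaError("track start must be >= 0")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def slice_bp(self, start: int, end: int) -> np.ndarray:
        """Values over genomic 0-based [start, end); zero outside the track."""
        if end <= start:
            return np.zeros(0)
        out = np.zeros(end - start)
        lo = max(start, self.start)
        hi = min(end, self.end)
        if hi > lo:
            out[lo - start: hi - start] = self.values[lo - self.start: hi - self.start]
        return out


@dataclass
class PolyASiteSet:
    """Ordered polyA sites of one gene (1-based genomic coordinates)."""

    gene_id: str
    chrom: str
    strand: str
    sites: Tuple[int, ...]  # transcript order: ascending (+) / descending (-)

    def __post_init__(self):
        self.sites = tuple(int(s) for s in self.sites)
        if len(self.sites) < 2:
            raise ApaError("need at least 2 polyA sites")
        if self.strand not in "+-":
            raise ApaError("strand must be + or -")
        diffs = np.diff(self.sites)
        if self.strand == "+" and not (diffs > 0).all():
            raise ApaError("+ strand sites must be strictly increasing")
        if self.strand == "-" and not (diffs < 0).all():
            raise ApaError("- strand sites must be strictly decreasing")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def coverage_cpm(track: CoverageTrack) -> CoverageTrack:
    """Scale per-base values to counts-per-million mapped reads."""
    if track.total_reads <= 0:
        raise ApaError("total mapped reads must be > 0")
    return CoverageTrack(
        chrom=track.chrom,
        start=track.start,
        values=track.values * 1e6 / track.total_reads,
        total_reads=1e6,
    )


def combine_and_subtract(
    tracks_signal: Sequence[CoverageTrack],
    tracks_background: Sequence[CoverageTrack] = (),
) -> CoverageTrack:
    """Mean of signal replicates minus mean of background, clamped at zero.

    All tracks must already be CPM-normalized and share the same interval.
    """
    if not tracks_signal:
        raise ApaError("need at least one signal track")
    ref = tracks_signal[0]
    for t in list(tracks_signal) + list(tracks_background):
        if (t.chrom, t.start, len(t.values)) != (ref.chrom, ref.start, len(ref.values)):
            raise ApaError("tracks must share chromosome and interval")
    signal = np.mean([t.values for t in tracks_signal], axis=0)
    if tracks_background:
        signal = signal - np.mean([t.values for t in tracks_background], axis=0)
    return CoverageTrack(
        chrom=ref.chrom, start=ref.start, values=np.maximum(signal, 0.0), total_reads=1e6
    )


def segment_intervals(sites: PolyASiteSet) -> List[Tuple[int, int]]:
    """0-based half-open genomic intervals of the transcript-order segments.

    Segment k (k = 1..n-1) lies between sites k and k+1.  Intervals tile the
    closed genomic span of the site list; on the - strand segment 1 occupies
    the highest coordinates.
    """
    s = sites.sites
    out: List[Tuple[int, int]] = []
    if sites.strand == "-":
        # descending coords: seg k = [c_{k+1}-1, c_k-1) plus site-1 base for k=1
        for k in range(len(s) - 1):
            hi = s[k] if k == 0 else s[k] - 1       # 0-based exclusive end
            lo = s[k + 1] - 1                        # 0-based inclusive start
            out.append((lo, hi))
    else:
        # ascending coords: seg k = [c_k, c_{k+1}) plus site-1 base for k=1
        for k in range(len(s) - 1):
            lo = s[k] - 1 if k == 0 else s[k]
            hi = s[k + 1]
            out.append((lo, hi))
    return out


def segment_counts(
    tracks: Dict[str, CoverageTrack], sites: PolyASiteSet
) -> pd.DataFrame:
    """Summed coverage per transcript-order segment per sample.

    Rows are segments ``seg_k_(k+1)``; columns are sample ids.  The sidecar
    columns ``seg_start``/``seg_end`` give each segment's 0-based half-open
    genomic interval.
    """
    ivs = segment_intervals(sites)
    names = [f"seg_{k + 1}_{k + 2}" for k in range(len(ivs))]
    data = {
        sid: [float(tr.slice_bp(lo, hi).sum()) for lo, hi in ivs]
        for sid, tr in tracks.items()
    }
    out = pd.DataFrame(data, index=pd.Index(names, name="segment"))
    out.insert(0, "seg_start", [lo for lo, _ in ivs])
    out.insert(1, "seg_end", [hi for _, hi in ivs])
    return out


def differential_segment_usage(
    seg_counts_wt: pd.DataFrame,
    seg_counts_mut: pd.DataFrame,
) -> pd.DataFrame:
    """Genotype contrast of per-segment counts via the NB Wald test + BH.

    Inputs are segment x sample tables (sample columns only, or the output
    of :func:`segment_counts` whose coordinate columns are ignored); needs
    >= 2 replicates per genotype.
    """
    wt = seg_counts_wt.drop(columns=["seg_start", "seg_end"], errors="ignore")
    mut = seg_counts_mut.drop(columns=["seg_start", "seg_end"], errors="ignore")
    if not wt.index.equals(mut.index):
        raise ApaError("WT and mutant tables must share segments")
    if wt.shape[1] < 2 or mut.shape[1] < 2:
        raise ApaError("need >= 2 replicates per genotype")
    counts = pd.concat([wt, mut], axis=1).round().astype(int)
    samples = pd.DataFrame(
        {
            "genotype": ["WT"] * wt.shape[1] + ["mutant"] * mut.shape[1],
            "assay": "rna",
            "replicate": list(range(1, wt.shape[1] + 1))
            + list(range(1, mut.shape[1] + 1)),
        },
        index=pd.Index(list(wt.columns) + list(mut.columns), name="sample"),
    )
    # segment usage is a within-gene contrast; depth is assumed equalized
    # upstream (CPM tracks), so unit size factors are used
    size_factors = pd.Series(1.0, index=counts.columns)
    res = nb_wald_test(counts, samples, size_factors)
    res["padj"] = bh_adjust(res["p"].to_numpy())
    return res


def detect_drop_site(
    wt_track: CoverageTrack,
    mut_track: CoverageTrack,
    sites: PolyASiteSet,
    ratio_threshold: float = 0.5,
) -> Optional[int]:
    """Smallest transcript-order site index where mutant read-through drops.

    For each candidate site k (2..n-1) the mutant/WT mean-coverage ratio is
    computed over the segment immediately downstream of site k (sites k to
    k+1) and over the segment immediately upstream (sites k-1 to k); site k
    is called when downstream_ratio / upstream_ratio falls below
    ``ratio_threshold``.  Returns None when no site qualifies.  Invariant to
    global rescaling of either track.
    """
    ivs = segment_intervals(sites)
    n = sites.n_sites

    def mean_cov(track, pairs):
        tot, bp = 0.0, 0
        for lo, hi in pairs:
            tot += float(track.slice_bp(lo, hi).sum())
            bp += hi - lo
        return tot / bp if bp else 0.0

    for k in range(2, n):
        up = [ivs[k - 2]]     # segment between sites k-1 and k
        down = [ivs[k - 1]]   # segment between sites k and k+1
        wt_up, wt_down = mean_cov(wt_track, up), mean_cov(wt_track, down)
        if wt_up <= 0 or wt_down <= 0:
            warnings.warn(
                f"site {k}: zero WT coverage in a compared region; skipped"
            )
            continue
        mut_up, mut_down = mean_cov(mut_track, up), mean_cov(mut_track, down)
        if mut_up <= 0:
            warnings.warn(f"site {k}: zero mutant upstream coverage; skipped")
            continue
        ratio = (mut_down / wt_down) / (mut_up / wt_up)
        if ratio < ratio_threshold:
            return k
    return None


# ---------------------------------------------------------------------------
# I/O: bedGraph tracks and polyA-site TSV
# ---------------------------------------------------------------------------


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph (0-based half-open), run-length compressed."""
    v = track.values
    with open(path, "w") as fh:
        fh.write(f"# total_reads={track.total_reads:g}\n")
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[j] == v[i]:
                j += 1
            fh.write(
                f"{track.chrom}\t{track.start + i}\t{track.start + j}\t{v[i]:g}\n"
            )
            i = j


def read_bedgraph(path) -> CoverageTrack:
    chrom = None
    spans: List[Tuple[int, int, float]] = []
    total = 1.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# total_reads="):
                total = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, val = line.split("\t")
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ApaError("multi-chromosome bedGraph not supported")
            spans.append((int(s), int(e), float(val)))
    if not spans:
        raise ApaError("empty bedGraph")
    start = min(s for s, _, _ in spans)
    end = max(e for _, e, _ in spans)
    values = np.zeros(end - start)
    for s, e, v in spans:
        values[s - start: e - start] = v
    return CoverageTrack(chrom=chrom, start=start, values=values, total_reads=total)


def write_polya_sites(sites: PolyASiteSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\tstrand\tsites\n")
        fh.write(
            f"{sites.gene_id}\t{sites.chrom}\t{sites.strand}\t"
            + ",".join(str(s) for s in sites.sites)
            + "\n"
        )


def read_polya_sites(path) -> PolyASiteSet:
    with open(path) as fh:
        header = fh.readline()
        line = fh.readline().strip()
    if not line:
        raise ApaError("polyA site file has no data row")
    gene, chrom, strand, sites = line.split("\t")
    return PolyASiteSet(
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        sites=tuple(int(s) for s in sites.split(",")),
    )
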