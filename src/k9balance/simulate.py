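"""Seeded synthetic-data generators with planted ground truth.

Every generator derives its RNG from an independent substream of one global
seed (annotation / counts / APA), so changing the configuration of one stage
never perturbs another.  Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import (
    AnnotationSet,
    ChromosomePartition,
    GeneRecord,
    GenomicInterval,
    TERecord,
)

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "generate_annotation",
    "generate_count_matrix",
    "generate_apa_dataset",
]

ASSAYS = ("rna", "chip_k9", "chip_h3", "input")

# substream indices for SeedSequence.spawn
_STREAM_ANNOTATION = 0
_STREAM_COUNTS = {"rna": 1, "chip_k9": 2, "chip_h3": 3, "input": 4}
_STREAM_APA = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study; all stages read from this."""

    seed: int = 0
    # genome layout
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    pericentromere_fraction: float = 0.3
    # genes
    n_genes: int = 600
    n_nlr: int = 60
    n_focal_nlr: int = 20
    gene_length_range: Tuple[int, int] = (1_000, 3_000)
    # TEs
    n_te: int = 1_500
    te_length_log_mean: float = 6.0   # log-normal parameters of TE length
    te_length_log_sd: float = 0.8
    te_pericentromere_density_ratio: float = 5.0
    planted_nlr_te_excess_bp: float = 236.0
    # count matrices
    n_samples_per_group: int = 3
    nb_mean_range: Tuple[float, float] = (20.0, 500.0)
    nb_dispersion: float = 0.05
    library_size_range: Tuple[float, float] = (0.7, 1.4)
    planted_up_fraction_rna: float = 0.05
    planted_down_fraction_rna: float = 0.04
    planted_up_fraction_k9: float = 0.05
    planted_down_fraction_k9: float = 0.02
    planted_fold_change: float = 4.0
    # APA stage
    apa_n_sites: int = 8
    apa_site_spacing: int = 60
    apa_gene_end: int = 9_490_000  # genomic coord of site #1 (minus strand)
    apa_wt_depth: float = 50.0
    apa_mut_depth: float = 50.0
    apa_drop_site: int = 6
    apa_drop_factor: float = 0.1
    apa_total_reads: float = 1_000_000.0

    def __post_init__(self):
        if min(self.n_chrom, self.chrom_length, self.n_genes, self.n_te) <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.pericentromere_fraction <= 1.0):
            raise ValueError("pericentromere_fraction must be in [0,1]")
        if self.n_nlr > self.n_genes or self.n_focal_nlr > self.n_nlr:
            raise ValueError("require n_focal_nlr <= n_nlr <= n_genes")
        for frac in (
            self.planted_up_fraction_rna,
            self.planted_down_fraction_rna,
            self.planted_up_fraction_k9,
            self.planted_down_fraction_k9,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("planted fractions must be in [0,1]")
        if not (2 <= self.apa_drop_site <= self.apa_n_sites - 1):
            raise ValueError("apa_drop_site must lie in [2, n_sites-1]")

    def rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(8)
        return np.random.default_rng(children[stream])


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    rna_direction: Dict[str, str] = field(default_factory=dict)   # feature -> up/down/ns
    k9_direction: Dict[str, str] = field(default_factory=dict)
    te_excess_group: Dict[str, str] = field(default_factory=dict)  # gene -> nlr/background
    apa_drop_site: Optional[int] = None
    apa_drop_factor: Optional[float] = None

    def direction_frame(self, assay: str) -> pd.DataFrame:
        src = self.rna_direction if assay == "rna" else self.k9_direction
        return pd.DataFrame(
            {"feature": list(src), "true_call": list(src.values())}
        ).set_index("feature")


# ---------------------------------------------------------------------------
# Annotation generator
# ---------------------------------------------------------------------------


def _make_partition(cfg: SyntheticConfig) -> Tuple[ChromosomePartition, Dict[str, int]]:
    segs = {}
    lengths = {}
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        L = cfg.chrom_length
        lengths[chrom] = L
        peri_len = int(round(L * cfg.pericentromere_fraction))
        peri_start = (L - peri_len) // 2
        parts = []
        if peri_start > 0:
            parts.append((GenomicInterval(chrom, 0, peri_start), "arm"))
        if peri_len > 0:
            parts.append(
                (GenomicInterval(chrom, peri_start, peri_start + peri_len), "pericentromere")
            )
        if peri_start + peri_len < L:
            parts.append((GenomicInterval(chrom, peri_start + peri_len, L), "arm"))
        segs[chrom] = tuple(parts)
    return ChromosomePartition(segs), lengths


def _compartment_spans(
    partition: ChromosomePartition, label: str
) -> List[GenomicInterval]:
    return [
        iv
        for segs in partition.segments.values()
        for iv, lab in segs
        if lab == label
    ]


def _place_in_spans(
    rng: np.random.Generator, spans: List[GenomicInterval], length: int
) -> Optional[GenomicInterval]:
    """Uniformly place an interval of ``length`` inside one of ``spans``."""
    fits = [s for s in spans if s.length >= length]
    if not fits:
        return None
    weights = np.array([s.length - length + 1 for s in fits], dtype=float)
    span = fits[rng.choice(len(fits), p=weights / weights.sum())]
    start = int(rng.integers(span.start, span.end - length + 1))
    return GenomicInterval(span.chrom, start, start + length)


def generate_annotation(cfg: SyntheticConfig) -> Tuple[AnnotationSet, PlantedTruth]:
    """Genes, TEs, and a chromosome partition with planted TE structure.

    TEs land in the pericentromere versus the arms with per-bp density ratio
    ``te_pericentromere_density_ratio``.  Each NLR gene additionally receives
    one dedicated TE insertion inside its span whose length averages
    ``planted_nlr_te_excess_bp``, planted at generation time (not edited in
    afterwards) so density invariants stay valid.
    """
    rng = cfg.rng(_STREAM_ANNOTATION)
    partition, lengths = _make_partition(cfg)
    arms = _compartment_spans(partition, "arm")
    peris = _compartment_spans(partition, "pericentromere")

    # genes in chromosome arms
    genes: List[GeneRecord] = []
    truth = PlantedTruth()
    nlr_idx = set(range(cfg.n_nlr))  # first n_nlr ids are NLRs
    focal_idx = set(range(cfg.n_focal_nlr))
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        glen = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
        iv = _place_in_spans(rng, arms, glen)
        if iv is None:
            raise ValueError("infeasible packing: gene exceeds arm capacity")
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1:0{width}d}"
        is_nlr = i in nlr_idx
        genes.append(
            GeneRecord(
                id=gid,
                interval=GenomicInterval(iv.chrom, iv.start, iv.end, strand),
                is_nlr=is_nlr,
                is_focal=i in focal_idx,
                categories=frozenset({"NLR"} if is_nlr else {"metabolic"}),
            )
        )
        truth.te_excess_group[gid] = "nlr" if is_nlr else "background"

    # background TEs: compartment chosen by per-bp density ratio
    arm_bp = sum(s.length for s in arms)
    peri_bp = sum(s.length for s in peris)
    r = cfg.te_pericentromere_density_ratio
    p_peri = (r * peri_bp) / (r * peri_bp + arm_bp) if peri_bp else 0.0
    tes: List[TERecord] = []
    fam_choices = np.array(["Gypsy", "Copia", "LINE", "DNA", "other"])
    fam_probs = np.array([0.45, 0.2, 0.1, 0.15, 0.1])
    te_width = len(str(cfg.n_te + cfg.n_nlr))
    k = 0
    for _ in range(cfg.n_te):
        tlen = int(np.clip(rng.lognormal(cfg.te_length_log_mean, cfg.te_length_log_sd), 50, 20_000))
        spans = peris if (peri_bp and rng.random() < p_peri) else arms
        iv = _place_in_spans(rng, spans, tlen)
        if iv is None:
            raise ValueError("infeasible packing: TE exceeds compartment capacity")
        k += 1
        tes.append(
            TERecord(
                id=f"te{k:0{te_width}d}",
                interval=iv,
                superfamily=str(rng.choice(fam_choices, p=fam_probs)),
            )
        )

    # planted NLR-proximal TE excess: one insertion inside each NLR gene span,
    # placed by rejection so it avoids existing TE bp (union counting would
    # otherwise erode the planted mean)
    if cfg.planted_nlr_te_excess_bp > 0:
        for g in genes:
            if not g.is_nlr:
                continue
            mean = cfg.planted_nlr_te_excess_bp
            tlen = int(np.clip(rng.normal(mean, 0.1 * mean), 1, g.interval.length))
            occupied = [
                t.interval
                for t in tes
                if t.interval.chrom == g.interval.chrom
                and t.interval.start < g.interval.end
                and g.interval.start < t.interval.end
            ]
            start = None
            for _attempt in range(100):
                cand = int(rng.integers(g.interval.start, g.interval.end - tlen + 1))
                if all(
                    cand + tlen <= iv.start or iv.end <= cand for iv in occupied
                ):
                    start = cand
                    break
            if start is None:  # gene too crowded; accept an overlapping spot
                start = int(rng.integers(g.interval.start, g.interval.end - tlen + 1))
            k += 1
            tes.append(
                TERecord(
                    id=f"te{k:0{te_width}d}",
                    interval=GenomicInterval(g.interval.chrom, start, start + tlen),
                    superfamily=str(rng.choice(fam_choices, p=fam_probs)),
                )
            )

    key = lambda rec: (rec.interval.chrom, rec.interval.start, rec.interval.end, rec.id)
    genes.sort(key=key)
    tes.sort(key=key)
    ann = AnnotationSet(genes=genes, tes=tes, partition=partition, chrom_lengths=lengths)
    return ann, truth


# ---------------------------------------------------------------------------
# Count-matrix generator
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + disp*mu^2)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_count_matrix(
    cfg: SyntheticConfig,
    annotation: AnnotationSet,
    assay: str,
    truth: Optional[PlantedTruth] = None,
):
    """Feature x sample NB counts with planted differential features.

    Returns ``(counts, samples, truth)`` where ``counts`` is a DataFrame
    indexed by feature id with sample-id columns and ``samples`` is the
    sample sheet (sample, genotype, assay, replicate).  Planted up/down
    features get their mutant mean multiplied/divided by the configured fold
    change; the truth table records every feature's direction.
    """
    if assay not in ASSAYS:
        raise ValueError(f"assay must be one of {ASSAYS}")
    rng = cfg.rng(_STREAM_COUNTS[assay])
    features = [g.id for g in annotation.genes] + [t.id for t in annotation.tes]
    n = len(features)

    lo, hi = cfg.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    if assay == "rna":
        up_frac, down_frac = cfg.planted_up_fraction_rna, cfg.planted_down_fraction_rna
    elif assay == "chip_k9":
        up_frac, down_frac = cfg.planted_up_fraction_k9, cfg.planted_down_fraction_k9
    else:
        up_frac = down_frac = 0.0

    direction = np.array(["ns"] * n, dtype=object)
    n_up = int(round(up_frac * n))
    n_down = int(round(down_frac * n))
    if n_up + n_down > 0:
        chosen = rng.choice(n, size=n_up + n_down, replace=False)
        direction[chosen[:n_up]] = "up"
        direction[chosen[n_up:]] = "down"

    fc = cfg.planted_fold_change
    mut_mean = base_mean.copy()
    mut_mean[direction == "up"] *= fc
    mut_mean[direction == "down"] /= fc

    m = cfg.n_samples_per_group
    sample_rows = []
    cols = {}
    for genotype, means in (("WT", base_mean), ("mutant", mut_mean)):
        for rep in range(1, m + 1):
            sid = f"{assay}_{genotype}_rep{rep}"
            lib = rng.uniform(*cfg.library_size_range)
            cols[sid] = _nb_draw(rng, means * lib, cfg.nb_dispersion)
            sample_rows.append(
                {"sample": sid, "genotype": genotype, "assay": assay, "replicate": rep, "true_size_factor": lib}
            )
    counts = pd.DataFrame(cols, index=pd.Index(features, name="feature"))
    samples = pd.DataFrame(sample_rows).set_index("sample")

    if truth is None:
        truth = PlantedTruth()
    target = truth.rna_direction if assay == "rna" else truth.k9_direction
    if assay in ("rna", "chip_k9"):
        for f, d in zip(features, direction):
            target[f] = d
    return counts, samples, truth


# ---------------------------------------------------------------------------
# APA generator
# ---------------------------------------------------------------------------


@dataclass
class ApaDataset:
    """Synthetic minus-strand gene with ordered polyA sites and coverage."""

    gene_id: str
    chrom: str
    strand: str
    sites: Tuple[int, ...]          # 1-based genomic coords, transcript order
    tracks: Dict[str, "np.ndarray"]  # sample id -> per-base coverage
    track_start: int                 # 0-based genomic start of the arrays
    total_reads: Dict[str, float]
    samples: pd.DataFrame


def generate_apa_dataset(cfg: SyntheticConfig) -> Tuple[ApaDataset, PlantedTruth]:
    """Coverage tracks around a minus-strand gene with 8 ordered polyA sites.

    Site #1 sits at the highest genomic coordinate; transcript order runs
    toward lower coordinates.  In the mutant, per-base depth downstream of
    the planted drop site is multiplied by ``apa_drop_factor``; WT
    read-through is maintained.
    """
    rng = cfg.rng(_STREAM_APA)
    n = cfg.apa_n_sites
    spacing = cfg.apa_site_spacing
    sites = tuple(cfg.apa_gene_end - i * spacing for i in range(n))  # descending
    lo = sites[-1] - 1       # 0-based start of track
    hi = sites[0]            # 0-based exclusive end (site #1 base included)
    length = hi - lo
    drop = cfg.apa_drop_site

    # segments tile the closed span from site #n to site #1, so the baseline
    # expected depth is uniform across the whole track
    base = np.ones(length)

    m = cfg.n_samples_per_group
    tracks: Dict[str, np.ndarray] = {}
    totals: Dict[str, float] = {}
    rows = []
    for genotype in ("WT", "mutant"):
        depth = cfg.apa_wt_depth if genotype == "WT" else cfg.apa_mut_depth
        profile = base * depth
        if genotype == "mutant":
            # downstream of site #drop in transcript order = genomic coords < site
            cutoff = sites[drop - 1]  # 1-based coord of drop site
            idx = np.arange(lo, hi)
            profile = profile.copy()
            profile[idx < cutoff - 1] *= cfg.apa_drop_factor
        for rep in range(1, m + 1):
            sid = f"apa_{genotype}_rep{rep}"
            tracks[sid] = rng.poisson(profile).astype(float)
            totals[sid] = float(cfg.apa_total_reads)
            rows.append({"sample": sid, "genotype": genotype, "assay": "rna", "replicate": rep})

    ds = ApaDataset(
        gene_id="geneAPA",
        chrom="chrA",
        strand="-",
        sites=sites,
        tracks=tracks,
        track_start=lo,
        total_reads=totals,
        samples=pd.DataFrame(rows).set_index("sample"),
    )
    truth = PlantedTruth(apa_drop_site=drop, apa_drop_factor=cfg.apa_drop_factor)
    return ds, truth


# ---------------------------------------------------------------------------
# Config file round-trip (flat key=value schema used by the CLI)
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {"gene_length_range", "nb_mean_range", "library_size_range"}


def config_to_text(cfg: SyntheticConfig) -> str:
    lines = []
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if f.name in _TUPLE_FIELDS:
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> SyntheticConfig:
    """Parse the flat key=value config; unknown keys are rejected."""
    fields = {f.name: f for f in dataclasses.fields(SyntheticConfig)}
    kwargs = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
        default = getattr(_DEFAULT_CONFIG, key)
        if key in _TUPLE_FIELDS:
            parts = [p.strip() for p in val.split(",")]
            conv = type(default[0])
            kwargs[key] = tuple(conv(p) for p in parts)
        else:
            kwargs[key] = type(default)(val)
    return SyntheticConfig(**kwargs)


_DEFAULT_CONFIG = SyntheticConfig()
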