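"""Synthetic human/mouse genome-pair fixtures with known conservation truth.

The generator plants block-structured annotations on one or more "human"
chromosomes — gene cassettes (UTR/CDS exons with introns), single-exon
non-coding genes, regulatory features, and TAD domains — then decides, for
every maximal single-category block, whether it aligns to the "mouse" genome
(Bernoulli with the per-category retention probability ``r_c``) and, if
aligned, whether its mouse image keeps the same annotation (probability
``1 - t_c`` with per-category turnover ``t_c``; turnover splits evenly
between feature loss and relabelling to another regulatory category).
Aligned blocks are packed into multi-block chains, a configurable fraction
on the ``-`` query strand.  Variant sites are planted inside chosen
categories, surrounded by records engineered to fail the ClinVar/GWAS
filters.

Because retention and turnover act on whole blocks, the expected fraction
aligned of category ``c`` is exactly ``r_c`` and the expected common
fraction is ``r_c * (1 - t_c)``; the emitted :class:`TruthTable` also
records the realized (post-coin-flip) counts, which the pipeline must
reproduce exactly.

No nucleotide sequence is simulated — the analysis is purely positional.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import AlignmentIndex, Chain, ChainBlock, write_chain
from .annotation import (
    CATEGORIES,
    REGULATORY_CATEGORIES,
    AnnotationConfig,
    CategoryMap,
    GeneModel,
    build_category_map,
    classify_exonic,
    derive_introns,
    derive_tad_boundaries,
    write_gtf,
)
from .intervals import GenomicInterval, IntervalSet

__all__ = ["SimConfig", "TruthTable", "FixtureBundle", "simulate_genome_pair", "write_fixtures"]


#: Default per-category probability that an annotated block has an
#: orthologous mouse segment, mirroring genome-wide human-mouse alignment
#: levels typical of each annotation class (coding exons nearly always
#: align; background sequence rarely does).
DEFAULT_RETENTION: Dict[str, float] = {
    "ExonCDS": 0.955,
    "ExonUTR": 0.676,
    "ExonOther": 0.50,
    "Promoter": 0.594,
    "EnhancerProximal": 0.418,
    "EnhancerDistal": 0.453,
    "CTCF": 0.414,
    "Miscellaneous": 0.392,
    "IntronProximal": 0.773,
    "IntronDistal": 0.296,
    "TADBoundary": 0.324,
    "Unannotated": 0.179,
}

#: Default expected common-annotation fraction r*(1-t) per category; the
#: turnover defaults below are derived from these.  Regulatory features
#: turn over far faster than coding sequence.
_DEFAULT_COMMON: Dict[str, float] = {
    "ExonCDS": 0.882,
    "ExonUTR": 0.408,
    "ExonOther": 0.25,
    "Promoter": 0.385,
    "EnhancerProximal": 0.092,
    "EnhancerDistal": 0.031,
    "CTCF": 0.10,
    "Miscellaneous": 0.026,
    "IntronProximal": 0.560,
    "IntronDistal": 0.15,
    "TADBoundary": 0.048,
    "Unannotated": 0.12,
}

DEFAULT_TURNOVER: Dict[str, float] = {
    c: 1.0 - _DEFAULT_COMMON[c] / DEFAULT_RETENTION[c] for c in CATEGORIES
}

#: Default planted coverage per directly-planted category (fraction of the
#: chromosome).  ExonCDS coverage determines the gene-cassette count, which
#: in turn fixes UTR/intron coverage; everything left over is Unannotated.
DEFAULT_COVERAGE: Dict[str, float] = {
    "ExonCDS": 0.020,
    "ExonOther": 0.010,
    "Promoter": 0.010,
    "EnhancerProximal": 0.010,
    "EnhancerDistal": 0.015,
    "CTCF": 0.008,
    "Miscellaneous": 0.010,
    "TADBoundary": 0.020,
}

#: Variant sites planted per (source, category).  Mendelian sites
#: concentrate in coding and promoter sequence; complex-disease sites sit
#: mostly in distal introns and unannotated background.
DEFAULT_VARIANT_COUNTS: Dict[Tuple[str, str], int] = {
    ("mendelian", "ExonCDS"): 300,
    ("mendelian", "ExonUTR"): 40,
    ("mendelian", "ExonOther"): 10,
    ("mendelian", "Promoter"): 25,
    ("mendelian", "EnhancerProximal"): 10,
    ("mendelian", "EnhancerDistal"): 10,
    ("mendelian", "CTCF"): 5,
    ("mendelian", "Miscellaneous"): 5,
    ("mendelian", "IntronProximal"): 60,
    ("mendelian", "IntronDistal"): 25,
    ("mendelian", "TADBoundary"): 5,
    ("mendelian", "Unannotated"): 5,
    ("complex", "ExonCDS"): 15,
    ("complex", "ExonUTR"): 15,
    ("complex", "ExonOther"): 10,
    ("complex", "Promoter"): 10,
    ("complex", "EnhancerProximal"): 15,
    ("complex", "EnhancerDistal"): 25,
    ("complex", "CTCF"): 10,
    ("complex", "Miscellaneous"): 15,
    ("complex", "IntronProximal"): 10,
    ("complex", "IntronDistal"): 180,
    ("complex", "TADBoundary"): 25,
    ("complex", "Unannotated"): 170,
}

_PASSING_TRAITS = (
    ("type 2 diabetes", "disease"),
    ("breast carcinoma", "cancer"),
    ("atrial fibrillation", "disorder"),
    ("Crohn's disease", "disease"),
)
_FAILING_TRAITS = (
    ("body mass index", "measurement"),
    ("educational attainment", "trait"),
    ("height", "measurement"),
)

_REG_WRITE_TYPES = {
    "Promoter": ("promoter",),
    "EnhancerProximal": ("promoter_flanking_region",),
    "EnhancerDistal": ("enhancer",),
    "CTCF": ("CTCF_binding_site",),
    # both regulatory-build source types that collapse into Miscellaneous
    "Miscellaneous": ("TF_binding_site", "open_chromatin_region"),
}

_PASS_SIG = ("Pathogenic", "Likely_pathogenic")
_PASS_REV = (
    "criteria_provided,_multiple_submitters,_no_conflicts",
    "criteria_provided,_single_submitter",
    "reviewed_by_expert_panel",
)
_FAIL_SIG = ("Benign", "Uncertain_significance", "Likely_benign")
_FAIL_REV = ("no_assertion_criteria_provided", "criteria_provided,_conflicting_interpretations")


@dataclass
class SimConfig:
    """Everything that determines a fixture pair, including the truth."""

    seed: int = 0
    chrom_lengths: Tuple[int, ...] = (300_000, 300_000)
    splice_window: int = 10
    tad_flank: int = 500
    coverage: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    retention: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RETENTION))
    turnover: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TURNOVER))
    variant_counts: Dict[Tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_COUNTS)
    )
    # gene cassette geometry (bp)
    utr_length: int = 120
    cds_exon_length: int = 150
    intron_length: int = 240
    exon_other_length: int = 300
    regulatory_length: int = 400
    tad_interior_length: Optional[int] = None  # default: 4 * tad_flank
    # layout
    gap_min: int = 50
    gap_max: int = 400
    margin: int = 200
    # alignment structure
    mean_blocks_per_chain: float = 4.0
    minus_strand_fraction: float = 0.3
    #: retention/turnover coin flips act on blocks no longer than this;
    #: longer single-category runs are chunked first (mimicking the finite
    #: ungapped-block structure of real chains and keeping the variance of
    #: the realized fractions commensurate with the planted bp)
    max_block_length: int = 2000
    # variant-file noise
    clinvar_fail_fraction: float = 0.4
    gwas_fail_fraction: float = 0.4
    gwas_duplicate_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name, probs in (("retention", self.retention), ("turnover", self.turnover)):
            for c, v in probs.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{c}] = {v} outside [0, 1]")
        if self.intron_length <= 2 * self.splice_window:
            raise ValueError("intron_length must exceed twice the splice window")
        if self.gap_min < 2 * (self.splice_window + 2):
            raise ValueError(
                "gap_min too small to keep mouse intron scaffolds clear of "
                "neighbouring images"
            )

    @property
    def chrom_names(self) -> Tuple[str, ...]:
        return tuple(str(i + 1) for i in range(len(self.chrom_lengths)))

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(
            splice_window=self.splice_window,
            tad_flank=self.tad_flank,
            autosomes=self.chrom_names,
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: sorted(v.items()) if isinstance(v, dict) else v
             for k, v in asdict(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TruthTable:
    """Ground truth for one simulated pair.

    ``expected`` holds the closed-form fractions (aligned = r, common =
    r*(1-t)); ``realized_annotation`` and ``realized_variants`` the exact
    post-coin-flip counts the pipeline must reproduce; ``block_stats`` the
    per-category block-length moments needed to compute the standard error
    of a block-Bernoulli fraction.
    """

    expected: pd.DataFrame
    realized_annotation: pd.DataFrame
    realized_variants: pd.DataFrame
    block_stats: pd.DataFrame


@dataclass
class _BlockFate:
    chrom: str
    start: int
    end: int
    category: str
    aligned: bool
    common: bool = False
    relabel_to: Optional[str] = None
    # mouse image (forward strand), filled during chain allocation
    qry_chrom: Optional[str] = None
    qry_start: Optional[int] = None
    strand: str = "+"


@dataclass
class FixtureBundle:
    """In-memory fixture pair plus its ground truth."""

    config: SimConfig
    chrom_lengths: Dict[str, int]
    mouse_chrom_lengths: Dict[str, int]
    human_genes: List[GeneModel]
    human_regulatory: List[Tuple[str, int, int, str]]
    human_domains: List[GenomicInterval]
    mouse_genes: List[GeneModel]
    mouse_regulatory: List[Tuple[str, int, int, str]]
    mouse_domains: List[GenomicInterval]
    chains: List[Chain]
    blocks: List[ChainBlock]
    clinvar_rows: List[dict]
    gwas_rows: List[dict]
    ontology_map: Dict[str, str]
    truth: TruthTable
    fates: List[_BlockFate]

    def annotation_config(self) -> AnnotationConfig:
        return self.config.annotation_config()

    def _map_from(
        self,
        genes: Sequence[GeneModel],
        regulatory: Sequence[Tuple[str, int, int, str]],
        domains: Sequence[GenomicInterval],
        chrom_lengths: Mapping[str, int],
        species: str,
    ) -> CategoryMap:
        cfg = self.annotation_config()
        fragments = classify_exonic(genes)
        fragments.update(derive_introns(genes, cfg))
        reg: Dict[str, List[GenomicInterval]] = {}
        for chrom, s, e, cat in regulatory:
            reg.setdefault(cat, []).append(GenomicInterval(chrom, s, e))
        for cat, ivs in reg.items():
            fragments[cat] = IntervalSet.from_intervals(ivs)
        fragments["TADBoundary"] = derive_tad_boundaries(domains, cfg, chrom_lengths)
        return build_category_map(
            fragments, chrom_lengths, cfg, species=species, assembly="sim"
        )

    def human_category_map(self) -> CategoryMap:
        return self._map_from(
            self.human_genes, self.human_regulatory, self.human_domains,
            self.chrom_lengths, "human",
        )

    def mouse_category_map(self) -> CategoryMap:
        return self._map_from(
            self.mouse_genes, self.mouse_regulatory, self.mouse_domains,
            self.mouse_chrom_lengths, "mouse",
        )

    def alignment_index(self) -> AlignmentIndex:
        return AlignmentIndex.from_blocks(
            self.blocks,
            ref_sizes=self.chrom_lengths,
            qry_sizes=self.mouse_chrom_lengths,
            resolve_overlaps=False,
        )

    def variant_sites(self) -> pd.DataFrame:
        """Planted passing sites with their truth flags."""
        rows = [
            r for r in self.clinvar_rows if r["passes"]
        ]
        cv = pd.DataFrame(rows) if rows else pd.DataFrame()
        gw = pd.DataFrame([r for r in self.gwas_rows if r["passes"]])
        return pd.concat([cv, gw], ignore_index=True) if len(cv) or len(gw) else pd.DataFrame()


# ----------------------------------------------------------------- planting
def _plan_cassettes(cfg: SimConfig, length: int, rng: np.random.Generator) -> List[str]:
    f = cfg.tad_flank
    interior = cfg.tad_interior_length if cfg.tad_interior_length is not None else 4 * f
    spans = {
        "gene": 2 * cfg.utr_length + 3 * cfg.cds_exon_length + 2 * cfg.intron_length,
        "exon_other": cfg.exon_other_length,
        "tad": 4 * f + interior,
        **{f"reg:{c}": cfg.regulatory_length for c in REGULATORY_CATEGORIES},
    }
    counts = {
        "gene": int(round(cfg.coverage.get("ExonCDS", 0.0) * length / (3 * cfg.cds_exon_length))),
        "exon_other": int(round(cfg.coverage.get("ExonOther", 0.0) * length / cfg.exon_other_length)),
        "tad": int(round(cfg.coverage.get("TADBoundary", 0.0) * length / (4 * f))),
        **{
            f"reg:{c}": int(round(cfg.coverage.get(c, 0.0) * length / cfg.regulatory_length))
            for c in REGULATORY_CATEGORIES
        },
    }
    cassettes = [kind for kind, n in counts.items() for _ in range(n)]
    budget = sum(spans[k] for k in cassettes) + len(cassettes) * cfg.gap_max + 2 * cfg.margin
    if budget > length:
        raise ValueError(
            f"infeasible coverage request: worst-case layout needs {budget} bp "
            f"on a {length} bp chromosome"
        )
    rng.shuffle(cassettes)
    return cassettes


def _plant_chromosome(
    cfg: SimConfig, chrom: str, length: int, rng: np.random.Generator,
    genes: List[GeneModel], regulatory: List[Tuple[str, int, int, str]],
    domains: List[GenomicInterval],
) -> None:
    f = cfg.tad_flank
    interior = cfg.tad_interior_length if cfg.tad_interior_length is not None else 4 * f
    U, C, L = cfg.utr_length, cfg.cds_exon_length, cfg.intron_length
    cursor = cfg.margin
    for kind in _plan_cassettes(cfg, length, rng):
        cursor += int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
        p = cursor
        if kind == "gene":
            gid = f"G{chrom}_{p}"
            exon1 = GenomicInterval(chrom, p, p + U + C)
            cds1 = GenomicInterval(chrom, p + U, p + U + C)
            e2s = p + U + C + L
            exon2 = GenomicInterval(chrom, e2s, e2s + C)
            e3s = e2s + C + L
            exon3 = GenomicInterval(chrom, e3s, e3s + C + U)
            cds3 = GenomicInterval(chrom, e3s, e3s + C)
            genes.append(
                GeneModel(
                    gene_id=gid, transcript_id=f"{gid}.t1", chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype="protein_coding",
                    exons=[exon1, exon2, exon3],
                    cds=[cds1, GenomicInterval(chrom, e2s, e2s + C), cds3],
                )
            )
            cursor = exon3.end
        elif kind == "exon_other":
            gid = f"N{chrom}_{p}"
            genes.append(
                GeneModel(
                    gene_id=gid, transcript_id=f"{gid}.t1", chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype="lncRNA",
                    exons=[GenomicInterval(chrom, p, p + cfg.exon_other_length)],
                )
            )
            cursor = p + cfg.exon_other_length
        elif kind == "tad":
            # reserved: [p, p+2f) left boundary | interior | right boundary
            domains.append(GenomicInterval(chrom, p + f, p + 3 * f + interior))
            cursor = p + 4 * f + interior
        elif kind.startswith("reg:"):
            cat = kind.split(":", 1)[1]
            regulatory.append((chrom, p, p + cfg.regulatory_length, cat))
            cursor = p + cfg.regulatory_length
        else:  # pragma: no cover
            raise AssertionError(kind)
    if cursor > length - cfg.margin:
        raise ValueError(f"layout overflow on chromosome {chrom}")


# -------------------------------------------------------------- block fates
def _assign_fates(
    human_map: CategoryMap, cfg: SimConfig, rng: np.random.Generator
) -> List[_BlockFate]:
    fates: List[_BlockFate] = []
    reg_cats = list(REGULATORY_CATEGORIES)
    for chrom in sorted(human_map.chrom_lengths):
        blocks: List[Tuple[int, int, str]] = []
        for cat in CATEGORIES:
            for s, e in human_map[cat].array(chrom):
                s, e = int(s), int(e)
                # chunk long runs; TAD boundaries stay whole so their mouse
                # realization remains a single domain edge
                if cat != "TADBoundary" and e - s > cfg.max_block_length:
                    n_chunks = -(-(e - s) // cfg.max_block_length)
                    edges = np.linspace(s, e, n_chunks + 1).astype(np.int64)
                    blocks.extend(
                        (int(a), int(b2), cat) for a, b2 in zip(edges[:-1], edges[1:])
                    )
                else:
                    blocks.append((s, e, cat))
        blocks.sort()
        covered = sum(e - s for s, e, _ in blocks)
        if covered != human_map.chrom_lengths[chrom]:
            raise AssertionError(
                "simulated categories overlap; block-level truth undefined"
            )
        for s, e, cat in blocks:
            fate = _BlockFate(chrom, s, e, cat, aligned=bool(rng.random() < cfg.retention[cat]))
            if fate.aligned:
                if rng.random() < cfg.turnover[cat]:
                    # turnover: half feature loss, half relabelling; the
                    # background category can only be "lost" by covering its
                    # image with something else, so it always relabels
                    if cat == "Unannotated" or rng.random() < 0.5:
                        choices = [c for c in reg_cats if c != cat]
                        fate.relabel_to = choices[int(rng.integers(len(choices)))]
                else:
                    fate.common = True
            fates.append(fate)
    return fates


# ------------------------------------------------------- chains & mouse side
def _allocate_mouse(
    fates: List[_BlockFate], cfg: SimConfig, rng: np.random.Generator
) -> Tuple[List[Chain], List[ChainBlock], Dict[str, int], Dict[str, int]]:
    """Group aligned blocks into chains and give them mouse coordinates.

    One mouse chromosome mirrors each human chromosome.  Within a ``+``
    chain mouse position increases with human position; within a ``-``
    chain it decreases (allocated by walking the chain's blocks in reverse).
    Returns chains, flat blocks, mouse cursors (per chromosome, end of the
    image zone) and chain-id bookkeeping via sequential ids.
    """
    chains: List[Chain] = []
    flat: List[ChainBlock] = []
    cursors: Dict[str, int] = {}
    chain_id = 0
    by_chrom: Dict[str, List[_BlockFate]] = {}
    for fate in fates:
        if fate.aligned:
            by_chrom.setdefault(fate.chrom, []).append(fate)
    p_new = 1.0 / max(cfg.mean_blocks_per_chain, 1.0)
    for chrom in sorted(by_chrom):
        aligned = sorted(by_chrom[chrom], key=lambda b: b.start)
        cursor = cfg.margin
        groups: List[List[_BlockFate]] = []
        for b in aligned:
            if not groups or rng.random() < p_new:
                groups.append([b])
            else:
                groups[-1].append(b)
        strands = ["-" if rng.random() < cfg.minus_strand_fraction else "+" for _ in groups]
        for group, strand in zip(groups, strands):
            chain_id += 1
            cursor += int(rng.integers(100, 301))
            order = group if strand == "+" else list(reversed(group))
            hi = max(cfg.gap_min + 100, 151)
            for b in order:
                cursor += int(rng.integers(cfg.gap_min, hi)) if b is not order[0] else 0
                b.qry_chrom = chrom
                b.qry_start = cursor
                b.strand = strand
                cursor += b.end - b.start
            size = sum(b.end - b.start for b in group)
            chains.append(
                Chain(
                    score=float(100 * size),
                    ref_chrom=chrom,
                    ref_size=0,  # filled by caller
                    qry_chrom=chrom,
                    qry_size=0,
                    qry_strand=strand,
                    chain_id=chain_id,
                    blocks=[(b.start, b.qry_start, b.end - b.start) for b in group],
                )
            )
            for b in group:
                flat.append(
                    ChainBlock(
                        ref_chrom=chrom, ref_start=b.start, ref_end=b.end,
                        qry_chrom=chrom, qry_start=b.qry_start, qry_strand=strand,
                        chain_id=chain_id, score=float(100 * size),
                    )
                )
        cursors[chrom] = cursor
    return chains, flat, cursors, {}


def _build_mouse_side(
    fates: List[_BlockFate], cursors: Dict[str, int], cfg: SimConfig,
    chrom_names: Sequence[str],
) -> Tuple[List[GeneModel], List[Tuple[str, int, int, str]], List[GenomicInterval], Dict[str, int]]:
    """Plant mouse features at the images of retained/relabelled blocks.

    Exonic and intronic images are realized with minimal scaffold
    transcripts (1 bp anchor exons around intron images); TAD boundary
    images become the left boundary of a mouse domain whose right edge sits
    in a scratch zone past all images.
    """
    w = cfg.splice_window
    f = cfg.tad_flank
    genes: List[GeneModel] = []
    regulatory: List[Tuple[str, int, int, str]] = []
    domains: List[GenomicInterval] = []
    scratch = {c: cursors.get(c, cfg.margin) + 4 * f + 100 for c in chrom_names}

    for fate in fates:
        if not fate.aligned or (not fate.common and fate.relabel_to is None):
            continue
        chrom = fate.qry_chrom
        s = fate.qry_start
        e = s + (fate.end - fate.start)
        if fate.relabel_to is not None:
            regulatory.append((chrom, s, e, fate.relabel_to))
            continue
        cat = fate.category
        if cat in REGULATORY_CATEGORIES:
            regulatory.append((chrom, s, e, cat))
        elif cat == "ExonCDS":
            gid = f"MC{chrom}_{s}"
            iv = GenomicInterval(chrom, s, e)
            genes.append(GeneModel(gid, f"{gid}.t1", chrom, "+", "protein_coding", [iv], [iv]))
        elif cat == "ExonUTR":
            gid = f"MU{chrom}_{s}"
            iv = GenomicInterval(chrom, s, e)
            genes.append(GeneModel(gid, f"{gid}.t1", chrom, "+", "protein_coding", [iv], []))
        elif cat == "ExonOther":
            gid = f"MO{chrom}_{s}"
            iv = GenomicInterval(chrom, s, e)
            genes.append(GeneModel(gid, f"{gid}.t1", chrom, "+", "lncRNA", [iv]))
        elif cat == "IntronProximal":
            if e - s > 2 * w:
                raise AssertionError("proximal image longer than twice the window")
            gid = f"MIP{chrom}_{s}"
            genes.append(
                GeneModel(gid, f"{gid}.t1", chrom, "+", "lncRNA",
                          [GenomicInterval(chrom, s - 1, s), GenomicInterval(chrom, e, e + 1)])
            )
        elif cat == "IntronDistal":
            gid = f"MID{chrom}_{s}"
            genes.append(
                GeneModel(
                    gid, f"{gid}.t1", chrom, "+", "lncRNA",
                    [GenomicInterval(chrom, s - w - 1, s - w),
                     GenomicInterval(chrom, e + w, e + w + 1)],
                )
            )
        elif cat == "TADBoundary":
            if e - s != 2 * f:
                raise AssertionError("boundary image is not 2*flank wide")
            right_edge = scratch[chrom] + f
            scratch[chrom] = right_edge + f + 50
            domains.append(GenomicInterval(chrom, s + f, right_edge))
        elif cat == "Unannotated":
            pass  # residual: an uncovered image is Unannotated by definition
        else:  # pragma: no cover
            raise AssertionError(cat)

    mouse_lengths = {c: scratch[c] + f + cfg.margin for c in chrom_names}
    return genes, regulatory, domains, mouse_lengths


# ------------------------------------------------------------------ variants
def _plant_variants(
    fates: List[_BlockFate], cfg: SimConfig, rng: np.random.Generator,
) -> Tuple[List[dict], List[dict], Dict[str, str]]:
    by_cat: Dict[str, List[_BlockFate]] = {}
    for fate in fates:
        by_cat.setdefault(fate.category, []).append(fate)

    def sample_sites(cat: str, n: int) -> List[Tuple[str, int, _BlockFate]]:
        blocks = by_cat.get(cat, [])
        lengths = np.array([b.end - b.start for b in blocks], dtype=np.int64)
        total = int(lengths.sum())
        if total < n:
            raise ValueError(
                f"cannot plant {n} {cat} sites: only {total} bp planted"
            )
        offsets = rng.choice(total, size=n, replace=False)
        cum = np.cumsum(lengths)
        out = []
        for off in sorted(int(o) for o in offsets):
            i = int(np.searchsorted(cum, off, side="right"))
            b = blocks[i]
            pos = b.start + off - (int(cum[i]) - (b.end - b.start))
            out.append((b.chrom, pos, b))
        return out

    bases = "ACGT"
    clinvar: List[dict] = []
    gwas: List[dict] = []
    for (source, cat), n in sorted(cfg.variant_counts.items()):
        if n <= 0:
            continue
        for chrom, pos, b in sample_sites(cat, n):
            ref = bases[int(rng.integers(4))]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
            row = {
                "chrom": chrom, "pos": pos, "source": source, "category": cat,
                "aligned": b.aligned, "common": b.aligned and b.common,
                "passes": True, "ref": ref, "alt": alt,
            }
            if source == "mendelian":
                row["significance"] = _PASS_SIG[int(rng.integers(len(_PASS_SIG)))]
                row["review"] = _PASS_REV[int(rng.integers(len(_PASS_REV)))]
                clinvar.append(row)
            else:
                trait, ocls = _PASSING_TRAITS[int(rng.integers(len(_PASSING_TRAITS)))]
                row["trait"], row["ontology_class"] = trait, ocls
                row["p_value"] = float(10.0 ** -(9 + 20 * rng.random()))
                gwas.append(row)
                if rng.random() < cfg.gwas_duplicate_fraction:
                    # same site reported for a second qualifying trait
                    t2, c2 = _PASSING_TRAITS[int(rng.integers(len(_PASSING_TRAITS)))]
                    dup = dict(row)
                    dup["trait"], dup["ontology_class"] = t2, c2
                    dup["passes"] = False  # duplicate, not a new site
                    dup["duplicate_of_passing"] = True
                    gwas.append(dup)

    # failing records: engineered to be dropped by each filter clause
    n_cv_pass = len(clinvar)
    n_cv_fail = int(round(cfg.clinvar_fail_fraction * n_cv_pass))
    chroms = sorted({f.chrom for f in fates})
    max_pos = {c: max(f.end for f in fates if f.chrom == c) for c in chroms}
    for i in range(n_cv_fail):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, max_pos[chrom]))
        mode = i % 3
        ref = bases[int(rng.integers(4))]
        row = {
            "chrom": chrom, "pos": pos, "source": "mendelian", "category": None,
            "aligned": None, "common": None, "passes": False,
            "ref": ref, "alt": bases[(bases.index(ref) + 1) % 4],
        }
        if mode == 0:  # fails significance
            row["significance"] = _FAIL_SIG[int(rng.integers(len(_FAIL_SIG)))]
            row["review"] = _PASS_REV[0]
        elif mode == 1:  # fails review status
            row["significance"] = _PASS_SIG[0]
            row["review"] = _FAIL_REV[int(rng.integers(len(_FAIL_REV)))]
        else:  # not an SNV
            row["ref"] = ref + "T"
            row["significance"] = _PASS_SIG[0]
            row["review"] = _PASS_REV[0]
        clinvar.append(row)

    n_gw_pass = sum(1 for r in gwas if r["passes"])
    n_gw_fail = int(round(cfg.gwas_fail_fraction * n_gw_pass))
    for i in range(n_gw_fail):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, max_pos[chrom]))
        mode = i % 3
        row = {
            "chrom": chrom, "pos": pos, "source": "complex", "category": None,
            "aligned": None, "common": None, "passes": False,
        }
        if mode == 0:  # wrong ontology class, excellent p-value
            trait, ocls = _FAILING_TRAITS[int(rng.integers(len(_FAILING_TRAITS)))]
            row["trait"], row["ontology_class"] = trait, ocls
            row["p_value"] = 1e-20
        elif mode == 1:  # right class, sub-threshold p-value
            trait, ocls = _PASSING_TRAITS[int(rng.integers(len(_PASSING_TRAITS)))]
            row["trait"], row["ontology_class"] = trait, ocls
            row["p_value"] = float(10.0 ** -(2 + 5 * rng.random()))
        else:  # unparseable p-value
            trait, ocls = _PASSING_TRAITS[int(rng.integers(len(_PASSING_TRAITS)))]
            row["trait"], row["ontology_class"] = trait, ocls
            row["p_value"] = None
        gwas.append(row)

    ontology_map = {t: c for t, c in (*_PASSING_TRAITS, *_FAILING_TRAITS)}
    return clinvar, gwas, ontology_map


# --------------------------------------------------------------------- truth
def _build_truth(cfg: SimConfig, fates: List[_BlockFate],
                 clinvar: List[dict], gwas: List[dict]) -> TruthTable:
    expected = pd.DataFrame(
        [
            {
                "category": c,
                "retention": cfg.retention[c],
                "turnover": cfg.turnover[c],
                "expected_aligned": cfg.retention[c],
                "expected_common": cfg.retention[c] * (1 - cfg.turnover[c]),
            }
            for c in CATEGORIES
        ]
    )
    rows = []
    stats_rows = []
    for cat in CATEGORIES:
        sub = [f for f in fates if f.category == cat]
        lens = np.array([f.end - f.start for f in sub], dtype=np.int64)
        denom = int(lens.sum())
        n_aligned = int(sum(le for f, le in zip(sub, lens) if f.aligned))
        n_common = int(sum(le for f, le in zip(sub, lens) if f.aligned and f.common))
        rows.append(
            {
                "category": cat, "denominator": denom,
                "n_aligned": n_aligned, "n_common": n_common,
                "fraction_aligned": n_aligned / denom if denom else float("nan"),
                "fraction_common": n_common / denom if denom else float("nan"),
            }
        )
        stats_rows.append(
            {
                "category": cat, "n_blocks": len(sub),
                "total_bp": denom, "sum_sq_bp": int((lens.astype(np.float64) ** 2).sum()),
            }
        )
    vrows = []
    planted = [r for r in clinvar + gwas if r["passes"]]
    for source in ("mendelian", "complex"):
        for cat in CATEGORIES:
            sub = [r for r in planted if r["source"] == source and r["category"] == cat]
            vrows.append(
                {
                    "source": source, "category": cat, "n_sites": len(sub),
                    "n_aligned": sum(1 for r in sub if r["aligned"]),
                    "n_common": sum(1 for r in sub if r["common"]),
                }
            )
    return TruthTable(
        expected=expected,
        realized_annotation=pd.DataFrame(rows),
        realized_variants=pd.DataFrame(vrows),
        block_stats=pd.DataFrame(stats_rows),
    )


# ----------------------------------------------------------------- top level
def simulate_genome_pair(config: SimConfig) -> FixtureBundle:
    """Generate one human/mouse fixture pair, deterministically per seed."""
    rng = np.random.default_rng(config.seed)
    chrom_lengths = dict(zip(config.chrom_names, config.chrom_lengths))

    genes: List[GeneModel] = []
    regulatory: List[Tuple[str, int, int, str]] = []
    domains: List[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        _plant_chromosome(config, chrom, length, rng, genes, regulatory, domains)

    cfg_ann = config.annotation_config()
    fragments = classify_exonic(genes)
    fragments.update(derive_introns(genes, cfg_ann))
    reg_frag: Dict[str, List[GenomicInterval]] = {}
    for chrom, s, e, cat in regulatory:
        reg_frag.setdefault(cat, []).append(GenomicInterval(chrom, s, e))
    for cat, ivs in reg_frag.items():
        fragments[cat] = IntervalSet.from_intervals(ivs)
    fragments["TADBoundary"] = derive_tad_boundaries(domains, cfg_ann, chrom_lengths)
    human_map = build_category_map(fragments, chrom_lengths, cfg_ann, species="human", assembly="sim")

    fates = _assign_fates(human_map, config, rng)
    chains, blocks, cursors, _ = _allocate_mouse(fates, config, rng)
    mouse_genes, mouse_reg, mouse_domains, mouse_lengths = _build_mouse_side(
        fates, cursors, config, config.chrom_names
    )
    for ch in chains:
        ch.ref_size = chrom_lengths[ch.ref_chrom]
        ch.qry_size = mouse_lengths[ch.qry_chrom]

    clinvar, gwas, ontology_map = _plant_variants(fates, config, rng)
    truth = _build_truth(config, fates, clinvar, gwas)

    return FixtureBundle(
        config=config,
        chrom_lengths=chrom_lengths,
        mouse_chrom_lengths=mouse_lengths,
        human_genes=genes,
        human_regulatory=regulatory,
        human_domains=domains,
        mouse_genes=mouse_genes,
        mouse_regulatory=mouse_reg,
        mouse_domains=mouse_domains,
        chains=chains,
        blocks=blocks,
        clinvar_rows=clinvar,
        gwas_rows=gwas,
        ontology_map=ontology_map,
        truth=truth,
        fates=fates,
    )


# --------------------------------------------------------------------- files
def _write_regulatory_gff(rows: Sequence[Tuple[str, int, int, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        counters: Dict[str, int] = {}
        for chrom, s, e, cat in sorted(rows):
            types = _REG_WRITE_TYPES[cat]
            i = counters.get(cat, 0)
            counters[cat] = i + 1
            ftype = types[i % len(types)]
            fh.write(
                f"{chrom}\tsim_regulatory_build\t{ftype}\t{s + 1}\t{e}\t.\t.\t.\t"
                f"ID={ftype}:{chrom}:{s}\n"
            )


def _write_clinvar_vcf(rows: Sequence[dict], chrom_lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write('##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">\n')
        fh.write('##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="ClinVar review status">\n')
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(sorted(rows, key=lambda r: (r["chrom"], r["pos"]))):
            fh.write(
                f"{r['chrom']}\t{r['pos'] + 1}\tsim{i}\t{r['ref']}\t{r['alt']}\t.\t.\t"
                f"CLNSIG={r['significance']};CLNREVSTAT={r['review']}\n"
            )


_GWAS_HEADER = ["CHR_ID", "CHR_POS", "SNPS", "DISEASE/TRAIT", "MAPPED_TRAIT", "P-VALUE"]


def _write_gwas_tsv(rows: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GWAS_HEADER) + "\n")
        for i, r in enumerate(sorted(rows, key=lambda r: (r["chrom"], r["pos"]))):
            p = "NR" if r["p_value"] is None else f"{r['p_value']:.2E}"
            fh.write(
                f"{r['chrom']}\t{r['pos'] + 1}\trs{900000 + i}\t{r['trait']}\t{r['trait']}\t{p}\n"
            )


def write_fixtures(bundle: FixtureBundle, directory, overwrite: bool = False) -> dict:
    """Serialize a bundle into standard-format files plus a manifest.

    Re-running with the same seed and config reproduces byte-identical
    files.  Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    paths = {name: directory / name for name in (
        "human.gtf", "mouse.gtf", "human_regulatory.gff", "mouse_regulatory.gff",
        "human_tads.bed", "mouse_tads.bed", "human_mouse.chain",
        "human.chrom.sizes", "mouse.chrom.sizes",
        "clinvar.vcf", "gwas_associations.tsv", "trait_ontology.tsv",
        "truth_expected.tsv", "truth_annotation.tsv", "truth_variants.tsv",
        "truth_block_stats.tsv",
    )}
    write_gtf(bundle.human_genes, paths["human.gtf"])
    write_gtf(bundle.mouse_genes, paths["mouse.gtf"])
    _write_regulatory_gff(bundle.human_regulatory, paths["human_regulatory.gff"])
    _write_regulatory_gff(bundle.mouse_regulatory, paths["mouse_regulatory.gff"])
    for key, doms in (("human_tads.bed", bundle.human_domains), ("mouse_tads.bed", bundle.mouse_domains)):
        with open(paths[key], "w") as fh:
            for d in sorted(doms, key=lambda d: (d.chrom, d.start)):
                fh.write(f"{d.chrom}\t{d.start}\t{d.end}\n")
    write_chain(bundle.chains, paths["human_mouse.chain"])
    for key, lengths in (
        ("human.chrom.sizes", bundle.chrom_lengths),
        ("mouse.chrom.sizes", bundle.mouse_chrom_lengths),
    ):
        with open(paths[key], "w") as fh:
            for c in sorted(lengths):
                fh.write(f"{c}\t{lengths[c]}\n")
    _write_clinvar_vcf(bundle.clinvar_rows, bundle.chrom_lengths, paths["clinvar.vcf"])
    _write_gwas_tsv(bundle.gwas_rows, paths["gwas_associations.tsv"])
    with open(paths["trait_ontology.tsv"], "w") as fh:
        fh.write("trait\tontology_class\n")
        for t in sorted(bundle.ontology_map):
            fh.write(f"{t}\t{bundle.ontology_map[t]}\n")
    bundle.truth.expected.to_csv(paths["truth_expected.tsv"], sep="\t", index=False)
    bundle.truth.realized_annotation.to_csv(paths["truth_annotation.tsv"], sep="\t", index=False)
    bundle.truth.realized_variants.to_csv(paths["truth_variants.tsv"], sep="\t", index=False)
    bundle.truth.block_stats.to_csv(paths["truth_block_stats.tsv"], sep="\t", index=False)

    manifest = {
        "seed": bundle.config.seed,
        "config_hash": bundle.config.config_hash(),
        "sim_config": {
            "splice_window": bundle.config.splice_window,
            "tad_flank": bundle.config.tad_flank,
            "chrom_names": list(bundle.config.chrom_names),
        },
        "n_chain_blocks": len(bundle.blocks),
        "n_transcripts_human": len(bundle.human_genes),
        "files": {
            name: {
                "path": str(p),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for name, p in sorted(paths.items())
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
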