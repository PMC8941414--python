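"""Base-level annotation of a genome into twelve categories.

The map combines three sources:

* gene models (GTF/GFF3, GENCODE dialect) — exon-CDS, exon-UTR, exon-other,
  plus introns split into proximal (within ``splice_window`` bp of a splice
  site, default 10) and distal bases;
* a regulatory build GFF — promoter, proximal/distal enhancer, CTCF binding
  site, and miscellaneous (unannotated TF-binding or open-chromatin);
* TAD domain calls — boundaries defined as ±``tad_flank`` bp (default 25 kb)
  around each domain edge.

Categories are allowed to overlap (a promoter can sit inside an intron); the
two residual categories are the exception: intron-distal keeps only bases
carrying no other annotation, and everything still unlabelled is
"Unannotated".  The union of all twelve categories therefore covers every
base of the configured autosomes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, normalize_chrom, write_bed

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "RESIDUAL_CATEGORIES",
    "REGULATORY_CATEGORIES",
    "EXONIC_CATEGORIES",
    "DEFAULT_REGULATORY_TYPE_MAP",
    "AnnotationConfig",
    "GeneModel",
    "CategoryMap",
    "read_chrom_lengths",
    "read_gene_models",
    "classify_exonic",
    "derive_introns",
    "read_regulatory_build",
    "read_tad_domains",
    "derive_tad_boundaries",
    "build_category_map",
    "coverage_summary",
    "overlap_matrix",
    "write_gtf",
]

#: The closed set of annotation categories, in display order.
CATEGORIES: Tuple[str, ...] = (
    "ExonCDS",
    "ExonUTR",
    "ExonOther",
    "Promoter",
    "EnhancerProximal",
    "EnhancerDistal",
    "CTCF",
    "Miscellaneous",
    "IntronProximal",
    "IntronDistal",
    "TADBoundary",
    "Unannotated",
)

#: Categories defined as "whatever is left": they never overlap any other.
RESIDUAL_CATEGORIES = frozenset({"IntronDistal", "Unannotated"})

REGULATORY_CATEGORIES: Tuple[str, ...] = (
    "Promoter",
    "EnhancerProximal",
    "EnhancerDistal",
    "CTCF",
    "Miscellaneous",
)

EXONIC_CATEGORIES: Tuple[str, ...] = ("ExonCDS", "ExonUTR", "ExonOther")

#: Ensembl Regulatory Build feature types -> category labels.  Promoter
#: flanking regions act as promoter-proximal enhancers; the standalone
#: "enhancer" type is the distal class.  Unannotated TF-binding sites and
#: open chromatin both collapse into Miscellaneous.
DEFAULT_REGULATORY_TYPE_MAP: Dict[str, str] = {
    "promoter": "Promoter",
    "promoter_flanking_region": "EnhancerProximal",
    "enhancer_proximal": "EnhancerProximal",
    "enhancer": "EnhancerDistal",
    "enhancer_distal": "EnhancerDistal",
    "ctcf_binding_site": "CTCF",
    "tf_binding_site": "Miscellaneous",
    "open_chromatin_region": "Miscellaneous",
}


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable distances and chromosome selection for the category map.

    ``splice_window`` is the number of intronic bases on each side of an
    exon-intron junction classed as intron-proximal; ``tad_flank`` is the
    half-width of a TAD boundary around each domain edge.  ``autosomes``
    restricts every reader to the named chromosomes; ``None`` keeps any
    chromosome whose normalized name is purely numeric.
    """

    splice_window: int = 10
    tad_flank: int = 25_000
    autosomes: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.splice_window < 0:
            raise ValueError("splice_window must be >= 0")
        if self.tad_flank < 0:
            raise ValueError("tad_flank must be >= 0")

    def keeps_chrom(self, chrom: str) -> bool:
        chrom = normalize_chrom(chrom)
        if self.autosomes is None:
            return chrom.isdigit()
        return chrom in self.autosomes


@dataclass
class GeneModel:
    """One transcript: its exons, CDS pieces and biotype."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    biotype: str
    exons: List[GenomicInterval] = field(default_factory=list)
    cds: List[GenomicInterval] = field(default_factory=list)

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"

    def sorted_exons(self) -> List[GenomicInterval]:
        return sorted(self.exons, key=lambda iv: iv.start)


@dataclass
class CategoryMap:
    """Per-category interval sets for one species' autosomes."""

    species: str
    assembly: str
    chrom_lengths: Dict[str, int]
    maps: Dict[str, IntervalSet]

    def __getitem__(self, category: str) -> IntervalSet:
        if category not in CATEGORIES:
            raise KeyError(f"unknown category {category!r}")
        return self.maps.get(category, IntervalSet.empty())

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def categories_at(self, chrom: str, pos: int) -> List[str]:
        """All categories covering one base, in canonical order."""
        return [c for c in CATEGORIES if self[c].contains(chrom, pos)]

    def validate(self) -> None:
        """Check the structural invariants of a finished map."""
        genome = IntervalSet.whole_genome(self.chrom_lengths)
        union = IntervalSet.union_all(self[c] for c in CATEGORIES)
        if (union & genome).total_length != genome.total_length or (union - genome):
            raise AssertionError("categories do not exactly cover the autosomes")
        for resid in RESIDUAL_CATEGORIES:
            others = IntervalSet.union_all(
                self[c] for c in CATEGORIES if c != resid
            )
            if (self[resid] & others).total_length != 0:
                raise AssertionError(f"residual category {resid} overlaps another")

    def write_beds(self, directory) -> Dict[str, str]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cat in CATEGORIES:
            p = directory / f"{cat}.bed"
            write_bed(self[cat], p, name=cat)
            paths[cat] = str(p)
        return paths


# --------------------------------------------------------------------- input
def read_chrom_lengths(path, config: AnnotationConfig | None = None) -> Dict[str, int]:
    """Read a two-column (chromosome, length) TSV."""
    config = config or AnnotationConfig()
    out: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            chrom = normalize_chrom(fields[0])
            if config.keeps_chrom(chrom):
                out[chrom] = int(fields[1])
    return out


def _validate_gtf_lines(path) -> None:
    """Cheap pre-scan so malformed rows fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF/GFF columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}:{lineno}: invalid 1-based span {start}-{end}"
                )


_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type")


def read_gene_models(path, config: AnnotationConfig | None = None) -> List[GeneModel]:
    """Load transcripts with exon and CDS intervals from a GTF/GFF3 file.

    Coordinates are converted from the file's 1-based inclusive convention
    to 0-based half-open.  Non-autosomal records are dropped.  A transcript
    whose CDS extends outside its exons is rejected with a warning.
    """
    import gffutils

    config = config or AnnotationConfig()
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: Dict[str, GeneModel] = {}
    for feat in db.features_of_type(("exon", "CDS")):
        chrom = normalize_chrom(feat.seqid)
        if not config.keeps_chrom(chrom):
            continue
        attrs = feat.attributes
        tids = attrs.get("transcript_id")
        if not tids:
            raise ValueError(
                f"{path}: {feat.featuretype} record at {feat.seqid}:{feat.start} "
                "lacks a transcript_id attribute"
            )
        tid = tids[0]
        if tid not in models:
            biotype = "unknown"
            for key in _BIOTYPE_KEYS:
                if attrs.get(key):
                    biotype = attrs[key][0]
                    break
            gid = (attrs.get("gene_id") or [tid])[0]
            models[tid] = GeneModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=chrom,
                strand=feat.strand if feat.strand in "+-" else "+",
                biotype=biotype,
            )
        iv = GenomicInterval(chrom, feat.start - 1, feat.end)  # 1-based -> half-open
        if feat.featuretype == "exon":
            models[tid].exons.append(iv)
        else:
            models[tid].cds.append(iv)

    out: List[GeneModel] = []
    for tid, model in models.items():
        if not model.exons:
            # CDS without exons cannot be validated against the transcript
            if model.cds:
                logger.warning("transcript %s has CDS but no exons; rejected", tid)
            continue
        exon_set = IntervalSet.from_intervals(model.exons)
        model.exons = sorted(exon_set.intervals(), key=lambda iv: iv.start)
        if model.cds:
            cds_set = IntervalSet.from_intervals(model.cds)
            if (cds_set - exon_set).total_length != 0:
                logger.warning(
                    "transcript %s has CDS outside its exons; rejected", tid
                )
                continue
            model.cds = sorted(cds_set.intervals(), key=lambda iv: iv.start)
        out.append(model)
    return out


# ------------------------------------------------------------ derivations
def classify_exonic(models: Sequence[GeneModel]) -> Dict[str, IntervalSet]:
    """Split exonic bases into CDS, UTR and non-coding-exon sets.

    ExonCDS is the union of all CDS intervals.  ExonUTR is the per-transcript
    difference exon minus CDS, restricted to protein-coding transcripts,
    unioned across transcripts — so a base translated in one isoform and
    untranslated in another belongs to both sets.  ExonOther collects the
    exons of non-protein-coding transcripts.
    """
    cds_all: List[GenomicInterval] = []
    utr_sets: List[IntervalSet] = []
    other: List[GenomicInterval] = []
    for m in models:
        if m.is_protein_coding:
            cds_all.extend(m.cds)
            exon_set = IntervalSet.from_intervals(m.exons)
            cds_set = IntervalSet.from_intervals(m.cds)
            utr_sets.append(exon_set - cds_set)
        else:
            other.extend(m.exons)
    return {
        "ExonCDS": IntervalSet.from_intervals(cds_all),
        "ExonUTR": IntervalSet.union_all(utr_sets) if utr_sets else IntervalSet.empty(),
        "ExonOther": IntervalSet.from_intervals(other),
    }


def derive_introns(
    models: Sequence[GeneModel], config: AnnotationConfig | None = None
) -> Dict[str, IntervalSet]:
    """Intron bases split at ``splice_window`` bp from each splice site.

    Returns raw sets: the distal set still contains bases that carry other
    annotations; :func:`build_category_map` applies the residual subtraction.
    An intron no longer than twice the window is entirely proximal.
    """
    config = config or AnnotationConfig()
    w = config.splice_window
    proximal: List[Tuple[str, int, int]] = []
    distal: List[Tuple[str, int, int]] = []
    for m in models:
        exons = m.sorted_exons()
        for left, right in zip(exons, exons[1:]):
            s, e = left.end, right.start
            if s >= e:
                continue  # adjacent or bookkeeping-merged exons: no intron
            if e - s <= 2 * w:
                proximal.append((m.chrom, s, e))
            else:
                proximal.append((m.chrom, s, s + w))
                proximal.append((m.chrom, e - w, e))
                distal.append((m.chrom, s + w, e - w))
    def build(triples):
        buckets: Dict[str, List[Tuple[int, int]]] = {}
        for c, s, e in triples:
            buckets.setdefault(c, []).append((s, e))
        return IntervalSet.from_pairs(buckets)

    return {"IntronProximal": build(proximal), "IntronDistal": build(distal)}


def read_regulatory_build(
    path,
    type_map: Mapping[str, str] | None = None,
    config: AnnotationConfig | None = None,
) -> Tuple[Dict[str, IntervalSet], Counter]:
    """Read a regulatory-build GFF into the five regulatory category sets.

    Feature types (GFF column 3) are mapped through ``type_map``
    (case-insensitive; defaults to the Ensembl Regulatory Build vocabulary).
    Returns the category fragments and a Counter of unrecognized feature
    types.  A file containing no recognized type at all is rejected.
    """
    config = config or AnnotationConfig()
    tmap = {k.lower(): v for k, v in (type_map or DEFAULT_REGULATORY_TYPE_MAP).items()}
    buckets: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
        c: {} for c in REGULATORY_CATEGORIES
    }
    unknown: Counter = Counter()
    n_recognized = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected GFF columns")
            chrom = normalize_chrom(fields[0])
            ftype = fields[2].lower()
            if ftype not in tmap:
                unknown[fields[2]] += 1
                continue
            if not config.keeps_chrom(chrom):
                continue
            cat = tmap[ftype]
            start, end = int(fields[3]) - 1, int(fields[4])  # 1-based -> half-open
            buckets[cat].setdefault(chrom, []).append((start, end))
            n_recognized += 1
    if n_recognized == 0:
        raise ValueError(
            f"{path}: no recognized regulatory feature types "
            f"(saw {sorted(unknown)!r}); is this a regulatory-build GFF?"
        )
    if unknown:
        logger.warning(
            "%s: %d records with unrecognized feature types: %s",
            path, sum(unknown.values()), dict(unknown),
        )
    fragments = {c: IntervalSet.from_pairs(b) for c, b in buckets.items()}
    return fragments, unknown


def read_tad_domains(path, config: AnnotationConfig | None = None) -> List[GenomicInterval]:
    """Read TAD domain calls from BED3 or BEDPE/Juicer domain lists.

    Rows are interpreted as 0-based half-open.  For BEDPE-style rows the
    domain spans from the leftmost to the rightmost coordinate of the two
    anchors (Arrowhead emits x1==y1, x2==y2).
    """
    config = config or AnnotationConfig()
    domains: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "chr1\tx1")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            chrom = normalize_chrom(fields[0])
            if not config.keeps_chrom(chrom):
                continue
            if len(fields) >= 6 and not fields[3].lstrip("-").isdigit():
                # BEDPE: chrom1 s1 e1 chrom2 s2 e2
                coords = [int(fields[1]), int(fields[2]), int(fields[4]), int(fields[5])]
                start, end = min(coords), max(coords)
            else:
                start, end = int(fields[1]), int(fields[2])
            if end - start < 1:
                logger.warning("%s:%d: zero-length domain rejected", path, lineno)
                continue
            domains.append(GenomicInterval(chrom, start, end))
    return domains


def derive_tad_boundaries(
    domains: Iterable[GenomicInterval],
    config: AnnotationConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Boundary regions: ±``tad_flank`` bp around each domain edge.

    Boundaries are clipped at position 0 and, when chromosome lengths are
    given, at the chromosome end; overlapping boundaries merge.
    """
    config = config or AnnotationConfig()
    f = config.tad_flank
    buckets: Dict[str, List[Tuple[int, int]]] = {}
    for d in domains:
        limit = chrom_lengths.get(d.chrom) if chrom_lengths else None
        for edge in (d.start, d.end):
            s, e = max(0, edge - f), edge + f
            if limit is not None:
                e = min(e, limit)
                s = min(s, limit)
            if s < e:
                buckets.setdefault(d.chrom, []).append((s, e))
    return IntervalSet.from_pairs(buckets)


# ------------------------------------------------------------------- build
def build_category_map(
    fragments: Mapping[str, IntervalSet],
    chrom_lengths: Mapping[str, int],
    config: AnnotationConfig | None = None,
    species: str = "human",
    assembly: str = "",
) -> CategoryMap:
    """Assemble the final map, applying the residual rules.

    Non-residual categories keep any mutual overlap.  IntronDistal is the
    raw distal set minus every other annotation; Unannotated is the
    complement of everything else, so the twelve sets jointly cover each
    autosomal base at least once.
    """
    config = config or AnnotationConfig()
    chrom_lengths = {
        normalize_chrom(c): int(n) for c, n in chrom_lengths.items()
        if config.keeps_chrom(c)
    }
    genome = IntervalSet.whole_genome(chrom_lengths)

    clipped: Dict[str, IntervalSet] = {}
    for cat, ivset in fragments.items():
        if cat not in CATEGORIES:
            raise KeyError(f"unknown category {cat!r}")
        kept = {c: a for c, a in ((c, ivset.array(c)) for c in ivset.chroms) if c in chrom_lengths}
        for c, arr in kept.items():
            if arr.size and arr[:, 1].max() > chrom_lengths[c]:
                raise ValueError(
                    f"{cat}: interval beyond chromosome {c} length {chrom_lengths[c]}"
                )
        clipped[cat] = IntervalSet(kept)

    maps: Dict[str, IntervalSet] = {
        cat: clipped.get(cat, IntervalSet.empty())
        for cat in CATEGORIES
        if cat not in RESIDUAL_CATEGORIES
    }
    non_residual_union = IntervalSet.union_all(maps.values())
    maps["IntronDistal"] = clipped.get("IntronDistal", IntervalSet.empty()) - non_residual_union
    covered = non_residual_union | maps["IntronDistal"]
    maps["Unannotated"] = genome - covered
    return CategoryMap(
        species=species,
        assembly=assembly,
        chrom_lengths=dict(chrom_lengths),
        maps=maps,
    )


def write_gtf(models: Sequence[GeneModel], path, source: str = "orthoannot") -> None:
    """Write gene models as GTF (1-based inclusive), inverse of the reader."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.biotype}"; transcript_biotype "{m.biotype}";'
            )
            spans = m.sorted_exons()
            tx_start, tx_end = spans[0].start + 1, spans[-1].end
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{tx_start}\t{tx_end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for iv in spans:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for iv in sorted(m.cds, key=lambda iv: iv.start):
                fh.write(
                    f"{m.chrom}\t{source}\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{m.strand}\t0\t{attrs}\n"
                )


# ----------------------------------------------------------------- summaries
def coverage_summary(cmap: CategoryMap) -> pd.DataFrame:
    """Per-category coverage in bp and as a percentage of the autosomes.

    Because non-residual categories may overlap, the percentages can sum
    to more than 100.
    """
    total = cmap.genome_length
    rows = []
    for cat in CATEGORIES:
        bp = cmap[cat].total_length
        rows.append({"category": cat, "bp": bp, "pct": 100.0 * bp / total if total else 0.0})
    return pd.DataFrame(rows, columns=["category", "bp", "pct"])


def overlap_matrix(cmap: CategoryMap) -> pd.DataFrame:
    """Symmetric 12x12 matrix of pairwise overlapping base pairs.

    The diagonal equals each category's coverage; residual categories have
    zero off-diagonal overlap by construction.
    """
    mat = np.zeros((len(CATEGORIES), len(CATEGORIES)), dtype=np.int64)
    for i, ci in enumerate(CATEGORIES):
        mat[i, i] = cmap[ci].total_length
        for j in range(i + 1, len(CATEGORIES)):
            ov = (cmap[ci] & cmap[CATEGORIES[j]]).total_length
            mat[i, j] = mat[j, i] = ov
    return pd.DataFrame(mat, index=CATEGORIES, columns=CATEGORIES)
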