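"""End-to-end orchestration: annotate both genomes, index the alignment,
filter variants, and write the conservation tables.

The pipeline is deterministic given its inputs; the output manifest records
SHA-256 hashes of every input and output so a run can be reproduced and
checked bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .alignment import read_chain
from .annotation import (
    AnnotationConfig,
    CategoryMap,
    build_category_map,
    classify_exonic,
    coverage_summary,
    derive_introns,
    derive_tad_boundaries,
    overlap_matrix,
    read_chrom_lengths,
    read_gene_models,
    read_regulatory_build,
    read_tad_domains,
)
from .stats import (
    DEFAULT_COMPARISONS,
    annotation_conservation,
    background_comparisons,
    variant_conservation,
)
from .variants import (
    DEFAULT_PRECEDENCE,
    assign_categories,
    filter_clinvar,
    filter_gwas,
    read_clinvar_summary,
    read_clinvar_vcf,
    read_gwas_catalog,
    read_ontology_map,
    sites_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "build_species_map"]


@dataclass
class RunConfig:
    """Paths and options for one full pipeline run."""

    human_gtf: str
    human_regulatory: str
    human_tads: str
    human_chrom_sizes: str
    mouse_gtf: str
    mouse_regulatory: str
    mouse_tads: str
    mouse_chrom_sizes: str
    chain: str
    out_dir: str
    clinvar: Optional[str] = None  # VCF (.vcf) or variant_summary TSV
    gwas: Optional[str] = None
    ontology_map: Optional[str] = None
    splice_window: int = 10
    tad_flank: int = 25_000
    autosomes: Optional[Tuple[str, ...]] = None
    min_chain_score: Optional[float] = None
    precedence: Tuple[str, ...] = DEFAULT_PRECEDENCE
    noncoding_definition: str = "non-cds"  # or "non-exonic"
    comparisons: Sequence[dict] = field(default_factory=lambda: list(DEFAULT_COMPARISONS))
    subset_chroms: Optional[Tuple[str, ...]] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("autosomes", "precedence", "subset_chroms"):
            if raw.get(key) is not None:
                raw[key] = tuple(str(x) for x in raw[key])
        return cls(**raw)

    def annotation_config(self) -> AnnotationConfig:
        autosomes = self.autosomes
        if self.subset_chroms is not None:
            autosomes = tuple(
                c for c in (autosomes or self.subset_chroms) if c in self.subset_chroms
            )
        return AnnotationConfig(
            splice_window=self.splice_window,
            tad_flank=self.tad_flank,
            autosomes=autosomes,
        )

    @classmethod
    def from_fixture_dir(cls, fixtures, out_dir, **overrides) -> "RunConfig":
        """Point every input at the standard file names of a fixture bundle."""
        d = Path(fixtures)
        defaults = dict(
            human_gtf=str(d / "human.gtf"),
            human_regulatory=str(d / "human_regulatory.gff"),
            human_tads=str(d / "human_tads.bed"),
            human_chrom_sizes=str(d / "human.chrom.sizes"),
            mouse_gtf=str(d / "mouse.gtf"),
            mouse_regulatory=str(d / "mouse_regulatory.gff"),
            mouse_tads=str(d / "mouse_tads.bed"),
            mouse_chrom_sizes=str(d / "mouse.chrom.sizes"),
            chain=str(d / "human_mouse.chain"),
            clinvar=str(d / "clinvar.vcf"),
            gwas=str(d / "gwas_associations.tsv"),
            ontology_map=str(d / "trait_ontology.tsv"),
            out_dir=str(out_dir),
        )
        defaults.update(overrides)
        return cls(**defaults)


def build_species_map(
    gtf,
    regulatory,
    tads,
    chrom_sizes,
    config: AnnotationConfig,
    species: str,
) -> CategoryMap:
    """Read one species' inputs and assemble its category map."""
    chrom_lengths = read_chrom_lengths(chrom_sizes, config)
    models = read_gene_models(gtf, config)
    fragments = classify_exonic(models)
    fragments.update(derive_introns(models, config))
    reg, _unknown = read_regulatory_build(regulatory, config=config)
    fragments.update(reg)
    domains = read_tad_domains(tads, config)
    fragments["TADBoundary"] = derive_tad_boundaries(domains, config, chrom_lengths)
    return build_category_map(fragments, chrom_lengths, config, species=species)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute annotate -> align -> variants -> tables; return the manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann_cfg = config.annotation_config()

    stage = "annotate-human"
    try:
        human_map = build_species_map(
            config.human_gtf, config.human_regulatory, config.human_tads,
            config.human_chrom_sizes, ann_cfg, "human",
        )
        stage = "annotate-mouse"
        mouse_ann_cfg = AnnotationConfig(
            splice_window=ann_cfg.splice_window,
            tad_flank=ann_cfg.tad_flank,
            autosomes=None if config.autosomes is None and config.subset_chroms is None
            else ann_cfg.autosomes,
        )
        mouse_map = build_species_map(
            config.mouse_gtf, config.mouse_regulatory, config.mouse_tads,
            config.mouse_chrom_sizes, mouse_ann_cfg, "mouse",
        )
        stage = "index-alignment"
        index = read_chain(config.chain, min_score=config.min_chain_score)
        if config.subset_chroms is not None:
            pass  # maps already restricted; index queries follow the maps

        stage = "tables"
        ann_table = annotation_conservation(
            human_map, mouse_map, index,
            noncoding_definition=config.noncoding_definition,
        )
        outputs: Dict[str, Path] = {}

        def save(name: str, df) -> None:
            p = out / name
            df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            outputs[name] = p

        save("annotation_conservation.tsv", ann_table)
        save("coverage_human.tsv", coverage_summary(human_map))
        save("coverage_mouse.tsv", coverage_summary(mouse_map))
        save("overlap_human.tsv", overlap_matrix(human_map).reset_index(names="category"))
        save("aligned_fraction_by_chrom.tsv", index.per_chrom_aligned_fractions())

        stage = "variants"
        sites = set()
        if config.clinvar:
            records = (
                read_clinvar_vcf(config.clinvar)
                if str(config.clinvar).endswith((".vcf", ".vcf.gz"))
                else read_clinvar_summary(config.clinvar)
            )
            mend, _ = filter_clinvar(records, ann_cfg)
            sites |= mend
        if config.gwas:
            omap = read_ontology_map(config.ontology_map) if config.ontology_map else {}
            gw_records = read_gwas_catalog(config.gwas, omap)
            complex_sites, _ = filter_gwas(gw_records, ann_cfg)
            sites |= complex_sites

        manifest_tables: Dict[str, str] = {}
        if sites:
            categorized = assign_categories(sorted(sites, key=lambda s: (s.source, s.chrom, s.pos)),
                                            human_map, config.precedence)
            var_table, flagged = variant_conservation(
                categorized, human_map, mouse_map, index,
                precedence=config.precedence,
                noncoding_definition=config.noncoding_definition,
            )
            save("variant_conservation.tsv", var_table)
            save("variant_sites.tsv", sites_to_frame(flagged))
            stage = "comparisons"
            comp = background_comparisons(var_table, ann_table, config.comparisons)
            save("comparisons.tsv", comp)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    manifest = {
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 3),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items() if not k.startswith("_") and k != "comparisons"
        },
        "inputs": {
            name: _sha256(p)
            for name, p in (
                ("human_gtf", config.human_gtf),
                ("human_regulatory", config.human_regulatory),
                ("human_tads", config.human_tads),
                ("human_chrom_sizes", config.human_chrom_sizes),
                ("mouse_gtf", config.mouse_gtf),
                ("mouse_regulatory", config.mouse_regulatory),
                ("mouse_tads", config.mouse_tads),
                ("mouse_chrom_sizes", config.mouse_chrom_sizes),
                ("chain", config.chain),
                ("clinvar", config.clinvar),
                ("gwas", config.gwas),
                ("ontology_map", config.ontology_map),
            )
            if p
        },
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
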