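"""End-to-end analysis: ordination, phylosymbiosis, humanization, sharing.

One call runs the whole study on a dataset (real files or a synthetic
bundle): rarefaction to a common depth, presence/absence conversion,
Sorensen-Dice distances and PCoA; family-collapsed profiles, UPGMA
dendrograms and phylosymbiosis tests for the wild and captive conditions;
per-family Monte-Carlo humanization tests; and per-family / per-taxon
ASV-sharing classification. Defaults are the canonical settings of this
analysis: rarefaction depth 10,000, 10,000 random trees, 999 permutations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dissimilarity import (
    pcoa,
    sorensen_dice,
    write_distance_matrix,
    write_ordination,
)
from .feature_tables import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    group_mean_ceiling,
    rarefy,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    to_presence_absence,
    write_feature_table,
)
from .humanization import humanization_scan, write_long_distances, write_scan_results
from .sharing import classify_sharing, count_exclusive_by_taxon, presence_sets, write_sharing_table
from .synthetic_data import SyntheticConfig, simulate_dataset
from .trees import (
    leaf_names,
    phylosymbiosis_test,
    read_newick,
    upgma,
    write_newick,
)

__all__ = ["PipelineConfig", "ValidationReport", "PipelineReport",
           "validate_inputs", "run_pipeline"]

logger = logging.getLogger("humgut")

#: Taxon subsets reported by default: (rank, name) pairs.
DEFAULT_TAXA = (
    ("domain", "Archaea"),
    ("genus", "Clostridium sensu stricto 1"),
    ("genus", "Bacteroides"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and settings for one pipeline run.

    Either the four input paths or `synthetic` must be given. The numeric
    defaults (depth 10,000; 10,000 random trees; 999 permutations) are the
    canonical settings of this analysis.
    """

    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    host_tree_path: str | None = None
    synthetic: SyntheticConfig | None = None
    depth: int = 10_000
    n_random_trees: int = 10_000
    n_permutations: int = 999
    tail: str = "two-sided"
    seed: int = 0
    output_dir: str = "humgut_out"
    #: 'individuals' averages all human samples into the Hominidae profile;
    #: 'populations' averages population means first.
    human_collapse: str = "individuals"
    null: str = "coalescent"
    taxa: tuple = DEFAULT_TAXA

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        if "taxa" in raw:
            raw["taxa"] = tuple((r, n) for r, n in raw["taxa"])
        return cls(synthetic=syn, **raw)


@dataclass
class ValidationReport:
    warnings: list = field(default_factory=list)
    fatal: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


@dataclass
class PipelineReport:
    """Everything a run computed, plus where it was written."""

    output_dir: Path
    dropped_samples: list
    phylosymbiosis: dict            # condition -> PhylosymbiosisResult
    humanization: list              # DistanceGroupTestResult per family
    sharing_counts: dict            # family -> category -> count
    taxon_counts: dict              # (family, rank, name) -> (n_cap_hum, n_wild_hum)


def validate_inputs(
    table: FeatureTable,
    meta: SampleMetadata,
    taxonomy: TaxonomyMap | None,
    host_tree,
) -> ValidationReport:
    """Cross-check the four inputs; fatal findings abort a run."""
    rep = ValidationReport()
    table_samples = set(table.sample_ids)
    meta_samples = set(meta.sample_ids)
    for s in sorted(table_samples - meta_samples):
        rep.fatal.append(f"sample {s!r} in table but not in metadata")
    for s in sorted(meta_samples - table_samples):
        rep.warnings.append(f"metadata sample {s!r} absent from table")
    leaves = leaf_names(host_tree)
    for fam in meta.families(include_human=True):
        if fam not in leaves:
            rep.fatal.append(f"family {fam!r} in metadata but absent from host tree")
    for leaf in sorted(leaves - set(meta.families(include_human=True))):
        rep.warnings.append(f"host-tree leaf {leaf!r} has no samples")
    for fam in meta.families():
        for status in ("wild", "captive"):
            if not meta.samples_where(family=fam, status=status):
                rep.warnings.append(f"family {fam!r} has no {status} samples")
    if not meta.samples_where(status="human"):
        rep.warnings.append("no human samples present")
    if taxonomy is not None:
        missing = [a for a in table.asv_ids if a not in taxonomy]
        if missing:
            rep.warnings.append(
                f"{len(missing)} ASVs lack taxonomy (first: {missing[0]!r})"
            )
    return rep


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        bundle = simulate_dataset(config.synthetic)
        return bundle.table, bundle.metadata, bundle.taxonomy, bundle.host_tree
    paths = (config.table_path, config.metadata_path, config.host_tree_path)
    if any(p is None for p in paths):
        raise ValueError("config needs either `synthetic` or table/metadata/host-tree paths")
    table = read_feature_table(config.table_path)
    meta = read_metadata(config.metadata_path)
    taxonomy = (
        read_taxonomy(config.taxonomy_path) if config.taxonomy_path else TaxonomyMap({})
    )
    host_tree = read_newick(config.host_tree_path)
    return table, meta, taxonomy, host_tree


def _human_profile_grouping(meta: SampleMetadata, mode: str, samples) -> dict:
    """Group labels for human samples when collapsing to family profiles."""
    if mode == "individuals":
        return {s: "Hominidae" for s in samples}
    # populations mode: collapse to per-population rows first (caller averages
    # those rows into Hominidae afterwards)
    return {s: f"Hominidae::{meta.frame.at[s, 'population']}" for s in samples}


def _condition_profile(table, meta, condition: str, mode: str) -> FeatureTable:
    """Mean-ceiling family profiles for one condition (wild or captive).

    Humans are always included as the Hominidae row, averaged over all
    individuals (default) or over population means first.
    """
    samples = [
        s for s in table.sample_ids
        if meta.status_of(s) == condition or meta.status_of(s) == "human"
    ]
    sub = table.select_samples(samples)
    grouping = {}
    for s in samples:
        if meta.status_of(s) == "human":
            grouping[s] = None  # filled below
        else:
            grouping[s] = meta.family_of(s)
    humans = [s for s in samples if meta.status_of(s) == "human"]
    grouping.update(_human_profile_grouping(meta, mode, humans))
    prof = group_mean_ceiling(sub, grouping)
    if mode == "populations":
        pop_rows = [s for s in prof.sample_ids if s.startswith("Hominidae::")]
        second = {r: ("Hominidae" if r in pop_rows else r) for r in prof.sample_ids}
        prof = group_mean_ceiling(prof, second)
    return prof


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and write the report bundle to disk."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_rarefy, s_phylo_w, s_phylo_c, s_perm = ss.spawn(4)

    table, meta, taxonomy, host_tree = _load_inputs(config)
    report = validate_inputs(table, meta, taxonomy, host_tree)
    for w in report.warnings:
        logger.warning(w)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.fatal))

    rarefied, dropped = rarefy(table, config.depth, s_rarefy)
    if dropped:
        logger.info("dropped %d samples below depth %d", len(dropped), config.depth)
    write_feature_table(rarefied, outdir / "rarefied_table.tsv")

    pa = to_presence_absence(rarefied)
    dm = sorensen_dice(pa)
    write_distance_matrix(dm, outdir / "sorensen_dice.tsv")
    ordination = pcoa(dm)
    write_ordination(ordination, outdir / "pcoa.tsv")

    # phylosymbiosis for each condition
    phylo = {}
    for condition, s_cond in (("wild", s_phylo_w), ("captive", s_phylo_c)):
        profile = _condition_profile(rarefied, meta, condition, config.human_collapse)
        prof_dm = sorensen_dice(to_presence_absence(profile))
        dendro = upgma(prof_dm)
        write_newick(dendro, outdir / f"{condition}_dendrogram.nwk")
        host = host_tree.shear(list(prof_dm.labels))
        phylo[condition] = phylosymbiosis_test(
            dendro, host, config.n_random_trees, s_cond, null=config.null
        )
    write_newick(host_tree, outdir / "host_tree.nwk")

    # per-family humanization tests
    kept = set(rarefied.sample_ids)
    families = [
        f for f in meta.families()
        if set(meta.samples_where(family=f, status="wild")) & kept
        and set(meta.samples_where(family=f, status="captive")) & kept
    ]
    scan = humanization_scan(
        dm, meta, families, config.n_permutations, s_perm, tail=config.tail
    )
    write_scan_results(scan, outdir / "humanization.tsv")
    write_long_distances(dm, meta, families, outdir / "distances_long.tsv")

    # sharing classification per family and per taxon
    sharing_counts, taxon_counts = {}, {}
    for fam in families:
        W, C, H = presence_sets(rarefied, meta, fam)
        cls = classify_sharing(W, C, H, rarefied.asv_ids, family=fam)
        sharing_counts[fam] = cls.counts()
        write_sharing_table(cls, rarefied, meta, taxonomy, outdir / f"sharing_{fam}.tsv")
        for rank, name in config.taxa:
            taxon_counts[(fam, rank, name)] = count_exclusive_by_taxon(
                rarefied, taxonomy, meta, fam, rank, name
            )
    with open(outdir / "sharing_taxon_counts.tsv", "w") as fh:
        fh.write("family\trank\ttaxon\tn_captive_human_exclusive\tn_wild_human_exclusive\n")
        for (fam, rank, name), (nc, nw) in sorted(taxon_counts.items()):
            fh.write(f"{fam}\t{rank}\t{name}\t{nc}\t{nw}\n")

    summary = {
        "phylosymbiosis": {
            cond: {
                "observed_nrf": r.observed_nrf,
                "n_random": r.n_random,
                "p_value": r.p_value,
                "p_value_plain": r.p_value_plain,
            }
            for cond, r in phylo.items()
        },
        "humanization": [dataclasses.asdict(r) for r in scan],
        "sharing_counts": sharing_counts,
        "dropped_samples": dropped,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    run_log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "defaults_applied": {
            "depth": config.depth,
            "n_random_trees": config.n_random_trees,
            "n_permutations": config.n_permutations,
            "tail": config.tail,
            "human_collapse": config.human_collapse,
            "null": config.null,
        },
        "dropped_samples": dropped,
        "validation_warnings": report.warnings,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)

    return PipelineReport(
        output_dir=outdir,
        dropped_samples=dropped,
        phylosymbiosis=phylo,
        humanization=scan,
        sharing_counts=sharing_counts,
        taxon_counts=taxon_counts,
    )


def hash_output_dir(outdir) -> str:
    """SHA-256 over the sorted contents of a run's output directory."""
    h = hashlib.sha256()
    for path in sorted(Path(outdir).rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
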