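"""ASV-sharing exclusivity classification across wild / captive / human hosts.

Within each host family, every ASV is classified by its presence pattern
across three strata -- the family's wild samples (W), its captive samples (C)
and all human samples (H). ASVs present in captive hosts and humans but never
in wild confamiliars (category ``captive_human_exclusive``) display the
distribution expected under transfer from humans to captive animals; the
mirror category ``wild_human_exclusive`` provides the natural control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feature_tables import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    filter_by_taxon,
)

__all__ = [
    "CATEGORIES",
    "SharingClassification",
    "presence_sets",
    "classify_sharing",
    "count_exclusive_by_taxon",
    "write_sharing_table",
]

#: Presence-bit patterns (W, C, H) -> category name.
CATEGORIES = {
    (True, True, True): "all_three",
    (True, True, False): "wild_captive_not_human",
    (True, False, True): "wild_human_exclusive",
    (False, True, True): "captive_human_exclusive",
    (True, False, False): "wild_only",
    (False, True, False): "captive_only",
    (False, False, True): "human_only",
    (False, False, False): "absent",
}


@dataclass(frozen=True)
class SharingClassification:
    """Partition of the ASV universe by wild/captive/human presence bits."""

    family: str
    categories: dict = field(repr=False)  # asv_id -> category name

    def of_category(self, category: str) -> set:
        return {a for a, c in self.categories.items() if c == category}

    def counts(self) -> dict:
        out = {c: 0 for c in CATEGORIES.values()}
        for c in self.categories.values():
            out[c] += 1
        return out


def presence_sets(
    table: FeatureTable,
    meta: SampleMetadata,
    family: str,
    min_prevalence: int = 1,
) -> tuple:
    """(W, C, H): ASVs present in >= `min_prevalence` samples of each stratum.

    W and C are the family's wild and captive samples; H pools all human
    samples. Presence means a count >= 1 post-rarefaction; the default
    prevalence floor of one sample matches the no-floor convention, and a
    higher floor is available for sensitivity analysis.
    """
    strata = {
        "W": meta.samples_where(family=family, status="wild"),
        "C": meta.samples_where(family=family, status="captive"),
        "H": meta.samples_where(status="human"),
    }
    out = []
    for name, samples in strata.items():
        samples = [s for s in samples if s in table.sample_ids]
        if not samples:
            raise ValueError(f"family {family!r}: stratum {name} has no samples")
        idx = [table.sample_ids.index(s) for s in samples]
        nprev = (table.counts[idx] > 0).sum(axis=0)
        out.append({a for a, k in zip(table.asv_ids, nprev) if k >= min_prevalence})
    return tuple(out)


def classify_sharing(W: set, C: set, H: set, universe, family: str = "") -> SharingClassification:
    """Classify every ASV in `universe` by its (W, C, H) presence bits."""
    universe = set(universe)
    for name, s in (("W", W), ("C", C), ("H", H)):
        extra = set(s) - universe
        if extra:
            raise ValueError(f"{name} contains ASVs outside the universe: {sorted(extra)[:5]}")
    cats = {
        a: CATEGORIES[(a in W, a in C, a in H)]
        for a in universe
    }
    return SharingClassification(family=family, categories=cats)


def count_exclusive_by_taxon(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    meta: SampleMetadata,
    family: str,
    rank: str,
    name: str,
    min_prevalence: int = 1,
) -> tuple:
    """Exclusivity counts within one taxon for one family.

    Restricts the table to ASVs whose lineage at `rank` is `name`, then counts
    ASVs shared by captive hosts and humans to the exclusion of wild hosts,
    and the mirror count shared by wild hosts and humans to the exclusion of
    captive hosts.

    Returns
    -------
    (n_captive_human, n_wild_human)
    """
    sub = filter_by_taxon(table, taxonomy, rank, name)
    if not sub.asv_ids:
        return 0, 0
    W, C, H = presence_sets(sub, meta, family, min_prevalence=min_prevalence)
    cls = classify_sharing(W, C, H, sub.asv_ids, family=family)
    counts = cls.counts()
    return counts["captive_human_exclusive"], counts["wild_human_exclusive"]


def write_sharing_table(
    classification: SharingClassification,
    table: FeatureTable,
    meta: SampleMetadata,
    taxonomy: TaxonomyMap,
    path,
) -> None:
    """Per-family TSV of ASV category and mean relative abundance per stratum."""
    fam = classification.family
    strata = {
        "wild": meta.samples_where(family=fam, status="wild"),
        "captive": meta.samples_where(family=fam, status="captive"),
        "human": meta.samples_where(status="human"),
    }
    rel = {}
    totals = table.sample_totals().astype(float)
    totals[totals == 0] = 1.0
    relabund = table.counts / totals[:, None]
    for name, samples in strata.items():
        idx = [table.sample_ids.index(s) for s in samples if s in table.sample_ids]
        rel[name] = relabund[idx].mean(axis=0) if idx else np.zeros(len(table.asv_ids))
    with open(path, "w") as fh:
        fh.write(
            "asv_id\ttaxonomy\tcategory\tmean_rel_abund_wild\t"
            "mean_rel_abund_captive\tmean_rel_abund_human\n"
        )
        for j, asv in enumerate(table.asv_ids):
            cat = classification.categories.get(asv, "absent")
            fh.write(
                f"{asv}\t{taxonomy.lineage_string(asv)}\t{cat}\t"
                f"{rel['wild'][j]:.6g}\t{rel['captive'][j]:.6g}\t"
                f"{rel['human'][j]:.6g}\n"
            )
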