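"""Synthetic microbiome datasets with known phylosymbiosis and humanization.

The generator emulates a multi-family host/microbiome survey: a rooted
ultrametric host phylogeny; per-family ASV repertoires evolved along it by a
two-state (absent/present) continuous-time Markov chain, which creates the
phylosymbiosis signal; a dedicated human community containing a pool of
human-associated ASVs absent from every wild family repertoire; and captive
samples that acquire each human-pool ASV independently with a per-family
humanization fraction h. Because the human pool is disjoint from wild
repertoires by construction, 'humanized' ASVs are unambiguous ground truth.

Per-sample read counts are drawn multinomially at a fixed depth over
log-normal relative abundances of the sample's present ASVs, so rarefaction,
presence/absence conversion and Sorensen-Dice distances all behave as they
would on real rarefied tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from skbio import TreeNode

from .feature_tables import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)
from .trees import write_newick

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "simulate_host_tree",
    "simulate_family_presence",
    "simulate_dataset",
    "write_bundle",
]

#: Fixed bank of Silva-style lineages (weights sum to 1). Includes the taxa
#: the taxon-subset operations target: Archaea, Clostridium sensu stricto 1,
#: and Bacteroides.
LINEAGE_BANK = (
    (0.05, ("Archaea", "Methanobacteriota", "Methanobacteria",
            "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter")),
    (0.10, ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
            "Clostridiaceae", "Clostridium sensu stricto 1")),
    (0.10, ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
            "Bacteroidaceae", "Bacteroides")),
    (0.15, ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
            "Prevotellaceae", "Prevotella")),
    (0.20, ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales",
            "Lachnospiraceae", "Blautia")),
    (0.20, ("Bacteria", "Firmicutes", "Clostridia", "Oscillospirales",
            "Ruminococcaceae", "Ruminococcus")),
    (0.10, ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
            "Enterobacterales", "Enterobacteriaceae", "Escherichia-Shigella")),
    (0.10, ("Bacteria", "Verrucomicrobiota", "Verrucomicrobiae",
            "Verrucomicrobiales", "Akkermansiaceae", "Akkermansia")),
)

HUMAN_POPULATIONS = ("Malawi", "Venezuela", "United States")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a survey of 8 mammalian host families (plus humans,
    family Hominidae) with 5 wild and 5 captive samples per family and 20
    human samples -- the small-group regime of real multi-family surveys --
    over 2,000 ASVs at a sequencing depth of 1,000 reads. The first half of
    the families are humanized at fraction 0.3; the rest are untouched.
    """

    n_families: int = 8
    n_wild: int = 5
    n_captive: int = 5
    n_humans: int = 20
    n_asvs: int = 2000
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    #: family -> humanization fraction h; None = first half at 0.3, rest 0.
    humanization: dict | None = None
    n_human_pool: int = 300
    depth: int = 1000
    abundance_dispersion: float = 1.0
    #: per-sample probability of flipping each non-pool presence bit.
    noise_flip_prob: float = 0.01
    #: probability a human-pool ASV leaks into a wild family repertoire.
    leak_rate: float = 0.0
    #: guarantee >= 1 read for every present ASV (requires depth >= richness).
    min_one_read: bool = False
    seed: int = 0

    def family_labels(self):
        return [f"Family_{i + 1}" for i in range(self.n_families)]

    def humanization_map(self) -> dict:
        fams = self.family_labels()
        if self.humanization is None:
            return {f: (0.3 if i < self.n_families // 2 else 0.0)
                    for i, f in enumerate(fams)}
        h = {f: 0.0 for f in fams}
        h.update(self.humanization)
        return h

    def validate(self) -> None:
        if self.n_families < 3:
            raise ValueError("n_families must be >= 3")
        if min(self.n_wild, self.n_captive, self.n_humans) < 1:
            raise ValueError("every stratum needs at least one sample")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("gain/loss rates must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.n_human_pool <= self.n_asvs:
            raise ValueError("n_human_pool must be in [0, n_asvs]")
        if not 0 <= self.noise_flip_prob <= 1 or not 0 <= self.leak_rate <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        for fam, h in self.humanization_map().items():
            if not 0 <= h <= 1:
                raise ValueError(f"humanization fraction for {fam} not in [0, 1]")
        extra = set(self.humanization or {}) - set(self.family_labels())
        if extra:
            raise ValueError(f"humanization names unknown families: {sorted(extra)}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth sufficient to recompute every expected sharing category."""

    host_tree_newick: str
    family_presence: pd.DataFrame = field(repr=False)
    human_pool: tuple = field(repr=False)
    humanization: dict = field(repr=False)
    #: sample id -> (family, status)
    sample_strata: dict = field(repr=False)
    #: sample id -> frozenset of ASVs with >= 1 read in the emitted table
    realized: dict = field(repr=False)
    #: captive sample id -> frozenset of human-pool ASVs injected into it
    injected: dict = field(repr=False)

    @property
    def humanized_families(self):
        return tuple(sorted(f for f, h in self.humanization.items() if h > 0))

    def realized_injected_pool(self, family: str) -> set:
        """Human-pool ASVs injected into >= 1 captive sample of `family` and
        realized (>= 1 read) there and in >= 1 human sample."""
        captive = {
            s for s, (f, st) in self.sample_strata.items()
            if f == family and st == "captive"
        }
        humans = {s for s, (_, st) in self.sample_strata.items() if st == "human"}
        realized_h = frozenset().union(*(self.realized[s] for s in humans))
        out = set()
        for s in captive:
            out |= self.injected[s] & self.realized[s]
        return out & realized_h

    def expected_sharing(self, family: str) -> dict:
        """Recompute expected (W, C, H)-category sets from realized sets."""
        from .sharing import CATEGORIES  # local import avoids a cycle

        def union(status, fam=None):
            ids = [
                s for s, (f, st) in self.sample_strata.items()
                if st == status and (fam is None or f == fam)
            ]
            return set().union(*(self.realized[s] for s in ids)) if ids else set()

        W = union("wild", family)
        C = union("captive", family)
        H = union("human")
        # the universe is every emitted ASV column, realized or not
        universe = set(self.family_presence.columns)
        return {
            a: CATEGORIES[(a in W, a in C, a in H)] for a in universe
        }


class SyntheticBundle(NamedTuple):
    table: FeatureTable
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    host_tree: TreeNode
    truth: SyntheticTruth


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _coalescent_tree(labels, rng) -> TreeNode:
    nodes = [TreeNode(name=x) for x in labels]
    heights = [0.0] * len(nodes)
    t = 0.0
    while len(nodes) > 1:
        m = len(nodes)
        t += rng.exponential(2.0 / (m * (m - 1)))
        i, j = sorted(rng.choice(m, size=2, replace=False))
        b, hb = nodes.pop(j), heights.pop(j)
        a, ha = nodes.pop(i), heights.pop(i)
        a.length = t - ha
        b.length = t - hb
        nodes.append(TreeNode(children=[a, b]))
        heights.append(t)
    root = nodes[0]
    for node in root.traverse(include_self=False):
        node.length = node.length / t  # normalize total height to 1
    root.length = None
    return root


def simulate_host_tree(n_families: int, seed, labels=None) -> TreeNode:
    """Random rooted binary ultrametric host tree of total height 1.

    Topology and node times follow a uniform coalescent (uniformly chosen
    pairs merge after exponential waiting times); leaves are labelled
    Family_1..n unless `labels` overrides.
    """
    if n_families < 3:
        raise ValueError("n_families must be >= 3")
    if labels is None:
        labels = [f"Family_{i + 1}" for i in range(n_families)]
    return _coalescent_tree(list(labels), _as_rng(seed))


def simulate_family_presence(
    tree: TreeNode, n_asvs: int, gain_rate: float, loss_rate: float, seed
) -> pd.DataFrame:
    """Evolve ASV presence/absence along the host tree.

    Each ASV follows an independent 2-state continuous-time Markov chain
    (absent <-> present) with the given per-unit-branch-length gain and loss
    rates. The root state is drawn from the stationary distribution
    gain/(gain+loss) (0.5 when both rates are zero, in which case states
    never change). Returns a boolean families x ASVs DataFrame.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = _as_rng(seed)
    rate = gain_rate + loss_rate
    pi1 = gain_rate / rate if rate > 0 else 0.5
    states = {id(tree): rng.random(n_asvs) < pi1}
    for node in tree.preorder(include_self=False):
        parent = states[id(node.parent)]
        t = node.length or 0.0
        if rate == 0 or t == 0:
            child = parent.copy()
        else:
            e = np.exp(-rate * t)
            p1 = np.where(parent, pi1 + (1 - pi1) * e, pi1 * (1 - e))
            child = rng.random(n_asvs) < p1
        states[id(node)] = child
    leaves = sorted(tree.tips(), key=lambda x: x.name)
    mat = np.vstack([states[id(leaf)] for leaf in leaves])
    cols = [f"ASV_{i:05d}" for i in range(n_asvs)]
    return pd.DataFrame(mat, index=[leaf.name for leaf in leaves], columns=cols)


def _draw_counts(intended: np.ndarray, depth: int, dispersion: float,
                 min_one_read: bool, rng) -> np.ndarray:
    idx = np.flatnonzero(intended)
    counts = np.zeros(intended.size, dtype=np.int64)
    if idx.size == 0:
        return counts
    w = rng.lognormal(0.0, dispersion, idx.size)
    p = w / w.sum()
    if min_one_read:
        if depth < idx.size:
            raise ValueError(
                f"depth {depth} < sample richness {idx.size}; cannot "
                "guarantee one read per present ASV"
            )
        counts[idx] = 1 + rng.multinomial(depth - idx.size, p)
    else:
        counts[idx] = rng.multinomial(depth, p)
    return counts


def simulate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate one full dataset (table, metadata, taxonomy, host tree, truth).

    The host tree spans the mammal families plus a Hominidae leaf. Wild
    samples of family F realise F's repertoire with per-bit noise; human
    samples realise the Hominidae repertoire plus the entire human pool;
    captive samples of F start from F's repertoire and additionally acquire
    each human-pool ASV independently with probability h(F). Noise never
    touches human-pool bits, so pool sharing patterns stay unambiguous
    ground truth (use `leak_rate` to relax this deliberately).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_pres, s_samp, s_tax = ss.spawn(4)
    labels = config.family_labels() + ["Hominidae"]
    tree = _coalescent_tree(labels, np.random.default_rng(s_tree))
    presence = simulate_family_presence(
        tree, config.n_asvs, config.gain_rate, config.loss_rate,
        np.random.default_rng(s_pres),
    )
    asv_ids = list(presence.columns)
    n_pool = config.n_human_pool
    pool_idx = np.arange(config.n_asvs - n_pool, config.n_asvs)
    pool_ids = tuple(asv_ids[i] for i in pool_idx)
    nonpool_idx = np.arange(config.n_asvs - n_pool)

    rng = np.random.default_rng(s_samp)
    base = presence.to_numpy().copy()
    base[:, pool_idx] = False  # pool disjoint from every repertoire
    fam_row = {f: base[presence.index.get_loc(f)] for f in labels}
    if config.leak_rate > 0:
        for f in config.family_labels():
            leak = rng.random(n_pool) < config.leak_rate
            fam_row[f] = fam_row[f].copy()
            fam_row[f][pool_idx[leak]] = True
    human_row = fam_row["Hominidae"].copy()
    human_row[pool_idx] = True

    hmap = config.humanization_map()
    rows, sample_ids, meta_rows = [], [], []
    injected: dict = {}
    intended_sets: dict = {}

    def add_sample(sid, fam, status, intended, population=""):
        sample_ids.append(sid)
        meta_rows.append((sid, fam, status, population))
        intended_sets[sid] = intended
        rows.append(
            _draw_counts(intended, config.depth, config.abundance_dispersion,
                         config.min_one_read, rng)
        )

    def noisy(vec):
        out = vec.copy()
        if config.noise_flip_prob > 0:
            flips = rng.random(nonpool_idx.size) < config.noise_flip_prob
            out[nonpool_idx] ^= flips
        return out

    for fam in config.family_labels():
        for i in range(config.n_wild):
            add_sample(f"{fam}_wild_{i + 1}", fam, "wild", noisy(fam_row[fam]))
        for i in range(config.n_captive):
            sid = f"{fam}_captive_{i + 1}"
            intended = noisy(fam_row[fam])
            take = rng.random(n_pool) < hmap[fam]
            intended[pool_idx[take]] = True
            injected[sid] = frozenset(asv_ids[k] for k in pool_idx[take])
            add_sample(sid, fam, "captive", intended)
    for i in range(config.n_humans):
        pop = HUMAN_POPULATIONS[i % len(HUMAN_POPULATIONS)]
        add_sample(f"Human_{i + 1}", "Hominidae", "human", noisy(human_row), pop)

    table = FeatureTable(sample_ids, asv_ids, np.asarray(rows))
    meta = SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "family", "status", "population"])
    )

    tax_rng = np.random.default_rng(s_tax)
    weights = np.array([w for w, _ in LINEAGE_BANK])
    picks = tax_rng.choice(len(LINEAGE_BANK), size=config.n_asvs, p=weights)
    taxonomy = TaxonomyMap({asv_ids[i]: LINEAGE_BANK[picks[i]][1]
                            for i in range(config.n_asvs)})

    realized = {
        sid: frozenset(a for a, c in zip(asv_ids, row) if c > 0)
        for sid, row in zip(sample_ids, rows)
    }
    truth = SyntheticTruth(
        host_tree_newick=str(tree).strip(),
        family_presence=pd.DataFrame(
            {f: fam_row[f] for f in labels}, index=asv_ids
        ).T,
        human_pool=pool_ids,
        humanization=hmap,
        sample_strata={sid: (fam, st) for sid, fam, st, _ in meta_rows},
        realized=realized,
        injected=injected,
    )
    return SyntheticBundle(table, meta, taxonomy, tree, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the synthetic bundle in the same formats the pipeline consumes."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(bundle.table, outdir / "feature_table.tsv")
    write_metadata(bundle.metadata, outdir / "metadata.tsv")
    write_taxonomy(bundle.taxonomy, bundle.table.asv_ids, outdir / "taxonomy.tsv")
    write_newick(bundle.host_tree, outdir / "host_tree.nwk")
    truth = bundle.truth
    payload = {
        "host_tree_newick": truth.host_tree_newick,
        "human_pool": list(truth.human_pool),
        "humanization": truth.humanization,
        "humanized_families": list(truth.humanized_families),
        "sample_strata": {k: list(v) for k, v in truth.sample_strata.items()},
        "realized": {k: sorted(v) for k, v in truth.realized.items()},
        "injected": {k: sorted(v) for k, v in truth.injected.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
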