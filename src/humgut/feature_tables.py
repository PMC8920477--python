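"""ASV feature tables, sample metadata and taxonomy.

The feature table (samples x ASVs, non-negative integer counts) is the
universal currency of the pipeline: everything downstream -- rarefaction,
presence/absence conversion, Sorensen-Dice dissimilarity, family-level
mean-ceiling collapsing, and taxon subsetting -- consumes or produces one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "STATUSES",
    "FeatureTable",
    "SampleMetadata",
    "TaxonomyMap",
    "read_feature_table",
    "write_feature_table",
    "rarefy",
    "to_presence_absence",
    "group_mean_ceiling",
    "filter_by_taxon",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
]

#: The six Silva-style lineage ranks used throughout.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Allowed host status labels.
STATUSES = ("wild", "captive", "human")

_SILVA_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")


@dataclass(frozen=True)
class FeatureTable:
    """A samples x ASVs matrix of non-negative integer counts.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique row identifiers.
    asv_ids : sequence of str
        Unique column identifiers.
    counts : ndarray of int, shape (n_samples, n_asvs)
    """

    sample_ids: tuple
    asv_ids: tuple
    counts: np.ndarray = field(repr=False)

    def __init__(self, sample_ids, asv_ids, counts):
        sample_ids = tuple(str(s) for s in sample_ids)
        asv_ids = tuple(str(a) for a in asv_ids)
        counts = np.asarray(counts)
        if counts.dtype.kind == "f":
            if not np.all(np.isfinite(counts)) or np.any(counts % 1 != 0):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        elif counts.dtype.kind not in "iu":
            raise ValueError("counts must be an integer array")
        counts = counts.astype(np.int64, copy=True)
        if counts.ndim != 2 or counts.shape != (len(sample_ids), len(asv_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(asv_ids)} ASVs"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(asv_ids)) != len(asv_ids):
            raise ValueError("duplicate ASV ids")
        counts.setflags(write=False)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "asv_ids", asv_ids)
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self):
        return self.counts.shape

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(sample_ids, self.asv_ids, self.counts[idx])

    def select_asvs(self, asv_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.asv_ids.index(a) for a in asv_ids]
        return FeatureTable(self.sample_ids, asv_ids, self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.asv_ids)
        )

    def __eq__(self, other):
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample host family, status and optional population label."""

    frame: pd.DataFrame = field(repr=False)

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"sample_id", "family", "status"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if "population" not in frame.columns:
            frame["population"] = ""
        frame["population"] = frame["population"].fillna("")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in metadata: {list(dups)}")
        bad = set(frame["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        human_fams = set(frame.loc[frame["status"] == "human", "family"])
        if human_fams - {"Hominidae"}:
            raise ValueError("status 'human' requires family 'Hominidae'")
        frame = frame.set_index("sample_id", drop=False)
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self):
        return tuple(self.frame["sample_id"])

    def family_of(self, sample_id: str) -> str:
        return self.frame.at[sample_id, "family"]

    def status_of(self, sample_id: str) -> str:
        return self.frame.at[sample_id, "status"]

    def families(self, include_human: bool = False):
        """Distinct non-human host families (sorted); Hominidae optional."""
        fams = sorted(set(self.frame["family"]))
        if not include_human:
            fams = [f for f in fams if f != "Hominidae"]
        return fams

    def samples_where(
        self, family: str | None = None, status: str | None = None,
        population: str | None = None,
    ) -> list:
        sel = pd.Series(True, index=self.frame.index)
        if family is not None:
            sel &= self.frame["family"] == family
        if status is not None:
            sel &= self.frame["status"] == status
        if population is not None:
            sel &= self.frame["population"] == population
        return sorted(self.frame.loc[sel, "sample_id"])


class TaxonomyMap:
    """ASV id -> 6-rank lineage (domain..genus), Silva style.

    Lineages are stored as fixed-length tuples of six strings; missing ranks
    are empty strings.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        clean = {}
        for asv, lin in lineages.items():
            lin = [str(x).strip() for x in lin]
            if len(lin) > len(RANKS):
                raise ValueError(f"{asv}: lineage longer than {len(RANKS)} ranks")
            lin = lin + [""] * (len(RANKS) - len(lin))
            clean[str(asv)] = tuple(lin)
        self._lineages = clean

    def __contains__(self, asv_id):
        return asv_id in self._lineages

    def __len__(self):
        return len(self._lineages)

    def lineage(self, asv_id: str):
        return self._lineages[asv_id]

    def at_rank(self, asv_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        lin = self._lineages.get(asv_id)
        return "" if lin is None else lin[RANKS.index(rank)]

    def lineage_string(self, asv_id: str) -> str:
        lin = self._lineages.get(asv_id, ("",) * len(RANKS))
        return "; ".join(p + v for p, v in zip(_SILVA_PREFIXES, lin))

    @classmethod
    def from_strings(cls, strings: Mapping[str, str]) -> "TaxonomyMap":
        """Parse Silva-style 'd__X; p__Y; ...' lineage strings."""
        out = {}
        for asv, s in strings.items():
            parts = [p.strip() for p in str(s).split(";")]
            lin = []
            for part in parts:
                for pref in _SILVA_PREFIXES:
                    if part.startswith(pref):
                        part = part[len(pref):]
                        break
                lin.append(part.strip())
            out[asv] = lin
        return cls(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv") -> FeatureTable:
    """Read a feature table from TSV (samples as rows) or BIOM-JSON.

    The TSV dialect has a header row of ASV ids and sample ids in the first
    column. Non-integer or negative counts are rejected.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown feature-table format {format!r}")


def _read_tsv(path: Path) -> FeatureTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    asv_ids = header[1:]
    if len(set(asv_ids)) != len(asv_ids):
        raise ValueError(f"{path}: duplicate ASV ids in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    vals = df.to_numpy()
    if vals.dtype.kind not in "iu":
        try:
            fvals = vals.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric count: {exc}") from None
        bad = np.argwhere(~np.isfinite(fvals) | (fvals % 1 != 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{path}: non-integer count {fvals[i, j]!r} at sample "
                f"{df.index[i]!r}, ASV {df.columns[j]!r}"
            )
        vals = fvals.astype(np.int64)
    return FeatureTable(list(df.index), asv_ids, vals)


def _read_biom_json(path: Path) -> FeatureTable:
    with open(path) as fh:
        text = fh.read()
    try:
        import biom

        table = biom.parse_table(text)
    except ImportError:  # pragma: no cover - biom ships with scikit-bio here
        table = None
    if table is not None:
        counts = np.asarray(table.matrix_data.todense()).T
        return FeatureTable(table.ids("sample"), table.ids("observation"), counts)
    # minimal BIOM 1.0 JSON fallback
    obj = json.loads(text)
    rows = [r["id"] for r in obj["rows"]]
    cols = [c["id"] for c in obj["columns"]]
    mat = np.zeros((len(rows), len(cols)))
    if obj.get("matrix_type") == "dense":
        mat = np.asarray(obj["data"], dtype=float)
    else:
        for i, j, v in obj["data"]:
            mat[int(i), int(j)] = v
    return FeatureTable(cols, rows, mat.T)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: taxonomy TSV needs asv_id + lineage columns")
    return TaxonomyMap.from_strings(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_taxonomy(tax: TaxonomyMap, asv_ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("asv_id\tlineage\n")
        for asv in asv_ids:
            fh.write(f"{asv}\t{tax.lineage_string(asv)}\n")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int, seed) -> tuple:
    """Subsample every sample to exactly `depth` reads without replacement.

    Samples whose total count is below `depth` are dropped; their ids are
    returned so attrition stays auditable. Subsampling is multivariate
    hypergeometric (uniform over reads, without replacement), the convention
    of standard rarefaction tooling. ASV columns that end up all-zero are
    retained so ASV indices stay stable across pipeline stages.

    Returns
    -------
    (FeatureTable, list of str)
        The rarefied table and the ids of dropped samples.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no samples at requested depth {depth}")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    rows = []
    for i, k in enumerate(keep):
        if not k:
            continue
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = FeatureTable(kept_ids, table.asv_ids, np.asarray(rows))
    return out, dropped


def to_presence_absence(table: FeatureTable) -> FeatureTable:
    """Map every positive count to 1, keeping zeros. Idempotent."""
    return FeatureTable(
        table.sample_ids, table.asv_ids, (table.counts > 0).astype(np.int64)
    )


def group_mean_ceiling(table: FeatureTable, grouping: Mapping[str, str]) -> FeatureTable:
    """Collapse samples into group profiles by ceiling-of-mean counts.

    Each output row is a group; each cell is ceil(mean(count)) over the
    group's member samples, mirroring the 'mean-ceiling' grouping mode of
    standard feature-table tooling. Output rows are sorted by group label.
    """
    missing = [s for s in table.sample_ids if s not in grouping]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    orphans = [s for s in grouping if s not in table.sample_ids]
    if orphans:
        raise ValueError(f"grouping names samples absent from table (empty-group risk): {orphans}")
    groups: dict = {}
    for i, s in enumerate(table.sample_ids):
        groups.setdefault(grouping[s], []).append(i)
    labels = sorted(groups)
    out = np.empty((len(labels), len(table.asv_ids)), dtype=np.int64)
    for r, g in enumerate(labels):
        mean = table.counts[groups[g]].mean(axis=0)
        out[r] = np.ceil(mean).astype(np.int64)
    return FeatureTable(labels, table.asv_ids, out)


def _norm_taxon(name: str) -> str:
    return str(name).strip().casefold()


def filter_by_taxon(
    table: FeatureTable, taxonomy: TaxonomyMap, rank: str, name: str
) -> FeatureTable:
    """Keep exactly the ASVs whose lineage at `rank` equals `name`.

    Matching is exact at the rank after whitespace trimming and case folding
    (never substring): Silva labels such as 'Clostridium sensu stricto 1'
    must be given as printed, so that 'Clostridium sensu stricto 1' and
    '... 13' are never silently merged.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    want = _norm_taxon(name)
    keep = [a for a in table.asv_ids if _norm_taxon(taxonomy.at_rank(a, rank)) == want]
    idx = [table.asv_ids.index(a) for a in keep]
    return FeatureTable(table.sample_ids, keep, table.counts[:, idx])
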