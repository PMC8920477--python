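"""Per-family Monte-Carlo permutation tests of gut-microbiota humanization.

For each host family the pairwise Sorensen-Dice dissimilarities between its
captive members and humans are compared with those between its wild members
and humans. A pooled-variance two-sample t statistic on the two groups of
pairwise distances is assessed against a Monte-Carlo permutation null that
shuffles the pooled distances, the convention of classic distance-boxplot
tooling. The permutation unit is the individual pairwise distance; because
pairwise distances sharing a sample are dependent, this test can be liberal,
and a sample-label permutation mode is provided for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dissimilarity import DistanceMatrix
from .feature_tables import SampleMetadata

__all__ = [
    "DistanceGroupTestResult",
    "between_group_distances",
    "two_sample_t",
    "mc_permutation_test",
    "humanization_scan",
    "write_scan_results",
    "write_long_distances",
]

TAILS = ("two-sided", "captive-lower")
_EPS = 1e-12


@dataclass(frozen=True)
class DistanceGroupTestResult:
    """Result of one family's captive-vs-wild comparison to humans."""

    family: str
    n_wild_pairs: int
    n_captive_pairs: int
    mean_wild: float
    mean_captive: float
    t_statistic: float
    n_permutations: int
    p_value: float
    tail: str


def between_group_distances(
    dm: DistanceMatrix, meta: SampleMetadata, family: str, status: str,
    human_populations=None,
) -> list:
    """All pairwise distances d(s, h): s of `family` with `status`, h human.

    Pairs are ordered by (sample id, human id) so output is deterministic.
    `human_populations` optionally restricts the human reference group to the
    named population labels.
    """
    group = [
        s for s in meta.samples_where(family=family, status=status)
        if s in dm.labels
    ]
    humans = [h for h in meta.samples_where(status="human") if h in dm.labels]
    if human_populations is not None:
        keep = set(human_populations)
        humans = [h for h in humans if meta.frame.at[h, "population"] in keep]
    if not group:
        raise ValueError(f"no {status} samples for family {family!r}")
    if not humans:
        raise ValueError("no human samples in the selected reference group")
    gi = [dm.labels.index(s) for s in group]
    hi = [dm.labels.index(h) for h in humans]
    return [float(dm.values[i, j]) for i in gi for j in hi]


def two_sample_t(x, y) -> float:
    """Pooled-variance Student t for the difference in means of x and y.

    Degenerate inputs (both groups constant) give 0 when the means are equal
    and signed infinity otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 values")
    nx, ny = x.size, y.size
    diff = x.mean() - y.mean()
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    if denom == 0:
        if diff == 0:
            return 0.0
        return float(np.sign(diff)) * float("inf")
    return float(diff / denom)


def _t_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise pooled t for matrices of x-groups and y-groups."""
    nx, ny = xs.shape[1], ys.shape[1]
    diff = xs.mean(axis=1) - ys.mean(axis=1)
    sp2 = ((nx - 1) * xs.var(axis=1, ddof=1) + (ny - 1) * ys.var(axis=1, ddof=1)) / (
        nx + ny - 2
    )
    denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero = denom == 0
    t[zero & (diff == 0)] = 0.0
    t[zero & (diff > 0)] = np.inf
    t[zero & (diff < 0)] = -np.inf
    return t


def mc_permutation_test(
    x, y, n_permutations: int, seed, tail: str = "two-sided"
):
    """Monte-Carlo permutation test on the pooled-t statistic.

    Pools x and y, shuffles, re-splits into the original group sizes and
    recomputes t for each of `n_permutations` permutations. Two-sided
    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_permutations); the one-sided
    'captive-lower' tail counts t_perm <= t_obs instead (x is the captive
    group by convention, so negative t means captive closer to humans).

    Returns
    -------
    (t_obs, p_value, p_value_plain)
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if tail not in TAILS:
        raise ValueError(f"unknown tail {tail!r}; expected one of {TAILS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t_obs = two_sample_t(x, y)
    rng = np.random.default_rng(seed)
    pool = np.concatenate([x, y])
    perms = rng.permuted(
        np.broadcast_to(pool, (n_permutations, pool.size)).copy(), axis=1
    )
    t_perm = _t_rows(perms[:, : x.size], perms[:, x.size:])
    if tail == "two-sided":
        k = int(np.sum(np.abs(t_perm) >= abs(t_obs) - _EPS))
    else:
        k = int(np.sum(t_perm <= t_obs + _EPS))
    return t_obs, (1 + k) / (1 + n_permutations), k / n_permutations


def humanization_scan(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    families,
    n_permutations: int,
    seed,
    tail: str = "two-sided",
    human_populations=None,
    permute: str = "distances",
) -> list:
    """One permutation test per family: captive-to-human vs wild-to-human.

    x = captive-human distances, y = wild-human distances, so a negative t
    (mean_captive < mean_wild) is the humanization direction. ``permute``
    selects the permutation unit: 'distances' shuffles the pooled pairwise
    distances (the classic, liberal convention); 'labels' shuffles the
    wild/captive status labels within the family and rebuilds both distance
    lists each permutation, respecting pairwise-distance dependence.
    """
    if permute not in ("distances", "labels"):
        raise ValueError(f"unknown permutation unit {permute!r}")
    known = set(meta.frame["family"])
    missing = [f for f in families if f not in known]
    if missing:
        raise ValueError(f"families absent from metadata: {missing}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    results = []
    for fam, child in zip(families, ss.spawn(len(families))):
        x = between_group_distances(
            dm, meta, fam, "captive", human_populations=human_populations
        )
        y = between_group_distances(
            dm, meta, fam, "wild", human_populations=human_populations
        )
        if permute == "distances":
            t_obs, p, _ = mc_permutation_test(
                x, y, n_permutations, child, tail=tail
            )
        else:
            t_obs, p = _label_permutation_test(
                dm, meta, fam, n_permutations, child, tail, human_populations
            )
        results.append(
            DistanceGroupTestResult(
                family=fam,
                n_wild_pairs=len(y),
                n_captive_pairs=len(x),
                mean_wild=float(np.mean(y)),
                mean_captive=float(np.mean(x)),
                t_statistic=t_obs,
                n_permutations=n_permutations,
                p_value=p,
                tail=tail,
            )
        )
    return results


def _label_permutation_test(
    dm, meta, family, n_permutations, seed, tail, human_populations
):
    """Permute wild/captive status labels within the family (sensitivity mode)."""
    rng = np.random.default_rng(seed)
    captive = [
        s for s in meta.samples_where(family=family, status="captive")
        if s in dm.labels
    ]
    wild = [
        s for s in meta.samples_where(family=family, status="wild")
        if s in dm.labels
    ]
    humans = [h for h in meta.samples_where(status="human") if h in dm.labels]
    if human_populations is not None:
        keep = set(human_populations)
        humans = [h for h in humans if meta.frame.at[h, "population"] in keep]
    hi = np.array([dm.labels.index(h) for h in humans])
    members = np.array([dm.labels.index(s) for s in captive + wild])
    nc = len(captive)

    def t_of(order):
        xs = dm.values[np.ix_(order[:nc], hi)].ravel()
        ys = dm.values[np.ix_(order[nc:], hi)].ravel()
        return two_sample_t(xs, ys)

    t_obs = t_of(members)
    k = 0
    for _ in range(n_permutations):
        perm = rng.permutation(members)
        t_p = t_of(perm)
        if tail == "two-sided":
            k += abs(t_p) >= abs(t_obs) - _EPS
        else:
            k += t_p <= t_obs + _EPS
    return t_obs, (1 + k) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_scan_results(results, path) -> None:
    cols = (
        "family\tn_wild_pairs\tn_captive_pairs\tmean_wild\tmean_captive\t"
        "t_statistic\tp_value\ttail\tn_permutations\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for r in results:
            fh.write(
                f"{r.family}\t{r.n_wild_pairs}\t{r.n_captive_pairs}\t"
                f"{r.mean_wild:.10g}\t{r.mean_captive:.10g}\t"
                f"{r.t_statistic:.10g}\t{r.p_value:.10g}\t{r.tail}\t"
                f"{r.n_permutations}\n"
            )


def write_long_distances(dm: DistanceMatrix, meta: SampleMetadata, families, path) -> None:
    """Boxplot-ready long-format TSV of every family-to-human pairwise distance."""
    with open(path, "w") as fh:
        fh.write("family\tstatus\tsample_id\thuman_id\tdistance\n")
        for fam in families:
            for status in ("wild", "captive"):
                group = [
                    s for s in meta.samples_where(family=fam, status=status)
                    if s in dm.labels
                ]
                humans = [
                    h for h in meta.samples_where(status="human") if h in dm.labels
                ]
                for s in group:
                    for h in humans:
                        fh.write(
                            f"{fam}\t{status}\t{s}\t{h}\t{dm.between(s, h):.10g}\n"
                        )
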