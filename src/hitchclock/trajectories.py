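"""Allele-frequency time courses: loading, clustering, lineage reconstruction.

The observable of the evolution experiment is a table of per-mutation
population frequencies measured by Sanger peak ratios at a handful of
generations.  Mutations that rode to fixation on the same genome move in
lockstep, so co-fixing mutations are grouped into clusters (one cluster ==
one sweeping genome), cluster means reconstruct genome-lineage frequencies,
and clone-isolation counts give an exact-binomial consistency check of the
Sanger frequencies.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import binom, binomtest

__all__ = [
    "TrajectoryTable",
    "Cluster",
    "ClusterSet",
    "GenomeLineage",
    "CloneCheck",
    "load_trajectories",
    "write_trajectories",
    "cluster_trajectories",
    "cluster_mean_trajectory",
    "build_lineages",
    "clone_consistency_test",
    "SANGER_SD",
    "DETECTION_FLOOR",
    "DEFAULT_TOLERANCE",
]

CATEGORIES = ("synonymous", "non-synonymous", "non-coding")

#: Standard deviation of a Sanger peak-ratio frequency estimate.
SANGER_SD = 0.062
#: Sanger detection limit; frequencies below it are censored, not zero.
DETECTION_FLOOR = 0.05
#: Default clustering tolerance, two Sanger standard deviations.
DEFAULT_TOLERANCE = 2 * SANGER_SD


class TrajectoryParseError(ValueError):
    """A trajectory table violated the S2 TSV dialect or its invariants."""


@dataclass
class TrajectoryTable:
    """Per-mutation frequency time series with category labels.

    ``freq`` holds fractions in [0, 1] indexed by mutation id with integer
    generation columns; censored (below detection limit) cells are NaN in
    ``freq`` and True in ``censored``.  ``meta`` carries ``gene``,
    ``category`` and an optional ``cluster`` label per mutation.
    """

    meta: pd.DataFrame
    freq: pd.DataFrame
    censored: pd.DataFrame

    def __post_init__(self) -> None:
        gens = list(self.freq.columns)
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise TrajectoryParseError(
                f"generations must be strictly increasing, got {gens}"
            )
        if not self.meta.index.equals(self.freq.index):
            raise TrajectoryParseError("meta and freq must share mutation ids")
        if self.meta.index.has_duplicates:
            dupes = self.meta.index[self.meta.index.duplicated()].tolist()
            raise TrajectoryParseError(f"duplicated mutation ids: {dupes}")
        bad_cat = set(self.meta["category"]) - set(CATEGORIES)
        if bad_cat:
            raise TrajectoryParseError(f"unknown categories: {sorted(bad_cat)}")
        vals = self.freq.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise TrajectoryParseError("frequencies must lie in [0, 1]")

    @property
    def generations(self) -> list[int]:
        return [int(g) for g in self.freq.columns]

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.freq.index)

    def __len__(self) -> int:
        return len(self.freq)

    def filled(self, fill: float = 0.0) -> pd.DataFrame:
        """Frequencies with censored cells replaced (for distances/plots)."""
        return self.freq.fillna(fill)


def _parse_gen_columns(columns: Sequence[str]) -> list[int]:
    gens = []
    for c in columns:
        m = re.fullmatch(r"g(\d+)", c)
        if not m:
            raise TrajectoryParseError(
                f"bad generation column {c!r}: expected g<generation>"
            )
        gens.append(int(m.group(1)))
    return gens


def load_trajectories(path, dialect: str = "s2") -> TrajectoryTable:
    """Read an S2-dialect TSV of percent frequencies.

    Header: ``mutation_id  gene  category  cluster  g<GEN> ...``; cells are
    percent values, with ``<5``-style entries marking censored observations
    (kept as censored, never zeroed).
    """
    if dialect != "s2":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    fixed_cols = ["mutation_id", "gene", "category", "cluster"]
    if list(raw.columns[:4]) != fixed_cols:
        raise TrajectoryParseError(
            f"expected leading columns {fixed_cols}, got {list(raw.columns[:4])}"
        )
    gen_cols = list(raw.columns[4:])
    gens = _parse_gen_columns(gen_cols)
    if raw["mutation_id"].duplicated().any():
        dupes = raw.loc[raw["mutation_id"].duplicated(), "mutation_id"].tolist()
        raise TrajectoryParseError(f"duplicated mutation ids: {dupes}")

    freq = np.full((len(raw), len(gens)), np.nan)
    cens = np.zeros_like(freq, dtype=bool)
    for i, row in enumerate(raw[gen_cols].itertuples(index=False)):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell.startswith("<"):
                cens[i, j] = True
                continue
            if cell == "":
                raise TrajectoryParseError(
                    f"empty frequency cell at row {i}, column {gen_cols[j]}"
                )
            try:
                pct = float(cell)
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"unparseable frequency {cell!r} at row {i}"
                ) from exc
            if not 0.0 <= pct <= 100.0:
                raise TrajectoryParseError(
                    f"frequency {pct} out of [0, 100]% at row {i}, "
                    f"column {gen_cols[j]}"
                )
            freq[i, j] = pct / 100.0

    index = pd.Index(raw["mutation_id"], name="mutation_id")
    meta = pd.DataFrame(
        {
            "gene": raw["gene"].values,
            "category": raw["category"].values,
            "cluster": raw["cluster"].replace("", None).values,
        },
        index=index,
    )
    return TrajectoryTable(
        meta=meta,
        freq=pd.DataFrame(freq, index=index, columns=gens),
        censored=pd.DataFrame(cens, index=index, columns=gens),
    )


def write_trajectories(table: TrajectoryTable, path, floor: float = DETECTION_FLOOR) -> None:
    """Write the S2-dialect TSV (percent values, ``<floor`` for censored)."""
    censored_token = f"<{floor * 100:g}"
    with open(path, "w", encoding="utf-8") as fh:
        gen_cols = "\t".join(f"g{g}" for g in table.generations)
        fh.write(f"mutation_id\tgene\tcategory\tcluster\t{gen_cols}\n")
        for mid in table.mutation_ids:
            meta = table.meta.loc[mid]
            cluster = "" if pd.isna(meta["cluster"]) else str(meta["cluster"])
            cells = []
            for g in table.freq.columns:
                if table.censored.at[mid, g]:
                    cells.append(censored_token)
                else:
                    cells.append(format(table.freq.at[mid, g] * 100.0, ".10g"))
            fh.write(
                f"{mid}\t{meta['gene']}\t{meta['category']}\t{cluster}\t"
                + "\t".join(cells) + "\n"
            )


@dataclass
class Cluster:
    """One group of co-fixing mutations — the footprint of one genome."""

    cluster_id: str
    members: list[str]
    onset_generation: int | None
    categories: Counter
    mean: pd.Series
    se: pd.Series


@dataclass
class ClusterSet:
    """Exhaustive, disjoint partition of the table's mutations."""

    clusters: list[Cluster]
    tolerance: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & set(c.members):
                raise ValueError("cluster membership is not disjoint")
            seen.update(c.members)

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, cluster_id: str) -> Cluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    @property
    def assignment(self) -> dict[str, str]:
        return {m: c.cluster_id for c in self.clusters for m in c.members}


def cluster_mean_trajectory(
    members: Iterable[str],
    table: TrajectoryTable,
    fallback_sd: float = SANGER_SD,
) -> tuple[pd.Series, pd.Series]:
    """Mean and standard error of member frequencies per time point.

    Censored cells enter the mean as 0 (they are below the detection limit
    by definition).  Singleton clusters have no between-member spread, so
    their SE falls back to the Sanger measurement SD.
    """
    members = list(members)
    if not members:
        raise ValueError("cluster must be non-empty")
    sub = table.filled(0.0).loc[members]
    mean = sub.mean(axis=0)
    if len(members) == 1:
        se = pd.Series(fallback_sd, index=mean.index)
    else:
        se = sub.std(axis=0, ddof=1) / np.sqrt(len(members))
    return mean, se


def _onset_generation(mean: pd.Series, floor: float) -> int | None:
    above = mean[mean > floor]
    return int(above.index[0]) if len(above) else None


def cluster_trajectories(
    table: TrajectoryTable,
    tolerance: float = DEFAULT_TOLERANCE,
    floor: float = DETECTION_FLOOR,
    fallback_sd: float = SANGER_SD,
) -> ClusterSet:
    """Group mutations whose trajectories move together into genome clusters.

    Single-linkage agglomeration under the Chebyshev distance
    ``d(i, j) = max_t |f_i(t) - f_j(t)|`` (censored treated as 0), merging
    while ``d <= tolerance``.  The default tolerance is two Sanger standard
    deviations, 0.124.  Rows are ordered lexicographically by mutation id
    before linkage, so the partition is invariant to input row order.
    """
    if len(table) == 0:
        raise ValueError("cannot cluster an empty table")
    ids = sorted(table.mutation_ids)
    X = table.filled(0.0).loc[ids].to_numpy(dtype=float)
    if len(ids) == 1:
        labels = np.array([1])
    else:
        D = pdist(X, metric="chebyshev")
        Z = linkage(D, method="single")
        labels = fcluster(Z, t=tolerance, criterion="distance")

    groups: dict[int, list[str]] = {}
    for mid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(mid)

    built = []
    for members in groups.values():
        mean, se = cluster_mean_trajectory(members, table, fallback_sd)
        built.append(
            (
                _onset_generation(mean, floor),
                members[0],
                members,
                mean,
                se,
            )
        )
    # order by onset (never-detected clusters last), tie-break on first member
    built.sort(key=lambda t: (t[0] is None, t[0], t[1]))
    width = max(2, len(str(len(built))))
    clusters = [
        Cluster(
            cluster_id=f"C{i + 1:0{width}d}",
            members=members,
            onset_generation=onset,
            categories=Counter(table.meta.loc[members, "category"]),
            mean=mean,
            se=se,
        )
        for i, (onset, _first, members, mean, se) in enumerate(built)
    ]
    return ClusterSet(clusters=clusters, tolerance=tolerance)


@dataclass
class GenomeLineage:
    """A root-to-terminal chain of clusters acquired by one genome lineage."""

    lineage_id: str
    clusters: list[str]
    frequency: pd.Series
    fate: str  # 'fixed-in-line' | 'extinct' | 'interfered'

    def __post_init__(self) -> None:
        if self.fate not in ("fixed-in-line", "extinct", "interfered"):
            raise ValueError(f"unknown fate {self.fate!r}")


def terminal_frequency(mean: pd.Series, window: int = 2) -> float:
    """Frequency at the end of a series, averaged over the last ``window``
    sample points so a single noisy observation cannot flip a fate call."""
    return float(mean.iloc[-window:].mean())


def classify_fate(
    mean: pd.Series,
    floor: float = DETECTION_FLOOR,
    fixed_threshold: float = 0.95,
) -> str:
    """Fate of a cluster/lineage trajectory at the end of observation.

    Fixation is absorbing in an asexual population, so a trajectory that
    truly reached the fixation threshold can only sit at ~1 afterwards,
    with occasional measurement dips; a cluster declining at the series
    end (lost to interference) drops and stays low.  ``fixed-in-line``
    therefore requires the trajectory to have reached ``fixed_threshold``
    at some point and to average a clear majority from that point on.
    ``extinct`` means the terminal frequency fell to the detection floor;
    anything else is still contending (``interfered``).
    """
    reached = np.flatnonzero(mean.to_numpy() >= fixed_threshold)
    if len(reached) and float(mean.iloc[reached[0]:].mean()) >= 0.7:
        return "fixed-in-line"
    if terminal_frequency(mean) <= floor:
        return "extinct"
    return "interfered"


def _contained_within(
    child: Cluster, parent: Cluster, se_factor: float = 2.0
) -> bool:
    margin = se_factor * (parent.se + child.se)
    return bool(np.all(child.mean <= parent.mean + margin))


def build_lineages(
    clusters: ClusterSet,
    floor: float = DETECTION_FLOOR,
    fixed_threshold: float = 0.95,
) -> list[GenomeLineage]:
    """Nest clusters into genome lineages by frequency-envelope containment.

    Later mutations arise on genomes already carrying earlier clusters, so a
    descendant cluster's frequency can never exceed its ancestor's.  Clusters
    are ordered by onset generation (ties broken by higher overall frequency,
    i.e. the earlier-sweeping cluster first); each cluster attaches to the
    latest preceding cluster whose mean trajectory bounds it everywhere
    within twice the combined SE, and roots start new lineages.  Every
    root-to-leaf path is one lineage, its frequency that of its most recent
    (terminal) cluster, its fate read off the terminal frequency at the
    last time point: >= ``fixed_threshold`` fixed-in-line, <= ``floor``
    extinct, otherwise interfered (still contending when observation ends).
    """
    ordered = sorted(
        (c for c in clusters if c.onset_generation is not None),
        key=lambda c: (c.onset_generation, -float(c.mean.sum()), c.cluster_id),
    )
    never_detected = [c for c in clusters if c.onset_generation is None]

    parent: dict[str, str | None] = {}
    for i, c in enumerate(ordered):
        parent[c.cluster_id] = None
        for p in reversed(ordered[:i]):
            if _contained_within(c, p):
                parent[c.cluster_id] = p.cluster_id
                break

    children: dict[str | None, list[str]] = {}
    for cid, pid in parent.items():
        children.setdefault(pid, []).append(cid)

    by_id = {c.cluster_id: c for c in ordered}
    paths: list[list[str]] = []

    def walk(cid: str, prefix: list[str]) -> None:
        path = prefix + [cid]
        kids = children.get(cid, [])
        if not kids:
            paths.append(path)
        else:
            for k in kids:
                walk(k, path)

    for root in children.get(None, []):
        walk(root, [])

    lineages = []
    for i, path in enumerate(paths):
        terminal = by_id[path[-1]]
        fate = classify_fate(terminal.mean, floor, fixed_threshold)
        lineages.append(
            GenomeLineage(
                lineage_id=f"L{i + 1:02d}",
                clusters=path,
                frequency=terminal.mean,
                fate=fate,
            )
        )
    for j, c in enumerate(never_detected):
        lineages.append(
            GenomeLineage(
                lineage_id=f"L{len(paths) + j + 1:02d}",
                clusters=[c.cluster_id],
                frequency=c.mean,
                fate="extinct",
            )
        )
    return lineages


@dataclass
class CloneCheck:
    """Exact-binomial agreement between clone counts and a Sanger frequency."""

    carriers: int
    clones_total: int
    sanger_frequency: float
    consistent: bool
    exact_binomial_p: float

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.clones_total:
            raise ValueError("need 0 <= carriers <= clones_total")


def clone_consistency_test(
    carriers: int, clones_total: int, sanger_frequency: float
) -> CloneCheck:
    """Is a clone-isolation count compatible with the Sanger frequency?

    ``consistent`` is true iff ``carriers`` falls inside the central 95%
    probability region of Binomial(clones_total, sanger_frequency); the exact
    two-sided binomial p-value is reported alongside.
    """
    if not 0 <= carriers <= clones_total:
        raise ValueError("need 0 <= carriers <= clones_total")
    if not 0.0 <= sanger_frequency <= 1.0:
        raise ValueError("sanger_frequency must lie in [0, 1]")
    lo = int(binom.ppf(0.025, clones_total, sanger_frequency))
    hi = int(binom.ppf(0.975, clones_total, sanger_frequency))
    pval = binomtest(carriers, clones_total, sanger_frequency).pvalue
    return CloneCheck(
        carriers=carriers,
        clones_total=clones_total,
        sanger_frequency=sanger_frequency,
        consistent=lo <= carriers <= hi,
        exact_binomial_p=float(pval),
    )
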