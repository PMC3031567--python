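"""Reference-profile database: per-compound sets of rank-ordered expression profiles.

A reference profile records one compound-vs-vehicle hybridisation as a
*signed rank* vector over a fixed gene universe: the most differentially
expressed probe carries |rank| = N (the universe size), the least carries
|rank| = 1, and the sign encodes the regulation direction (+ up, - down)
relative to the vehicle control.  All profiles sharing a compound form a
reference set; the number of profiles in a set is its SetSize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DB_COLUMNS = ("compound", "profile_id", "probe_id", "value")


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered collection of unique probe identifiers."""

    probe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 2:
            raise ValueError("gene universe needs at least 2 probes")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe IDs in gene universe")
        # index lookup built once; frozen dataclass so stash via __dict__
        object.__setattr__(
            self, "_index", {p: i for i, p in enumerate(self.probe_ids)}
        )

    @property
    def n_genes(self) -> int:
        return len(self.probe_ids)

    def index_of(self, probe_id: str) -> int:
        try:
            return self._index[probe_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"probe {probe_id!r} not in gene universe") from None

    def __contains__(self, probe_id: object) -> bool:
        return probe_id in self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return self.n_genes


@dataclass(frozen=True)
class ReferenceProfile:
    """One compound-vs-vehicle hybridisation as signed ranks over the universe.

    ``ranks`` is aligned with ``universe.probe_ids``; absolute values form a
    permutation of 1..N and the sign carries the regulation direction.
    """

    profile_id: str
    compound: str
    universe: GeneUniverse
    ranks: np.ndarray  # int array aligned with universe.probe_ids

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=np.int64)
        object.__setattr__(self, "ranks", ranks)
        n = self.universe.n_genes
        if ranks.shape != (n,):
            raise ValueError(
                f"profile {self.profile_id!r}: expected {n} ranks, got {ranks.shape}"
            )
        mags = np.sort(np.abs(ranks))
        if not np.array_equal(mags, np.arange(1, n + 1)):
            raise ValueError(
                f"profile {self.profile_id!r}: |ranks| are not a permutation of 1..{n}"
            )

    def signed_rank(self, probe_id: str) -> int:
        return int(self.ranks[self.universe.index_of(probe_id)])

    def as_mapping(self) -> dict[str, int]:
        return dict(zip(self.universe.probe_ids, self.ranks.tolist()))


@dataclass(frozen=True)
class ReferenceSet:
    """All reference profiles for one compound; SetSize = number of profiles."""

    compound: str
    profiles: tuple[ReferenceProfile, ...]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError(f"reference set {self.compound!r} is empty")
        for p in self.profiles:
            if p.compound != self.compound:
                raise ValueError(
                    f"profile {p.profile_id!r} labelled {p.compound!r}, "
                    f"expected {self.compound!r}"
                )

    @property
    def set_size(self) -> int:
        return len(self.profiles)

    @property
    def universe(self) -> GeneUniverse:
        return self.profiles[0].universe

    def mean_ranks(self) -> np.ndarray:
        """Mean signed rank per probe across the set's profiles.

        The set-level connection score is linear in the profile ranks, so
        this single vector suffices for scoring against any signature.
        """
        return np.mean([p.ranks for p in self.profiles], axis=0)


@dataclass(frozen=True)
class ReferenceDatabase:
    universe: GeneUniverse
    sets: tuple[ReferenceSet, ...]

    def __post_init__(self) -> None:
        names = [s.compound for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound keys in reference database")
        for s in self.sets:
            if s.universe is not self.universe and s.universe != self.universe:
                raise ValueError(
                    f"reference set {s.compound!r} uses a different gene universe"
                )

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def significance_threshold(self) -> float:
        """Default p-value threshold 1/n_sets: one expected false connection
        per signature queried against the whole database."""
        return 1.0 / self.n_sets

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(s.compound for s in self.sets)

    def get_set(self, compound: str) -> ReferenceSet:
        for s in self.sets:
            if s.compound == compound:
                return s
        raise KeyError(f"compound {compound!r} not in database")


def rank_profile(
    values: Mapping[str, float] | Sequence[tuple[str, float]],
) -> dict[str, int]:
    """Convert signed differential-expression values to signed ranks.

    The probe with the largest |value| receives |rank| = N, the smallest
    |rank| = 1; the sign of the rank is the sign of the value.  Ties in
    |value| are broken by stable input order (the earlier probe gets the
    larger |rank|).  A zero value is assigned sign + by convention and
    logged, since its direction is undefined.
    """
    items = list(values.items()) if isinstance(values, Mapping) else list(values)
    probes = [p for p, _ in items]
    if len(set(probes)) != len(probes):
        raise ValueError("duplicate probe IDs in profile values")
    vals = np.asarray([v for _, v in items], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = [p for p, v in zip(probes, vals) if not np.isfinite(v)]
        raise ValueError(f"non-finite differential values for probes {bad}")
    n = len(vals)
    if n == 0:
        raise ValueError("empty profile")
    n_zero = int(np.count_nonzero(vals == 0))
    if n_zero:
        logger.warning(
            "%d probe(s) with zero differential value: sign set to + by convention",
            n_zero,
        )
    # stable sort on -|value|: ties keep input order, earlier probe ranks higher
    order = np.argsort(-np.abs(vals), kind="stable")
    mags = np.empty(n, dtype=np.int64)
    mags[order] = np.arange(n, 0, -1)
    signs = np.where(vals < 0, -1, 1)
    return {p: int(s * m) for p, s, m in zip(probes, signs, mags)}


def _profiles_from_long(
    table: pd.DataFrame, universe: GeneUniverse, ranked: bool
) -> list[ReferenceProfile]:
    profiles: list[ReferenceProfile] = []
    for (compound, profile_id), grp in table.groupby(
        ["compound", "profile_id"], sort=False
    ):
        dup = grp["probe_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate probe {grp['probe_id'][dup].iloc[0]!r} in profile "
                f"{profile_id!r}"
            )
        probes = set(grp["probe_id"])
        missing = [p for p in universe.probe_ids if p not in probes]
        if missing:
            raise ValueError(
                f"profile {profile_id!r} is missing probe(s) {missing[:5]} "
                f"({len(missing)} of {universe.n_genes} absent)"
            )
        if ranked:
            mapping = dict(zip(grp["probe_id"], grp["value"].astype(np.int64)))
        else:
            mapping = rank_profile(list(zip(grp["probe_id"], grp["value"])))
        ranks = np.array([mapping[p] for p in universe.probe_ids], dtype=np.int64)
        profiles.append(
            ReferenceProfile(
                profile_id=str(profile_id),
                compound=str(compound),
                universe=universe,
                ranks=ranks,
            )
        )
    return profiles


def database_from_profiles(profiles: Iterable[ReferenceProfile]) -> ReferenceDatabase:
    """Group profiles by compound (first-appearance order) into a database."""
    by_compound: dict[str, list[ReferenceProfile]] = {}
    for p in profiles:
        by_compound.setdefault(p.compound, []).append(p)
    if not by_compound:
        raise ValueError("no profiles supplied")
    universe = next(iter(by_compound.values()))[0].universe
    sets = tuple(
        ReferenceSet(compound=c, profiles=tuple(ps)) for c, ps in by_compound.items()
    )
    return ReferenceDatabase(universe=universe, sets=sets)


def read_reference_db(path, ranked: bool = False) -> ReferenceDatabase:
    """Read a reference database from tab-delimited long format.

    Columns: ``compound  profile_id  probe_id  value``.  ``value`` is the
    signed differential-expression amplitude and is converted to signed
    ranks per profile; with ``ranked=True`` it is taken as an already
    computed integer signed rank.  The gene universe is the union of probe
    IDs in first-appearance order; every profile must cover it exactly.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str, 2: str})
    missing_cols = [c for c in DB_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"reference DB {path} missing column(s) {missing_cols}")
    probe_order = table["probe_id"].drop_duplicates().tolist()
    universe = GeneUniverse(tuple(probe_order))
    profiles = _profiles_from_long(table, universe, ranked=ranked)
    return database_from_profiles(profiles)


def write_reference_db(db: ReferenceDatabase, path, ranked: bool = True) -> None:
    """Write a database in the long tab-delimited format.

    With ``ranked=True`` (default) the ``value`` column holds the signed
    integer ranks, so a read with ``ranked=True`` round-trips exactly.
    """
    rows = []
    for s in db.sets:
        for p in s.profiles:
            rows.append(
                pd.DataFrame(
                    {
                        "compound": s.compound,
                        "profile_id": p.profile_id,
                        "probe_id": db.universe.probe_ids,
                        "value": p.ranks,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
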