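"""Synthetic data: null and planted-connection reference databases, and
two-group expression matrices with planted differentially expressed probes.

Every generator is a pure function of its parameters and seed.  The
reference-database generators emulate a compound-profile database at desk
scale: a *null* database is i.i.d. random signed-rank permutations; a
*planted* database blends, per profile of a chosen compound, a "perfect"
differential-expression pattern (target genes at the top ranks with
concordant — or, for an inverse plant, anti-concordant — signs) with a
random pattern, then re-ranks, so the result is a valid signed-rank
permutation at every planting strength.  The expression generator draws
Gaussian log2 intensities with a mean shift on the planted probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refdb import (
    GeneUniverse,
    ReferenceDatabase,
    ReferenceProfile,
    ReferenceSet,
)
from .signature import ExpressionMatrix, GeneSignature


@dataclass(frozen=True)
class PlantSpec:
    """A compound whose profiles carry a detectable connection signal.

    ``strength`` interpolates between pure noise (0) and the target genes
    forced to the very top ranks with the prescribed signs (1).
    ``direction`` ``mimic`` plants signs concordant with the target signs
    (positive setscore against a matching signature); ``inverse`` plants
    the opposite signs (negative setscore).
    """

    compound: str
    target_genes: tuple[tuple[str, int], ...]
    strength: float = 1.0
    direction: str = "mimic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if self.direction not in ("mimic", "inverse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.target_genes:
            raise ValueError("plant needs at least one target gene")


@dataclass(frozen=True)
class DEPlantSpec:
    """Parameters of a two-group log2 expression matrix with planted DE."""

    n_genes: int = 1000
    n_de: int = 40
    effect_log2: float = 2.0
    sigma: float = 0.5
    baseline_log2: float = 7.0
    n_control: int = 20
    n_case: int = 20

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed the universe size")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("each group needs >= 2 samples")


def _probe_ids(n_genes: int) -> tuple[str, ...]:
    width = len(str(n_genes))
    return tuple(f"g{str(i + 1).zfill(width)}_at" for i in range(n_genes))


def _random_profile(
    rng: np.random.Generator, universe: GeneUniverse, profile_id: str, compound: str
) -> ReferenceProfile:
    n = universe.n_genes
    mags = rng.permutation(n) + 1
    signs = rng.integers(0, 2, size=n) * 2 - 1
    return ReferenceProfile(
        profile_id=profile_id,
        compound=compound,
        universe=universe,
        ranks=mags * signs,
    )


def make_null_db(
    n_sets: int,
    profiles_per_set: int,
    n_genes: int,
    seed: int,
    compound_prefix: str = "cmp",
) -> ReferenceDatabase:
    """Database of i.i.d. uniform random signed-rank profiles."""
    if min(n_sets, profiles_per_set, n_genes) < 1:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    universe = GeneUniverse(_probe_ids(n_genes))
    width = len(str(n_sets))
    sets = []
    for s in range(n_sets):
        compound = f"{compound_prefix}{str(s + 1).zfill(width)}"
        profiles = tuple(
            _random_profile(rng, universe, f"{compound}_p{r + 1}", compound)
            for r in range(profiles_per_set)
        )
        sets.append(ReferenceSet(compound=compound, profiles=profiles))
    return ReferenceDatabase(universe=universe, sets=tuple(sets))


def _planted_profile(
    rng: np.random.Generator,
    universe: GeneUniverse,
    profile_id: str,
    plant: PlantSpec,
) -> ReferenceProfile:
    """Convex blend of a perfect plant pattern with a random pattern, re-ranked.

    The perfect pattern puts target gene j at signed value +/-(N - j); the
    remaining magnitudes 1..N-m go to non-targets in random order with
    random signs.  Blended values v = strength * perfect + (1 - strength) *
    random are re-ranked by |v| with sign(v), so |ranks| always form a
    permutation.
    """
    n = universe.n_genes
    m = len(plant.target_genes)
    flip = -1 if plant.direction == "inverse" else 1

    perfect = np.empty(n, dtype=float)
    target_idx = np.array(
        [universe.index_of(p) for p, _ in plant.target_genes], dtype=np.intp
    )
    target_signs = np.array([s for _, s in plant.target_genes], dtype=float) * flip
    perfect[target_idx] = target_signs * (n - np.arange(m))
    rest = np.setdiff1d(np.arange(n), target_idx)
    rest_mags = rng.permutation(n - m) + 1
    rest_signs = rng.integers(0, 2, size=n - m) * 2 - 1
    perfect[rest] = rest_mags * rest_signs

    random_part = (rng.permutation(n) + 1) * (rng.integers(0, 2, size=n) * 2 - 1)
    v = plant.strength * perfect + (1.0 - plant.strength) * random_part

    order = np.argsort(-np.abs(v), kind="stable")
    mags_out = np.empty(n, dtype=np.int64)
    mags_out[order] = np.arange(n, 0, -1)
    signs_out = np.where(v < 0, -1, 1)
    return ReferenceProfile(
        profile_id=profile_id,
        compound=plant.compound,
        universe=universe,
        ranks=mags_out * signs_out,
    )


def make_planted_db(
    n_sets: int,
    profiles_per_set: int,
    n_genes: int,
    seed: int,
    plants: tuple[PlantSpec, ...] | list[PlantSpec] = (),
    compound_prefix: str = "cmp",
) -> ReferenceDatabase:
    """Null database in which the named compounds carry planted signal.

    Plant compounds must be distinct; their names replace the first
    ``len(plants)`` null compounds so n_sets is unchanged.  Target genes
    must be drawn from the generated universe (``g0001_at`` style IDs).
    """
    names = [p.compound for p in plants]
    if len(set(names)) != len(names):
        raise ValueError("plant compounds must be distinct")
    if len(plants) > n_sets:
        raise ValueError("more plants than reference sets")
    base = make_null_db(n_sets, profiles_per_set, n_genes, seed, compound_prefix)
    rng = np.random.default_rng((seed + 0x5EED) % 2**31)
    universe = base.universe
    for plant in plants:
        for probe, _ in plant.target_genes:
            if probe not in universe:
                raise ValueError(f"plant target {probe!r} not in universe")
    new_sets = list(base.sets)
    for i, plant in enumerate(plants):
        profiles = tuple(
            _planted_profile(rng, universe, f"{plant.compound}_p{r + 1}", plant)
            for r in range(profiles_per_set)
        )
        new_sets[i] = ReferenceSet(compound=plant.compound, profiles=profiles)
    return ReferenceDatabase(universe=universe, sets=tuple(new_sets))


def signature_from_plant(plant: PlantSpec, label: str | None = None) -> GeneSignature:
    """The signature that matches a plant's targets (signs as planted targets)."""
    return GeneSignature(
        entries=tuple(plant.target_genes), label=label or f"sig:{plant.compound}"
    )


def make_expression(
    spec: DEPlantSpec, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group Gaussian log2 expression matrix with planted shifts.

    Control samples draw Normal(baseline, sigma) per probe; case samples
    add +/- effect_log2 on the first n_de probes (sign random per probe).
    Returns the matrix and a truth table (probe_id, sign) of planted probes.
    """
    rng = np.random.default_rng(seed)
    probes = _probe_ids(spec.n_genes)
    n_samples = spec.n_control + spec.n_case
    values = rng.normal(spec.baseline_log2, spec.sigma, (spec.n_genes, n_samples))
    de_idx = np.arange(spec.n_de)
    de_signs = rng.integers(0, 2, size=spec.n_de) * 2 - 1
    values[de_idx, spec.n_control :] += de_signs[:, None] * spec.effect_log2

    sample_ids = [f"ctrl{i + 1}" for i in range(spec.n_control)] + [
        f"case{i + 1}" for i in range(spec.n_case)
    ]
    groups = {s: ("control" if s.startswith("ctrl") else "case") for s in sample_ids}
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=list(probes), columns=sample_ids),
        groups=groups,
    )
    truth = pd.DataFrame(
        {"probe_id": [probes[i] for i in de_idx], "sign": de_signs}
    )
    return expr, truth
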