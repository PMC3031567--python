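"""Connection scoring of signed gene signatures against reference sets.

The per-profile connection strength is the dot product of the profile's
signed ranks with the signature's regulation signs, normalised by the
maximum attainable value (the signature genes occupying the top-m ranks
with fully concordant signs), so every score lies in [-1, 1].  The
set-level *setscore* is the arithmetic mean of the per-profile scores.

Significance is assessed against the empirical null of random signatures:
m distinct genes drawn uniformly without replacement, each with an
independent random +/- sign.  The p-value is two-sided on |setscore|.
Querying a whole database, a connection is declared significant when its
p-value falls strictly below 1/n_sets, the threshold at which one false
connection per signature is expected by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import comb
from typing import Sequence

import numpy as np

from .refdb import ReferenceDatabase, ReferenceProfile, ReferenceSet
from .signature import GeneSignature

EXHAUSTIVE_CAP = 2_000_000  # max enumerated null signatures


@dataclass(frozen=True)
class NullModel:
    """Empirical-null configuration.

    mode ``monte_carlo`` draws K random signatures (seeded); ``exhaustive``
    enumerates all C(N, m) * 2^m signed signatures and is only permitted
    when that count is at most ``EXHAUSTIVE_CAP``.
    """

    mode: str = "monte_carlo"
    K: int = 100_000
    seed: int = 0
    signed: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("monte_carlo", "exhaustive"):
            raise ValueError(f"unknown null mode {self.mode!r}")
        if self.mode == "monte_carlo" and self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass(frozen=True)
class ConnectionResult:
    compound: str
    setscore: float
    p_value: float
    significant: bool
    set_size: int
    signature_label: str


def _max_score(n_genes: int, m: int) -> float:
    """Sum of the top-m rank magnitudes N + (N-1) + ... + (N-m+1)."""
    return float(sum(n_genes - j for j in range(m)))


def _signature_indices(
    sig: GeneSignature, universe, missing: str = "error"
) -> tuple[np.ndarray, np.ndarray]:
    """Map signature probes to universe indices; signs alongside.

    ``missing`` policy for probes absent from the universe: ``error``
    (default) raises; ``drop`` removes them (the normalisation then uses
    the reduced signature length).
    """
    if missing not in ("error", "drop"):
        raise ValueError(f"unknown missing-gene policy {missing!r}")
    idx: list[int] = []
    signs: list[int] = []
    absent: list[str] = []
    for probe, sign in sig.entries:
        if probe in universe:
            idx.append(universe.index_of(probe))
            signs.append(sign)
        else:
            absent.append(probe)
    if absent and missing == "error":
        raise KeyError(
            f"signature probe(s) {absent[:5]} not in the reference universe "
            "(pass missing='drop' to score on the overlap)"
        )
    if not idx:
        raise ValueError("no signature probe overlaps the reference universe")
    return np.asarray(idx, dtype=np.intp), np.asarray(signs, dtype=np.int64)


def connection_strength(
    profile: ReferenceProfile, sig: GeneSignature, missing: str = "error"
) -> float:
    """Normalised signed-rank score of one profile against a signature."""
    idx, signs = _signature_indices(sig, profile.universe, missing)
    raw = float(np.dot(profile.ranks[idx], signs))
    return raw / _max_score(profile.universe.n_genes, len(idx))


def setscore(refset: ReferenceSet, sig: GeneSignature, missing: str = "error") -> float:
    """Mean connection strength over the set's profiles."""
    idx, signs = _signature_indices(sig, refset.universe, missing)
    raw = float(np.dot(refset.mean_ranks()[idx], signs))
    return raw / _max_score(refset.universe.n_genes, len(idx))


def _draw_null_signatures(
    n_genes: int, m: int, K: int, rng: np.random.Generator, signed: bool
) -> tuple[np.ndarray, np.ndarray]:
    """K random signatures as (K, m) index and sign arrays."""
    # argpartition of uniform noise = uniform m-subset per row
    noise = rng.random((K, n_genes))
    idx = np.argpartition(noise, m - 1, axis=1)[:, :m].astype(np.intp)
    if signed:
        signs = rng.integers(0, 2, size=(K, m)) * 2 - 1
    else:
        signs = np.ones((K, m), dtype=np.int64)
    return idx, signs


def _null_scores_from_draws(
    mean_ranks: np.ndarray, idx: np.ndarray, signs: np.ndarray, c_max: float
) -> np.ndarray:
    return (mean_ranks[idx] * signs).sum(axis=1) / c_max


def _exhaustive_null(
    mean_ranks: np.ndarray, n_genes: int, m: int, c_max: float, signed: bool
) -> np.ndarray:
    n_sigs = comb(n_genes, m) * (2**m if signed else 1)
    if n_sigs > EXHAUSTIVE_CAP:
        raise ValueError(
            f"exhaustive null would enumerate {n_sigs} signatures "
            f"(cap {EXHAUSTIVE_CAP}); use monte_carlo"
        )
    sign_patterns = (
        list(product((1, -1), repeat=m)) if signed else [(1,) * m]
    )
    scores = np.empty(n_sigs, dtype=float)
    pos = 0
    for subset in combinations(range(n_genes), m):
        base = mean_ranks[list(subset)]
        for pat in sign_patterns:
            scores[pos] = float(np.dot(base, pat)) / c_max
            pos += 1
    return scores


def null_distribution(
    refset: ReferenceSet, m: int, null: NullModel
) -> np.ndarray:
    """Empirical distribution of setscore under random signatures of length m."""
    n_genes = refset.universe.n_genes
    if m > n_genes:
        raise ValueError(f"signature length {m} exceeds universe size {n_genes}")
    mean_ranks = refset.mean_ranks()
    c_max = _max_score(n_genes, m)
    if null.mode == "exhaustive":
        return _exhaustive_null(mean_ranks, n_genes, m, c_max, null.signed)
    rng = np.random.default_rng(null.seed)
    idx, signs = _draw_null_signatures(n_genes, m, null.K, rng, null.signed)
    return _null_scores_from_draws(mean_ranks, idx, signs, c_max)


def p_value(observed: float, nulldist: np.ndarray, exhaustive: bool = False) -> float:
    """Two-sided empirical p-value of an observed setscore.

    Monte-Carlo: (b + 1) / (K + 1) with b the number of null |scores| at or
    above |observed|, so p is never exactly 0.  Exhaustive: the exact
    proportion, no pseudocount.
    """
    nulldist = np.asarray(nulldist, dtype=float)
    if nulldist.size == 0:
        raise ValueError("empty null distribution")
    b = int(np.count_nonzero(np.abs(nulldist) >= abs(observed)))
    if exhaustive:
        return b / nulldist.size
    return (b + 1) / (nulldist.size + 1)


def query(
    db: ReferenceDatabase,
    sig: GeneSignature,
    null: NullModel,
    threshold_override: float | None = None,
    missing: str = "error",
) -> list[ConnectionResult]:
    """Score a signature against every reference set in the database.

    Returns one ConnectionResult per set, sorted by ascending p-value
    (ties by compound name).  A connection is significant when its p-value
    is strictly below 1/n_sets, or below ``threshold_override`` if given.

    In Monte-Carlo mode one pool of K random signatures is drawn and scored
    against every set's mean-rank vector; each set's null distribution is
    still its own, and sharing the draws does not bias the per-set p-values
    because the nulls are independent of the observed signature.
    """
    idx_obs, signs_obs = _signature_indices(sig, db.universe, missing)
    m = len(idx_obs)
    n_genes = db.universe.n_genes
    c_max = _max_score(n_genes, m)
    threshold = (
        threshold_override
        if threshold_override is not None
        else db.significance_threshold
    )

    mean_rank_matrix = np.stack([s.mean_ranks() for s in db.sets])  # (S, N)
    observed = mean_rank_matrix[:, idx_obs] @ signs_obs / c_max  # (S,)

    if null.mode == "exhaustive":
        pvals = np.empty(db.n_sets)
        for i, s in enumerate(db.sets):
            nd = _exhaustive_null(
                mean_rank_matrix[i], n_genes, m, c_max, null.signed
            )
            pvals[i] = p_value(float(observed[i]), nd, exhaustive=True)
    else:
        rng = np.random.default_rng(null.seed)
        exceed = np.zeros(db.n_sets, dtype=np.int64)
        chunk = max(1, min(null.K, 10_000_000 // max(1, db.n_sets * m)))
        done = 0
        while done < null.K:
            k = min(chunk, null.K - done)
            idx, signs = _draw_null_signatures(n_genes, m, k, rng, null.signed)
            # (S, k): null setscores of this chunk against every set
            null_scores = np.einsum(
                "skm,km->sk", mean_rank_matrix[:, idx], signs
            ) / c_max
            exceed += (np.abs(null_scores) >= np.abs(observed)[:, None]).sum(axis=1)
            done += k
        pvals = (exceed + 1) / (null.K + 1)

    results = [
        ConnectionResult(
            compound=s.compound,
            setscore=float(observed[i]),
            p_value=float(pvals[i]),
            significant=bool(pvals[i] < threshold),
            set_size=s.set_size,
            signature_label=sig.label,
        )
        for i, s in enumerate(db.sets)
    ]
    results.sort(key=lambda r: (r.p_value, r.compound))
    return results
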