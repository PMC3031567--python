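"""Leave-one-out gene-signature perturbation and stability ranking.

A length-m signature yields m perturbation signatures, each omitting
exactly one gene.  The original and all perturbations (TabNo = m + 1
signatures in total) are queried against the reference database; for each
compound, SS counts how many of those TabNo connections are significant,
and the perturbation stability PS = SS / TabNo.  PS = 1 means the
connection survives every single-gene omission — the candidate is stable
against small changes to the signature.  Candidates are ranked by PS,
then by SetSize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .refdb import ReferenceDatabase
from .scoring import ConnectionResult, NullModel, query
from .signature import GeneSignature

_SEED_MOD = 2**31


@dataclass(frozen=True)
class PerturbationRecord:
    """One compound's aggregate over the original + leave-one-out queries.

    Field names follow the output table: REF (compound), TabNo, SS, PS,
    SetNo (setscore of the *original* signature), SetS (set size).
    """

    compound: str
    tab_no: int
    ss: int
    setscore_original: float
    set_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.ss <= self.tab_no:
            raise ValueError(f"SS={self.ss} outside 0..TabNo={self.tab_no}")

    @property
    def ps(self) -> float:
        return self.ss / self.tab_no


def generate_perturbations(sig: GeneSignature) -> list[GeneSignature]:
    """All m leave-one-out variants; the i-th omits the i-th entry."""
    m = len(sig)
    if m < 2:
        raise ValueError(
            "perturbation needs a signature of length >= 2 "
            "(a length-0 perturbation signature is meaningless)"
        )
    out = []
    for i in range(m):
        entries = sig.entries[:i] + sig.entries[i + 1 :]
        out.append(
            GeneSignature(entries=entries, label=f"{sig.label}(-{sig.entries[i][0]})")
        )
    return out


def perturbation_stability(flags: Sequence[bool]) -> float:
    """Proportion of significant connections among the TabNo queries."""
    if not flags:
        raise ValueError("need at least one significance flag")
    return sum(bool(f) for f in flags) / len(flags)


def _subseed(base: int, i: int) -> int:
    return (base + i) % _SEED_MOD


def perturbation_analysis(
    db: ReferenceDatabase,
    sig: GeneSignature,
    null: NullModel,
    scope: str = "any_significant",
    threshold_override: float | None = None,
    missing: str = "error",
) -> list[PerturbationRecord]:
    """Query the original and every leave-one-out signature; aggregate.

    Each of the TabNo = m + 1 queries uses a deterministically derived
    sub-seed (base seed + signature index), so a run is reproducible while
    the nulls are not artificially shared across signatures of different
    lengths.  ``scope`` controls which compounds get a record:
    ``any_significant`` (default) — significant under at least one of the
    TabNo signatures; ``original_significant`` — significant under the
    original signature.
    """
    if scope not in ("any_significant", "original_significant"):
        raise ValueError(f"unknown scope {scope!r}")
    signatures = [sig] + generate_perturbations(sig)
    tab_no = len(signatures)

    sig_counts: dict[str, int] = {}
    original_score: dict[str, float] = {}
    original_sig: dict[str, bool] = {}
    set_sizes: dict[str, int] = {}

    for i, s in enumerate(signatures):
        sub_null = NullModel(
            mode=null.mode, K=null.K, seed=_subseed(null.seed, i), signed=null.signed
        )
        results = query(
            db, s, sub_null, threshold_override=threshold_override, missing=missing
        )
        for r in results:
            sig_counts[r.compound] = sig_counts.get(r.compound, 0) + int(r.significant)
            set_sizes[r.compound] = r.set_size
            if i == 0:
                original_score[r.compound] = r.setscore
                original_sig[r.compound] = r.significant

    records = []
    for compound in db.compounds:
        if scope == "original_significant" and not original_sig[compound]:
            continue
        if scope == "any_significant" and sig_counts[compound] == 0:
            continue
        records.append(
            PerturbationRecord(
                compound=compound,
                tab_no=tab_no,
                ss=sig_counts[compound],
                setscore_original=original_score[compound],
                set_size=set_sizes[compound],
            )
        )
    return records


def rank_candidates(
    records: Sequence[PerturbationRecord],
    direction: str = "inverse",
    min_set_size: int = 1,
    min_ps: float = 0.0,
) -> list[PerturbationRecord]:
    """Filter by connection direction, PS and SetSize; order deterministically.

    ``inverse`` keeps negative original setscores (candidate-therapeutic
    direction), ``positive`` keeps positive ones, ``both`` keeps all.
    Sort: PS descending, SetSize descending, |setscore| descending, then
    compound name — a total order.
    """
    if direction not in ("inverse", "positive", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    kept = [
        r
        for r in records
        if (
            direction == "both"
            or (direction == "inverse" and r.setscore_original < 0)
            or (direction == "positive" and r.setscore_original > 0)
        )
        and r.ps >= min_ps
        and r.set_size >= min_set_size
    ]
    kept.sort(
        key=lambda r: (-r.ps, -r.set_size, -abs(r.setscore_original), r.compound)
    )
    return kept
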