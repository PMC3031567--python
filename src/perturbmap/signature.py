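"""Signed gene signatures and their construction from two-group expression data.

A gene signature is a concise ordered list of probes with regulation signs
(+1 up, -1 down) characterising a biological state.  Signatures are built
from a control-vs-case log2 expression matrix by a fixed recipe: per-probe
two-sample t-tests, a cut on the expected number of false positives (ENFP),
a mean-intensity filter, an absolute fold-change filter, and finally the
top-k probes by ascending p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_SIGN_TOKENS = {"+1": 1, "1": 1, "-1": -1, "−1": -1}  # accepts unicode minus


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe x sample matrix of log2 intensities with a two-group design."""

    values: pd.DataFrame  # rows = probes, columns = samples
    groups: dict[str, str]  # sample_id -> "control" | "case"

    def __post_init__(self) -> None:
        unknown = set(self.groups.values()) - {"control", "case"}
        if unknown:
            raise ValueError(f"unknown group label(s) {sorted(unknown)}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"sample(s) without group label: {missing[:5]}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe IDs in expression matrix")
        if not self.control_samples or not self.case_samples:
            raise ValueError("both control and case groups must be non-empty")

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "control"]

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "case"]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class DEResult:
    probe_id: str
    t_statistic: float
    p_value: float
    mean_control: float
    mean_case: float

    @property
    def log2_ratio(self) -> float:
        return self.mean_case - self.mean_control

    @property
    def sign(self) -> int:
        # zero difference defaults to + (direction undefined)
        return -1 if self.log2_ratio < 0 else 1


@dataclass(frozen=True)
class GeneSignature:
    """Ordered (probe_id, sign) pairs; when built here, ordered by ascending
    differential-expression p-value."""

    entries: tuple[tuple[str, int], ...]
    label: str = "signature"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("signature must contain at least one gene")
        probes = [p for p, _ in self.entries]
        if len(set(probes)) != len(probes):
            raise ValueError("duplicate probe IDs in signature")
        for p, s in self.entries:
            if s not in (1, -1):
                raise ValueError(f"sign for probe {p!r} must be +1 or -1, got {s}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.entries)

    @property
    def signs(self) -> tuple[int, ...]:
        return tuple(s for _, s in self.entries)

    def flipped(self) -> "GeneSignature":
        """Same probes with every regulation sign negated."""
        return GeneSignature(
            entries=tuple((p, -s) for p, s in self.entries),
            label=f"{self.label}(flipped)",
        )


def ttest_all(
    expr: ExpressionMatrix,
    equal_var: bool = False,
    paired: bool = False,
) -> list[DEResult]:
    """Per-probe two-sample t-tests, control vs case.

    Welch's unequal-variance test by default; ``equal_var=True`` gives the
    pooled-variance test, ``paired=True`` the paired test (samples matched
    by position within each group).  A probe with zero variance in both
    groups carries no evidence and is assigned p = 1.
    """
    ctrl = expr.values[expr.control_samples].to_numpy(dtype=float)
    case = expr.values[expr.case_samples].to_numpy(dtype=float)
    if ctrl.shape[1] < 2 or case.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples for t-tests")
    if paired:
        if ctrl.shape[1] != case.shape[1]:
            raise ValueError("paired test requires equal group sizes")
        t, p = stats.ttest_rel(case, ctrl, axis=1)
    else:
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # a probe constant in both groups carries no evidence either way
    degenerate = (ctrl.var(axis=1) == 0) & (case.var(axis=1) == 0)
    degenerate |= ~np.isfinite(p)
    if degenerate.any():
        logger.warning(
            "%d probe(s) with zero variance in both groups: p set to 1",
            int(degenerate.sum()),
        )
        p[degenerate] = 1.0
        t[degenerate] = 0.0
    mc = ctrl.mean(axis=1)
    ma = case.mean(axis=1)
    return [
        DEResult(
            probe_id=probe,
            t_statistic=float(ti),
            p_value=float(pi),
            mean_control=float(mci),
            mean_case=float(mai),
        )
        for probe, ti, pi, mci, mai in zip(expr.probe_ids, t, p, mc, ma)
    ]


def enfp_threshold(
    results: Sequence[DEResult], enfp_cut: float
) -> tuple[float, list[DEResult]]:
    """Size the significant list by the expected number of false positives.

    With G probes tested, ENFP at p-threshold t is t*G under the global
    null; the threshold is set to t = enfp_cut / G and probes with
    p <= t are retained.  Returns (threshold, retained results).
    """
    if enfp_cut <= 0:
        raise ValueError("enfp_cut must be positive")
    g = len(results)
    if g == 0:
        raise ValueError("no t-test results supplied")
    t = enfp_cut / g
    kept = [r for r in results if r.p_value <= t]
    if not kept:
        logger.warning("no probe passes ENFP threshold %.3g", t)
    return t, kept


def intensity_filter(
    results: Sequence[DEResult], min_log2: float = 6.0
) -> list[DEResult]:
    """Drop probes dim in BOTH groups: keep iff mean log2 intensity >= min_log2
    in the control group or in the case group."""
    return [
        r
        for r in results
        if r.mean_control >= min_log2 or r.mean_case >= min_log2
    ]


def foldchange_filter(
    results: Sequence[DEResult], min_abs_log2_ratio: float = 1.0
) -> list[DEResult]:
    """Keep probes with |log2 ratio| strictly above the threshold."""
    if min_abs_log2_ratio < 0:
        raise ValueError("min_abs_log2_ratio must be >= 0")
    return [r for r in results if abs(r.log2_ratio) > min_abs_log2_ratio]


def build_signature(
    expr: ExpressionMatrix,
    k: int,
    enfp_cut: float = 1.0,
    min_log2: float = 6.0,
    min_abs_log2_ratio: float = 1.0,
    label: str = "signature",
    equal_var: bool = False,
    paired: bool = False,
) -> GeneSignature:
    """Full recipe: t-tests -> ENFP cut -> intensity filter -> fold-change
    filter -> sort by ascending p -> take the first min(k, survivors) probes,
    signed by the direction of the mean log2 difference."""
    if k < 1:
        raise ValueError("k must be >= 1")
    results = ttest_all(expr, equal_var=equal_var, paired=paired)
    _, kept = enfp_threshold(results, enfp_cut)
    kept = intensity_filter(kept, min_log2)
    kept = foldchange_filter(kept, min_abs_log2_ratio)
    if not kept:
        raise ValueError(
            "no probes survive the filters; consider a larger enfp_cut or "
            "looser intensity / fold-change thresholds"
        )
    kept.sort(key=lambda r: r.p_value)  # stable: ties keep probe input order
    if k > len(kept):
        logger.warning(
            "requested k=%d but only %d probes survive; using all survivors",
            k,
            len(kept),
        )
    top = kept[: min(k, len(kept))]
    return GeneSignature(
        entries=tuple((r.probe_id, r.sign) for r in top), label=label
    )


def read_signature(path, label: str | None = None) -> GeneSignature:
    """Read a signature file: two tab-separated columns, probe ID and a
    regulation token in {+1, 1, -1}.  A third column is ignored with a
    warning; anything else is an error naming the offending line."""
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    warned_extra = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            if len(fields) > 2 and not warned_extra:
                logger.warning(
                    "%s:%d: extra column(s) ignored", path, lineno
                )
                warned_extra = True
            probe, token = fields[0].strip(), fields[1].strip()
            if token not in _SIGN_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: invalid sign token {token!r} "
                    "(expected +1 or -1)"
                )
            if probe in seen:
                raise ValueError(f"{path}:{lineno}: duplicate probe {probe!r}")
            seen.add(probe)
            entries.append((probe, _SIGN_TOKENS[token]))
    if not entries:
        raise ValueError(f"{path}: empty signature file")
    return GeneSignature(entries=tuple(entries), label=label or str(path))


def write_signature(sig: GeneSignature, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for probe, sign in sig.entries:
            fh.write(f"{probe}\t{'+1' if sign > 0 else '-1'}\n")


def read_expression(matrix_path, groups_path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (first column probe IDs, header
    row of sample IDs) plus a two-column ``sample_id  group`` file with group
    values ``control`` / ``case``."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    values.index = values.index.astype(str)
    grp = pd.read_csv(
        groups_path, sep="\t", comment="#", dtype=str, header=0
    )
    if list(grp.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(
            f"{groups_path}: expected header 'sample_id\\tgroup', "
            f"got {list(grp.columns)}"
        )
    groups = dict(zip(grp["sample_id"], grp["group"]))
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(expr: ExpressionMatrix, matrix_path, groups_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
    pd.DataFrame(
        {
            "sample_id": list(expr.values.columns),
            "group": [expr.groups[s] for s in expr.values.columns],
        }
    ).to_csv(groups_path, sep="\t", index=False)
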