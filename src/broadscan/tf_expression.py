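"""TF motif composition vs breadth of expression.

Transcription factors carry a tissue specificity score (TSPS): 0 for
uniform expression across tissues, ~5 for single-tissue expression. TFs
with TSPS >= 1 are "specific", TSPS < 1 "broad". For each TF the mean GC
and CpG content over its binding motifs is computed from PWM probabilities
(probability-weighted expectations; consensus-string counting is available
as an alternative mode), the two groups are compared by rank-sum tests,
and a squared semipartial correlation asks whether CpG content explains
breadth of expression beyond GC content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import rank_sum_p
from .motif_scan import PWM, ALPHABET

__all__ = [
    "TFRecord",
    "MotifComposition",
    "tsps_breadth_class",
    "motif_gc",
    "motif_cpg",
    "resolve_complex_tsps",
    "load_tf_table",
    "compose",
    "compare_composition",
    "semipartial_cpg_given_gc",
]

_C = ALPHABET.index("C")
_G = ALPHABET.index("G")


def tsps_breadth_class(tsps: float) -> str:
    """TSPS >= 1 -> "specific", TSPS < 1 -> "broad" (boundary is specific)."""
    if tsps < 0:
        raise ValueError("TSPS must be nonnegative")
    return "specific" if tsps >= 1 else "broad"


@dataclass(frozen=True)
class TFRecord:
    """A TF with its tissue specificity score and binding motifs."""

    tf_name: str
    tsps: float
    motifs: tuple[PWM, ...]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError(f"{self.tf_name}: motifs must be nonempty")
        if self.tsps < 0:
            raise ValueError(f"{self.tf_name}: TSPS must be nonnegative")

    @property
    def breadth_class(self) -> str:
        return tsps_breadth_class(self.tsps)


@dataclass(frozen=True)
class MotifComposition:
    tf_name: str
    mean_gc: float
    mean_cpg: float


def motif_gc(pwm: PWM, mode: str = "pwm") -> float:
    """Expected GC fraction of the motif.

    ``"pwm"``: (1/L) sum_i [p_i(C) + p_i(G)] — the expectation over
    realizations of the probability model. ``"consensus"``: GC fraction of
    the consensus string.
    """
    if mode == "consensus":
        c = pwm.consensus
        return sum(b in "GC" for b in c) / len(c)
    if mode != "pwm":
        raise ValueError(f"unknown mode {mode!r}")
    return float(pwm.probs[:, [_C, _G]].sum(axis=1).mean())


def motif_cpg(pwm: PWM, mode: str = "pwm") -> float:
    """Expected CpG dinucleotide rate per bp: (1/(L-1)) sum_i p_i(C)*p_{i+1}(G).

    Undefined (NaN) for single-column motifs.
    """
    L = len(pwm)
    if L < 2:
        return math.nan
    if mode == "consensus":
        c = pwm.consensus
        return sum(c[i : i + 2] == "CG" for i in range(L - 1)) / (L - 1)
    if mode != "pwm":
        raise ValueError(f"unknown mode {mode!r}")
    return float((pwm.probs[:-1, _C] * pwm.probs[1:, _G]).sum() / (L - 1))


def resolve_complex_tsps(component_tsps: Sequence[float]) -> float:
    """TSPS of a TF complex = max over components (a complex cannot be more
    broadly expressed than its most specific member)."""
    if not len(component_tsps):
        raise ValueError("empty component list")
    return float(max(component_tsps))


def load_tf_table(
    table: pd.DataFrame, motifs: Mapping[str, PWM], strict: bool = False
) -> list[TFRecord]:
    """Join a (tf_name, tsps, motif_ids) table with a motif collection.

    Rows whose motif ids are all missing from the collection, and motifs
    referenced by no row, are reported; unpaired rows are dropped (or raise
    with ``strict``).
    """
    records = []
    used: set[str] = set()
    dropped = []
    for row in table.itertuples(index=False):
        ids = [m for m in str(row.motif_ids).split(",") if m]
        found = tuple(motifs[m] for m in ids if m in motifs)
        used.update(m for m in ids if m in motifs)
        if not found:
            dropped.append(row.tf_name)
            continue
        records.append(TFRecord(str(row.tf_name), float(row.tsps), found))
    orphans = sorted(set(motifs) - used)
    if (dropped or orphans) and strict:
        raise ValueError(
            f"unpaired TFs: {dropped[:5]}...; unpaired motifs: {orphans[:5]}..."
        )
    if dropped:
        import warnings

        warnings.warn(
            f"dropped {len(dropped)} TF(s) with no known motif", stacklevel=2
        )
    return records


def compose(records: Sequence[TFRecord], mode: str = "pwm") -> pd.DataFrame:
    """Per-TF mean GC and CpG content over its motifs."""
    rows = [
        {
            "tf_name": r.tf_name,
            "tsps": r.tsps,
            "breadth_class": r.breadth_class,
            "mean_gc": float(np.mean([motif_gc(m, mode) for m in r.motifs])),
            "mean_cpg": float(np.mean([motif_cpg(m, mode) for m in r.motifs])),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def compare_composition(
    records: Sequence[TFRecord], mode: str = "pwm"
) -> dict[str, float]:
    """Group means of motif GC/CpG for broad vs specific TFs with two-sided
    rank-sum P-values."""
    df = compose(records, mode)
    broad = df[df.breadth_class == "broad"]
    specific = df[df.breadth_class == "specific"]
    if broad.empty or specific.empty:
        raise ValueError("need both broad and specific TFs")
    return {
        "n_broad": int(len(broad)),
        "n_specific": int(len(specific)),
        "gc_broad_mean": float(broad.mean_gc.mean()),
        "gc_specific_mean": float(specific.mean_gc.mean()),
        "gc_p": rank_sum_p(broad.mean_gc, specific.mean_gc),
        "cpg_broad_mean": float(broad.mean_cpg.mean()),
        "cpg_specific_mean": float(specific.mean_cpg.mean()),
        "cpg_p": rank_sum_p(broad.mean_cpg, specific.mean_cpg),
    }


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return math.nan
    return 1 - (resid**2).sum() / tss


def semipartial_cpg_given_gc(
    gc: Sequence[float],
    cpg: Sequence[float],
    response: Sequence[float],
) -> tuple[float, float]:
    """Squared semipartial correlation of CpG beyond GC, with its F-test P.

    sr^2 = R^2(response ~ GC + CpG) - R^2(response ~ GC);
    F = sr^2 * (n - 3) / (1 - R^2_full) on (1, n - 3) df.

    ``response`` is either the continuous TSPS or a broad/specific dummy.
    When CpG is an exact linear function of GC the full model adds nothing
    and sr^2 = 0 (rank-deficient fits go through least squares). Constant
    predictors or response return NaN.
    """
    gc = np.asarray(gc, dtype=float)
    cpg = np.asarray(cpg, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 records")
    if np.ptp(gc) == 0 or np.ptp(cpg) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r2_reduced = _r2(gc[:, None], y)
    r2_full = _r2(np.column_stack([gc, cpg]), y)
    sr2 = max(r2_full - r2_reduced, 0.0)
    if 1 - r2_full <= 0:
        return sr2, 0.0 if sr2 > 0 else 1.0
    F = sr2 * (n - 3) / (1 - r2_full)
    p = float(stats.f.sf(F, 1, n - 3))
    return float(sr2), p
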