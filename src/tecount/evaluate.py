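"""Validation summaries: truth-recovery correlation and null-expression audit."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from scipy import stats

from tecount.count import CountTable, format_count
from tecount.errors import DataError


@dataclass
class ValidationReport:
    """Summary of one validation run.

    ``spearman_rho`` is None when undefined (fewer than 3 TEs, or a
    constant vector); it is never coerced to 0.
    """

    spearman_rho: Optional[float] = None
    n_te: int = 0
    n_nonzero_truth: int = 0
    false_positive_te: list[tuple[str, float]] = field(default_factory=list)


def spearman_rho(truth: dict[str, float], estimated: dict[str, float]) -> Optional[float]:
    """Tie-corrected (average-rank) Spearman correlation over matched keys.

    Symmetric in its arguments.  Returns None when either vector is
    constant (rank correlation undefined).
    """
    if set(truth) != set(estimated):
        raise DataError(
            "truth and estimated tables have mismatched TE id sets: "
            f"{sorted(set(truth) ^ set(estimated))[:5]}..."
        )
    if len(truth) < 3:
        raise DataError("Spearman correlation needs at least 3 TEs")
    keys = sorted(truth)
    x = [float(truth[k]) for k in keys]
    y = [float(estimated[k]) for k in keys]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return None
    rho = stats.spearmanr(x, y).statistic
    return None if math.isnan(rho) else float(rho)


def audit_null(table: CountTable) -> list[tuple[str, float]]:
    """Every TE with positive count mass; an empty list means the null
    experiment passes (no exonized-fragment leakage into TE counts)."""
    return [(te, c) for te, c in table.counts.items() if c > 0]


def validation_report(
    truth: Optional[dict[str, float]],
    estimated: Optional[CountTable] = None,
    null_table: Optional[CountTable] = None,
) -> ValidationReport:
    report = ValidationReport()
    if truth is not None and estimated is not None:
        report.n_te = len(truth)
        report.n_nonzero_truth = sum(1 for v in truth.values() if v > 0)
        try:
            report.spearman_rho = spearman_rho(truth, dict(estimated.counts))
        except DataError:
            report.spearman_rho = None
    if null_table is not None:
        report.false_positive_te = audit_null(null_table)
    return report


def write_report(report: ValidationReport, path: Union[str, Path]) -> None:
    with open(path, "wt") as out:
        out.write("metric\tvalue\n")
        rho = "undefined" if report.spearman_rho is None else f"{report.spearman_rho:.6f}"
        out.write(f"spearman_rho\t{rho}\n")
        out.write(f"n_te\t{report.n_te}\n")
        out.write(f"n_nonzero_truth\t{report.n_nonzero_truth}\n")
        out.write(f"n_false_positive_te\t{len(report.false_positive_te)}\n")
        for te, c in report.false_positive_te:
            out.write(f"false_positive\t{te}={format_count(c)}\n")
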