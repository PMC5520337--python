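"""Percent splicing index (ψ), same-day Δψ, change calls and screen summaries.

ψ is the molar percentage of the inclusion isoform among the two isoforms
of a cassette-exon event (0–100).  Δψ for a knockdown sample is its ψ minus
the ψ of the mock-transfected control processed on the same batch day, so a
positive Δψ means a shift toward exon inclusion.  An event in a cell line
is called *changed* when both independent siRNAs shift Δψ by at least the
threshold (default 8 percentage points) in the same direction; discordant
or sub-threshold responses are vetoed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairingError",
    "compute_psi",
    "compute_delta_psi",
    "call_change",
    "call_changes",
    "ScreenSummary",
    "summarize_screen",
    "ConsensusDistribution",
    "consensus_distribution",
    "format_percent",
]

SIRNAS = ("siRNA1", "siRNA2")
MOCK = "mock"

#: schema of the per-sample ψ table
PSI_COLUMNS = ["ase_id", "cell_line", "condition", "batch_day", "psi"]
#: schema of the per-siRNA Δψ table
DELTA_COLUMNS = ["ase_id", "cell_line", "sirna", "delta_psi"]
#: schema of the per-(event, cell line) change-call table
CALL_COLUMNS = ["ase_id", "cell_line", "changed", "direction", "dpsi1", "dpsi2", "reason"]


class PairingError(ValueError):
    """A knockdown sample has no same-day mock control to compare against."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def compute_psi(
    inclusion_molar: float | None,
    exclusion_molar: float | None,
    min_total: float = 0.05,
) -> float:
    """ψ = 100 · inclusion / (inclusion + exclusion), on molar amounts.

    Returns NaN ("not evaluable") when both amounts are missing or their
    total falls below ``min_total``.  A single missing slot is treated as a
    zero amount only when the other slot alone exceeds the floor — an
    isoform can genuinely be absent, but two weak signals are not trusted.
    """
    inc_missing = _is_missing(inclusion_molar)
    exc_missing = _is_missing(exclusion_molar)
    if inc_missing and exc_missing:
        return float("nan")
    inc = 0.0 if inc_missing else float(inclusion_molar)
    exc = 0.0 if exc_missing else float(exclusion_molar)
    if inc < 0 or exc < 0:
        raise ValueError("molar amounts must be non-negative")
    if (inc_missing or exc_missing) and max(inc, exc) < min_total:
        return float("nan")
    total = inc + exc
    if total < min_total:
        return float("nan")
    return 100.0 * inc / total


def compute_delta_psi(psi_records: pd.DataFrame) -> pd.DataFrame:
    """Δψ per (event, cell line, siRNA) against the same-day mock.

    ``psi_records`` follows :data:`PSI_COLUMNS`.  Every (cell line,
    batch day) holding a knockdown record must also hold a mock record;
    otherwise a :class:`PairingError` names the offending sample.  Missing ψ
    on either side propagates to a missing Δψ.
    """
    df = psi_records.copy()
    mocks = df[df["condition"] == MOCK]
    mock_psi = mocks.set_index(["cell_line", "batch_day", "ase_id"])["psi"]
    if mock_psi.index.duplicated().any():
        dup = mock_psi.index[mock_psi.index.duplicated()][0]
        raise PairingError(f"multiple mock records for {dup}")
    rows = []
    kd = df[df["condition"].isin(SIRNAS)]
    for rec in kd.itertuples(index=False):
        key = (rec.cell_line, rec.batch_day, rec.ase_id)
        if key not in mock_psi.index:
            raise PairingError(
                f"no same-day mock for cell_line={rec.cell_line} "
                f"batch_day={rec.batch_day} ase_id={rec.ase_id}"
            )
        rows.append(
            {
                "ase_id": rec.ase_id,
                "cell_line": rec.cell_line,
                "sirna": rec.condition,
                "delta_psi": rec.psi - mock_psi.loc[key],
            }
        )
    return pd.DataFrame(rows, columns=DELTA_COLUMNS)


def call_change(
    dpsi1: float | None,
    dpsi2: float | None,
    threshold: float = 8.0,
    lenient: bool = False,
) -> tuple[bool, str, str]:
    """Apply the dual-siRNA concordance rule to one (event, cell line).

    Strict mode (default): changed iff both Δψ are present, share a nonzero
    sign, and **both** magnitudes reach ``threshold`` (inclusive).  Lenient
    mode relaxes the magnitude requirement to at least one siRNA, keeping
    the same-direction requirement.  Returns (changed, direction, reason)
    with direction in {"inclusion", "exclusion", "none"}.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if _is_missing(dpsi1) or _is_missing(dpsi2):
        return False, "none", "missing_dpsi"
    d1, d2 = float(dpsi1), float(dpsi2)
    s1, s2 = np.sign(d1), np.sign(d2)
    if s1 == 0 or s2 == 0 or s1 != s2:
        return False, "none", "discordant"
    mags = (abs(d1), abs(d2))
    passed = min(mags) >= threshold if not lenient else max(mags) >= threshold
    if not passed:
        return False, "none", "below_threshold"
    return True, ("inclusion" if s1 > 0 else "exclusion"), "changed"


def call_changes(
    delta_records: pd.DataFrame,
    threshold: float = 8.0,
    lenient: bool = False,
) -> pd.DataFrame:
    """Change-call table over all (event, cell line) pairs.

    ``delta_records`` follows :data:`DELTA_COLUMNS`; the output follows
    :data:`CALL_COLUMNS` with one row per (ase_id, cell_line).  A pair with
    a missing siRNA record is not evaluable (changed = False).
    """
    wide = delta_records.pivot_table(
        index=["ase_id", "cell_line"],
        columns="sirna",
        values="delta_psi",
        aggfunc="first",
        dropna=False,
    )
    rows = []
    for (ase_id, cell_line), rec in wide.iterrows():
        d1 = rec.get("siRNA1", float("nan"))
        d2 = rec.get("siRNA2", float("nan"))
        changed, direction, reason = call_change(d1, d2, threshold, lenient)
        rows.append(
            {
                "ase_id": ase_id,
                "cell_line": cell_line,
                "changed": changed,
                "direction": direction,
                "dpsi1": d1,
                "dpsi2": d2,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def format_percent(numerator: float, denominator: float, mode: str = "nearest") -> str:
    """Format a ratio as a percentage string.

    ``nearest``: round half up to an integer (28/96 → "29%").  ``trunc1``:
    truncate to one decimal (11/14 → "78.5%"), the convention some screen
    reports use for multi-line fractions.  Raw fractions should always be
    stored alongside; this only controls display.
    """
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    pct = 100.0 * numerator / denominator
    if mode == "nearest":
        return f"{math.floor(pct + 0.5):d}%"
    if mode == "trunc1":
        return f"{math.floor(pct * 10) / 10:.1f}%"
    raise ValueError(f"unknown percent format mode: {mode}")


@dataclass
class ScreenSummary:
    """Integer counts and derived percentages for one screen."""

    n_ases: int
    n_changed_any: int
    per_cell_line: dict[str, int]
    multiplicity: dict[int, int]
    n_inclusion_events: int
    n_exclusion_events: int
    pct_changed_any: float = field(init=False)
    pct_inclusion_events: float = field(init=False)

    def __post_init__(self) -> None:
        self.pct_changed_any = 100.0 * self.n_changed_any / self.n_ases if self.n_ases else 0.0
        total_events = self.n_inclusion_events + self.n_exclusion_events
        self.pct_inclusion_events = (
            100.0 * self.n_inclusion_events / total_events if total_events else 0.0
        )

    @property
    def pct_changed_any_str(self) -> str:
        return format_percent(self.n_changed_any, self.n_ases)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_ases", self.n_ases),
            ("n_changed_any", self.n_changed_any),
            ("pct_changed_any", self.pct_changed_any),
            ("n_inclusion_events", self.n_inclusion_events),
            ("n_exclusion_events", self.n_exclusion_events),
            ("pct_inclusion_events", self.pct_inclusion_events),
        ]
        rows += [(f"changed_in_{cl}", n) for cl, n in sorted(self.per_cell_line.items())]
        rows += [(f"changed_in_exactly_{k}_lines", n) for k, n in sorted(self.multiplicity.items())]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize_screen(calls: pd.DataFrame, n_ases: int) -> ScreenSummary:
    """Counts of changed events, per-line totals, multiplicities, directions."""
    n_distinct = calls["ase_id"].nunique()
    if n_ases < n_distinct:
        raise ValueError(f"n_ases={n_ases} < {n_distinct} distinct events in calls")
    changed = calls[calls["changed"]]
    per_line = changed.groupby("cell_line")["ase_id"].nunique().to_dict()
    per_line = {cl: int(per_line.get(cl, 0)) for cl in calls["cell_line"].unique()}
    counts = changed.groupby("ase_id")["cell_line"].nunique()
    multiplicity = counts.value_counts().sort_index()
    return ScreenSummary(
        n_ases=int(n_ases),
        n_changed_any=int(counts.size),
        per_cell_line=per_line,
        multiplicity={int(k): int(v) for k, v in multiplicity.items()},
        n_inclusion_events=int((changed["direction"] == "inclusion").sum()),
        n_exclusion_events=int((changed["direction"] == "exclusion").sum()),
    )


@dataclass
class ConsensusDistribution:
    """Which events recur across cell lines, and how often."""

    histogram: dict[int, int]
    exactly: dict[int, list[str]]
    at_least: dict[int, list[str]]


def consensus_distribution(calls: pd.DataFrame) -> ConsensusDistribution:
    """Multiplicity histogram: events changed in exactly / at least k lines."""
    n_lines = calls["cell_line"].nunique()
    if n_lines < 2:
        raise ValueError("consensus distribution needs calls from >= 2 cell lines")
    changed = calls[calls["changed"]]
    counts = changed.groupby("ase_id")["cell_line"].nunique()
    exactly = {
        k: sorted(counts.index[counts == k].tolist()) for k in range(1, n_lines + 1)
    }
    at_least = {
        k: sorted(counts.index[counts >= k].tolist()) for k in range(1, n_lines + 1)
    }
    histogram = {k: len(v) for k, v in exactly.items() if v}
    return ConsensusDistribution(histogram=histogram, exactly=exactly, at_least=at_least)
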