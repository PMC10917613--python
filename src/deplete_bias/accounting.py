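"""Read-filtering bookkeeping.

Shallow shotgun runs are summarized per sample by three read totals — reads
produced by the sequencer, reads surviving quality filtering, and reads
retained after alignment-based human-read removal — from which the percentage
of host-filtered reads is derived.  The arithmetic is exact: the percentage
is the count ratio rounded half-up at two decimals, so a published filtering
table can be reproduced bit-for-bit from its count columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ValidationError


@dataclass(frozen=True)
class ReadAccounting:
    """Per-sample read totals across the filtering cascade.

    Invariant: ``retained_after_host_filter <= high_quality_reads <= reads_produced``.
    """

    sample_id: str
    reads_produced: int
    high_quality_reads: int
    retained_after_host_filter: int

    def __post_init__(self) -> None:
        for name in ("reads_produced", "high_quality_reads", "retained_after_host_filter"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name} must be an integer >= 0, got {v!r}"
                )
        if not (
            self.retained_after_host_filter
            <= self.high_quality_reads
            <= self.reads_produced
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: expected retained <= high-quality <= produced, "
                f"got {self.retained_after_host_filter} <= {self.high_quality_reads} "
                f"<= {self.reads_produced}"
            )


def percent_host_filtered(acc: ReadAccounting) -> float:
    """Percentage of high-quality reads removed by host filtering.

    Returns ``100 * (HQ - retained) / HQ`` rounded half-up at 2 decimals.
    Raises :class:`ValidationError` when no high-quality reads exist (the
    percentage is undefined).
    """
    if acc.high_quality_reads == 0:
        raise ValidationError(
            f"sample {acc.sample_id!r}: host-filtered percentage undefined "
            "(zero high-quality reads)"
        )
    filtered = acc.high_quality_reads - acc.retained_after_host_filter
    pct = (Decimal(filtered) * 100) / Decimal(acc.high_quality_reads)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def host_reduction(
    treated: ReadAccounting, untreated: ReadAccounting
) -> tuple[float, float | None]:
    """Contrast the host-filtered percentage between a treated/untreated pair.

    Returns ``(absolute difference in percent points, relative reduction in %)``;
    the relative reduction is ``None`` when the untreated percentage is zero.
    Both are computed from the 2-decimal rounded percentages so they match a
    published table read off by eye.
    """
    pct_t = percent_host_filtered(treated)
    pct_u = percent_host_filtered(untreated)
    absolute = pct_u - pct_t
    relative = 100.0 * absolute / pct_u if pct_u > 0 else None
    return absolute, relative


def accounting_frame(accs: Sequence[ReadAccounting]) -> pd.DataFrame:
    """Machine-readable table: one row per sample, input order preserved."""
    if not accs:
        raise ValidationError("empty accounting list")
    rows = []
    for acc in accs:
        rows.append(
            {
                "sample_id": acc.sample_id,
                "reads_produced": acc.reads_produced,
                "high_quality_reads": acc.high_quality_reads,
                "retained_after_host_filter": acc.retained_after_host_filter,
                "percent_host_filtered": percent_host_filtered(acc),
            }
        )
    return pd.DataFrame(rows)


def filtering_table(accs: Sequence[ReadAccounting]) -> str:
    """Human-readable filtering table with thousands-separated counts."""
    frame = accounting_frame(accs)
    header = (
        "Sample",
        "Reads produced",
        "High-quality reads",
        "Retained after host filtering",
        "% filtered host",
    )
    body = [
        (
            r.sample_id,
            f"{r.reads_produced:,}",
            f"{r.high_quality_reads:,}",
            f"{r.retained_after_host_filter:,}",
            f"{r.percent_host_filtered:.2f}%",
        )
        for r in frame.itertuples()
    ]
    widths = [max(len(h), *(len(row[i]) for row in body)) for i, h in enumerate(header)]
    lines = ["\t".join(h.ljust(widths[i]) for i, h in enumerate(header))]
    for row in body:
        lines.append("\t".join(cell.ljust(widths[i]) for i, cell in enumerate(row)))
    return "\n".join(lines)


def read_accounting_tsv(path: str | Path) -> list[ReadAccounting]:
    """Read accounting records from a TSV with the four standard columns."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "sample_id",
        "reads_produced",
        "high_quality_reads",
        "retained_after_host_filter",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        ReadAccounting(
            sample_id=str(row.sample_id),
            reads_produced=int(row.reads_produced),
            high_quality_reads=int(row.high_quality_reads),
            retained_after_host_filter=int(row.retained_after_host_filter),
        )
        for row in frame.itertuples()
    ]


def write_accounting_tsv(accs: Iterable[ReadAccounting], path: str | Path) -> None:
    accounting_frame(list(accs)).to_csv(path, sep="\t", index=False)
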