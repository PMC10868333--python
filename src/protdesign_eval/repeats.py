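"""Continuous-repeat statistics for designed sequences.

Design models often emit runs of the same amino acid (poly-A, poly-V ...),
which fold poorly in natural conditions and promote amyloid-like
aggregation.  This module finds maximal runs, attributes each run to its
majority secondary-structure state, and aggregates totals per method and
residue type.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DimensionMismatchError
from .io import SequenceRecord

#: Runs shorter than this are ubiquitous in natural sequences and ignored.
DEFAULT_MIN_RUN = 3


@dataclass(frozen=True)
class RepeatRun:
    """A maximal run of one residue type within a sequence."""

    residue: str
    start: int          # 0-based
    length: int
    ss_context: str | None = None  # majority 3-state label over the run


def find_repeat_runs(seq: SequenceRecord | str,
                     min_run: int = DEFAULT_MIN_RUN) -> list[RepeatRun]:
    """All maximal runs of length ≥ *min_run*, left to right."""
    if min_run < 2:
        raise ConfigError("min_run must be ≥ 2")
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    runs = []
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        if j - i >= min_run:
            runs.append(RepeatRun(residue=s[i], start=i, length=j - i))
        i = j
    return runs


def run_ss_context(run: RepeatRun, ss: str) -> str:
    """Majority 3-state label over the run's span; ties resolve to coil."""
    span = ss[run.start:run.start + run.length]
    counts = Counter(span)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "C"
    return top[0][0]


@dataclass
class RepeatProfile:
    """Aggregated repeat-run statistics.

    ``records`` holds one row per run (method, sequence id, residue,
    start, length, ss_context); the pivot properties derive totals from
    it, so totals always equal the sum of constituent run lengths.
    """

    records: pd.DataFrame

    @property
    def total_by_method_residue(self) -> pd.DataFrame:
        """Total repeated length per method × residue type."""
        return self.records.pivot_table(
            index="method", columns="residue", values="length",
            aggfunc="sum", fill_value=0,
        )

    @property
    def total_by_sequence(self) -> pd.Series:
        return self.records.groupby(["method", "sequence_id"])["length"].sum()

    @property
    def ss_crosstab(self) -> pd.DataFrame:
        """Total repeated length per residue type × secondary-structure state."""
        with_ss = self.records.dropna(subset=["ss_context"])
        return with_ss.pivot_table(
            index="residue", columns="ss_context", values="length",
            aggfunc="sum", fill_value=0,
        )


def aggregate_repeat_runs(
    runs_by_method: Mapping[str, Mapping[str, Sequence[RepeatRun]]],
    ss_strings: Mapping[str, str] | None = None,
    sequence_lengths: Mapping[str, int] | None = None,
) -> RepeatProfile:
    """Aggregate runs into a :class:`RepeatProfile`.

    *runs_by_method* maps method → sequence id → runs; *ss_strings*
    optionally maps sequence id → 3-state string, which must cover each
    run's span (checked against *sequence_lengths* when provided).
    """
    rows = []
    for method, by_seq in runs_by_method.items():
        for seq_id, runs in by_seq.items():
            ss = ss_strings.get(seq_id) if ss_strings else None
            if ss is not None and sequence_lengths is not None:
                if len(ss) != sequence_lengths[seq_id]:
                    raise DimensionMismatchError(
                        f"sequence {seq_id!r}: secondary-structure string "
                        f"length {len(ss)} does not match sequence length "
                        f"{sequence_lengths[seq_id]}"
                    )
            for run in runs:
                if ss is not None and run.start + run.length > len(ss):
                    raise DimensionMismatchError(
                        f"sequence {seq_id!r}: run at {run.start} exceeds "
                        "the secondary-structure string"
                    )
                rows.append({
                    "method": method,
                    "sequence_id": seq_id,
                    "residue": run.residue,
                    "start": run.start,
                    "length": run.length,
                    "ss_context": run_ss_context(run, ss) if ss else None,
                })
    records = pd.DataFrame(
        rows, columns=["method", "sequence_id", "residue", "start",
                       "length", "ss_context"],
    )
    return RepeatProfile(records=records)
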