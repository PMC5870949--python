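"""Minimum-mutation parsimony mapping of events onto a duplication trio.

Given three aligned proteins — two paralogs and a distant outgroup
ortholog — every variable alignment column is explained by the fewest
character changes on the three branches joining the sequences at the
single internal node of their (only possible) unrooted tree:

- two sequences share a residue and the third differs: one substitution on
  the branch leading to the differing sequence;
- all three residues distinct: one substitution on each of the three
  branches (the minimum; this slightly inflates the total count at such
  columns but cancels from relative-density comparisons);
- all identical: no event.

Gap/residue differences yield indel events, either one per gap column
(``per_column``) or one per maximal gap run (``per_run``, the default:
a contiguous insertion or deletion is a single mutational event, charged
at its first column). Columns containing 'X' in any sequence are skipped:
parsimony is undefined on missing states.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .sequence_io import ProteinAlignment, Role

logger = logging.getLogger(__name__)

BRANCHES = (Role.OUTGROUP, Role.PARALOG1, Role.PARALOG2)


@dataclass
class TrioAlignment:
    """A ProteinAlignment restricted to exactly one record per trio role."""

    alignment: ProteinAlignment

    def __post_init__(self) -> None:
        for role in BRANCHES:
            self.alignment.by_role(role)  # raises unless exactly one

    @classmethod
    def from_records(cls, outgroup: tuple[str, str], paralog1: tuple[str, str],
                     paralog2: tuple[str, str]) -> "TrioAlignment":
        return cls(ProteinAlignment([
            (outgroup[0], Role.OUTGROUP, outgroup[1]),
            (paralog1[0], Role.PARALOG1, paralog1[1]),
            (paralog2[0], Role.PARALOG2, paralog2[1]),
        ]))

    @property
    def length(self) -> int:
        return self.alignment.length

    def sequences(self) -> dict[Role, str]:
        return {role: self.alignment.by_role(role)[1] for role in BRANCHES}


@dataclass
class Event:
    """One inferred mutational event on a trio branch."""

    column: int  # 1-based alignment column
    type: str    # "substitution" | "indel"
    states: str  # column states in (outgroup, paralog1, paralog2) order


@dataclass
class BranchEventMap:
    """Per-branch event lists with totals; the input to hotspot scanning."""

    length: int
    events: dict[Role, list[Event]] = field(
        default_factory=lambda: {b: [] for b in BRANCHES}
    )
    skipped_columns: list[int] = field(default_factory=list)

    @property
    def totals(self) -> dict[Role, int]:
        return {b: len(evts) for b, evts in self.events.items()}

    @property
    def n_total(self) -> int:
        return sum(len(evts) for evts in self.events.values())

    def positions(self, branch: Role) -> list[int]:
        return [e.column for e in self.events[branch]]


def assign_events(trio: TrioAlignment, indel_mode: str = "per_run"
                  ) -> BranchEventMap:
    """Map substitution and indel events onto the three trio branches.

    Parameters
    ----------
    trio:
        The aligned (outgroup, paralog1, paralog2) protein trio.
    indel_mode:
        ``"per_run"`` (default): a maximal run of contiguous indel columns
        charged to one branch counts as a single event at its first column.
        ``"per_column"``: every gap/residue column is its own event.
    """
    if indel_mode not in ("per_run", "per_column"):
        raise ValueError(f"unknown indel_mode {indel_mode!r}")
    seqs = trio.sequences()
    L = trio.length
    emap = BranchEventMap(length=L)

    # indicator per branch: column carries an indel charged to that branch
    indel_flags: dict[Role, list[bool]] = {b: [False] * L for b in BRANCHES}

    for i in range(L):
        col = {b: seqs[b][i] for b in BRANCHES}
        states = "".join(col[b] for b in BRANCHES)
        if "X" in states:
            emap.skipped_columns.append(i + 1)
            continue
        gapped = [b for b in BRANCHES if col[b] == "-"]
        if len(gapped) == 3:
            continue  # no information
        if len(gapped) == 2:
            # two gapped, one residue: the residue-bearing branch carries
            # the indel (an insertion specific to that lineage)
            (bearer,) = (b for b in BRANCHES if col[b] != "-")
            indel_flags[bearer][i] = True
            continue
        if len(gapped) == 1:
            # one gapped: indel on the gapped branch; the two residues do
            # not support a parsimony-unambiguous substitution call
            indel_flags[gapped[0]][i] = True
            continue
        # all residues: substitution parsimony
        distinct = set(states)
        if len(distinct) == 1:
            continue
        if len(distinct) == 3:
            for b in BRANCHES:
                emap.events[b].append(Event(i + 1, "substitution", states))
        else:
            # one branch differs from the shared state of the other two
            for b in BRANCHES:
                others = [col[o] for o in BRANCHES if o is not b]
                if others[0] == others[1] and col[b] != others[0]:
                    emap.events[b].append(Event(i + 1, "substitution", states))
                    break

    for b in BRANCHES:
        flags = indel_flags[b]
        if indel_mode == "per_column":
            for i, on in enumerate(flags):
                if on:
                    states = "".join(seqs[r][i] for r in BRANCHES)
                    emap.events[b].append(Event(i + 1, "indel", states))
        else:
            i = 0
            while i < L:
                if flags[i]:
                    start = i
                    while i < L and flags[i]:
                        i += 1
                    states = "".join(seqs[r][start] for r in BRANCHES)
                    emap.events[b].append(Event(start + 1, "indel", states))
                else:
                    i += 1

    for b in BRANCHES:
        emap.events[b].sort(key=lambda e: e.column)
    if emap.skipped_columns:
        logger.info("skipped %d columns containing 'X'", len(emap.skipped_columns))
    return emap


def event_table(emap: BranchEventMap, path: str | Path | None = None) -> list[dict]:
    """Flatten a BranchEventMap into rows (branch, column, type, states).

    Rows are sorted by column then branch order (outgroup, paralog1,
    paralog2). If ``path`` is given, a tab-delimited file with header is
    written.
    """
    rows = []
    for b in BRANCHES:
        for e in emap.events[b]:
            rows.append({"branch": b.value, "column": e.column,
                         "type": e.type, "states": e.states})
    order = {b.value: i for i, b in enumerate(BRANCHES)}
    rows.sort(key=lambda r: (r["column"], order[r["branch"]]))
    if path is not None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["branch", "column", "type", "states"],
                delimiter="\t")
            writer.writeheader()
            writer.writerows(rows)
    return rows


def read_event_table(path: str | Path, length: int) -> BranchEventMap:
    """Reconstruct a BranchEventMap from an event TSV written by
    :func:`event_table`."""
    emap = BranchEventMap(length=length)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            emap.events[Role(row["branch"])].append(
                Event(int(row["column"]), row["type"], row["states"])
            )
    for b in BRANCHES:
        emap.events[b].sort(key=lambda e: e.column)
    return emap
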