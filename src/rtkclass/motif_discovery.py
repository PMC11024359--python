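"""Supervised group-conservation motif discovery from labeled alignments.

Given an alignment whose rows carry group labels, derive per-group
consensus strings (modal residue where within-group conservation reaches a
threshold tau, 'x' elsewhere), universally conserved positions, positions
that discriminate between groups, and per-column residue proportions for
logo rendering.

X is a 21st residue category: it counts toward column totals but can never
become a consensus residue.  Modal ties are broken alphabetically; with
tau > 0.5 a tied column can never reach tau, so consensus output is
deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from rtkclass.alphabet import AA20, GAP, UNKNOWN
from rtkclass.sequence_io import GroupedAlignment

__all__ = [
    "GroupColumn",
    "ColumnProfile",
    "DiagnosticPosition",
    "column_profiles",
    "group_consensus",
    "universal_positions",
    "diagnostic_positions",
    "residue_proportions",
]

DEFAULT_TAU = 0.8
DEFAULT_GAMMA = 0.5


@dataclass(frozen=True)
class GroupColumn:
    """One group's view of one alignment column."""

    modal_residue: Optional[str]  # None when the group column is all gap/X
    modal_freq: float
    gap_freq: float


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts for one alignment column, overall and per group."""

    index: int  # 0-based column index
    counts: dict  # residue/X/gap -> count over all rows
    per_group: dict  # group label -> GroupColumn


@dataclass(frozen=True)
class DiagnosticPosition:
    """Column fixed within every group; universal or discriminative."""

    index: int  # 0-based column index
    residues: dict  # group label -> frozenset of residues
    kind: str  # 'universal' | 'discriminative'


def _check_tau(tau: float) -> None:
    if not 0.5 < tau <= 1.0:
        raise ValueError(f"tau must be in (0.5, 1], got {tau}")


def column_profiles(aln: GroupedAlignment) -> list[ColumnProfile]:
    """Per-column residue counts overall and per group.

    Requires at least two groups with at least one sequence each.
    Frequencies are relative to group size; gaps are counted separately
    from residues and X can never be modal.
    """
    groups = aln.groups
    if len(groups) < 2:
        raise ValueError(f"discovery needs >= 2 groups, got {len(groups)}")
    members = {g: aln.members(g) for g in groups}
    for g, idx in members.items():
        if not idx:
            raise ValueError(f"group {g!r} is empty")

    profiles = []
    for col in range(aln.n_cols):
        chars = [row[col] for row in aln.rows]
        counts = dict(Counter(chars))
        per_group = {}
        for g, idx in members.items():
            n = len(idx)
            sub = Counter(chars[i] for i in idx)
            gap_freq = sub.get(GAP, 0) / n
            residue_counts = {
                aa: c for aa, c in sub.items() if aa not in (GAP, UNKNOWN)
            }
            if residue_counts:
                top = max(residue_counts.values())
                modal = min(aa for aa, c in residue_counts.items() if c == top)
                per_group[g] = GroupColumn(modal, top / n, gap_freq)
            else:
                per_group[g] = GroupColumn(None, 0.0, gap_freq)
        profiles.append(ColumnProfile(index=col, counts=counts, per_group=per_group))
    return profiles


def group_consensus(
    profiles: list[ColumnProfile],
    tau: float = DEFAULT_TAU,
    gamma: float = DEFAULT_GAMMA,
) -> dict[str, str]:
    """Per-group consensus strings over the profiled columns.

    A column contributes the group's modal residue when its within-group
    frequency is >= tau and the group's gap frequency is <= gamma,
    otherwise 'x'.  Columns whose gap frequency exceeds gamma in every
    group are dropped from all consensuses, keeping strings equal length.
    """
    _check_tau(tau)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if not profiles:
        return {}
    groups = sorted(profiles[0].per_group)
    out = {g: [] for g in groups}
    for prof in profiles:
        if all(prof.per_group[g].gap_freq > gamma for g in groups):
            continue
        for g in groups:
            gc = prof.per_group[g]
            if (
                gc.modal_residue is not None
                and gc.modal_freq >= tau - 1e-12
                and gc.gap_freq <= gamma + 1e-12
            ):
                out[g].append(gc.modal_residue)
            else:
                out[g].append("x")
    return {g: "".join(chars) for g, chars in out.items()}


def universal_positions(consensuses: dict[str, str]) -> list[int]:
    """0-based columns where every group has the same fixed residue."""
    strings = list(consensuses.values())
    if not strings:
        return []
    lengths = {len(s) for s in strings}
    if len(lengths) != 1:
        raise ValueError(f"consensus strings of unequal length: {sorted(lengths)}")
    out = []
    for i in range(strings[0].__len__()):
        column = {s[i] for s in strings}
        if len(column) == 1 and "x" not in column:
            out.append(i)
    return out


def diagnostic_positions(
    profiles: list[ColumnProfile], tau: float = DEFAULT_TAU
) -> list[DiagnosticPosition]:
    """Columns fixed (modal frequency >= tau) within every group.

    kind='universal' when all groups share the residue, otherwise
    'discriminative'.  With tau > 0.5 the per-group residue set is always
    a singleton.
    """
    _check_tau(tau)
    out = []
    for prof in profiles:
        residues = {}
        ok = True
        for g, gc in prof.per_group.items():
            if gc.modal_residue is None or gc.modal_freq < tau - 1e-12:
                ok = False
                break
            residues[g] = frozenset(gc.modal_residue)
        if not ok:
            continue
        kind = "universal" if len(set(residues.values())) == 1 else "discriminative"
        out.append(DiagnosticPosition(index=prof.index, residues=residues, kind=kind))
    return out


def residue_proportions(
    aln: GroupedAlignment, include_gaps: bool = True
) -> pd.DataFrame:
    """Per-column residue proportions (rows = columns, columns = categories).

    Categories are the 20 residues, X, and the gap.  With
    ``include_gaps=True`` every row sums to 1; with ``include_gaps=False``
    proportions are renormalized over non-gap characters (an all-gap
    column yields zeros).
    """
    categories = list(AA20) + [UNKNOWN, GAP]
    cat_index = {c: k for k, c in enumerate(categories)}
    n_rows = len(aln.rows)
    table = np.zeros((aln.n_cols, len(categories)), dtype=float)
    for row in aln.rows:
        for col, ch in enumerate(row):
            table[col, cat_index[ch]] += 1
    if include_gaps:
        table /= n_rows
    else:
        table = table[:, :-1]
        categories = categories[:-1]
        totals = table.sum(axis=1, keepdims=True)
        np.divide(table, totals, out=table, where=totals > 0)
    return pd.DataFrame(table, columns=categories, index=range(aln.n_cols))
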