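"""Synthetic RTK protein families with planted motifs and known truth.

Sequences are assembled from random-background linkers plus the packaged
consensus motifs of the requested class/subtype:

    [N-terminal linker (+ FN3 subtype motif for InsR)]
    [Gly-loop instance] [spacer] [catalytic cassette] [spacer] [DFG] [tail]

Wildcard positions are filled from the background distribution.
Substitutions are applied with probability ``p_fix`` at fixed positions of
planted motifs and ``p_bg`` everywhere else; a substitution replaces the
residue with a uniformly drawn different residue.  All randomness flows
from a single integer seed, so identical specs reproduce byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from rtkclass.alphabet import AA20
from rtkclass.motif_model import (
    DFG,
    GLY_LOOP,
    DegenerateMotif,
    MotifLibrary,
    load_motif_library,
)
from rtkclass.sequence_io import GroupedAlignment, SequenceRecord, write_fasta

__all__ = [
    "SyntheticSpec",
    "TruthRecord",
    "generate_sequence",
    "generate_dataset",
    "generate_grouped_alignment",
]

_LIBRARY: Optional[MotifLibrary] = None


def _library() -> MotifLibrary:
    global _LIBRARY
    if _LIBRARY is None:
        _LIBRARY = load_motif_library()
    return _LIBRARY


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one labeled family."""

    rtk_class: str
    subtype: str
    n: int = 1
    background: Optional[dict] = None  # residue -> probability; None = uniform
    p_fix: float = 0.0  # substitution probability at fixed motif positions
    p_bg: float = 0.0  # substitution probability elsewhere
    truncation: Optional[str] = None  # None | 'n_terminal' | 'c_terminal'
    retained_fraction: float = 1.0
    nterm_linker: tuple = (200, 400)
    spacer: tuple = (30, 80)
    cassette_spacer: tuple = (5, 15)
    tail: tuple = (30, 60)
    seed: int = 0
    id_prefix: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p in (self.p_fix, self.p_bg):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"substitution probability {p} outside [0, 1]")
        if self.truncation not in (None, "n_terminal", "c_terminal"):
            raise ValueError(f"unknown truncation kind {self.truncation!r}")
        if not 0.0 < self.retained_fraction <= 1.0:
            raise ValueError("retained_fraction must be in (0, 1]")


@dataclass
class TruthRecord:
    """Planted label and motif offsets for one generated sequence."""

    seq_id: str
    rtk_class: str
    subtype: str
    motif_offsets: dict  # motif name -> 0-based offset (fully retained motifs)
    truncation: Optional[str] = None
    evidence_lost: bool = False


def _background_probs(background: Optional[dict]) -> np.ndarray:
    if background is None:
        return np.full(20, 1 / 20)
    probs = np.zeros(20)
    for aa, p in background.items():
        probs[AA20.index(aa)] = p
    total = probs.sum()
    if total <= 0:
        raise ValueError("background distribution sums to zero")
    return probs / total


def _random_linker(rng: np.random.Generator, bounds: tuple, probs: np.ndarray) -> str:
    length = int(rng.integers(bounds[0], bounds[1] + 1))
    return "".join(AA20[i] for i in rng.choice(20, size=length, p=probs))


def _instantiate(motif: DegenerateMotif, rng: np.random.Generator,
                 probs: np.ndarray) -> tuple[str, list[int]]:
    """Fill a motif's wildcards from the background; return fixed indices."""
    chars = []
    fixed_idx = []
    for i, p in enumerate(motif.positions):
        if p is None:
            chars.append(AA20[int(rng.choice(20, p=probs))])
        else:
            chars.append(sorted(p)[0])
            fixed_idx.append(i)
    return "".join(chars), fixed_idx


def _subtype_cassette(spec: SyntheticSpec) -> DegenerateMotif:
    lib = _library()
    if spec.rtk_class == "InsR":
        return lib.insr_catalytic
    for m in lib.subtype_motifs(spec.rtk_class):
        if m.subtype == spec.subtype:
            return m
    raise ValueError(f"no cassette motif for {spec.rtk_class}/{spec.subtype}")


def generate_sequence(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    index: int = 0,
) -> tuple[SequenceRecord, TruthRecord]:
    """Generate one sequence plus its truth record."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    probs = _background_probs(spec.background)
    lib = _library()

    parts: list[str] = []
    planted: list[tuple[str, int, list[int]]] = []  # (name, offset, fixed idx)
    pos = 0

    def _push(fragment: str) -> int:
        nonlocal pos
        parts.append(fragment)
        start = pos
        pos += len(fragment)
        return start

    def _plant(motif: DegenerateMotif) -> None:
        inst, fixed_idx = _instantiate(motif, rng, probs)
        start = _push(inst)
        planted.append((motif.name, start, fixed_idx))

    _push(_random_linker(rng, spec.nterm_linker, probs))
    if spec.rtk_class == "InsR":
        for m in lib.subtype_motifs("InsR"):
            if m.subtype == spec.subtype:
                _plant(m)
                break
        else:
            raise ValueError(f"unknown InsR subtype {spec.subtype!r}")
        _push(_random_linker(rng, spec.spacer, probs))
    _plant(GLY_LOOP)
    _push(_random_linker(rng, spec.spacer, probs))
    _plant(_subtype_cassette(spec))
    _push(_random_linker(rng, spec.cassette_spacer, probs))
    _plant(DFG)
    _push(_random_linker(rng, spec.tail, probs))

    residues = np.frombuffer("".join(parts).encode(), dtype=np.uint8).copy()

    # substitution mask: p_fix on planted fixed positions, p_bg elsewhere
    fixed_mask = np.zeros(len(residues), dtype=bool)
    for _, start, fixed_idx in planted:
        for i in fixed_idx:
            fixed_mask[start + i] = True
    p_vec = np.where(fixed_mask, spec.p_fix, spec.p_bg)
    hit = rng.random(len(residues)) < p_vec
    if hit.any():
        for i in np.nonzero(hit)[0]:
            current = chr(residues[i])
            choices = [aa for aa in AA20 if aa != current]
            residues[i] = ord(choices[int(rng.integers(len(choices)))])
    sequence = residues.tobytes().decode()

    # truncation: drop the flagged end, keeping retained_fraction of length
    offsets = {name: start for name, start, _ in planted}
    evidence_lost = False
    if spec.truncation is not None:
        keep = max(1, int(round(spec.retained_fraction * len(sequence))))
        if spec.truncation == "n_terminal":
            cut = len(sequence) - keep
            sequence = sequence[cut:]
            shifted = {}
            for name, start, _ in planted:
                if start >= cut:
                    shifted[name] = start - cut
            offsets = shifted
        else:  # c_terminal
            sequence = sequence[:keep]
            offsets = {
                name: start
                for name, start, _ in planted
                if start + len(_motif_by_name(name)) <= keep
            }
        evidence_lost = not offsets

    label = spec.id_prefix or f"syn{spec.subtype}"
    seq_id = f"{label}_{index:04d}"
    record = SequenceRecord(
        id=seq_id,
        residues=sequence,
        is_partial=spec.truncation is not None,
    )
    truth = TruthRecord(
        seq_id=seq_id,
        rtk_class=spec.rtk_class,
        subtype=spec.subtype,
        motif_offsets=offsets,
        truncation=spec.truncation,
        evidence_lost=evidence_lost,
    )
    return record, truth


def _motif_by_name(name: str) -> DegenerateMotif:
    if name == GLY_LOOP.name:
        return GLY_LOOP
    if name == DFG.name:
        return DFG
    return _library()[name]


def generate_dataset(
    specs: list[SyntheticSpec],
    out_fasta=None,
    out_truth=None,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate all specs; optionally write FASTA plus a truth TSV."""
    if not specs:
        raise ValueError("at least one spec required")
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    seen: set[str] = set()
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        for k in range(spec.n):
            rec, truth = generate_sequence(spec, rng=rng, index=k)
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(rec)
            truths.append(truth)
    if out_fasta is not None:
        write_fasta(records, out_fasta)
    if out_truth is not None:
        with open(out_truth, "w") as fh:
            fh.write("id\tclass\tsubtype\toffsets\ttruncation\tevidence_lost\n")
            for t in truths:
                offs = ",".join(f"{k}:{v}" for k, v in sorted(t.motif_offsets.items()))
                fh.write(
                    f"{t.seq_id}\t{t.rtk_class}\t{t.subtype}\t{offs}\t"
                    f"{t.truncation or ''}\t{int(t.evidence_lost)}\n"
                )
    return records, truths


def generate_grouped_alignment(
    motifs: dict[str, str],
    n_per_group: int,
    wildcard_policy: str = "rotation",
    seed: int = 0,
    rotation_residues: str = "ACDE",
    max_freq: float = 0.25,
    background: Optional[dict] = None,
) -> GroupedAlignment:
    """Pre-aligned rows per group: fixed positions copied, wildcards filled.

    ``rotation`` cycles ``rotation_residues`` across rows and columns so no
    residue's within-column frequency exceeds ``max_freq``; ``background``
    draws wildcard residues at random.  No indels are introduced, so rows
    are aligned by construction.
    """
    if not motifs:
        raise ValueError("at least one group consensus required")
    lengths = {len(s) for s in motifs.values()}
    if len(lengths) != 1:
        raise ValueError(f"group consensus strings of unequal length: {sorted(lengths)}")
    if wildcard_policy not in ("rotation", "background"):
        raise ValueError(f"unknown wildcard policy {wildcard_policy!r}")
    if wildcard_policy == "rotation":
        k = len(set(rotation_residues))
        if k < 2 or 1.0 / k > max_freq + 1e-12:
            raise ValueError(
                f"{k} rotation residues cannot cap column frequency at {max_freq}"
            )
    rng = np.random.default_rng(seed)
    probs = _background_probs(background)

    ids: list[str] = []
    rows: list[str] = []
    group_of: dict[str, str] = {}
    for group in sorted(motifs):
        consensus = motifs[group]
        for r in range(n_per_group):
            chars = []
            for c, ch in enumerate(consensus):
                if ch == "x":
                    if wildcard_policy == "rotation":
                        chars.append(
                            rotation_residues[(r + c) % len(rotation_residues)]
                        )
                    else:
                        chars.append(AA20[int(rng.choice(20, p=probs))])
                else:
                    chars.append(ch)
            rid = f"{group}_{r:03d}"
            ids.append(rid)
            rows.append("".join(chars))
            group_of[rid] = group
    return GroupedAlignment(ids=ids, rows=rows, group_of=group_of)
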