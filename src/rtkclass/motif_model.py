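"""Degenerate consensus motifs, window scanning, and kinase landmarks.

A motif is an ordered list of positions; each position is either a fixed
residue set (usually a singleton) or a wildcard matching any residue.
Scoring counts only fixed positions: score = fixed_matched / fixed_total.
``X`` in a subject never matches a fixed position.  Universal positions
(conserved across all subtypes of a class; bold in the source tables) are
tracked separately so callers can demand ``universal_ok`` independently of
the overall score.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from rtkclass.alphabet import AA20, N_CODES, X_CODE, encode
from rtkclass.sequence_io import SequenceRecord

__all__ = [
    "DegenerateMotif",
    "MotifMatch",
    "AnchorPair",
    "KinaseLandmarks",
    "compile_motif",
    "motif_from_sets",
    "match_at",
    "scan",
    "best_match",
    "find_anchored_region",
    "locate_kinase_landmarks",
    "MotifLibrary",
    "load_motif_library",
    "GLY_LOOP",
    "CATALYTIC_LOOP",
    "DFG",
]

SubjectLike = Union[str, SequenceRecord]


def _subject_codes(seq: SubjectLike) -> np.ndarray:
    if isinstance(seq, SequenceRecord):
        return encode(seq.residues)
    return encode(seq)


@dataclass(frozen=True)
class DegenerateMotif:
    """Fixed-length degenerate pattern; ``None`` positions are wildcards."""

    name: str
    positions: tuple  # tuple[frozenset[str] | None, ...]
    universal_mask: tuple  # tuple[bool, ...]
    rtk_class: Optional[str] = None
    subtype: Optional[str] = None
    region: Optional[str] = None  # 'fn3' or 'catalytic' for library motifs
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.universal_mask):
            raise ValueError(f"motif {self.name!r}: mask/positions length mismatch")
        if not any(p is not None for p in self.positions):
            raise ValueError(f"motif {self.name!r}: no fixed position")
        for p, uni in zip(self.positions, self.universal_mask):
            if uni and p is None:
                raise ValueError(
                    f"motif {self.name!r}: universal position must be fixed"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def fixed_total(self) -> int:
        return sum(1 for p in self.positions if p is not None)

    def consensus_string(self) -> str:
        """Wildcards as 'x'; multi-residue sets as bracket groups."""
        out = []
        for p in self.positions:
            if p is None:
                out.append("x")
            elif len(p) == 1:
                out.append(next(iter(p)))
            else:
                out.append("[" + "".join(sorted(p)) + "]")
        return "".join(out)

    # --- compiled scan tables, built once per motif -----------------------
    def _tables(self):
        cached = _TABLE_CACHE.get(id(self))
        if cached is not None and cached[0] is self:
            return cached[1]
        offsets = []
        allowed_rows = []
        universal_rows = []
        for i, (p, uni) in enumerate(zip(self.positions, self.universal_mask)):
            if p is None:
                continue
            row = np.zeros(N_CODES, dtype=bool)
            for aa in p:
                row[AA20.index(aa)] = True
            row[X_CODE] = False  # X never matches a fixed position
            offsets.append(i)
            allowed_rows.append(row)
            universal_rows.append(uni)
        tables = (
            np.asarray(offsets, dtype=np.intp),
            np.asarray(allowed_rows, dtype=bool),
            np.asarray(universal_rows, dtype=bool),
        )
        _TABLE_CACHE[id(self)] = (self, tables)
        return tables


_TABLE_CACHE: dict = {}


@dataclass(frozen=True)
class MotifMatch:
    """One scored placement of a motif on a subject (0-based half-open)."""

    motif_name: str
    start: int
    end: int
    score: float
    fixed_matched: int
    fixed_total: int
    universal_ok: bool


def compile_motif(
    consensus: str,
    bold_positions: Iterable[int] = (),
    name: str = "",
    rtk_class: Optional[str] = None,
    subtype: Optional[str] = None,
    source: str = "",
) -> DegenerateMotif:
    """Compile a consensus string ('x' = wildcard) into a DegenerateMotif.

    ``bold_positions`` are 1-based indices of universally conserved
    positions; they must point at fixed (non-'x') characters.
    """
    if not consensus:
        raise ValueError("empty consensus string")
    bold = set(int(b) for b in bold_positions)
    for b in bold:
        if b < 1 or b > len(consensus):
            raise ValueError(f"bold position {b} outside motif of length {len(consensus)}")
    positions = []
    mask = []
    for i, ch in enumerate(consensus, start=1):
        if ch == "x":
            if i in bold:
                raise ValueError(f"bold position {i} points at a wildcard")
            positions.append(None)
            mask.append(False)
        elif ch in AA20:
            positions.append(frozenset(ch))
            mask.append(i in bold)
        else:
            raise ValueError(
                f"character {ch!r} at position {i} outside motif alphabet"
            )
    return DegenerateMotif(
        name=name or consensus,
        positions=tuple(positions),
        universal_mask=tuple(mask),
        rtk_class=rtk_class,
        subtype=subtype,
        source=source,
    )


def motif_from_sets(
    sets: Sequence[Optional[str]],
    name: str,
    universal: Iterable[int] = (),
    **kw,
) -> DegenerateMotif:
    """Build a motif from per-position residue strings (None = wildcard)."""
    uni = set(universal)
    positions = tuple(frozenset(s) if s is not None else None for s in sets)
    mask = tuple((i + 1) in uni for i in range(len(sets)))
    return DegenerateMotif(name=name, positions=positions, universal_mask=mask, **kw)


def _window_scores(codes: np.ndarray, motif: DegenerateMotif):
    """Vectorized per-window fixed-match and universal-match counts."""
    offsets, allowed, universal = motif._tables()
    w = len(motif)
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return None
    matched = np.zeros(n_win, dtype=np.int32)
    uni_matched = np.zeros(n_win, dtype=np.int32)
    for j in range(len(offsets)):
        hits = allowed[j][codes[offsets[j] : offsets[j] + n_win]]
        matched += hits
        if universal[j]:
            uni_matched += hits
    return matched, uni_matched, int(universal.sum())


def match_at(seq: SubjectLike, motif: DegenerateMotif, offset: int) -> MotifMatch:
    """Score a motif at one offset on the subject."""
    codes = _subject_codes(seq)
    if offset < 0 or offset > len(codes) - len(motif):
        raise ValueError(
            f"offset {offset} out of range for subject of length {len(codes)} "
            f"and motif of length {len(motif)}"
        )
    offsets, allowed, universal = motif._tables()
    window = codes[offset : offset + len(motif)]
    hits = allowed[np.arange(len(offsets)), window[offsets]]
    fixed_matched = int(hits.sum())
    n_uni = int(universal.sum())
    universal_ok = bool(hits[universal].all()) if n_uni else True
    return MotifMatch(
        motif_name=motif.name,
        start=offset,
        end=offset + len(motif),
        score=fixed_matched / motif.fixed_total,
        fixed_matched=fixed_matched,
        fixed_total=motif.fixed_total,
        universal_ok=universal_ok,
    )


def scan(seq: SubjectLike, motif: DegenerateMotif, min_score: float = 1.0) -> list[MotifMatch]:
    """All windows with score >= min_score, sorted (score desc, start asc)."""
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must be in [0, 1], got {min_score}")
    codes = _subject_codes(seq)
    res = _window_scores(codes, motif)
    if res is None:
        return []
    matched, uni_matched, n_uni = res
    total = motif.fixed_total
    keep = np.nonzero(matched >= min_score * total - 1e-12)[0]
    w = len(motif)
    out = [
        MotifMatch(
            motif_name=motif.name,
            start=int(s),
            end=int(s) + w,
            score=int(matched[s]) / total,
            fixed_matched=int(matched[s]),
            fixed_total=total,
            universal_ok=bool(uni_matched[s] == n_uni),
        )
        for s in keep
    ]
    out.sort(key=lambda m: (-m.score, m.start))
    return out


def best_match(seq: SubjectLike, motif: DegenerateMotif) -> Optional[MotifMatch]:
    """Top-scoring window (leftmost on ties), or None if subject too short."""
    codes = _subject_codes(seq)
    res = _window_scores(codes, motif)
    if res is None:
        return None
    matched, uni_matched, n_uni = res
    s = int(np.argmax(matched))
    total = motif.fixed_total
    w = len(motif)
    return MotifMatch(
        motif_name=motif.name,
        start=s,
        end=s + w,
        score=int(matched[s]) / total,
        fixed_matched=int(matched[s]),
        fixed_total=total,
        universal_ok=bool(uni_matched[s] == n_uni),
    )


@dataclass(frozen=True)
class AnchorPair:
    """Two anchor motifs bounding a region with an interior length window."""

    n_anchor: DegenerateMotif
    c_anchor: DegenerateMotif
    gap_min: int
    gap_max: int

    def __post_init__(self) -> None:
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min must be <= gap_max")


def find_anchored_region(seq: SubjectLike, anchors: AnchorPair) -> list[tuple[int, int, int]]:
    """Regions (start, end, interior length) bounded by full anchor matches.

    For each full n-anchor match the closest downstream full c-anchor match
    is paired (innermost pairing); pairs whose interior length falls outside
    [gap_min, gap_max] are discarded.
    """
    n_hits = scan(seq, anchors.n_anchor, min_score=1.0)
    c_hits = scan(seq, anchors.c_anchor, min_score=1.0)
    if not n_hits or not c_hits:
        return []
    c_starts = sorted((m.start, m.end) for m in c_hits)
    regions = []
    for n in sorted(n_hits, key=lambda m: m.start):
        downstream = [(cs, ce) for cs, ce in c_starts if cs >= n.end]
        if not downstream:
            continue
        cs, ce = downstream[0]
        interior = cs - n.end
        if anchors.gap_min <= interior <= anchors.gap_max:
            regions.append((n.start, ce, interior))
    return regions


# --- kinase landmarks shared by all four RTK classes ----------------------

GLY_LOOP = compile_motif("GxGxFG", name="gly_loop", source="shared-landmark")
#: catalytic loop accepts the canonical R and the G variant seen in one class
CATALYTIC_LOOP = motif_from_sets(
    ["H", "GR", "D", "L", "A"], name="catalytic_loop", source="shared-landmark"
)
DFG = compile_motif("DFG", name="dfg", source="shared-landmark")


@dataclass(frozen=True)
class KinaseLandmarks:
    """Best consistent placement of the three shared kinase landmarks."""

    gly_loop: Optional[MotifMatch] = None
    catalytic_loop: Optional[MotifMatch] = None
    dfg: Optional[MotifMatch] = None

    @property
    def complete(self) -> bool:
        return all(
            m is not None for m in (self.gly_loop, self.catalytic_loop, self.dfg)
        )


def locate_kinase_landmarks(
    seq: SubjectLike,
    gly_cat_gap: tuple[int, int] = (6, 600),
    cat_dfg_gap: tuple[int, int] = (0, 400),
) -> KinaseLandmarks:
    """Locate Gly-loop, catalytic loop, and DFG with ordering constraints.

    Prefers the leftmost triple satisfying gly < catalytic < DFG within the
    spacing bounds.  When no consistent triple exists, individually found
    landmarks are still reported, subject to the ordering invariant.
    """
    gly_hits = sorted(scan(seq, GLY_LOOP, 1.0), key=lambda m: m.start)
    cat_hits = sorted(scan(seq, CATALYTIC_LOOP, 1.0), key=lambda m: m.start)
    dfg_hits = sorted(scan(seq, DFG, 1.0), key=lambda m: m.start)

    for g in gly_hits:
        for c in cat_hits:
            gap1 = c.start - g.end
            if c.start <= g.start or not gly_cat_gap[0] <= gap1 <= gly_cat_gap[1]:
                continue
            for d in dfg_hits:
                gap2 = d.start - c.end
                if d.start > c.start and cat_dfg_gap[0] <= gap2 <= cat_dfg_gap[1]:
                    return KinaseLandmarks(gly_loop=g, catalytic_loop=c, dfg=d)

    # no consistent triple: report what can be placed without violating order
    cat = cat_hits[0] if cat_hits else None
    if cat is not None:
        gly = next((g for g in gly_hits if g.start < cat.start), None)
        dfg = next((d for d in dfg_hits if d.start > cat.start), None)
    else:
        gly = gly_hits[0] if gly_hits else None
        dfg = dfg_hits[0] if dfg_hits else None
    return KinaseLandmarks(gly_loop=gly, catalytic_loop=cat, dfg=dfg)


# --- packaged motif library ----------------------------------------------

RTK_CLASSES = ("InsR", "EGFR", "FGFR", "PVR")
SUBTYPES = {
    "InsR": ("InsR1", "InsR2", "InsR3"),
    "EGFR": ("EGFR1",),
    "FGFR": ("FGFR1", "FGFR2", "FGFR3"),
    "PVR": ("PVR1", "PVR2A", "PVR2B"),
}


@dataclass
class MotifLibrary:
    """Compiled motif set keyed by name, with class/region views."""

    motifs: dict[str, DegenerateMotif]
    raw_consensus: dict[str, str] = field(default_factory=dict)
    relaxed_catloop: bool = False

    def __getitem__(self, name: str) -> DegenerateMotif:
        return self.motifs[name]

    def subtype_motifs(self, rtk_class: str) -> list[DegenerateMotif]:
        """Subtype-discriminating motifs for one class.

        InsR subtypes are discriminated by the FN3-region motifs; the other
        classes by their catalytic-domain motifs.
        """
        region = "fn3" if rtk_class == "InsR" else "catalytic"
        return [
            m
            for m in self.motifs.values()
            if m.rtk_class == rtk_class and m.subtype is not None
            and m.region == region
        ]

    @property
    def insr_catalytic(self) -> DegenerateMotif:
        return self.motifs["InsR_catalytic"]

    @property
    def egfr_fixture(self) -> DegenerateMotif:
        return self.motifs["EGFR1_catalytic"]

    def with_relaxed_catloop(self) -> "MotifLibrary":
        """Copy where the PVR catalytic-loop G position also admits R.

        Motivated by a published variant in which the glycine of HGDLA is
        replaced by arginine.
        """
        if self.relaxed_catloop:
            return self
        new = dict(self.motifs)
        for name, motif in self.motifs.items():
            if motif.rtk_class != "PVR":
                continue
            positions = list(motif.positions)
            idx = _hgdla_g_index(positions)
            if idx is None:
                continue
            positions[idx] = frozenset("GR")
            new[name] = replace(motif, positions=tuple(positions))
        return MotifLibrary(
            motifs=new, raw_consensus=dict(self.raw_consensus), relaxed_catloop=True
        )


def _hgdla_g_index(positions) -> Optional[int]:
    """Index of the G in the first H-G-D-L-A run of fixed positions."""
    want = "HGDLA"
    for i in range(len(positions) - 4):
        window = positions[i : i + 5]
        if all(p is not None and len(p) == 1 for p in window):
            if "".join(next(iter(p)) for p in window) == want:
                return i + 1
    return None


def load_motif_library(path=None) -> MotifLibrary:
    """Load and compile the packaged (or a user-supplied) motif TSV.

    Columns: name, rtk_class, subtype, region, consensus, bold_positions,
    source.  A '-' in a consensus (alignment-gap artifact) is stripped
    before compilation; the verbatim string is kept in ``raw_consensus``.
    """
    if path is None:
        ref = resources.files("rtkclass").joinpath("data/motifs.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    motifs: dict[str, DegenerateMotif] = {}
    raw: dict[str, str] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        consensus = row["consensus"]
        bold = [int(b) for b in row["bold_positions"].split(",") if b]
        if "-" in consensus:
            stripped, bold = _strip_gaps(consensus, bold)
        else:
            stripped = consensus
        subtype = row["subtype"] or None
        motif = compile_motif(
            stripped,
            bold_positions=bold,
            name=row["name"],
            rtk_class=row["rtk_class"] or None,
            subtype=subtype,
            source=row["source"],
        )
        motif = replace(motif, region=row["region"] or None)
        motifs[motif.name] = motif
        raw[motif.name] = consensus
    return MotifLibrary(motifs=motifs, raw_consensus=raw)


def _strip_gaps(consensus: str, bold: list[int]) -> tuple[str, list[int]]:
    keep = [i for i, ch in enumerate(consensus, start=1) if ch != "-"]
    remap = {old: new for new, old in enumerate(keep, start=1)}
    return consensus.replace("-", ""), [remap[b] for b in bold if b in remap]
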