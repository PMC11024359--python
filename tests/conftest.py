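import pytest

from rtkclass.alphabet import UNKNOWN
from rtkclass.motif_model import MotifMatch, load_motif_library


@pytest.fixture(scope="session")
def library():
    return load_motif_library()


def naive_window_score(residues: str, motif, offset: int):
    """Brute-force per-window recomputation, independent of the scanner."""
    matched = total = 0
    uni_ok = True
    for i, (pos, uni) in enumerate(zip(motif.positions, motif.universal_mask)):
        if pos is None:
            continue
        total += 1
        ch = residues[offset + i]
        hit = ch != UNKNOWN and ch in pos
        matched += hit
        if uni and not hit:
            uni_ok = False
    return matched / total, matched, total, uni_ok


def naive_scan(residues: str, motif, min_score: float):
    """Reference implementation of scan(): enumerate every window."""
    out = []
    for offset in range(len(residues) - len(motif) + 1):
        score, matched, total, uni_ok = naive_window_score(residues, motif, offset)
        if score >= min_score - 1e-12:
            out.append(
                MotifMatch(
                    motif_name=motif.name,
                    start=offset,
                    end=offset + len(motif),
                    score=score,
                    fixed_matched=matched,
                    fixed_total=total,
                    universal_ok=uni_ok,
                )
            )
    out.sort(key=lambda m: (-m.score, m.start))
    return out


@pytest.fixture(scope="session")
def oracle_scan():
    return naive_scan
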