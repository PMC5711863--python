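"""Sequence primitives: IUPAC-aware window matching and oligo Tm.

Probes hybridize as ungapped, equal-length duplexes, so specificity is
measured with Hamming distance over sliding windows rather than edit
distance.  Degenerate (IUPAC) bases in target sequences are treated as
matching any compatible base: a position counts as a mismatch only when
the two base sets are disjoint.  This is conservative for specificity
screening — an ambiguous base is assumed capable of cross-hybridizing.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "encode",
    "reverse_complement",
    "gc_fraction",
    "hamming_profile",
    "hamming_min_over_windows",
    "edit_min_over_windows",
    "tm_nearest_neighbor",
]

# 4-bit encoding: A=1, C=2, G=4, T=8; IUPAC codes are unions.
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
_ENC = np.zeros(256, dtype=np.uint8)
for _b, _v in _IUPAC_BITS.items():
    _ENC[ord(_b)] = _v
    _ENC[ord(_b.lower())] = _v

# complement of the bitmask: A<->T is bit1<->bit8, C<->G is bit2<->bit4
_COMP = np.zeros(16, dtype=np.uint8)
for _m in range(16):
    c = 0
    if _m & 1:
        c |= 8
    if _m & 8:
        c |= 1
    if _m & 2:
        c |= 4
    if _m & 4:
        c |= 2
    _COMP[_m] = c

_COMP_STR = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to the 4-bit IUPAC mask array."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = seq[int(np.argmax(arr == 0))]
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return arr


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C") + s.count("S")) / len(s)


def hamming_profile(query: np.ndarray, subject: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``subject``.

    Both arguments are encoded arrays.  Position i of the result is the
    number of IUPAC-incompatible positions when the query is laid over
    ``subject[i : i + len(query)]``.
    """
    k, n = len(query), len(subject)
    if k > n:
        raise ValueError(f"query ({k} nt) longer than subject ({n} nt)")
    windows = np.lib.stride_tricks.sliding_window_view(subject, k)
    return np.count_nonzero((windows & query) == 0, axis=1)


def hamming_min_over_windows(
    query: str, subject: str, both_strands: bool = True
) -> tuple[int, int, str]:
    """Best ungapped match of ``query`` anywhere in ``subject``.

    Returns ``(min_mismatches, position, strand)`` with ``position`` the
    0-based offset of the best window on the subject's forward coordinates
    and ``strand`` in {"+", "-"}.  Exhaustive over all offsets; ties break
    to the smallest position, then to the "+" strand.
    """
    q = encode(query)
    fwd = hamming_profile(q, encode(subject))
    best_mm = int(fwd.min())
    best_pos = int(fwd.argmin())
    best_strand = "+"
    if both_strands:
        rev = hamming_profile(encode(reverse_complement(query)), encode(subject))
        rc_mm = int(rev.min())
        if rc_mm < best_mm:
            best_mm = rc_mm
            best_pos = int(rev.argmin())
            best_strand = "-"
        elif rc_mm == best_mm:
            rc_pos = int(rev.argmin())
            if rc_pos < best_pos:
                best_pos = rc_pos
                best_strand = "-"
    return best_mm, best_pos, best_strand


def edit_min_over_windows(
    query: str, subject: str, both_strands: bool = True
) -> tuple[int, int, str]:
    """Edit-distance analogue of :func:`hamming_min_over_windows` (edlib HW mode)."""
    import edlib

    if len(query) > len(subject):
        raise ValueError("query longer than subject")
    res = edlib.align(query, subject, mode="HW", task="locations")
    best_mm, best_pos, best_strand = res["editDistance"], res["locations"][0][0], "+"
    if both_strands:
        rres = edlib.align(reverse_complement(query), subject, mode="HW",
                           task="locations")
        if rres["editDistance"] < best_mm or (
            rres["editDistance"] == best_mm
            and rres["locations"][0][0] < best_pos
        ):
            best_mm, best_pos, best_strand = (
                rres["editDistance"], rres["locations"][0][0], "-")
    return best_mm, best_pos or 0, best_strand


# ---------------------------------------------------------------------------
# Nearest-neighbor melting temperature
#
# Unified NN parameters (SantaLucia 1998, 1 M NaCl): dH kcal/mol, dS cal/(mol K)
# for each stacked pair read 5'->3' on the top strand.

_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "AC": (-8.4, -22.4),
    "AG": (-7.8, -21.0), "TA": (-7.2, -21.3), "TT": (-7.9, -22.2),
    "TC": (-8.2, -22.2), "TG": (-8.5, -22.7), "CA": (-8.5, -22.7),
    "CT": (-7.8, -21.0), "CC": (-8.0, -19.9), "CG": (-10.6, -27.2),
    "GA": (-8.2, -22.2), "GT": (-8.4, -22.4), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# duplex initiation with a terminal G:C / A:T pair
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)

_R = 1.987  # cal/(mol K)


def tm_nearest_neighbor(
    sequence: str, na_mM: float = 50.0, oligo_uM: float = 0.25
) -> float:
    """Duplex melting temperature (°C) of an oligo against its perfect complement.

    Two-state nearest-neighbor model with unified stacking parameters and the
    entropic monovalent-salt correction dS += 0.368 * (N-1) * ln[Na+]; oligo
    concentration enters as CT/4 (non-self-complementary assumption).
    """
    s = sequence.upper()
    if not s or any(c not in "ACGT" for c in s):
        raise ValueError("Tm model requires a non-empty ACGT sequence")
    if len(s) < 2:
        raise ValueError("Tm model requires at least 2 nt")
    dh, ds = 0.0, 0.0
    for end in (s[0], s[-1]):
        ih, is_ = _INIT_GC if end in "GC" else _INIT_AT
        dh += ih
        ds += is_
    for i in range(len(s) - 1):
        h, v = _NN[s[i:i + 2]]
        dh += h
        ds += v
    ds += 0.368 * (len(s) - 1) * np.log(na_mM / 1000.0)
    ct = oligo_uM * 1e-6
    tm_K = (dh * 1000.0) / (ds + _R * np.log(ct / 4.0))
    return tm_K - 273.15
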