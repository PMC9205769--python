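"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive position-by-position scans and O(n*k) loops so
they share no code path with the package.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_cut_sites(seq: str, motif: str, offset: int) -> list[int]:
    """All cut coordinates from forward and reverse-strand motif matches,
    found by scanning every position."""
    motif = motif.upper()
    rcm = rc(motif)
    cuts = set()
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i : i + len(motif)]
        if window == motif:
            cuts.add(i + offset)
        if rcm != motif and window == rcm:
            cuts.add(i + len(motif) - offset)
    return sorted(c for c in cuts if 0 <= c <= len(seq))


def brute_digest(seq: str, m1: str, o1: int, m2: str, o2: int):
    """Partition a sequence into primary fragments and end regions.

    Returns a list of dicts, one per fragment end, with the same semantics
    as the package's digestion: left end from fragment start to the first
    secondary cut in [start, end], right end from the last secondary cut;
    fragments without a secondary cut give two blind full-fragment ends,
    zero-length regions are blind.
    """
    primary = brute_cut_sites(seq, m1, o1)
    secondary = brute_cut_sites(seq, m2, o2)
    bounds = sorted({0, len(seq), *primary})
    out = []
    for fs, fe in zip(bounds[:-1], bounds[1:]):
        inner = [c for c in secondary if fs <= c <= fe]
        if not inner:
            out.append(dict(frag=(fs, fe), side="left", region=(fs, fe), blind=True))
            out.append(dict(frag=(fs, fe), side="right", region=(fs, fe), blind=True))
        else:
            out.append(
                dict(frag=(fs, fe), side="left", region=(fs, inner[0]), blind=inner[0] == fs)
            )
            out.append(
                dict(frag=(fs, fe), side="right", region=(inner[-1], fe), blind=inner[-1] == fe)
            )
    return out


def brute_rolling_mean(values: list[float], k: int) -> list[float]:
    """O(n*k) centered windowed mean with edge truncation."""
    half = k // 2
    out = []
    for i in range(len(values)):
        window = values[max(0, i - half) : i + half + 1]
        out.append(sum(window) / len(window))
    return out


def count_substring(haystack: str, needle: str) -> int:
    """Overlapping occurrence count by scanning every start position."""
    return sum(
        1
        for i in range(len(haystack) - len(needle) + 1)
        if haystack[i : i + len(needle)] == needle
    )
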