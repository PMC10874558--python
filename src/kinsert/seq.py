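"""Small sequence helpers used throughout the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_all(haystack: str, needle: str, lo: int = 0, hi: int | None = None) -> list[int]:
    """All 0-based start positions of exact occurrences of ``needle``.

    ``lo``/``hi`` bound the *start* positions searched (hi exclusive).
    Overlapping occurrences are reported.
    """
    if hi is None:
        hi = len(haystack)
    out = []
    i = haystack.find(needle, lo)
    while i != -1 and i < hi:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out
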