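"""Small sequence helpers shared across modules."""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def mismatches(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings, with optional early exit.

    Returns ``limit + 1`` as soon as the count exceeds ``limit``.
    """
    if a == b:
        return 0
    n = 0
    if limit is None:
        return sum(x != y for x, y in zip(a, b))
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n
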