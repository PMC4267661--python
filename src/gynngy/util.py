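"""Small shared helpers: sequence access, reverse complement, rounding."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) (0-based half-open) as an uppercase string.

    ``genome`` may be a plain dict of chromosome strings or any object
    with string-slicing access by chromosome key (e.g. pyfaidx.Fasta).
    """
    if start < 0 or end < start:
        raise ValueError(f"invalid interval [{start}, {end}) on {chrom}")
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"reference {chrom!r} absent from genome") from exc
    return str(seq[start:end]).upper()


def tx_fetch(genome, chrom: str, strand: str, start: int, end: int) -> str:
    """Fetch a genomic interval in transcript orientation.

    For '+' this is genome[start:end); for '-' the reverse complement, so
    the returned string reads 5'->3' along the transcript.
    """
    seq = fetch_seq(genome, chrom, start, end)
    return revcomp(seq) if strand == "-" else seq


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages).

    Python's built-in round() is banker's rounding; printed tables round
    0.5 up, so 44.6 -> 45 and 14.705 -> 14.71.
    """
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to `decimals`."""
    if denominator == 0:
        raise ZeroDivisionError("proportion with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)
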