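"""Degenerate CArG-box consensus patterns and sequence scanning.

MADS-domain transcription factors bind CArG boxes, quasi-palindromic
A/T-rich elements. The field recognises several consensus classes:

* ``canonical`` — C(C/T)(A/T)6(A/G)G, the general 10-mer consensus;
* ``srf_like``  — CC(A/T)6GG, the SRF/serum-response-element core;
* ``n10_like``  — CTA(A/T)4TAG, the MEF2-class N10 core;
* ``intermediate`` — C(A/T)6AG, an 8-mer intermediate class.

"Atypical" sites deviate from the canonical consensus at one or two
positions; the mismatch budget is configurable (default 2, the minimal rule
consistent with published atypical examples from the tomato LeEXP1 and
LeACS4 promoters).

Coordinates are 0-based half-open. Scanning both strands is the default
because CArG boxes are quasi-palindromic; exact palindromic duplicates
(same window, identical matched sequence on both strands) are reported once
on the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import InvalidAlphabetError, LengthError
from .io import revcomp

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate consensus: one allowed-base set per position."""

    name: str
    positions: tuple[frozenset, ...]
    max_atypical: int = 2

    def __post_init__(self) -> None:
        for i, allowed in enumerate(self.positions):
            if not allowed or not set(allowed) <= _ACGT:
                raise InvalidAlphabetError(
                    f"pattern {self.name}: position {i} set {allowed!r} "
                    "must be a nonempty subset of ACGT"
                )
        if self.max_atypical < 0:
            raise ValueError("max_atypical must be >= 0")

    def __len__(self) -> int:
        return len(self.positions)

    def mismatches(self, window: str) -> int:
        """Count positions of ``window`` outside the allowed set."""
        if len(window) != len(self):
            raise LengthError(
                f"window length {len(window)} != pattern length {len(self)}"
            )
        return sum(base not in allowed for base, allowed in zip(window, self.positions))


@dataclass(frozen=True)
class MotifHit:
    """A located (possibly atypical) CArG-box match."""

    seq_id: str
    start: int
    end: int
    strand: str
    matched_seq: str
    pattern_name: str
    n_atypical: int


def _sets(spec: str) -> tuple[frozenset, ...]:
    # spec like "C,CT,AT,AT,AT,AT,AT,AT,AG,G"
    return tuple(frozenset(tok) for tok in spec.split(","))


CANONICAL = MotifPattern("canonical", _sets("C,CT,AT,AT,AT,AT,AT,AT,AG,G"))
SRF_LIKE = MotifPattern("srf_like", _sets("C,C,AT,AT,AT,AT,AT,AT,G,G"))
N10_LIKE = MotifPattern("n10_like", _sets("C,T,A,AT,AT,AT,AT,T,A,G"))
INTERMEDIATE = MotifPattern("intermediate", _sets("C,AT,AT,AT,AT,AT,AT,A,G"))

#: Classification precedence for ties: canonical beats srf_like beats n10_like.
_CLASSIFY_ORDER = (CANONICAL, SRF_LIKE, N10_LIKE)


def builtin_patterns() -> list[MotifPattern]:
    """The four named CArG-box consensus classes."""
    return [CANONICAL, SRF_LIKE, N10_LIKE, INTERMEDIATE]


def get_pattern(name: str) -> MotifPattern:
    for p in builtin_patterns():
        if p.name == name:
            return p
    raise KeyError(f"unknown pattern {name!r}")


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _ACGT
    if bad:
        raise InvalidAlphabetError(f"invalid characters {sorted(bad)}")
    return seq


def classify_carg(decamer: str, max_atypical: int = 2) -> tuple[str, int | None]:
    """Classify a 10-mer against the CArG consensus classes.

    Returns ``(pattern_name, n_atypical)`` for the best-matching 10-mer
    pattern (fewest deviating positions; ties broken canonical > srf_like >
    n10_like), or ``("none", None)`` when every pattern needs more than
    ``max_atypical`` deviations.
    """
    decamer = _validate_seq(decamer)
    if len(decamer) != 10:
        raise LengthError(f"expected a 10-mer, got length {len(decamer)}")
    best_name, best_n = "none", None
    for pattern in _CLASSIFY_ORDER:
        n = pattern.mismatches(decamer)
        if n <= max_atypical and (best_n is None or n < best_n):
            best_name, best_n = pattern.name, n
    return best_name, best_n


def scan_sequence(
    seq_id: str,
    sequence: str,
    patterns: Iterable[MotifPattern] | None = None,
    max_atypical: int = 2,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan a sequence for CArG-box matches within a mismatch budget.

    Every window on the requested strand(s) matching a pattern with at most
    ``max_atypical`` deviations yields one hit; hits come back sorted by
    (start, strand). A window whose minus-strand match reads identically to
    its plus-strand match (an exact palindrome) is reported once, on "+".
    """
    sequence = _validate_seq(sequence)
    if patterns is None:
        patterns = builtin_patterns()
    hits: dict[tuple, MotifHit] = {}
    for pattern in patterns:
        k = len(pattern)
        for i in range(len(sequence) - k + 1):
            window = sequence[i : i + k]
            for strand in ("+", "-") if both_strands else ("+",):
                probe = window if strand == "+" else revcomp(window)
                n = pattern.mismatches(probe)
                if n > max_atypical:
                    continue
                key = (pattern.name, i, strand)
                hit = MotifHit(
                    seq_id=seq_id,
                    start=i,
                    end=i + k,
                    strand=strand,
                    matched_seq=probe,
                    pattern_name=pattern.name,
                    n_atypical=n,
                )
                # palindromic duplicate: same window, same matched bases on
                # both strands -> keep only the "+" report
                plus_key = (pattern.name, i, "+")
                if strand == "-" and plus_key in hits and hits[plus_key].matched_seq == probe:
                    continue
                hits[key] = hit
    out = sorted(hits.values(), key=lambda h: (h.start, h.strand, h.pattern_name))
    return out


def hits_to_bed(hits: Sequence[MotifHit]) -> str:
    """Render hits as BED6-like TSV lines (name = pattern/n_atypical)."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.seq_id,
                    str(h.start),
                    str(h.end),
                    f"{h.pattern_name}/{h.n_atypical}",
                    str(h.n_atypical),
                    h.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
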