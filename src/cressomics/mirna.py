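"""MIRNA candidate curation against structural and read-based criteria.

Plant miRNA annotations are notoriously noisy, so candidate hairpins are
screened with hard rules on the precursor and on the miRNA/miRNA* duplex:
a hairpin of at most 300 nt folding into a single stem-loop across the
duplex span, at least 75% of the locus reads belonging to the duplex, a
mature length of 20-24 nt, at most five mismatched positions of which at
most three are nucleotides in asymmetric bulges, no internal loops, and
two-nucleotide 3' overhangs on both duplex ends.

Secondary structure is an input (dot-bracket from any folding engine);
no folding is performed here.

Definitions used for duplex oppositions (an "opposition" is a stretch of
``a`` unpaired nucleotides on the mature strand facing ``b`` unpaired on
the star strand between two closing pairs):

* mismatch        — a 1:1 opposition (counted once);
* asymmetric bulge — the ``|a - b|`` surplus nucleotides when one strand
  has more unpaired nucleotides than the other;
* internal loop   — an opposition with a >= 2 and b >= 2 (disallowed).

``mismatch_count`` accumulates min(a, b) per opposition plus the
asymmetric-bulge nucleotides, so the bulge allowance is a subset of the
mismatch allowance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_HAIRPIN_LEN = 300
MIN_DUPLEX_READ_FRACTION = 0.75
MATURE_LEN_RANGE = (20, 24)
MAX_MISMATCHES = 5
MAX_BULGE_NT = 3
DUPLEX_READ_SLACK = 2  # nt of end slack when matching reads to duplex arms


@dataclass
class HairpinCandidate:
    """A candidate precursor: sequence, dot-bracket fold and read stack.

    ``reads`` are (start, end, copy count) in hairpin coordinates
    (0-based half-open); ``mature`` is the proposed mature-arm interval,
    or None to use the most abundant read.
    """

    id: str
    sequence: str
    structure: str
    reads: list[tuple[int, int, int]] = field(default_factory=list)
    mature: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError(f"{self.id}: sequence and structure lengths differ")
        n = len(self.sequence)
        for s, e, c in self.reads:
            if not (0 <= s < e <= n):
                raise ValueError(f"{self.id}: read [{s},{e}) outside hairpin")
            if c <= 0:
                raise ValueError(f"{self.id}: non-positive read count")


@dataclass
class CurationVerdict:
    id: str
    passed: bool
    criteria: dict[str, bool]
    measured: dict[str, object]
    reasons: list[str] = field(default_factory=list)


CRITERIA = (
    "hairpin_length",
    "single_stem",
    "duplex_read_fraction",
    "mature_length",
    "mismatch_count",
    "asymmetric_bulge_count",
    "internal_loops",
    "three_prime_overhang",
)


def parse_structure(structure: str) -> np.ndarray:
    """Pair table from a dot-bracket string.

    Returns an int array where ``table[i]`` is the partner of position i,
    or -1 if unpaired. Raises ValueError naming the first offending index
    on unbalanced brackets or foreign characters.
    """
    table = np.full(len(structure), -1, dtype=int)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at index {i}")
            j = stack.pop()
            table[i] = j
            table[j] = i
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at index {i}")
    if stack:
        raise ValueError(f"unmatched '(' at index {stack[0]}")
    return table


def render_structure(table: np.ndarray) -> str:
    """Inverse of :func:`parse_structure`."""
    chars = []
    for i, j in enumerate(table):
        chars.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(chars)


def terminal_loops(table: np.ndarray, lo: int = 0, hi: int | None = None) -> int:
    """Number of hairpin (terminal) loops with closing pair inside [lo, hi)."""
    hi = len(table) if hi is None else hi
    n_loops = 0
    for i in range(lo, hi):
        j = table[i]
        if j > i and j < hi:  # candidate closing pair (i, j)
            if all(table[k] == -1 for k in range(i + 1, j)):
                n_loops += 1
    return n_loops


@dataclass
class DuplexDescription:
    mature: tuple[int, int]
    star: tuple[int, int]
    mismatches: int  # 1:1 (and min(a,b) of mixed) oppositions
    bulge_nt: int  # nucleotides in asymmetric bulges
    internal_loops: int  # >=2:>=2 oppositions
    overhang_mature_3p: int | None
    overhang_star_3p: int | None
    spans_loop: bool


def _most_abundant_read(candidate: HairpinCandidate) -> tuple[int, int]:
    if not candidate.reads:
        raise ValueError(f"{candidate.id}: no reads and no proposed mature interval")
    s, e, _ = max(candidate.reads, key=lambda r: (r[2], -(r[1] - r[0])))
    return s, e


def extract_duplex(
    candidate: HairpinCandidate, table: np.ndarray | None = None
) -> DuplexDescription:
    """Locate the miRNA* and classify every duplex opposition.

    The star interval is the span of positions pairing with the mature,
    shifted by the canonical 2-nt 3' offset of Dicer processing. 3'
    overhangs are measured on both duplex ends; a value of 2 on each is
    the expected signature. If the mature arm spans the terminal loop the
    duplex is flagged (``spans_loop``) rather than raising.
    """
    if table is None:
        table = parse_structure(candidate.structure)
    m0, m1 = candidate.mature if candidate.mature else _most_abundant_read(candidate)
    partners = [(i, table[i]) for i in range(m0, m1) if table[i] >= 0]
    if not partners:
        return DuplexDescription((m0, m1), (m0, m1), 0, 0, 0, None, None, True)
    part = np.array([p for _, p in partners])
    spans_loop = bool(part.min() < m0 and part.max() >= m1) or bool(
        ((part >= m0) & (part < m1)).any()
    )
    qmin, qmax = int(part.min()), int(part.max())
    if spans_loop:
        return DuplexDescription((m0, m1), (qmin, qmax + 1), 0, 0, 0, None, None, True)

    # The miRNA* spans the partners of the mature shifted by the 2-nt
    # 3' processing offset; antiparallel pairing makes the shift the same
    # whichever arm carries the mature.
    n = len(table)
    star = (max(0, qmin + 2), min(n, qmax + 3))

    # walk consecutive paired mature positions and classify oppositions
    mism = 0
    bulge = 0
    loops = 0
    for (i, pi), (j, pj) in zip(partners, partners[1:]):
        a = j - i - 1  # unpaired on mature strand
        b = abs(pi - pj) - 1  # unpaired on star strand
        if a >= 2 and b >= 2:
            loops += 1
        else:
            mism += min(a, b)
            bulge += abs(a - b)

    m_lo, m_hi = partners[0][0], partners[-1][0]
    # 3' overhang of the mature = its tail beyond the star 5' end's partner;
    # with the 2-nt processing offset this equals 2 + unpaired mature 3' tail
    # (and symmetrically for the star 3' end vs the mature 5' head).
    overhang_mature = 2 + (m1 - 1 - m_hi)
    overhang_star = 2 + (m_lo - m0)
    return DuplexDescription(
        (m0, m1), star, mism, bulge, loops, overhang_mature, overhang_star, False
    )


def duplex_read_fraction(
    candidate: HairpinCandidate,
    mature: tuple[int, int],
    star: tuple[int, int],
    slack: int = DUPLEX_READ_SLACK,
) -> float | None:
    """Copy-weighted fraction of hairpin reads matching either duplex arm.

    A read belongs to the duplex when both of its ends fall within
    ``slack`` nt of the mature or the star interval ends. Returns None
    when the candidate carries no reads.
    """
    total = sum(c for _, _, c in candidate.reads)
    if total == 0:
        return None
    inside = 0
    for s, e, c in candidate.reads:
        for a0, a1 in (mature, star):
            if abs(s - a0) <= slack and abs(e - a1) <= slack:
                inside += c
                break
    return inside / total


def evaluate_candidate(
    candidate: HairpinCandidate,
    max_hairpin_len: int = MAX_HAIRPIN_LEN,
    min_duplex_fraction: float = MIN_DUPLEX_READ_FRACTION,
    mature_len_range: tuple[int, int] = MATURE_LEN_RANGE,
    max_mismatches: int = MAX_MISMATCHES,
    max_bulge_nt: int = MAX_BULGE_NT,
    require_both_overhangs: bool = True,
) -> CurationVerdict:
    """Apply every curation rule and return the per-criterion verdict."""
    table = parse_structure(candidate.structure)
    duplex = extract_duplex(candidate, table)
    m0, m1 = duplex.mature
    crit: dict[str, bool] = {}
    meas: dict[str, object] = {}
    reasons: list[str] = []

    meas["hairpin_length"] = len(candidate.sequence)
    crit["hairpin_length"] = len(candidate.sequence) <= max_hairpin_len

    span_lo = min(m0, duplex.star[0])
    span_hi = max(m1, duplex.star[1])
    n_loops = terminal_loops(table, span_lo, span_hi)
    meas["terminal_loops"] = n_loops
    crit["single_stem"] = (not duplex.spans_loop) and n_loops == 1
    if duplex.spans_loop:
        reasons.append("mature arm spans the terminal loop")

    frac = duplex_read_fraction(candidate, duplex.mature, duplex.star)
    meas["duplex_read_fraction"] = frac
    if frac is None:
        crit["duplex_read_fraction"] = False
        reasons.append("no reads: duplex read fraction undefined")
    else:
        crit["duplex_read_fraction"] = frac >= min_duplex_fraction

    meas["mature_length"] = m1 - m0
    crit["mature_length"] = mature_len_range[0] <= m1 - m0 <= mature_len_range[1]

    mism_total = duplex.mismatches + duplex.bulge_nt
    meas["mismatch_count"] = mism_total
    crit["mismatch_count"] = mism_total <= max_mismatches
    meas["asymmetric_bulge_count"] = duplex.bulge_nt
    crit["asymmetric_bulge_count"] = duplex.bulge_nt <= max_bulge_nt
    meas["internal_loops"] = duplex.internal_loops
    crit["internal_loops"] = duplex.internal_loops == 0

    meas["overhangs"] = (duplex.overhang_mature_3p, duplex.overhang_star_3p)
    if duplex.overhang_mature_3p is None:
        crit["three_prime_overhang"] = False
    elif require_both_overhangs:
        crit["three_prime_overhang"] = (
            duplex.overhang_mature_3p == 2 and duplex.overhang_star_3p == 2
        )
    else:
        crit["three_prime_overhang"] = 2 in (
            duplex.overhang_mature_3p,
            duplex.overhang_star_3p,
        )

    return CurationVerdict(
        id=candidate.id,
        passed=all(crit.values()),
        criteria=crit,
        measured=meas,
        reasons=reasons,
    )
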