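"""Splice-acceptor consensus classification and ref/alt impact calls.

A functional 3' splice site ends the intron with the mammalian consensus
N[C/T]AG|G: any base, a pyrimidine, then the invariant AG dinucleotide,
followed by G as the first exonic base (| marks the splice point).  A
variant that breaks this consensus in a gene copy whose reference passes it
is predicted to occlude canonical splicing — a high-impact acceptor variant.
Only this five-position rule is scored; branch points and the
polypyrimidine tract are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

# offsets relative to the splice point: -4..-1 intronic, 0 first exonic base
CONSENSUS = (
    (-4, "N", set("ACGTN")),
    (-3, "C/T", set("CT")),
    (-2, "A", set("A")),
    (-1, "G", set("G")),
    (0, "G", set("G")),
)


def reverse_complement(seq: str) -> str:
    _validate_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_alphabet(seq: str) -> None:
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(
            f"sequence contains characters outside A/C/G/T/N: {sorted(bad)}"
        )


@dataclass(frozen=True)
class AcceptorSite:
    """An acceptor context: sequence, splice point and strand.

    ``splice_point`` indexes the exon's first base within ``seq`` as given;
    for minus-strand sites classification reverse-complements first, so the
    same genomic site yields the same verdict regardless of which strand the
    sequence was extracted from.
    """

    seq: str
    splice_point: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        _validate_alphabet(self.seq)
        object.__setattr__(self, "seq", self.seq.upper())
        if not 0 <= self.splice_point <= len(self.seq):
            raise ValueError("splice_point outside sequence")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def oriented(self) -> tuple[str, int]:
        """Sequence and splice point on the gene (sense) strand."""
        if self.strand == "+":
            return self.seq, self.splice_point
        return reverse_complement(self.seq), len(self.seq) - self.splice_point


@dataclass
class AcceptorVerdict:
    """Classification outcome for one acceptor context."""

    passes: bool
    failed_positions: list[tuple[int, str, str]] = field(default_factory=list)
    impact: str = "none"  # {"none", "high"}
    ref_failed: bool = False  # set by compare_acceptors when ref is non-consensus

    def __post_init__(self) -> None:
        if self.passes != (not self.failed_positions):
            raise ValueError("passes must mirror an empty failed_positions list")


def classify_acceptor(site: AcceptorSite) -> AcceptorVerdict:
    """Score an acceptor context against N[C/T]AG|G.

    Positions -4..-1 before the splice point must read N, [C/T], A, G and
    position 0 (the exon's first base) must be G.  An N in the input matches
    only the degenerate N slot: at any constrained position it fails, so
    masked or uncertain bases never silently pass.  A context without four
    intronic and one exonic base raises rather than silently passing.
    """
    seq, sp = site.oriented()
    if sp < 4 or sp >= len(seq):
        raise ValueError(
            f"acceptor context too short: need 4 intronic and 1 exonic base around "
            f"splice point {sp} in a sequence of length {len(seq)}"
        )
    failed: list[tuple[int, str, str]] = []
    for offset, expected, allowed in CONSENSUS:
        base = seq[sp + offset]
        if base == "N" and expected != "N":
            failed.append((offset, expected, base))
        elif base not in allowed:
            failed.append((offset, expected, base))
    return AcceptorVerdict(passes=not failed, failed_positions=failed)


def compare_acceptors(ref: AcceptorSite, alt: AcceptorSite) -> AcceptorVerdict:
    """Impact call for *alt* relative to *ref*.

    impact is "high" iff the reference passes the consensus and the
    alternate breaks it (canonical splicing predicted to be occluded).  When
    the reference itself fails, no impact is assigned and the verdict is
    flagged, since the comparison baseline is already non-functional.
    """
    ref_verdict = classify_acceptor(ref)
    alt_verdict = classify_acceptor(alt)
    impact = "high" if (ref_verdict.passes and not alt_verdict.passes) else "none"
    return AcceptorVerdict(
        passes=alt_verdict.passes,
        failed_positions=alt_verdict.failed_positions,
        impact=impact,
        ref_failed=not ref_verdict.passes,
    )


def scan_acceptors(seq: str, strand: str = "both") -> list[AcceptorSite]:
    """All positions in *seq* matching the 5-base acceptor consensus.

    Returns one :class:`AcceptorSite` per hit, with coordinates on the input
    sequence; minus-strand hits carry strand "-" and a splice point such
    that classification (which reverse-complements) passes.
    """
    _validate_alphabet(seq)
    seq = seq.upper()
    if strand not in ("+", "-", "both"):
        raise ValueError(f"invalid strand {strand!r}")
    hits: list[AcceptorSite] = []
    if strand in ("+", "both"):
        for i in range(len(seq) - 4):
            if _matches_consensus(seq, i):
                hits.append(AcceptorSite(seq, splice_point=i + 4, strand="+"))
    if strand in ("-", "both"):
        rc = reverse_complement(seq)
        for i in range(len(rc) - 4):
            if _matches_consensus(rc, i):
                # rc splice point i+4 maps back to len - (i+4) on the input
                hits.append(AcceptorSite(seq, splice_point=len(seq) - (i + 4), strand="-"))
    return hits


def _matches_consensus(seq: str, i: int) -> bool:
    w = seq[i : i + 5]
    return (
        w[0] in "ACGTN"
        and w[1] in "CT"
        and w[2] == "A"
        and w[3] == "G"
        and w[4] == "G"
    )
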