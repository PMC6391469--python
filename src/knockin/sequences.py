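"""Genomic sequence primitives for SpCas9 knock-in design.

Handles PAM (NGG) scanning on both strands, the blunt cut-site convention,
the signed mutation-to-cut distance, and construction of single-stranded
oligodeoxynucleotide (ssODN) donors homologous to the PAM strand.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open on the forward reference
strand.  The Cas9 cut is modelled as a blunt double-strand break 3 bp 5' of
the PAM, i.e. at the inter-base boundary between protospacer positions 17
and 18 (1-based positions on the guide strand).

The mutation-to-cut distance is signed on the PAM strand (the strand
carrying the NGG): with ``m`` the 0-based index of the edited base and
``c`` the cut boundary, both in PAM-strand orientation, the distance is
``c - m``.  Distance 0 therefore denotes the first base 3' of the cut
(toward the PAM), positive distances lie 5' of the cut and negative
distances 3' of the cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

NUCLEOTIDES = frozenset("ACGT")
NUCLEOTIDES_N = frozenset("ACGTN")

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN  # 23
#: bases between the cut boundary and the PAM (blunt SpCas9 cut)
CUT_OFFSET_FROM_PAM = 3


class SequenceError(ValueError):
    """Raised for malformed sequences or inconsistent design requests."""


def _validate_dna(seq: str, *, allow_n: bool = False, what: str = "sequence") -> str:
    seq = seq.upper()
    alphabet = NUCLEOTIDES_N if allow_n else NUCLEOTIDES
    bad = set(seq) - alphabet
    if bad:
        raise SequenceError(
            f"{what} contains non-nucleotide characters {sorted(bad)!r}; "
            f"expected only {''.join(sorted(alphabet))}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over the alphabet ACGTN."""
    seq = _validate_dna(seq, allow_n=True)
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class DesiredEdit:
    """A single-nucleotide substitution the user wants to install.

    ``position`` is 1-based (VCF convention) on ``contig``; ``ref`` must
    match the reference base at that position whenever the reference
    sequence is available to check against.
    """

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for name in ("ref", "alt"):
            base = getattr(self, name).upper()
            if base not in NUCLEOTIDES:
                raise SequenceError(f"{name} allele must be one of A,C,G,T, got {base!r}")
            object.__setattr__(self, name, base)
        if self.ref == self.alt:
            raise SequenceError("ref and alt alleles must differ")
        if self.position < 1:
            raise SequenceError("position is 1-based and must be >= 1")


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt SpCas9 protospacer adjacent to an NGG PAM.

    ``protospacer`` and ``pam`` are given in guide-strand orientation;
    ``start`` is the 0-based forward-strand start of the protospacer.
    """

    protospacer: str
    pam: str
    strand: str  # "+" or "-"
    start: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SequenceError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise SequenceError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got {len(self.protospacer)}"
            )
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise SequenceError(f"PAM must match NGG, got {self.pam!r}")

    @property
    def end(self) -> int:
        """0-based half-open forward-strand end of the protospacer."""
        return self.start + PROTOSPACER_LEN

    @property
    def cut_boundary(self) -> int:
        """0-based inter-base cut coordinate on the forward strand."""
        return cut_boundary(self)

    def protospacer_offset(self, forward_index: int) -> int:
        """1-based protospacer position of a forward-strand base index.

        Returns a value in 1..20 when the base lies inside the protospacer;
        values outside that range indicate the base is outside it.
        """
        if self.strand == "+":
            return forward_index - self.start + 1
        return self.end - forward_index


def cut_boundary(candidate: GuideCandidate) -> int:
    """Blunt cut boundary (0-based inter-base, forward strand) of a guide.

    The break sits 3 bp 5' of the PAM: between protospacer positions 17 and
    18.  For a + strand protospacer at [s, s+20) this is s+17; for a -
    strand protospacer at [a, a+20) (PAM at [a-3, a)) it is a+3.
    """
    if candidate.strand == "+":
        return candidate.start + PROTOSPACER_LEN - CUT_OFFSET_FROM_PAM
    return candidate.start + CUT_OFFSET_FROM_PAM


def find_guide_candidates(
    sequence: str,
    region: Optional[tuple[int, int]] = None,
) -> list[GuideCandidate]:
    """Enumerate every NGG guide on either strand of ``sequence``.

    ``region`` restricts the scan to a 0-based half-open forward-strand
    interval; the full 23-nt site (protospacer + PAM) must lie inside it.
    Protospacers containing N are excluded; the degenerate PAM position
    accepts any of A,C,G,T but not N.  Candidates are sorted by forward
    start, then strand (+ before -).
    """
    sequence = _validate_dna(sequence, allow_n=True)
    lo, hi = region if region is not None else (0, len(sequence))
    if not (0 <= lo <= hi <= len(sequence)):
        raise SequenceError(f"region {region} outside sequence of length {len(sequence)}")
    if hi - lo < SITE_LEN:
        warnings.warn(
            f"region of length {hi - lo} is shorter than a {SITE_LEN}-nt target site; "
            "no guides can be found",
            stacklevel=2,
        )
        return []

    out: list[GuideCandidate] = []
    for s in range(lo, hi - SITE_LEN + 1):
        # + strand: protospacer [s, s+20), PAM [s+20, s+23) reading NGG
        proto = sequence[s : s + PROTOSPACER_LEN]
        pam = sequence[s + PROTOSPACER_LEN : s + SITE_LEN]
        if pam[1:] == "GG" and pam[0] in NUCLEOTIDES and "N" not in proto:
            out.append(GuideCandidate(proto, pam, "+", s))
        # - strand: forward sequence reads CCN at [s, s+3), protospacer [s+3, s+23)
        fpam = sequence[s : s + PAM_LEN]
        fproto = sequence[s + PAM_LEN : s + SITE_LEN]
        if fpam[:2] == "CC" and fpam[2] in NUCLEOTIDES and "N" not in fproto:
            out.append(
                GuideCandidate(
                    reverse_complement(fproto),
                    reverse_complement(fpam),
                    "-",
                    s + PAM_LEN,
                )
            )
    out.sort(key=lambda g: (g.start, g.strand))
    return out


def mutation_cut_distance(candidate: GuideCandidate, edit_forward_index: int) -> int:
    """Signed distance (bases) from the cut to the edited base, PAM strand.

    ``edit_forward_index`` is the 0-based forward-strand index of the edited
    base.  The distance is measured in the guide's PAM-strand orientation:
    0 = first base 3' of the cut, positive = 5' of the cut, negative = 3'
    of the cut (toward the PAM).
    """
    c = cut_boundary(candidate)
    if candidate.strand == "+":
        return c - edit_forward_index
    return edit_forward_index + 1 - c


@dataclass(frozen=True)
class SsODN:
    """A single-stranded donor: the edit flanked by homology arms.

    The sequence is homologous to the PAM strand of the targeted guide.
    ``center_index`` (= arm5) is the 0-based position of the edited base;
    total length is arm5 + 1 + arm3.
    """

    sequence: str
    arm5: int
    arm3: int
    edit: DesiredEdit
    strand: str = "+"

    def __post_init__(self) -> None:
        _validate_dna(self.sequence, what="ssODN sequence")
        if len(self.sequence) != self.arm5 + 1 + self.arm3:
            raise SequenceError(
                f"ssODN length {len(self.sequence)} != arm5 + 1 + arm3 "
                f"= {self.arm5 + 1 + self.arm3}"
            )
        # the alt allele expressed in PAM-strand orientation
        expected = self.edit.alt if self.strand == "+" else reverse_complement(self.edit.alt)
        if self.sequence[self.center_index] != expected:
            raise SequenceError(
                f"ssODN centre base {self.sequence[self.center_index]!r} does not "
                f"carry the alt allele ({expected!r} in PAM-strand orientation)"
            )

    @property
    def center_index(self) -> int:
        return self.arm5


def design_ssodn(
    context: str,
    edit: DesiredEdit,
    candidate: GuideCandidate,
    arm5: int = 70,
    arm3: int = 70,
    edit_index: Optional[int] = None,
) -> SsODN:
    """Design an ssODN donor homologous to the guide's PAM strand.

    ``context`` is forward-strand reference sequence containing the edit;
    ``edit_index`` locates the edited base within it (default: centre of
    the context).  Arm lengths are counted in PAM-strand orientation, so
    for a - strand guide the donor is the reverse complement of the
    forward-reference window with the alt base substituted.
    """
    context = _validate_dna(context, what="reference context")
    if edit_index is None:
        edit_index = len(context) // 2
    if not (0 <= edit_index < len(context)):
        raise SequenceError(f"edit_index {edit_index} outside context")
    if context[edit_index] != edit.ref:
        raise SequenceError(
            f"reference mismatch at edit site: context has "
            f"{context[edit_index]!r}, edit declares ref {edit.ref!r}"
        )
    # arm lengths in PAM-strand orientation map onto the forward window
    left, right = (arm5, arm3) if candidate.strand == "+" else (arm3, arm5)
    lo, hi = edit_index - left, edit_index + right + 1
    if lo < 0 or hi > len(context):
        raise SequenceError(
            f"context too short: designing arms {arm5}/{arm3} requires "
            f"{left} bases 5' and {right} bases 3' of the edit on the forward "
            f"strand (span {arm5 + 1 + arm3}), context provides "
            f"{edit_index} and {len(context) - edit_index - 1}"
        )
    window = context[lo:edit_index] + edit.alt + context[edit_index + 1 : hi]
    if candidate.strand == "-":
        window = reverse_complement(window)
    return SsODN(window, arm5=arm5, arm3=arm3, edit=edit, strand=candidate.strand)
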