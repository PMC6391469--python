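"""Rule-based base-editing strategy finder.

Cytosine base editors (CBE) convert C·G to T·A and adenine base editors
(ABE) convert A·T to G·C, but only within a narrow "editing window" of the
protospacer (positions numbered 1..20 from the 5' end, PAM at 21..23;
default window 4..8).  A desired substitution is achievable when the edited
base, read on the strand where it is the editor's substrate (C for CBE, A
for ABE), falls inside the window of some NGG guide.

Any other same-letter base inside the window is a *proximal off-target*
(bystander) that the deaminase may convert alongside the intended base.
Plans are never discarded for carrying bystanders — they are flagged and
ranked (fewest bystanders first, then most central target position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .sequences import (
    DesiredEdit,
    GuideCandidate,
    SequenceError,
    find_guide_candidates,
    _validate_dna,
)

#: editing window as inclusive 1-based protospacer positions
DEFAULT_WINDOW = (4, 8)

#: substitution -> (editor, strand of the guide relative to the edit's strand)
#: "same": the guide's protospacer strand carries the substrate base as given;
#: "opposite": the substrate sits on the complementary strand.
EDITOR_RULES: dict[tuple[str, str], tuple[str, str]] = {
    ("C", "T"): ("CBE", "same"),
    ("G", "A"): ("CBE", "opposite"),
    ("A", "G"): ("ABE", "same"),
    ("T", "C"): ("ABE", "opposite"),
}

#: substrate base each editor deaminates, in protospacer orientation
SUBSTRATE = {"CBE": "C", "ABE": "A"}


def applicable_editors(ref: str, alt: str) -> list[tuple[str, str]]:
    """Editors able to install ref->alt, with the guide strand relative to ref.

    Returns an empty list for substitutions outside the base-editing
    repertoire (those need HDR instead).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise SequenceError("ref and alt must differ")
    rule = EDITOR_RULES.get((ref, alt))
    return [rule] if rule is not None else []


@dataclass(frozen=True)
class BaseEditPlan:
    """One guide able to place the desired edit inside its editing window."""

    editor: str  # "CBE" | "ABE"
    guide: GuideCandidate
    target_offset: int  # 1-based protospacer position of the edited base
    window: tuple[int, int]
    proximal_offtargets: tuple[int, ...]  # same-letter window positions != target

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo <= self.target_offset <= hi):
            raise ValueError(
                f"target offset {self.target_offset} outside editing window {self.window}"
            )

    @property
    def centrality(self) -> float:
        """Distance of the target from the window centre (lower = better)."""
        lo, hi = self.window
        return abs(self.target_offset - (lo + hi) / 2)


def find_base_edit_plans(
    sequence: str,
    edit: DesiredEdit,
    window: tuple[int, int] = DEFAULT_WINDOW,
    *,
    edit_index: Optional[int] = None,
) -> list[BaseEditPlan]:
    """All NGG guides placing ``edit`` inside a base editor's window.

    ``sequence`` is forward-strand context around the edit; ``edit_index``
    is the 0-based index of the edited base within it (default: the edit's
    1-based ``position`` interpreted directly on ``sequence``).  Returns an
    empty list when no editor covers the substitution or no guide places
    the base in-window; HDR is then the fallback strategy.
    """
    sequence = _validate_dna(sequence, allow_n=True)
    if edit_index is None:
        edit_index = edit.position - 1
    if not (0 <= edit_index < len(sequence)):
        raise SequenceError(f"edit index {edit_index} outside the provided sequence")
    if sequence[edit_index] != edit.ref:
        raise SequenceError(
            f"reference mismatch: sequence has {sequence[edit_index]!r} at the edit "
            f"site, edit declares ref {edit.ref!r}"
        )
    rules = applicable_editors(edit.ref, edit.alt)
    if not rules:
        return []
    lo, hi = window
    if not (1 <= lo <= hi <= 20):
        raise ValueError(f"editing window must lie within protospacer positions 1..20, got {window}")

    plans: list[BaseEditPlan] = []
    for editor, rel_strand in rules:
        substrate = SUBSTRATE[editor]
        # the guide must read the substrate base at the edit site: for a
        # "same"-strand rule that is a + strand guide (protospacer strand ==
        # reference forward strand when ref base == substrate); "opposite"
        # means the - strand guide reads the substrate.
        want_strand = "+" if rel_strand == "same" else "-"
        for g in find_guide_candidates(sequence):
            if g.strand != want_strand:
                continue
            offset = g.protospacer_offset(edit_index)
            if not (lo <= offset <= hi):
                continue
            if g.protospacer[offset - 1] != substrate:
                # inconsistent context (should not happen when ref matches)
                continue
            bystanders = tuple(
                pos
                for pos in range(lo, hi + 1)
                if pos != offset and g.protospacer[pos - 1] == substrate
            )
            plans.append(
                BaseEditPlan(
                    editor=editor,
                    guide=g,
                    target_offset=offset,
                    window=window,
                    proximal_offtargets=bystanders,
                )
            )
    plans.sort(key=lambda p: (len(p.proximal_offtargets), p.centrality, p.guide.start))
    return plans
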