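"""Sequence feature encodings for HDR-efficiency modelling.

Guide encodings form a nested family:

* ``G1`` (20 features) — mono- plus overlapping di-nucleotide counts of the
  20-nt protospacer.
* ``G2`` (25) — G1 plus generic repeat features: the longest homopolymer
  run per base and the number of bases inside any run of length >= 3.
* ``G3`` (29) — G2 plus weak/strong (AT/CG) composition: A+T count, C+G
  count, and the longest AT-only and CG-only runs.
* ``G4`` (33) — G3 plus purine/pyrimidine composition: counts and longest
  single-class runs.
* ``G5`` — positional one-hot encoding (one indicator per position x base),
  optionally over PAM and flanking context; dimension 4 x positions.

Donor (ssODN) encodings take the composition of a region that starts at the
edited centre base and extends outward into one arm (or the whole donor),
mirroring how resection-driven annealing engages the donor from its 3' end.
The mixed encoding ``M1`` concatenates the guide G1 vector with the 3'-arm
composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sequences import GuideCandidate, SequenceError, SsODN, _validate_dna

MONO = ("A", "C", "G", "T")
DI = tuple("".join(p) for p in itertools.product(MONO, repeat=2))
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: dimensions of the guide encoding family
GUIDE_SCHEME_DIMS = {"G1": 20, "G2": 25, "G3": 29, "G4": 33}
SCHEMES = ("G1", "G2", "G3", "G4", "G5", "O1", "O2", "O3", "M1")


@dataclass(frozen=True)
class FeatureVector:
    """An ordered, named numeric encoding of a guide or donor."""

    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def concat(self, other: "FeatureVector", scheme: str) -> "FeatureVector":
        return FeatureVector(
            scheme, self.names + other.names, np.concatenate([self.values, other.values])
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.scheme)


def _as_seq(obj: Union[str, GuideCandidate]) -> str:
    seq = obj.protospacer if isinstance(obj, GuideCandidate) else obj
    return _validate_dna(seq)


def mono_composition(seq: str) -> FeatureVector:
    """Counts of A, C, G, T; they sum to len(seq)."""
    seq = _validate_dna(seq)
    values = [seq.count(b) for b in MONO]
    return FeatureVector("mono", MONO, np.array(values))


def di_composition(seq: str) -> FeatureVector:
    """Counts of the 16 overlapping dinucleotides; they sum to len(seq) - 1."""
    seq = _validate_dna(seq)
    if len(seq) < 2:
        import warnings

        warnings.warn("sequence shorter than 2 nt has no dinucleotides", stacklevel=2)
        return FeatureVector("di", DI, np.zeros(16))
    counts = dict.fromkeys(DI, 0)
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    return FeatureVector("di", DI, np.array([counts[d] for d in DI]))


def _runs(seq: str) -> Iterable[tuple[str, int]]:
    for base, grp in itertools.groupby(seq):
        yield base, sum(1 for _ in grp)


def _longest_run(seq: str, alphabet: frozenset) -> int:
    """Longest run of consecutive characters all drawn from ``alphabet``."""
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch in alphabet else 0
        best = max(best, cur)
    return best


def _composition_vector(seq: str) -> FeatureVector:
    return mono_composition(seq).concat(di_composition(seq), "composition")


def g1_encode(guide: Union[str, GuideCandidate]) -> FeatureVector:
    """Guide (di)nucleotide composition: 20 features."""
    seq = _as_seq(guide)
    if len(seq) != 20:
        raise SequenceError(f"expected a 20-nt protospacer, got {len(seq)} nt")
    fv = _composition_vector(seq)
    return FeatureVector("G1", fv.names, fv.values)


def _repeat_features(seq: str) -> FeatureVector:
    """Generic repeats: longest homopolymer per base + bases in runs >= 3."""
    longest = dict.fromkeys(MONO, 0)
    in_runs = 0
    for base, n in _runs(seq):
        longest[base] = max(longest[base], n)
        if n >= 3:
            in_runs += n
    names = tuple(f"run_{b}" for b in MONO) + ("bases_in_runs_ge3",)
    return FeatureVector("repeats", names, np.array([*longest.values(), in_runs]))


def _at_cg_features(seq: str) -> FeatureVector:
    """Weak/strong composition: AT and CG counts and longest single-class runs."""
    at = sum(seq.count(b) for b in "AT")
    cg = sum(seq.count(b) for b in "CG")
    values = [at, cg, _longest_run(seq, frozenset("AT")), _longest_run(seq, frozenset("CG"))]
    return FeatureVector("atcg", ("count_AT", "count_CG", "run_AT", "run_CG"), np.array(values))


def _pur_pyr_features(seq: str) -> FeatureVector:
    """Purine/pyrimidine composition: counts and longest single-class runs."""
    pur = sum(1 for ch in seq if ch in PURINES)
    pyr = len(seq) - pur
    values = [pur, pyr, _longest_run(seq, PURINES), _longest_run(seq, PYRIMIDINES)]
    names = ("count_purine", "count_pyrimidine", "run_purine", "run_pyrimidine")
    return FeatureVector("purpyr", names, np.array(values))


def g2_g3_g4_encode(guide: Union[str, GuideCandidate], scheme: str) -> FeatureVector:
    """Nested guide encodings G2 (25), G3 (29), G4 (33)."""
    if scheme not in ("G2", "G3", "G4"):
        raise ValueError(f"unknown scheme {scheme!r}; expected G2, G3 or G4")
    seq = _as_seq(guide)
    fv = g1_encode(seq).concat(_repeat_features(seq), "G2")
    if scheme >= "G3":
        fv = fv.concat(_at_cg_features(seq), "G3")
    if scheme == "G4":
        fv = fv.concat(_pur_pyr_features(seq), "G4")
    return FeatureVector(scheme, fv.names, fv.values)


def g5_encode(
    guide: Union[str, GuideCandidate],
    context: str = "",
) -> FeatureVector:
    """Positional one-hot encoding of the guide (optionally plus context).

    Every (position, base) pair becomes an indicator named ``N_<pos>_<base>``
    with positions numbered 1..L over protospacer followed by any context
    (e.g. the PAM and flanks).  Exactly one indicator per position is set.
    """
    seq = _as_seq(guide) + _validate_dna(context) if context else _as_seq(guide)
    names: list[str] = []
    values: list[int] = []
    for i, ch in enumerate(seq, start=1):
        for b in MONO:
            names.append(f"N_{i}_{b}")
            values.append(1 if ch == b else 0)
    return FeatureVector("G5", tuple(names), np.array(values))


def g5_decode(fv: FeatureVector) -> str:
    """Invert :func:`g5_encode` back to the encoded sequence."""
    length = len(fv) // 4
    out = []
    for i in range(1, length + 1):
        hits = [b for b in MONO if fv.values[fv.names.index(f"N_{i}_{b}")] == 1]
        if len(hits) != 1:
            raise ValueError(f"position {i} does not have exactly one indicator set")
        out.append(hits[0])
    return "".join(out)


@dataclass(frozen=True)
class ArmRegion:
    """A donor region starting at the centre base and extending outward."""

    side: str  # "5prime" or "3prime"
    length_k: int
    sequence: str

    def __post_init__(self) -> None:
        if self.side not in ("5prime", "3prime"):
            raise ValueError(f"side must be '5prime' or '3prime', got {self.side!r}")
        if len(self.sequence) != self.length_k:
            raise ValueError("region sequence length does not match length_k")


def _ssodn_parts(ssodn: Union[SsODN, tuple[str, int]]) -> tuple[str, int]:
    if isinstance(ssodn, SsODN):
        return ssodn.sequence, ssodn.center_index
    seq, center = ssodn
    return _validate_dna(seq), center


def extract_arm_region(
    ssodn: Union[SsODN, tuple[str, int]], side: str, k: int
) -> ArmRegion:
    """The k bases adjacent to the centre on one side, read outward.

    The 3' region is bases centre+1 .. centre+k; the 5' region is bases
    centre-k .. centre-1.  Both are returned reading *outward from the
    centre*, so that the two sides are anchored identically: a donor whose
    arms mirror each other about the centre yields equal 5' and 3'
    encodings.  ``ssodn`` may be an :class:`SsODN` or a
    ``(sequence, center_index)`` pair.
    """
    seq, center = _ssodn_parts(ssodn)
    arm5, arm3 = center, len(seq) - center - 1
    max_k = arm3 if side == "3prime" else arm5
    if side not in ("5prime", "3prime"):
        raise ValueError(f"side must be '5prime' or '3prime', got {side!r}")
    if k < 0 or k > max_k:
        raise SequenceError(f"region length {k} exceeds the {side} arm; max permitted k is {max_k}")
    if side == "3prime":
        region = seq[center + 1 : center + 1 + k]
    else:
        region = seq[center - k : center][::-1]
    return ArmRegion(side, k, region)


def o_encode(
    ssodn: Union[SsODN, tuple[str, int]],
    side: Optional[str] = None,
    k: Optional[int] = None,
    *,
    include_di: bool = True,
) -> FeatureVector:
    """Composition of a donor region (whole donor when ``side`` is None).

    Mono-nucleotide counts, plus overlapping dinucleotide counts unless
    ``include_di=False``.  Feature names carry a region prefix (``full_``,
    ``arm3_``, ``arm5_``) so mixed encodings stay unambiguous.
    """
    seq, center = _ssodn_parts(ssodn)
    if side is None:
        region, prefix, scheme = seq, "full", "O-full"
    else:
        if k is None:
            k = (len(seq) - center - 1) if side == "3prime" else center
        region = extract_arm_region((seq, center), side, k).sequence
        prefix = "arm3" if side == "3prime" else "arm5"
        scheme = f"O-{prefix}"
    fv = _composition_vector(region) if include_di else mono_composition(region)
    return FeatureVector(scheme, tuple(f"{prefix}_{n}" for n in fv.names), fv.values)


def m1_encode(
    guide: Union[str, GuideCandidate],
    ssodn: Union[SsODN, tuple[str, int]],
    k3: Optional[int] = None,
    *,
    include_di: bool = True,
) -> FeatureVector:
    """Mixed encoding: guide G1 composition plus 3'-arm donor composition."""
    fv = g1_encode(guide).concat(
        o_encode(ssodn, "3prime", k3, include_di=include_di), "M1"
    )
    return FeatureVector("M1", fv.names, fv.values)


class OneHotExpander:
    """Expand categorical columns into indicator columns named <col>_<value>.

    Numeric columns pass through unchanged.  Category sets are learned at
    fit time; unseen categories at transform time either raise (default)
    or yield an all-zero indicator group (``unseen='zero'``).
    """

    def __init__(self, columns: Optional[Sequence[str]] = None, unseen: str = "error"):
        if unseen not in ("error", "zero"):
            raise ValueError("unseen must be 'error' or 'zero'")
        self.columns = list(columns) if columns is not None else None
        self.unseen = unseen
        self.categories_: dict[str, list] = {}

    def fit(self, table: pd.DataFrame) -> "OneHotExpander":
        cols = self.columns
        if cols is None:
            cols = [c for c in table.columns if not pd.api.types.is_numeric_dtype(table[c])]
        self.categories_ = {c: sorted(table[c].astype(str).unique()) for c in cols}
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not self.categories_:
            raise RuntimeError("OneHotExpander must be fit before transform")
        out = {}
        for col in table.columns:
            if col not in self.categories_:
                out[col] = table[col]
                continue
            vals = table[col].astype(str)
            cats = self.categories_[col]
            unseen_mask = ~vals.isin(cats)
            if unseen_mask.any() and self.unseen == "error":
                bad = sorted(vals[unseen_mask].unique())
                raise ValueError(f"column {col!r} has unseen categories {bad}")
            for cat in cats:
                out[f"{col}_{cat}"] = (vals == cat).astype(int)
        return pd.DataFrame(out, index=table.index)

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Recover the original categorical columns from indicator groups."""
        out = {}
        consumed: set[str] = set()
        for col, cats in self.categories_.items():
            group = [f"{col}_{c}" for c in cats]
            consumed.update(group)
            sub = table[group].to_numpy()
            vals = []
            for row in sub:
                hits = [c for c, v in zip(cats, row) if v == 1]
                vals.append(hits[0] if len(hits) == 1 else None)
            out[col] = vals
        for col in table.columns:
            if col not in consumed:
                out[col] = table[col]
        return pd.DataFrame(out, index=table.index)


def one_hot_expand(
    table: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    unseen: str = "error",
) -> pd.DataFrame:
    """One-shot categorical expansion (fit + transform on the same table)."""
    return OneHotExpander(columns, unseen).fit_transform(table)


def encode_guide(guide: Union[str, GuideCandidate], scheme: str, context: str = "") -> FeatureVector:
    """Dispatch a guide through one of the G-family encodings."""
    if scheme == "G1":
        return g1_encode(guide)
    if scheme in ("G2", "G3", "G4"):
        return g2_g3_g4_encode(guide, scheme)
    if scheme == "G5":
        return g5_encode(guide, context)
    raise ValueError(f"unknown guide scheme {scheme!r}")


def encode_sample(
    guide: Union[str, GuideCandidate],
    ssodn: Union[SsODN, tuple[str, int]],
    scheme: str,
    *,
    k: Optional[int] = None,
    include_di: bool = True,
    g5_context: str = "",
) -> FeatureVector:
    """Encode one (guide, donor) pair under any supported scheme.

    O1 = whole-donor composition, O2 = 3' arm, O3 = 5' arm; M1 = G1 + 3' arm.
    """
    if scheme in ("G1", "G2", "G3", "G4", "G5"):
        return encode_guide(guide, scheme, g5_context)
    if scheme == "O1":
        fv = o_encode(ssodn, None, include_di=include_di)
    elif scheme == "O2":
        fv = o_encode(ssodn, "3prime", k, include_di=include_di)
    elif scheme == "O3":
        fv = o_encode(ssodn, "5prime", k, include_di=include_di)
    elif scheme == "M1":
        return m1_encode(guide, ssodn, k, include_di=include_di)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return FeatureVector(scheme, fv.names, fv.values)
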