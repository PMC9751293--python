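"""PROSITE-style conserved-residue motifs for glycine reductase screening.

Glycine reductase (GrdB) and its paralog sarcosine reductase (GrdF) are
selenoprotein subunits whose homologs are hard to tell apart by
similarity alone.  This module implements a small motif grammar over
protein sequences — literal residues, ``x`` wildcards, ``x(n)`` /
``x(n,m)`` bounded runs, and ``[...]`` alternative sets — and ships the
two conserved-residue patterns used to screen Grd homolog collections:
a GrdF pattern (sarcosine reductase) and a GrdB pattern (glycine
reductase).  Classification applies GrdF first: any sequence carrying
the GrdF signature is labelled GrdF-like even if it also satisfies the
GrdB pattern, mirroring the subtraction step used when curating GrdB
sets.

Selenocysteine (``U``) substitutes for cysteine at catalytic positions,
so ``U`` satisfies literal ``C`` anchors (and any wildcard); ambiguous
``X`` satisfies wildcards only.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .errors import MotifParseError

__all__ = [
    "AMINO_ACIDS", "Literal", "AnyOf", "Gap", "MotifPattern", "MotifMatch",
    "GrdLabel", "parse_motif", "match_motif", "classify_grd",
    "classify_grd_clusters", "read_fasta", "GRDB_MOTIF", "GRDF_MOTIF",
    "GRDB_MOTIF_TEXT", "GRDF_MOTIF_TEXT",
]

#: the 20 standard residues
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in input sequences (adds selenocysteine and unknown)
SEQUENCE_ALPHABET = AMINO_ACIDS + "UX"


@dataclass(frozen=True)
class Literal:
    residue: str

    def accepts(self, c: str) -> bool:
        return c == self.residue or (c == "U" and self.residue == "C")

    def serialize(self) -> str:
        return self.residue


@dataclass(frozen=True)
class AnyOf:
    residues: Tuple[str, ...]  # sorted, unique

    def accepts(self, c: str) -> bool:
        return c in self.residues or (c == "U" and "C" in self.residues)

    def serialize(self) -> str:
        return "[" + "".join(self.residues) + "]"


@dataclass(frozen=True)
class Gap:
    """``min``..``max`` arbitrary residues; ``x`` is Gap(1, 1)."""

    min: int
    max: int

    def __post_init__(self):
        if not (0 <= self.min <= self.max):
            raise ValueError(f"invalid gap bounds ({self.min},{self.max})")

    def serialize(self) -> str:
        if self.min == self.max:
            return "x" if self.min == 1 else f"x({self.min})"
        return f"x({self.min},{self.max})"


Element = Union[Literal, AnyOf, Gap]


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: Tuple[Element, ...]

    def serialize(self) -> str:
        return "".join(el.serialize() for el in self.elements)

    @property
    def min_length(self) -> int:
        return sum(el.min if isinstance(el, Gap) else 1
                   for el in self.elements)

    @property
    def max_length(self) -> int:
        return sum(el.max if isinstance(el, Gap) else 1
                   for el in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    pattern: str
    matched: bool
    span: Optional[Tuple[int, int]] = None   # 0-based, half-open
    anchors: Tuple[int, ...] = ()            # start position of each element


@dataclass(frozen=True)
class GrdLabel:
    sequence_id: str
    label: str  # GrdF-like | GrdB-like | non-Grd
    evidence: Dict[str, bool] = field(default_factory=dict)


def parse_motif(text: str, name: str = "") -> MotifPattern:
    """Parse the motif grammar.

    Capital letters are literal residues, ``x`` any residue, ``x(n)``
    exactly n, ``x(n,m)`` n..m, ``[...]`` an alternative set.
    Whitespace separates segments with zero implied distance.
    """
    elements: List[Element] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "x":
            i += 1
            if i < n and text[i] == "(":
                j = text.find(")", i)
                if j < 0:
                    raise MotifParseError("unclosed gap bounds", i)
                body = text[i + 1:j]
                parts = body.split(",")
                try:
                    nums = [int(p) for p in parts]
                except ValueError:
                    raise MotifParseError(f"bad gap bounds {body!r}", i) from None
                if len(nums) == 1:
                    lo = hi = nums[0]
                elif len(nums) == 2:
                    lo, hi = nums
                else:
                    raise MotifParseError(f"bad gap bounds {body!r}", i)
                if not (0 <= lo <= hi):
                    raise MotifParseError(
                        f"inverted or negative gap bounds ({lo},{hi})", i)
                elements.append(Gap(lo, hi))
                i = j + 1
            else:
                elements.append(Gap(1, 1))
        elif c == "[":
            j = text.find("]", i)
            if j < 0:
                raise MotifParseError("unclosed alternative set", i)
            body = text[i + 1:j]
            if not body:
                raise MotifParseError("empty alternative set", i)
            bad = [r for r in body if r not in AMINO_ACIDS]
            if bad:
                raise MotifParseError(f"unknown residues {bad} in set", i)
            elements.append(AnyOf(tuple(sorted(set(body)))))
            i = j + 1
        elif c in AMINO_ACIDS:
            elements.append(Literal(c))
            i += 1
        else:
            raise MotifParseError(f"unexpected character {c!r}", i)
    return MotifPattern(name=name, elements=tuple(elements))


# Conserved-residue signatures distinguishing the sarcosine reductase
# substrate subunit (GrdF) from the glycine reductase one (GrdB).
GRDF_MOTIF_TEXT = ("YxNx(6)GGE x(34,38) CGD x(27,35) GPxF[NF]AGRYG "
                   "x(150,181) IHGGYDRx(6)[IP]x(4)PxD x(19,20) "
                   "TTGTGTx(7)F x(12) [HILV]")
GRDB_MOTIF_TEXT = ("YxNx(6)GGE x(34,38) CGD x(27,35) GPxF[NF]AGRYG "
                   "x(157,178) AHGGxD[QTAP] x(8) RV[IL]PxD x(19,20) "
                   "TxGNxTxV")

GRDF_MOTIF = parse_motif(GRDF_MOTIF_TEXT, name="GrdF")
GRDB_MOTIF = parse_motif(GRDB_MOTIF_TEXT, name="GrdB")


def _search_from(seq: str, elements: Sequence[Element], pos: int, idx: int,
                 fail: set) -> Optional[List[int]]:
    """Backtracking matcher; returns element anchor positions or None.
    Gap lengths are tried ascending, so the first solution found uses
    minimal gaps (leftmost-earliest span convention)."""
    if idx == len(elements):
        return []
    key = (idx, pos)
    if key in fail:
        return None
    el = elements[idx]
    if isinstance(el, Gap):
        hi = min(el.max, len(seq) - pos)
        for glen in range(el.min, hi + 1):
            rest = _search_from(seq, elements, pos + glen, idx + 1, fail)
            if rest is not None:
                return [pos] + rest
    else:
        if pos < len(seq) and el.accepts(seq[pos]):
            rest = _search_from(seq, elements, pos + 1, idx + 1, fail)
            if rest is not None:
                return [pos] + rest
    fail.add(key)
    return None


def match_motif(pattern: MotifPattern, sequence: str,
                sequence_id: str = "") -> MotifMatch:
    """Leftmost-earliest match of ``pattern`` in ``sequence``.

    Deterministic; unmatched sequences yield ``matched=False`` rather
    than an error.
    """
    seq = sequence.upper()
    fail: set = set()
    last_start = len(seq) - pattern.min_length
    for start in range(0, last_start + 1):
        anchors = _search_from(seq, pattern.elements, start, 0, fail)
        if anchors is not None:
            # end = anchor of last element + its consumed length
            if pattern.elements:
                last = pattern.elements[-1]
                consumed = 1 if not isinstance(last, Gap) else _gap_consumed(
                    anchors, pattern, seq)
                end = anchors[-1] + consumed
            else:
                end = start
            return MotifMatch(sequence_id=sequence_id, pattern=pattern.name,
                              matched=True, span=(start, end),
                              anchors=tuple(anchors))
    return MotifMatch(sequence_id=sequence_id, pattern=pattern.name,
                      matched=False)


def _gap_consumed(anchors: List[int], pattern: MotifPattern, seq: str) -> int:
    # minimal-gap convention: a trailing gap consumes its minimum length
    return pattern.elements[-1].min


def prefix_match_length(pattern: MotifPattern, sequence: str) -> int:
    """Diagnostic: the largest k such that the first k elements of
    ``pattern`` match somewhere in ``sequence`` (in order).  Full-length
    matches equal ``len(pattern.elements)``; partial conservation (for
    example the divergent archaeal Grd homolog) scores lower."""
    seq = sequence.upper()
    for k in range(len(pattern.elements), 0, -1):
        sub = MotifPattern(name=f"{pattern.name}[:{k}]",
                           elements=pattern.elements[:k])
        if match_motif(sub, seq).matched:
            return k
    return 0


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a protein FASTA into (id, sequence) pairs (order preserved)."""
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _as_pairs(sequences) -> List[Tuple[str, str]]:
    if isinstance(sequences, (str, Path)):
        return read_fasta(sequences)
    return [(str(i), str(s)) for i, s in sequences]


def classify_grd(sequences, grdb: MotifPattern = GRDB_MOTIF,
                 grdf: MotifPattern = GRDF_MOTIF) -> List[GrdLabel]:
    """Label each sequence GrdF-like / GrdB-like / non-Grd.

    GrdF takes precedence: GrdF-like ⇔ the GrdF pattern matches
    (regardless of GrdB); GrdB-like ⇔ GrdB matches and GrdF does not.
    ``sequences`` is a FASTA path or an iterable of (id, sequence).
    """
    pairs = _as_pairs(sequences)
    seen: Dict[str, int] = {}
    for sid, _ in pairs:
        seen[sid] = seen.get(sid, 0) + 1
    dups = sorted(sid for sid, k in seen.items() if k > 1)
    if dups:
        raise ValueError(f"duplicate sequence ids: {dups}")
    labels = []
    for sid, seq in pairs:
        f = match_motif(grdf, seq, sid).matched
        b = match_motif(grdb, seq, sid).matched
        if f:
            label = "GrdF-like"
        elif b:
            label = "GrdB-like"
        else:
            label = "non-Grd"
        labels.append(GrdLabel(sequence_id=sid, label=label,
                               evidence={"GrdB": b, "GrdF": f}))
    return labels


def classify_grd_clusters(sequences, threshold: float = 0.75,
                          grdb: MotifPattern = GRDB_MOTIF,
                          grdf: MotifPattern = GRDF_MOTIF):
    """Cluster-level screening: cluster at ``threshold`` identity, then
    label a whole cluster GrdF-like if *any* member carries the GrdF
    motif (the subtraction step applied at cluster granularity),
    GrdB-like if any member carries GrdB and none GrdF, else non-Grd.

    Returns (clusters, {representative_id: label}).
    """
    from .cluster import cluster_identity
    pairs = _as_pairs(sequences)
    per_seq = {lab.sequence_id: lab for lab in classify_grd(pairs, grdb, grdf)}
    clusters = cluster_identity(pairs, threshold=threshold)
    labels = {}
    for cl in clusters:
        evid = [per_seq[m].evidence for m in cl.members]
        if any(e["GrdF"] for e in evid):
            labels[cl.representative] = "GrdF-like"
        elif any(e["GrdB"] for e in evid):
            labels[cl.representative] = "GrdB-like"
        else:
            labels[cl.representative] = "non-Grd"
    return clusters, labels
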