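"""Kinase-substrate consensus motif inference and proteome scanning.

A consensus motif is an ordered run of positions, each a fixed residue, a
small residue class (rendered ``[AVM]``), or a wildcard ``x``; one position
may be flagged as the phosphoacceptor and is rendered with a trailing ``*``
(e.g. ``LxRxxS*[AVM]Pxx[ILV]``).  A wildcard means exactly one arbitrary
residue — the motif has fixed spacing, so pattern width never varies.

Motifs are inferred from aligned ±N-residue windows around known
phosphosites, scanned against protein sequences, and candidate sites are
annotated with mass-spec confirmation and a secondary pattern such as the
14-3-3 docking motif ``R[ST]xSxP``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifPosition:
    """One motif position: () = wildcard, 1 residue = fixed, 2+ = class.

    ``residues`` keeps a rendering order (most frequent first); equality and
    hashing use the residue SET, so two motifs that differ only in member
    order compare equal.
    """

    residues: tuple = ()

    @property
    def is_wildcard(self) -> bool:
        return len(self.residues) == 0

    @property
    def is_fixed(self) -> bool:
        return len(self.residues) == 1

    def matches(self, ch: Optional[str]) -> bool:
        """``ch`` is None when the position falls outside the sequence; only a
        wildcard tolerates that."""
        if self.is_wildcard:
            return True
        return ch is not None and ch in self.residues

    def __eq__(self, other) -> bool:
        if not isinstance(other, MotifPosition):
            return NotImplemented
        return frozenset(self.residues) == frozenset(other.residues)

    def __hash__(self) -> int:
        return hash(frozenset(self.residues))


@dataclass(frozen=True)
class ConsensusMotif:
    """Fixed-width motif; ``phospho_index`` indexes ``positions`` (None for
    plain patterns with no designated phosphoacceptor)."""

    positions: tuple
    phospho_index: Optional[int] = None

    def __post_init__(self):
        if self.phospho_index is not None:
            pos = self.positions[self.phospho_index]
            if pos.is_wildcard or not set(pos.residues) <= {"S", "T"}:
                raise ValueError("phospho position must be S, T or [ST]")

    @property
    def width(self) -> int:
        return len(self.positions)

    def offsets(self):
        """Offsets of each position relative to the phosphoacceptor."""
        if self.phospho_index is None:
            raise ValueError("motif has no phospho position")
        return range(-self.phospho_index, self.width - self.phospho_index)


@dataclass(frozen=True)
class PhosphoSiteWindow:
    """±flank sequence context of one phosphosite (1-based ``position``);
    terminus overhang is padded with '-'."""

    protein_id: str
    position: int
    residue: str
    window: str

    @property
    def flank(self) -> int:
        return (len(self.window) - 1) // 2


@dataclass
class MotifMatch:
    protein_id: str
    position: int  # 1-based index of the phosphoacceptor residue
    window: str
    confirmed_by_ms: bool = False
    matches_14_3_3: bool = False


def extract_windows(
    proteome: Mapping[str, str],
    sites: Iterable,
    flank: int = 5,
) -> list:
    """Cut a gap-padded ±``flank`` window around each (protein_id, position)
    phosphosite.  Positions are 1-based; the residue there must be S or T."""
    out = []
    for protein_id, position in sites:
        try:
            seq = proteome[protein_id]
        except KeyError:
            raise KeyError(f"protein {protein_id!r} not in proteome") from None
        if not (1 <= position <= len(seq)):
            raise ValueError(f"{protein_id}: position {position} outside sequence")
        residue = seq[position - 1]
        if residue not in ("S", "T"):
            raise ValueError(
                f"{protein_id} position {position}: expected S/T, found {residue}"
            )
        lo, hi = position - 1 - flank, position + flank
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(seq))
        window = GAP * left_pad + seq[max(lo, 0): min(hi, len(seq))] + GAP * right_pad
        out.append(PhosphoSiteWindow(protein_id, position, residue, window))
    return out


def infer_consensus(windows: Sequence[PhosphoSiteWindow], max_class: int = 3) -> ConsensusMotif:
    """Column-wise consensus over aligned windows.

    One distinct residue at a column -> fixed; 2..``max_class`` distinct ->
    a residue class ordered by descending frequency (ties by first
    appearance); more -> wildcard.  Gaps never count as residues.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    width = len(windows[0].window)
    if any(len(w.window) != width for w in windows):
        raise ValueError("windows differ in width")
    flank = windows[0].flank
    positions = []
    for col in range(width):
        chars = [w.window[col] for w in windows if w.window[col] != GAP]
        counts = Counter(chars)
        if col == flank and not set(counts) <= {"S", "T"}:
            raise ValueError("phosphoacceptor column contains non-S/T residues")
        if len(counts) == 0 or len(counts) > max_class:
            positions.append(MotifPosition())
        else:
            first_seen = {ch: chars.index(ch) for ch in counts}
            ordered = sorted(counts, key=lambda ch: (-counts[ch], first_seen[ch]))
            positions.append(MotifPosition(tuple(ordered)))
    return ConsensusMotif(tuple(positions), phospho_index=flank)


def render_motif(m: ConsensusMotif) -> str:
    """Render in bracket notation, with '*' after the phospho position."""
    parts = []
    for i, pos in enumerate(m.positions):
        if pos.is_wildcard:
            tok = "x"
        elif pos.is_fixed:
            tok = pos.residues[0]
        else:
            tok = "[" + "".join(pos.residues) + "]"
        if i == m.phospho_index:
            tok += "*"
        parts.append(tok)
    return "".join(parts)


def parse_motif(text: str) -> ConsensusMotif:
    """Parse bracket notation back into a :class:`ConsensusMotif`.

    Round-trips with :func:`render_motif`.  A pattern without '*' has no
    phospho position (``phospho_index`` is None).
    """
    positions = []
    phospho_index = None
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "x":
            positions.append(MotifPosition())
            i += 1
        elif ch == "[":
            end = text.find("]", i)
            if end == -1:
                raise ValueError(f"unclosed bracket at column {i}")
            members = text[i + 1: end]
            if not members or any(c not in AMINO_ACIDS for c in members):
                raise ValueError(f"invalid class {members!r} at column {i}")
            positions.append(MotifPosition(tuple(members)))
            i = end + 1
        elif ch == "*":
            if not positions or phospho_index is not None:
                raise ValueError(f"misplaced '*' at column {i}")
            phospho_index = len(positions) - 1
            i += 1
        elif ch == "]":
            raise ValueError(f"unmatched ']' at column {i}")
        elif ch in AMINO_ACIDS:
            positions.append(MotifPosition((ch,)))
            i += 1
        else:
            raise ValueError(f"unexpected character {ch!r} at column {i}")
    if not positions:
        raise ValueError("empty motif")
    return ConsensusMotif(tuple(positions), phospho_index=phospho_index)


def _matches_at(seq: str, anchor_pos0: int, motif: ConsensusMotif, anchor_index: int) -> bool:
    """Does ``motif`` match ``seq`` with positions[anchor_index] aligned on
    0-based ``anchor_pos0``?  Non-wildcard positions outside the sequence
    fail."""
    start = anchor_pos0 - anchor_index
    for j, pos in enumerate(motif.positions):
        k = start + j
        ch = seq[k] if 0 <= k < len(seq) else None
        if not pos.matches(ch):
            return False
    return True


def scan_proteome(
    proteome: Mapping[str, str],
    motif: ConsensusMotif,
    target_residues: frozenset = frozenset({"S"}),
) -> list:
    """Report every target residue whose aligned context satisfies the motif.

    Overlapping matches are all reported; windows truncated at a terminus
    fail any non-wildcard position that falls outside the sequence.
    """
    if motif.phospho_index is None:
        raise ValueError("motif has no phospho position to anchor the scan")
    flank = max(motif.phospho_index, motif.width - 1 - motif.phospho_index)
    matches = []
    for pid in proteome:
        seq = proteome[pid]
        for i, ch in enumerate(seq):
            if ch not in target_residues:
                continue
            if _matches_at(seq, i, motif, motif.phospho_index):
                lo, hi = i - flank, i + flank + 1
                window = (GAP * max(0, -lo)
                          + seq[max(lo, 0): min(hi, len(seq))]
                          + GAP * max(0, hi - len(seq)))
                matches.append(MotifMatch(pid, i + 1, window))
    return matches


def secondary_anchor_index(motif: ConsensusMotif) -> int:
    """Anchor for aligning a secondary pattern on a candidate phosphosite:
    the motif's phospho position if designated, else its last fixed S (the
    phosphoserine of the mode-1 14-3-3 pattern R[ST]xSxP)."""
    if motif.phospho_index is not None:
        return motif.phospho_index
    for i in range(motif.width - 1, -1, -1):
        pos = motif.positions[i]
        if pos.is_fixed and pos.residues[0] == "S":
            return i
    raise ValueError("secondary motif has neither a phospho position nor a fixed S")


def annotate_matches(
    matches: Sequence[MotifMatch],
    proteome: Mapping[str, str],
    ms_confirmed_sites: Iterable = (),
    secondary_motif: Optional[ConsensusMotif] = None,
    anchor_index: Optional[int] = None,
) -> list:
    """Flag each match as mass-spec confirmed and/or matching a secondary
    motif aligned on the candidate phosphosite."""
    confirmed = {(pid, int(pos)) for pid, pos in ms_confirmed_sites}
    if secondary_motif is not None and anchor_index is None:
        anchor_index = secondary_anchor_index(secondary_motif)
    out = []
    for m in matches:
        sec = False
        if secondary_motif is not None:
            sec = _matches_at(proteome[m.protein_id], m.position - 1,
                              secondary_motif, anchor_index)
        out.append(replace_match(m, (m.protein_id, m.position) in confirmed, sec))
    return out


def replace_match(m: MotifMatch, confirmed: bool, secondary: bool) -> MotifMatch:
    return MotifMatch(m.protein_id, m.position, m.window,
                      confirmed_by_ms=confirmed, matches_14_3_3=secondary)


# The canonical mode-1 14-3-3 docking pattern; its phosphoserine is the S at
# the 4th symbol, so scans anchor it at offsets -3..+2 around a candidate.
MOTIF_14_3_3 = "R[ST]xSxP"
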