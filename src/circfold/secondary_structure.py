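"""Circular secondary structure: dot-bracket parsing, loop decomposition,
back-splicing-junction (BSJ) classification, and base-pair restraint export.

A circular RNA's secondary structure arrives as a linear dot-bracket string
whose two string ends meet at the BSJ; with 1-based indexing the BSJ is always
the backbone edge (N, 1).  Loop decomposition is carried out on the circular
backbone graph, so the usual "exterior" region of a linear structure becomes
an ordinary loop containing the BSJ edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .errors import FormatError, TopologyError

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class PairTable:
    """Base pairs of a (possibly circular) secondary structure.

    ``pairs`` holds (i, j) with 1 <= i < j <= N; each index occurs in at most
    one pair and the pairs are non-crossing in the linear string (pseudoknot
    free).  ``sequence`` is retained for restraint classing.
    """

    length: int
    pairs: frozenset
    circular: bool
    sequence: str = ""

    def partner(self) -> Dict[int, int]:
        out: Dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class Loop:
    closing_pairs: List[Tuple[int, int]]
    unpaired_runs: List[Tuple[int, int]]  # inclusive 1-based (start, end) along the walk
    edges: List[int]  # backbone edges in this loop; edge e joins nt e and nt e % N + 1
    exterior: bool = False  # only meaningful for linear structures


@dataclass
class LoopDecomposition:
    loops: List[Loop]
    stem_edges: Set[int]


@dataclass(frozen=True)
class BSJClass:
    """BSJ location type: helix, hairpin, internal, junction, or unstructured."""

    value: str

    VALID = ("helix", "hairpin", "internal", "junction", "unstructured")

    def __post_init__(self) -> None:
        if self.value not in self.VALID:
            raise ValueError(f"unknown BSJ class {self.value!r}")


# ---------------------------------------------------------------------------
# Parsing / rendering
# ---------------------------------------------------------------------------

def parse_dotbracket(sequence: str, db: str, circular: bool) -> PairTable:
    """Parse a nested dot-bracket string via stack matching.

    Only ``(``, ``)`` and ``.`` are accepted (no pseudoknot layers).  Raises
    :class:`FormatError` on length mismatch, unbalanced brackets or foreign
    characters, and :class:`TopologyError` on hairpin loops shorter than 3 nt.
    """
    sequence = sequence.strip().upper().replace("T", "U")
    db = db.strip()
    if len(sequence) != len(db):
        raise FormatError(
            f"sequence length {len(sequence)} != structure length {len(db)}"
        )
    bad = set(sequence) - set("ACGU")
    if bad:
        raise FormatError(f"sequence contains non-RNA letters {sorted(bad)}")
    bad = set(db) - set("().")
    if bad:
        raise FormatError(
            f"structure contains characters outside '().': {sorted(bad)} "
            "(pseudoknot layers are unsupported)"
        )
    stack: List[int] = []
    pairs = set()
    hairpins = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            if pos - i - 1 < 3:
                hairpins.append((i, pos))
            pairs.add((i, pos))
    if stack:
        raise FormatError(f"unbalanced '(' at position(s) {stack}")
    # bracket-balance errors take precedence over loop-geometry errors
    if hairpins:
        i, pos = hairpins[0]
        raise TopologyError(
            f"hairpin loop closed by pair ({i},{pos}) has fewer than 3 nt")
    return PairTable(len(db), frozenset(pairs), circular, sequence)


def render_dotbracket(pt: PairTable) -> str:
    chars = ["."] * pt.length
    for i, j in pt.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# Loop decomposition on the circular backbone graph
# ---------------------------------------------------------------------------

def _stem_edges(pt: PairTable) -> Set[int]:
    """Backbone edges interior to helices.

    Edge e (joining nt e and its successor) is a stem edge when both endpoints
    are paired and the two pairs stack: partner(e+1) + 1 == partner(e), i.e.
    the pairs (e, p) and (e+1, p-1) enclose the 4-cycle of a helix step.  The
    complementary strand edge (p-1, p) is marked by the same rule.
    """
    partner = pt.partner()
    n = pt.length
    stems: Set[int] = set()
    edges = range(1, n + 1) if pt.circular else range(1, n)
    for e in edges:
        a, b = e, e % n + 1
        pa, pb = partner.get(a), partner.get(b)
        if pa is not None and pb is not None and pb % n + 1 == pa:
            stems.add(e)
    return stems


def loop_decomposition(pt: PairTable) -> LoopDecomposition:
    """Decompose the structure into loops by walking the faces of the diagram.

    Every backbone edge of the (circular) graph lands in exactly one loop or
    is a stem edge.  For linear tables the same walk runs on the closed circle
    but the loop containing the missing edge (N, 1) is flagged ``exterior``.
    """
    n = pt.length
    partner = pt.partner()
    stems = _stem_edges(pt)
    seen: Set[int] = set()
    loops: List[Loop] = []

    for start_edge in range(1, n + 1):
        if start_edge in stems or start_edge in seen:
            continue
        # Walk the face that lies "inside" this backbone edge.  From nt a we
        # step to its successor b; a paired b hops across its pair and
        # continues from the partner's successor.
        edges: List[int] = []
        closing: List[Tuple[int, int]] = []
        unpaired: List[int] = []
        a = start_edge
        while True:
            edges.append(a)
            b = a % n + 1
            if b in partner:
                j = partner[b]
                closing.append((min(b, j), max(b, j)))
                a = j
            else:
                unpaired.append(b)
                a = b
            if a == start_edge:
                break
        seen.update(edges)
        runs = _runs(unpaired, n)
        loops.append(Loop(closing, runs, edges, exterior=(not pt.circular and n in edges)))
    return LoopDecomposition(loops, stems)


def _runs(indices: List[int], n: int) -> List[Tuple[int, int]]:
    """Group sorted-on-circle nucleotide indices into consecutive runs."""
    if not indices:
        return []
    idx = sorted(set(indices))
    runs: List[Tuple[int, int]] = []
    start = prev = idx[0]
    for k in idx[1:]:
        if k == prev + 1:
            prev = k
        else:
            runs.append((start, prev))
            start = prev = k
    runs.append((start, prev))
    # merge a wrap-around run (… n) (1 …) on the circle
    if len(runs) >= 2 and runs[0][0] == 1 and runs[-1][1] == n:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])
    return runs


# ---------------------------------------------------------------------------
# BSJ classification
# ---------------------------------------------------------------------------

def classify_edge(pt: PairTable, edge: int) -> BSJClass:
    """Classify the loop context of one backbone edge of a circular table."""
    n = pt.length
    partner = pt.partner()
    a, b = edge, edge % n + 1
    pa, pb = partner.get(a), partner.get(b)
    if pa is not None and pb is not None and pb % n + 1 == pa:
        return BSJClass("helix")
    decomp = loop_decomposition(pt)
    for loop in decomp.loops:
        if edge in loop.edges:
            k = len(loop.closing_pairs)
            if k == 0:
                return BSJClass("unstructured")
            if k == 1:
                return BSJClass("hairpin")
            if k == 2:
                return BSJClass("internal")
            return BSJClass("junction")
    raise TopologyError(f"edge {edge} not covered by the loop decomposition")


def classify_bsj(pt: PairTable) -> BSJClass:
    """Type the back-splicing junction: helix-, hairpin-, internal- or
    junction-circular, depending on where the BSJ edge (N, 1) falls in the
    2D structure.  A fully unpaired circle is reported as ``unstructured``.
    """
    if not pt.circular:
        raise TopologyError("BSJ classification requires a circular pair table")
    return classify_edge(pt, pt.length)


def rotate_pair_table(pt: PairTable, shift: int) -> Tuple[PairTable, int]:
    """Re-thread a circular table with the cut moved ``shift`` nt forward.

    Returns the rotated table and the edge index in the new numbering that
    corresponds to the original BSJ edge (N, 1).  Raises
    :class:`TopologyError` if the rotation makes the pair set crossing in the
    new linear string (the circular structure itself is unchanged, but it can
    no longer be written as a nested dot-bracket from that cut).
    """
    if not pt.circular:
        raise TopologyError("can only rotate circular tables")
    n = pt.length

    def newpos(i: int) -> int:
        return (i - 1 - shift) % n + 1

    pairs = frozenset(
        (min(newpos(i), newpos(j)), max(newpos(i), newpos(j))) for i, j in pt.pairs
    )
    for (i, j) in pairs:
        for (k, l) in pairs:
            if i < k < j < l:
                raise TopologyError("rotation produces a crossing linear threading")
    seq = pt.sequence[shift:] + pt.sequence[:shift] if pt.sequence else ""
    new_edge = (n - shift) % n
    if new_edge == 0:
        new_edge = n
    return PairTable(n, pairs, True, seq), new_edge


# ---------------------------------------------------------------------------
# Restraint export
# ---------------------------------------------------------------------------

def pair_restraints(pt: PairTable) -> List[Tuple[int, int, str]]:
    """One restraint per base pair, classed WC (AU/GC), wobble (GU) or
    noncanonical (anything else, flagged with a warning but still restrained).
    """
    out: List[Tuple[int, int, str]] = []
    for i, j in sorted(pt.pairs):
        if pt.sequence:
            duo = (pt.sequence[i - 1], pt.sequence[j - 1])
            if duo in WC_PAIRS:
                cls = "WC"
            elif duo in WOBBLE_PAIRS:
                cls = "wobble"
            else:
                cls = "noncanonical"
                warnings.warn(
                    f"pair ({i},{j}) {duo[0]}-{duo[1]} is noncanonical; restrained anyway",
                    stacklevel=2,
                )
        else:
            cls = "WC"
        out.append((i, j, cls))
    return out


def restraints_tsv(pt: PairTable) -> str:
    lines = ["i\tj\tclass"]
    for i, j, cls in pair_restraints(pt):
        lines.append(f"{i}\t{j}\t{cls}")
    return "\n".join(lines) + "\n"
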