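"""RNA secondary structures as sets of basepairs.

A secondary structure over a sequence is a set of basepairs {i, j} between
non-adjacent bases, subject to two combinatorial constraints: no base may
participate in more than one pair (no triples) and no two pairs may cross
(no pseudoknots).  Two pairs that cannot coexist under these rules —
because they share an endpoint or cross — are said to *conflict*; the
conflict relation is what makes the Boltzmann ensemble multimodal and is
the object the rest of the package analyses.

Coordinates are 1-based inclusive throughout, matching the {i, j} notation
of the field and the CT file format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, TextIO

from Bio import SeqIO

__all__ = [
    "Sequence",
    "BasePair",
    "SecondaryStructure",
    "ParseError",
    "can_pair",
    "conflicts",
    "read_structures",
    "read_fasta",
    "write_dotbracket",
    "write_dotbracket_file",
    "validate_structure",
]

#: Allowed pairings: Watson-Crick (A-U, G-C) and wobble (G-U).
_ALLOWED = {frozenset("AU"), frozenset("GC"), frozenset("GU")}

_NUCLEOTIDES = frozenset("ACGU")


class ParseError(ValueError):
    """Malformed structure or sequence input."""


def _normalize_residues(raw: str, context: str = "sequence") -> str:
    s = raw.upper().replace("T", "U")
    for ch in s:
        if ch not in _NUCLEOTIDES:
            raise ParseError(
                f"invalid character {ch!r} in {context}: only A, C, G, U "
                f"(or T, normalized to U) are accepted"
            )
    return s


@dataclass(frozen=True)
class Sequence:
    """An RNA sequence over the alphabet {A, C, G, U}.

    T is accepted on input and silently normalized to U; lowercase is
    uppercased.  Any other letter is an error.
    """

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        norm = _normalize_residues(self.residues)
        if not norm:
            raise ParseError("sequence must have length >= 1")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Base at 1-based position ``i``."""
        return self.residues[i - 1]


class BasePair(NamedTuple):
    """A pair between positions ``i < j`` (1-based, inclusive)."""

    i: int
    j: int

    def positions(self) -> frozenset[int]:
        return frozenset((self.i, self.j))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.i},{self.j})"


def pair(i: int, j: int) -> BasePair:
    """Construct a :class:`BasePair`, normalizing endpoint order."""
    if i == j:
        raise ValueError(f"a base cannot pair with itself (position {i})")
    if i > j:
        i, j = j, i
    if j - i < 2:
        raise ValueError(f"adjacent bases cannot pair: ({i},{j})")
    if i < 1:
        raise ValueError(f"positions are 1-based: ({i},{j})")
    return BasePair(i, j)


def can_pair(a: str, b: str) -> bool:
    """True iff bases ``a`` and ``b`` can form a Watson-Crick or wobble pair.

    Symmetric in its arguments; raises on non-nucleotide letters.
    """
    a, b = a.upper(), b.upper()
    for ch in (a, b):
        if ch not in _NUCLEOTIDES:
            raise ValueError(f"not a nucleotide: {ch!r}")
    return frozenset((a, b)) in _ALLOWED


def conflicts(p: BasePair, q: BasePair) -> bool:
    """True iff pairs ``p`` and ``q`` cannot coexist in one structure.

    {i,j} and {k,l} conflict if they share an endpoint (a triple) or if
    they cross, i < k < j < l or k < i < l < j (a pseudoknot).
    """
    if p.positions() & q.positions():
        return True
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of basepairs over a sequence.

    Construction validates the no-triples / no-pseudoknots constraints and
    endpoint ranges; use ``validate=False`` only for speed on trusted input.
    """

    sequence: Sequence
    pairs: frozenset[BasePair] = field(default_factory=frozenset)
    validate: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        if self.validate:
            problems = validate_structure(self)
            if problems:
                raise ParseError("; ".join(problems))

    def sorted_pairs(self) -> list[BasePair]:
        return sorted(self.pairs)

    def partner_of(self, i: int) -> int | None:
        for p in self.pairs:
            if p.i == i:
                return p.j
            if p.j == i:
                return p.i
        return None

    def __contains__(self, p: BasePair) -> bool:
        return p in self.pairs


def validate_structure(s: SecondaryStructure) -> list[str]:
    """Return a list of constraint violations (empty iff ``s`` is valid).

    Checks positions in range, non-adjacency (j - i >= 2), no triples and
    no pseudoknots.  Violations are returned as data, naming the offending
    pair(s) and the rule, rather than raised.
    """
    n = len(s.sequence)
    out: list[str] = []
    seen: dict[int, BasePair] = {}
    plist = sorted(s.pairs)
    for p in plist:
        if not (1 <= p.i < p.j <= n):
            out.append(f"pair {p} out of range for length-{n} sequence")
            continue
        if p.j - p.i < 2:
            out.append(f"pair {p} joins adjacent bases (j - i >= 2 required)")
        for pos in (p.i, p.j):
            if pos in seen and seen[pos] != p:
                out.append(f"triple: position {pos} in both {seen[pos]} and {p}")
            seen[pos] = p
    for a in range(len(plist)):
        i, j = plist[a]
        for b in range(a + 1, len(plist)):
            k, l = plist[b]
            if i < k < j < l:
                out.append(f"pseudoknot: {plist[a]} crosses {plist[b]}")
    return out


# ---------------------------------------------------------------------------
# I/O: FASTA, dot-bracket, CT


def read_fasta(source: str | TextIO) -> Sequence:
    """Read the first record of a FASTA file (path or handle)."""
    handle = open(source) if isinstance(source, str) else source
    try:
        record = next(SeqIO.parse(handle, "fasta"), None)
    finally:
        if isinstance(source, str):
            handle.close()
    if record is None:
        raise ParseError("no FASTA record found")
    return Sequence(str(record.seq), name=record.id)


def _parse_dotbracket_line(line: str, n: int, lineno: int) -> frozenset[BasePair]:
    if len(line) != n:
        raise ParseError(
            f"line {lineno}: structure length {len(line)} != sequence length {n}"
        )
    stack: list[int] = []
    pairs = set()
    for idx, ch in enumerate(line, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ParseError(f"line {lineno}: unbalanced ')' at position {idx}")
            pairs.add(BasePair(stack.pop(), idx))
        elif ch in "[]{}<>":
            raise ParseError(
                f"line {lineno}: bracket layer {ch!r} found - pseudoknots unsupported"
            )
        elif ch != ".":
            raise ParseError(f"line {lineno}: invalid structure character {ch!r}")
    if stack:
        raise ParseError(f"line {lineno}: unbalanced '(' opened at position {stack[-1]}")
    return frozenset(pairs)


def _read_dotbracket(lines: list[tuple[int, str]]) -> tuple[Sequence, list[SecondaryStructure]]:
    if not lines:
        raise ParseError("empty input")
    pos = 0
    name = ""
    if lines[pos][1].startswith(">"):
        name = lines[pos][1][1:].strip().split()[0] if lines[pos][1][1:].strip() else ""
        pos += 1
        if pos >= len(lines):
            raise ParseError("FASTA header without sequence line")
    seq = Sequence(lines[pos][1], name=name)
    pos += 1
    structures = []
    for lineno, line in lines[pos:]:
        if line.startswith(">"):
            raise ParseError(f"line {lineno}: unexpected second FASTA header")
        token = line.split()[0]  # tolerate trailing energy annotations
        pairs = _parse_dotbracket_line(token, len(seq), lineno)
        structures.append(SecondaryStructure(seq, pairs))
    return seq, structures


def _read_ct(lines: list[tuple[int, str]]) -> tuple[Sequence, list[SecondaryStructure]]:
    structures: list[SecondaryStructure] = []
    seq: Sequence | None = None
    pos = 0
    while pos < len(lines):
        lineno, header = lines[pos]
        try:
            n = int(header.split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"line {lineno}: expected CT header starting with a length")
        if pos + n >= len(lines) + 1 and len(lines) - pos - 1 < n:
            raise ParseError(f"line {lineno}: CT record truncated ({n} rows expected)")
        bases = [""] * n
        pairs = set()
        for row in range(n):
            lno, text = lines[pos + 1 + row]
            cols = text.split()
            if len(cols) < 5:
                raise ParseError(f"line {lno}: CT row needs >= 5 columns")
            idx, base, partner = int(cols[0]), cols[1], int(cols[4])
            if idx != row + 1:
                raise ParseError(f"line {lno}: CT rows out of order ({idx} != {row + 1})")
            bases[row] = base
            if partner > idx:
                pairs.add(BasePair(idx, partner))
        record_seq = Sequence("".join(bases))
        if seq is None:
            seq = record_seq
        elif record_seq.residues != seq.residues:
            raise ParseError(
                f"line {lineno}: CT record sequence differs from the first record"
            )
        structures.append(SecondaryStructure(seq, frozenset(pairs)))
        pos += 1 + n
    if seq is None:
        raise ParseError("empty CT input")
    return seq, structures


def read_structures(
    source: str | TextIO, format: str = "auto"
) -> tuple[Sequence, list[SecondaryStructure]]:
    """Read a multi-structure file; returns the shared sequence and structures.

    Parameters
    ----------
    source
        Path or text handle.  Dot-bracket layout: an optional ``>name``
        header, one sequence line, then one structure string per line.
        CT layout: one or more concatenated connect-format records over the
        same sequence (the convention of stochastic-sampler output).
    format
        ``"dotbracket"``, ``"ct"`` or ``"auto"`` (sniffed from the first line).
    """
    if isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    lines = [
        (lineno, ln.strip())
        for lineno, ln in enumerate(text.splitlines(), start=1)
        if ln.strip()
    ]
    if not lines:
        raise ParseError("empty input")
    if format == "auto":
        first = lines[0][1]
        format = "ct" if first.split()[0].isdigit() else "dotbracket"
    if format == "dotbracket":
        return _read_dotbracket(lines)
    if format == "ct":
        return _read_ct(lines)
    raise ValueError(f"unknown format {format!r}")


def write_dotbracket(s: SecondaryStructure) -> str:
    """Render one structure as a dot-bracket line (inverse of parsing)."""
    chars = ["."] * len(s.sequence)
    for p in s.pairs:
        chars[p.i - 1] = "("
        chars[p.j - 1] = ")"
    return "".join(chars)


def write_dotbracket_file(
    structures: Iterable[SecondaryStructure],
    dest: str | TextIO,
    sequence: Sequence | None = None,
) -> None:
    """Write a multi-structure dot-bracket file (header, sequence, one line each)."""
    structures = list(structures)
    if sequence is None:
        if not structures:
            raise ValueError("need a sequence or at least one structure")
        sequence = structures[0].sequence
    buf = io.StringIO()
    if sequence.name:
        buf.write(f">{sequence.name}\n")
    buf.write(sequence.residues + "\n")
    for s in structures:
        buf.write(write_dotbracket(s) + "\n")
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            fh.write(buf.getvalue())
    else:
        dest.write(buf.getvalue())
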