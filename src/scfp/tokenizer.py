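"""SMILES canonicalization and tokenization.

A molecule is first normalized to a single canonical, Kekulé-form SMILES
string (uppercase atoms, explicit double bonds; aromaticity is carried as an
atom feature downstream, not as lowercase symbols).  The canonical string is
then split into a sequence of typed tokens: ATOM tokens (one per emitted
atom, with bracket contents such as attached hydrogens folded in) and GRAMMAR
tokens covering the 21 structural SMILES symbols — branches, brackets, bond
symbols, stereo markers, charges, ion-charge digits and ring open/close
labels.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "GrammarClass",
    "TokenKind",
    "Token",
    "TokenSequence",
    "SmilesParseError",
    "SmilesStructureError",
    "canonicalize",
    "tokenize",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class SmilesStructureError(ValueError):
    """Raised when a canonical SMILES has unmatched rings or brackets."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (at offset {offset})")
        self.offset = offset


class TokenKind(enum.Enum):
    ATOM = "atom"
    GRAMMAR = "grammar"


class GrammarClass(enum.Enum):
    """The 21 structural SMILES symbol classes (grammar block features)."""

    NONE = -1  # atoms
    BRANCH_START = 0
    BRANCH_END = 1
    BRACKET_OPEN = 2
    BRACKET_CLOSE = 3
    IONIC_BOND = 4
    AROMATIC_BOND = 5
    DOUBLE_BOND = 6
    TRIPLE_BOND = 7
    CIS = 8
    TRANS = 9
    CHIRALITY = 10
    CATION = 11
    ANION = 12
    ION_CHARGE_2 = 13
    ION_CHARGE_3 = 14
    ION_CHARGE_4 = 15
    ION_CHARGE_5 = 16
    ION_CHARGE_6 = 17
    ION_CHARGE_7 = 18
    RING_START = 19
    RING_END = 20


_SINGLE_CHAR_GRAMMAR = {
    "(": GrammarClass.BRANCH_START,
    ")": GrammarClass.BRANCH_END,
    "[": GrammarClass.BRACKET_OPEN,
    "]": GrammarClass.BRACKET_CLOSE,
    ".": GrammarClass.IONIC_BOND,
    ":": GrammarClass.AROMATIC_BOND,
    "=": GrammarClass.DOUBLE_BOND,
    "#": GrammarClass.TRIPLE_BOND,
    "\\": GrammarClass.CIS,
    "/": GrammarClass.TRANS,
    "@": GrammarClass.CHIRALITY,
    "+": GrammarClass.CATION,
    "-": GrammarClass.ANION,
}

_ION_CHARGE = {
    "2": GrammarClass.ION_CHARGE_2,
    "3": GrammarClass.ION_CHARGE_3,
    "4": GrammarClass.ION_CHARGE_4,
    "5": GrammarClass.ION_CHARGE_5,
    "6": GrammarClass.ION_CHARGE_6,
    "7": GrammarClass.ION_CHARGE_7,
}

# Two-letter elements writable without brackets in canonical SMILES.
_TWO_LETTER_ORGANIC = ("Cl", "Br")

_ELEMENT_RE = re.compile(r"[A-Z][a-z]?|[bcnops]")


@dataclass(frozen=True)
class Token:
    text: str
    kind: TokenKind
    grammar_class: GrammarClass = GrammarClass.NONE
    atom_ordinal: int | None = None
    source_span: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.kind is TokenKind.ATOM:
            assert self.grammar_class is GrammarClass.NONE
            assert self.atom_ordinal is not None
        else:
            assert self.grammar_class is not GrammarClass.NONE
            assert self.atom_ordinal is None


@dataclass
class TokenSequence:
    canonical_smiles: str
    tokens: list[Token] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return sum(1 for t in self.tokens if t.kind is TokenKind.ATOM)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`SmilesParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"empty or non-string SMILES input: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def _kekule_canonical(mol: Chem.Mol) -> tuple[str, list[int]]:
    """Kekulé canonical SMILES plus the emitted-atom -> mol-atom index map."""
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    smiles = Chem.MolToSmiles(kek, kekuleSmiles=True)
    order = [int(x) for x in kek.GetProp("_smilesAtomOutputOrder").strip("[],").split(",") if x]
    return smiles, order


def canonicalize(smiles: str) -> str:
    """Normalize a SMILES string to the unique Kekulé canonical form.

    Idempotent: feeding the output back in returns the same string.  Two
    generic SMILES of the same molecule canonicalize identically.
    """
    return _kekule_canonical(mol_from_smiles(smiles))[0]


def atom_output_order(smiles: str) -> list[int]:
    """Map the i-th atom emitted in ``canonicalize(smiles)`` to its RDKit
    atom index in ``MolFromSmiles(canonicalize(smiles))``."""
    can = canonicalize(smiles)
    return _kekule_canonical(mol_from_smiles(can))[1]


def _normalize_repeated_signs(smiles: str) -> str:
    """Rewrite runs of '+'/'-' inside brackets as sign + magnitude."""

    def repl(m: re.Match) -> str:
        run = m.group(0)
        return run[0] + str(len(run))

    return re.sub(r"\+{2,}|-{2,}", repl, smiles)


def tokenize(canonical_smiles: str) -> TokenSequence:
    """Split a canonical SMILES string into typed tokens.

    Every character of the input is consumed exactly once; concatenating the
    token texts reproduces the input.  Ring-closure digits (including the
    ``%nn`` form) pair first-open/then-close under a per-label matching rule;
    labels become reusable once closed.  Bracket atoms fold isotope digits
    and attached-H counts into the ATOM token; chirality and charge marks
    inside brackets are separate GRAMMAR tokens.
    """
    s = _normalize_repeated_signs(canonical_smiles)
    tokens: list[Token] = []
    open_rings: dict[str, int] = {}  # label -> offset where opened
    atom_ordinal = 0
    i = 0
    n = len(s)

    def emit_atom(text: str, start: int, end: int):
        nonlocal atom_ordinal
        tokens.append(Token(text, TokenKind.ATOM, GrammarClass.NONE, atom_ordinal, (start, end)))
        atom_ordinal += 1

    def emit_grammar(text: str, cls: GrammarClass, start: int, end: int):
        tokens.append(Token(text, TokenKind.GRAMMAR, cls, None, (start, end)))

    def emit_ring(label: str, start: int, end: int):
        if label in open_rings:
            del open_rings[label]
            emit_grammar(s[start:end], GrammarClass.RING_END, start, end)
        else:
            open_rings[label] = start
            emit_grammar(s[start:end], GrammarClass.RING_START, start, end)

    in_bracket = False
    bracket_open_at = -1
    bracket_atom_seen = False

    while i < n:
        c = s[i]
        if in_bracket:
            if c == "]":
                if not bracket_atom_seen:
                    raise SmilesStructureError("bracket with no atom", bracket_open_at)
                emit_grammar(c, GrammarClass.BRACKET_CLOSE, i, i + 1)
                in_bracket = False
                i += 1
                continue
            if c == "@":
                if i + 1 < n and s[i + 1] == "@":
                    emit_grammar("@@", GrammarClass.CHIRALITY, i, i + 2)
                    i += 2
                else:
                    emit_grammar("@", GrammarClass.CHIRALITY, i, i + 1)
                    i += 1
                continue
            if c in "+-":
                emit_grammar(c, _SINGLE_CHAR_GRAMMAR[c], i, i + 1)
                i += 1
                if i < n and s[i] in _ION_CHARGE:
                    emit_grammar(s[i], _ION_CHARGE[s[i]], i, i + 1)
                    i += 1
                continue
            if c.isdigit():
                # isotope digits before the element symbol: folded into the
                # upcoming atom token (parsed but carrying no feature)
                if bracket_atom_seen:
                    raise SmilesStructureError("unexpected digits in bracket", i)
                j = i
                while j < n and s[j].isdigit():
                    j += 1
                m = _ELEMENT_RE.match(s, j)
                if m is None:
                    raise SmilesStructureError("digits without element in bracket", i)
                emit_atom(s[i : m.end()], i, m.end())
                bracket_atom_seen = True
                i = m.end()
                continue
            if c == "H" and bracket_atom_seen:
                # Attached hydrogens are not standalone atoms: fold "H"/"Hn"
                # into the preceding token's text.  That is the atom token
                # itself ([NH4+]) unless a chirality mark intervenes ([C@H]),
                # in which case the text rides on the chirality token so that
                # token texts still concatenate to the exact input.  The H
                # count itself is recovered from toolkit perception, never
                # from token text.
                j = i + 1
                while j < n and s[j].isdigit():
                    j += 1
                last = tokens[-1]
                tokens[-1] = Token(
                    last.text + s[i:j],
                    last.kind,
                    last.grammar_class,
                    last.atom_ordinal,
                    (last.source_span[0], j),
                )
                i = j
                continue
            m = _ELEMENT_RE.match(s, i)
            if m is not None and not bracket_atom_seen:
                emit_atom(m.group(0), i, m.end())
                bracket_atom_seen = True
                i = m.end()
                continue
            raise SmilesStructureError(f"unexpected character {c!r} in bracket", i)

        if c == "[":
            emit_grammar(c, GrammarClass.BRACKET_OPEN, i, i + 1)
            in_bracket = True
            bracket_open_at = i
            bracket_atom_seen = False
            i += 1
            continue
        if c == "]":
            raise SmilesStructureError("unmatched ']'", i)
        if c == "%":
            if i + 2 < n + 1 and s[i + 1 : i + 3].isdigit():
                emit_ring(s[i + 1 : i + 3], i, i + 3)
                i += 3
                continue
            raise SmilesStructureError("'%' without two-digit ring label", i)
        if c.isdigit():
            emit_ring(c, i, i + 1)
            i += 1
            continue
        if c == "@":
            if i + 1 < n and s[i + 1] == "@":
                emit_grammar("@@", GrammarClass.CHIRALITY, i, i + 2)
                i += 2
            else:
                emit_grammar("@", GrammarClass.CHIRALITY, i, i + 1)
                i += 1
            continue
        if c in _SINGLE_CHAR_GRAMMAR:
            emit_grammar(c, _SINGLE_CHAR_GRAMMAR[c], i, i + 1)
            i += 1
            continue
        if s.startswith(_TWO_LETTER_ORGANIC, i):
            emit_atom(s[i : i + 2], i, i + 2)
            i += 2
            continue
        m = _ELEMENT_RE.match(s, i)
        if m is not None:
            emit_atom(m.group(0), i, m.end())
            i = m.end()
            continue
        raise SmilesStructureError(f"unexpected character {c!r}", i)

    if in_bracket:
        raise SmilesStructureError("unclosed bracket", bracket_open_at)
    if open_rings:
        label, off = next(iter(open_rings.items()))
        raise SmilesStructureError(f"unmatched ring label {label!r}", off)

    seq = TokenSequence(canonical_smiles=s, tokens=tokens)
    assert "".join(t.text for t in seq) == s
    return seq
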