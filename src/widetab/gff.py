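"""GroupFilterFormat catalogs.

A catalog maps original per-item codes (e.g. pharmaceutical product codes)
into named groups — the columns of the wide table — and optionally attaches
numeric values (dose, price, ...) to each code.  The textual format is

    groupname (item1 [value1, value2, ...], item2, ...), groupname2 (...)

Whitespace (including newlines) between tokens is insignificant.  Group
names and item codes are maximal runs of characters excluding ``, ( ) [ ]``
and whitespace; there is no quoting mechanism, so codes containing those
delimiters are rejected at tokenization.  A code may appear in several
groups, each membership carrying its own value tuple; within one group a
code may appear only once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import (
    DuplicateGroupNameError,
    DuplicateItemCodeError,
    EmptyCatalogError,
    GffSyntaxError,
    NonNumericValueError,
)

__all__ = [
    "ItemSpec",
    "GroupSpec",
    "GroupCatalog",
    "parse_gff",
    "serialize_gff",
    "read_gff",
    "write_gff",
]

_DELIMS = {",", "(", ")", "[", "]"}


@dataclass(frozen=True)
class ItemSpec:
    """One item code with its ordered tuple of attached numeric values."""

    code: str
    values: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.code:
            raise ValueError("item code must be non-empty")


@dataclass(frozen=True)
class GroupSpec:
    """One wide-table field: a new group name and its member items."""

    name: str
    items: tuple[ItemSpec, ...]

    def __post_init__(self):
        if not self.name:
            raise ValueError("group name must be non-empty")
        if not self.items:
            raise ValueError(f"group {self.name!r} has no items")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(item.code for item in self.items)


class GroupCatalog:
    """An ordered collection of groups plus a code-membership index.

    Column order of any derived wide table equals group declaration order.
    """

    def __init__(self, groups: Iterable[GroupSpec]):
        self.groups: tuple[GroupSpec, ...] = tuple(groups)
        seen: set[str] = set()
        for g in self.groups:
            if g.name in seen:
                raise ValueError(f"duplicate group name {g.name!r}")
            seen.add(g.name)
        # code -> [(group name, values), ...] in declaration order
        self._index: dict[str, list[tuple[str, tuple[float, ...]]]] = {}
        for g in self.groups:
            codes_in_group: set[str] = set()
            for item in g.items:
                if item.code in codes_in_group:
                    raise ValueError(
                        f"duplicate item code {item.code!r} in group {g.name!r}"
                    )
                codes_in_group.add(item.code)
                self._index.setdefault(item.code, []).append((g.name, item.values))
        self._groups_by_name = {g.name: g for g in self.groups}

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    @property
    def codes(self) -> frozenset[str]:
        """All codes defined anywhere in the catalog."""
        return frozenset(self._index)

    def group(self, name: str) -> GroupSpec:
        return self._groups_by_name[name]

    def lookup(self, code: str) -> list[tuple[str, tuple[float, ...]]]:
        """All (group name, values) memberships of *code*, declaration order.

        Unknown codes yield an empty list.
        """
        return list(self._index.get(code, ()))

    def values_for(self, group_name: str, code: str) -> tuple[float, ...]:
        """The value tuple attached to *code* within *group_name*.

        Raises KeyError if the code is not an item of that group.
        """
        for item in self._groups_by_name[group_name].items:
            if item.code == code:
                return item.values
        raise KeyError(f"code {code!r} is not an item of group {group_name!r}")

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def __iter__(self) -> Iterator[GroupSpec]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupCatalog) and self.groups == other.groups

    def __hash__(self):
        return hash(self.groups)

    def __repr__(self) -> str:
        return f"GroupCatalog({len(self.groups)} groups, {len(self._index)} codes)"


# --- tokenizer ---------------------------------------------------------------

@dataclass(frozen=True)
class _Token:
    kind: str  # "sym" (one of , ( ) [ ]) or "word"
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, col = 1, 1
    word: list[str] = []
    word_pos = (1, 1)
    for ch in text:
        if ch in _DELIMS or ch.isspace():
            if word:
                tokens.append(_Token("word", "".join(word), *word_pos))
                word = []
            if ch in _DELIMS:
                tokens.append(_Token("sym", ch, line, col))
        else:
            if not word:
                word_pos = (line, col)
            word.append(ch)
        if ch == "\n":
            line += 1
            col = 1
        else:
            col += 1
    if word:
        tokens.append(_Token("word", "".join(word), *word_pos))
    return tokens


# --- parser ------------------------------------------------------------------

class _Parser:
    def __init__(self, tokens: list[_Token], text: str):
        self.tokens = tokens
        self.pos = 0
        # end-of-input position for error messages
        nlines = text.count("\n") + 1
        last = text.rsplit("\n", 1)[-1]
        self.eof = (nlines, len(last) + 1)

    def peek(self) -> _Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def where(self) -> tuple[int, int]:
        tok = self.peek()
        return (tok.line, tok.column) if tok else self.eof

    def fail(self, message: str, cls=GffSyntaxError):
        raise cls(message, *self.where())

    def expect_sym(self, sym: str) -> _Token:
        tok = self.peek()
        if tok is None or tok.kind != "sym" or tok.text != sym:
            got = repr(tok.text) if tok else "end of input"
            self.fail(f"expected {sym!r}, got {got}")
        self.pos += 1
        return tok

    def take_word(self, what: str) -> _Token:
        tok = self.peek()
        if tok is None or tok.kind != "word":
            got = repr(tok.text) if tok else "end of input"
            self.fail(f"expected {what}, got {got}")
        self.pos += 1
        return tok

    def at_sym(self, sym: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "sym" and tok.text == sym

    def parse_catalog(self) -> GroupCatalog:
        groups = [self.parse_group()]
        names = {groups[0].name}
        while self.peek() is not None:
            self.expect_sym(",")
            start = self.where()
            g = self.parse_group()
            if g.name in names:
                raise DuplicateGroupNameError(
                    f"duplicate group name {g.name!r}", *start
                )
            names.add(g.name)
            groups.append(g)
        return GroupCatalog(groups)

    def parse_group(self) -> GroupSpec:
        name_tok = self.take_word("a group name")
        self.expect_sym("(")
        if self.at_sym(")"):
            self.fail(f"group {name_tok.text!r} has an empty body")
        items = [self.parse_item(name_tok.text, set())]
        codes = {items[0].code}
        while self.at_sym(","):
            self.pos += 1
            items.append(self.parse_item(name_tok.text, codes))
            codes.add(items[-1].code)
        self.expect_sym(")")
        return GroupSpec(name_tok.text, tuple(items))

    def parse_item(self, group_name: str, seen_codes: set[str]) -> ItemSpec:
        code_tok = self.take_word("an item code")
        if code_tok.text in seen_codes:
            raise DuplicateItemCodeError(
                f"duplicate item code {code_tok.text!r} in group {group_name!r}",
                code_tok.line,
                code_tok.column,
            )
        values: tuple[float, ...] = ()
        if self.at_sym("["):
            self.pos += 1
            values = self.parse_values()
            self.expect_sym("]")
        return ItemSpec(code_tok.text, values)

    def parse_values(self) -> tuple[float, ...]:
        values = [self.parse_number()]
        while self.at_sym(","):
            self.pos += 1
            values.append(self.parse_number())
        return tuple(values)

    def parse_number(self) -> float:
        tok = self.take_word("a numeric value")
        try:
            return float(tok.text)
        except ValueError:
            raise NonNumericValueError(
                f"non-numeric value {tok.text!r}", tok.line, tok.column
            ) from None


def parse_gff(text: str) -> GroupCatalog:
    """Parse GroupFilterFormat text into a :class:`GroupCatalog`.

    Raises :class:`EmptyCatalogError` on blank input and
    :class:`GffSyntaxError` (with 1-based line/column) on malformed text.
    """
    if not text.strip():
        raise EmptyCatalogError("catalog text is empty")
    parser = _Parser(_tokenize(text), text)
    return parser.parse_catalog()


# --- serialization -----------------------------------------------------------

def _format_number(v: float) -> str:
    f = float(v)
    if f.is_integer() and abs(f) < 1e16:
        return str(int(f))
    return repr(f)


def serialize_gff(catalog: GroupCatalog) -> str:
    """Canonical single-space rendering; ``parse_gff`` round-trips it."""
    parts = []
    for g in catalog.groups:
        items = []
        for item in g.items:
            if item.values:
                vals = ", ".join(_format_number(v) for v in item.values)
                items.append(f"{item.code} [{vals}]")
            else:
                items.append(item.code)
        parts.append(f"{g.name} ({', '.join(items)})")
    return ", ".join(parts)


def read_gff(path) -> GroupCatalog:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_gff(fh.read())


def write_gff(catalog: GroupCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_gff(catalog) + "\n")
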