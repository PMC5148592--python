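"""Parser and renderer for the supported AQL subset.

Grammar (EBNF, keywords case-insensitive)::

    query     : "SELECT" selitem ("," selitem)*
                "FROM" "EHR" IDENT contains*
                ("WHERE" condition)?
    selitem   : IDENT pathtail? ("AS" IDENT)?
    contains  : "CONTAINS" IDENT IDENT ("[" CLASSID "]")?
    pathtail  : ("/" step)+
    step      : NAME ("[" CODE "]")?
    condition : or_expr
    or_expr   : and_expr ("OR" and_expr)*
    and_expr  : not_expr ("AND" not_expr)*
    not_expr  : "NOT" not_expr | "(" condition ")" | predicate
    predicate : IDENT pathtail? comp literal
              | IDENT pathtail? ("MATCHES"|"IN") "{" literal ("," literal)* "}"
              | "EXISTS" IDENT pathtail?
    comp      : "=" | "!=" | ">" | ">=" | "<" | "<="
    literal   : NUMBER | STRING | "TRUE" | "FALSE"

A ``contains`` clause names a reference-model type (e.g. OBSERVATION), a
variable, and optionally a bracketed archetype id; without the bracket
the pattern is the wildcard ``*``.  ORDER BY and TIMEWINDOW are
recognized and rejected as unsupported.  ``IN`` is an alias of
``MATCHES``; ``EXISTS path`` is a predicate that holds when the path
resolves to at least one value.

``parse`` and ``render`` are mutual inverses on the query-model domain
(AND/OR nodes are n-ary and flattened, so the canonical form is unique).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Union

from .index import ContainmentChain
from .records import RelPath

__all__ = [
    "AQLError",
    "AQLSyntaxError",
    "AndNode",
    "BindingError",
    "ContainsSpec",
    "Location",
    "NotNode",
    "OrNode",
    "Predicate",
    "QueryObjectModel",
    "SelectItem",
    "Selection",
    "UnsupportedClauseError",
    "location_of",
    "parse",
    "render",
]


class AQLError(ValueError):
    pass


class AQLSyntaxError(AQLError):
    def __init__(self, message: str, line: int, column: int) -> None:
        super().__init__(f"syntax error at line {line}, column {column}: {message}")
        self.line = line
        self.column = column


class UnsupportedClauseError(AQLError):
    pass


class BindingError(AQLError):
    pass


# ---------------------------------------------------------------------------
# query object model


@dataclass(frozen=True)
class SelectItem:
    variable: str
    path: RelPath = RelPath()
    alias: str | None = None

    @property
    def column_name(self) -> str:
        if self.alias:
            return self.alias
        return self.variable + self.path.render()


@dataclass(frozen=True)
class Selection:
    items: tuple[SelectItem, ...]


@dataclass(frozen=True)
class ContainsSpec:
    rm_type: str
    variable: str
    class_pattern: str = "*"


@dataclass(frozen=True)
class Location:
    ehr_variable: str
    chain: tuple[ContainsSpec, ...] = ()

    @property
    def level(self) -> int:
        """Containment level: the number of CONTAINS clauses."""
        return len(self.chain)


Literal = Union[str, int, float, bool]

COMPARISON_OPS = ("=", "!=", ">=", "<=", ">", "<")


@dataclass(frozen=True)
class Predicate:
    variable: str
    path: RelPath
    operator: str  # comparison op, "matches", or "exists"
    literal: Literal | None = None
    values: tuple[Literal, ...] = ()


@dataclass(frozen=True)
class AndNode:
    children: tuple["Condition", ...]


@dataclass(frozen=True)
class OrNode:
    children: tuple["Condition", ...]


@dataclass(frozen=True)
class NotNode:
    child: "Condition"


Condition = Union[Predicate, AndNode, OrNode, NotNode]


@dataclass(frozen=True)
class QueryObjectModel:
    selection: Selection
    location: Location
    condition: Condition | None = None

    @property
    def containment_level(self) -> int:
        return self.location.level

    @property
    def bound_variables(self) -> tuple[str, ...]:
        return (self.location.ehr_variable,) + tuple(
            c.variable for c in self.location.chain
        )


def location_of(qom: QueryObjectModel) -> ContainmentChain:
    """The location part handed to the index service: class patterns in
    FROM order, one per CONTAINS."""
    return ContainmentChain(tuple(c.class_pattern for c in qom.location.chain))


# ---------------------------------------------------------------------------
# tokenizer

_KEYWORDS = {
    "select", "from", "where", "contains", "as", "and", "or", "not",
    "matches", "in", "exists", "ehr", "order", "by", "timewindow",
    "true", "false",
}

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>-?\d+(\.\d+)?([eE][+-]?\d+)?)
  | (?P<string>'(?:[^'\\]|\\.)*'|"(?:[^"\\]|\\.)*")
  | (?P<name>[A-Za-z_][A-Za-z0-9_\-.]*)
  | (?P<sym>!=|>=|<=|[=><,/\[\]{}()])
    """,
    re.VERBOSE,
)


@dataclass
class Token:
    kind: str  # keyword | name | number | string | sym | eof
    text: str
    line: int
    column: int


def _tokenize(text: str) -> Iterator[Token]:
    line, col, pos = 1, 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise AQLSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        token_text = m.group(0)
        kind = m.lastgroup
        if kind != "ws":
            if kind == "name" and token_text.lower() in _KEYWORDS:
                yield Token("keyword", token_text.lower(), line, col)
            else:
                yield Token(kind or "sym", token_text, line, col)
        newlines = token_text.count("\n")
        if newlines:
            line += newlines
            col = len(token_text) - token_text.rfind("\n")
        else:
            col += len(token_text)
        pos = m.end()
    yield Token("eof", "", line, col)


# ---------------------------------------------------------------------------
# parser


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = list(_tokenize(text))
        self.i = 0

    @property
    def cur(self) -> Token:
        return self.tokens[self.i]

    def advance(self) -> Token:
        tok = self.cur
        if tok.kind != "eof":
            self.i += 1
        return tok

    def error(self, message: str) -> AQLSyntaxError:
        return AQLSyntaxError(message, self.cur.line, self.cur.column)

    def at_keyword(self, *kws: str) -> bool:
        return self.cur.kind == "keyword" and self.cur.text in kws

    def expect_keyword(self, kw: str) -> Token:
        if not self.at_keyword(kw):
            raise self.error(f"expected {kw.upper()}, found {self.cur.text!r}")
        return self.advance()

    def at_sym(self, sym: str) -> bool:
        return self.cur.kind == "sym" and self.cur.text == sym

    def expect_sym(self, sym: str) -> Token:
        if not self.at_sym(sym):
            raise self.error(f"expected {sym!r}, found {self.cur.text!r}")
        return self.advance()

    def expect_name(self, what: str) -> str:
        if self.cur.kind != "name":
            raise self.error(f"expected {what}, found {self.cur.text!r}")
        return self.advance().text

    def expect_step(self) -> str:
        # path steps may collide with keywords (e.g. /state/not/value)
        if self.cur.kind not in ("name", "keyword"):
            raise self.error(f"expected path step, found {self.cur.text!r}")
        return self.advance().text

    # -- grammar ------------------------------------------------------------

    def parse_query(self) -> QueryObjectModel:
        self.expect_keyword("select")
        items = [self.parse_select_item()]
        while self.at_sym(","):
            self.advance()
            items.append(self.parse_select_item())
        self.expect_keyword("from")
        self.expect_keyword("ehr")
        ehr_var = self.expect_name("EHR variable")
        chain: list[ContainsSpec] = []
        while self.at_keyword("contains"):
            self.advance()
            chain.append(self.parse_contains())
        condition = None
        if self.at_keyword("where"):
            self.advance()
            condition = self.parse_or()
        if self.at_keyword("order"):
            raise UnsupportedClauseError("ORDER BY is not supported")
        if self.at_keyword("timewindow"):
            raise UnsupportedClauseError("TIMEWINDOW is not supported")
        if self.cur.kind != "eof":
            raise self.error(f"unexpected trailing input {self.cur.text!r}")
        qom = QueryObjectModel(
            selection=Selection(tuple(items)),
            location=Location(ehr_var, tuple(chain)),
            condition=condition,
        )
        _check_bindings(qom)
        return qom

    def parse_select_item(self) -> SelectItem:
        var = self.expect_name("selection variable")
        path = self.parse_pathtail()
        alias = None
        if self.at_keyword("as"):
            self.advance()
            alias = self.expect_name("alias")
        return SelectItem(var, path, alias)

    def parse_contains(self) -> ContainsSpec:
        rm_type = self.expect_name("reference-model type")
        var = self.expect_name("containment variable")
        pattern = "*"
        if self.at_sym("["):
            self.advance()
            pattern = self.expect_name("archetype id")
            self.expect_sym("]")
        return ContainsSpec(rm_type, var, pattern)

    def parse_pathtail(self) -> RelPath:
        steps: list[str] = []
        while self.at_sym("/"):
            self.advance()
            name = self.expect_step()
            if self.at_sym("["):
                self.advance()
                code = self.expect_name("node code")
                self.expect_sym("]")
                name = f"{name}[{code}]"
            steps.append(name)
        return RelPath(tuple(steps))

    def parse_or(self) -> Condition:
        parts = [self.parse_and()]
        while self.at_keyword("or"):
            self.advance()
            parts.append(self.parse_and())
        if len(parts) == 1:
            return parts[0]
        return OrNode(tuple(parts))

    def parse_and(self) -> Condition:
        parts = [self.parse_not()]
        while self.at_keyword("and"):
            self.advance()
            parts.append(self.parse_not())
        if len(parts) == 1:
            return parts[0]
        return AndNode(tuple(parts))

    def parse_not(self) -> Condition:
        if self.at_keyword("not"):
            self.advance()
            return NotNode(self.parse_not())
        if self.at_sym("("):
            self.advance()
            inner = self.parse_or()
            self.expect_sym(")")
            return inner
        return self.parse_predicate()

    def parse_predicate(self) -> Predicate:
        if self.at_keyword("exists"):
            self.advance()
            var = self.expect_name("variable")
            path = self.parse_pathtail()
            return Predicate(var, path, "exists")
        var = self.expect_name("variable")
        path = self.parse_pathtail()
        if self.at_keyword("matches", "in"):
            self.advance()
            self.expect_sym("{")
            values = [self.parse_literal()]
            while self.at_sym(","):
                self.advance()
                values.append(self.parse_literal())
            self.expect_sym("}")
            return Predicate(var, path, "matches", values=tuple(values))
        if self.cur.kind == "sym" and self.cur.text in COMPARISON_OPS:
            op = self.advance().text
            return Predicate(var, path, op, literal=self.parse_literal())
        raise self.error(f"expected comparison operator, found {self.cur.text!r}")

    def parse_literal(self) -> Literal:
        tok = self.cur
        if tok.kind == "number":
            self.advance()
            if re.fullmatch(r"-?\d+", tok.text):
                return int(tok.text)
            return float(tok.text)
        if tok.kind == "string":
            self.advance()
            body = tok.text[1:-1]
            return body.replace("\\'", "'").replace('\\"', '"').replace("\\\\", "\\")
        if tok.kind == "keyword" and tok.text in ("true", "false"):
            self.advance()
            return tok.text == "true"
        raise self.error(f"expected literal, found {tok.text!r}")


def _iter_predicates(cond: Condition) -> Iterator[Predicate]:
    if isinstance(cond, Predicate):
        yield cond
    elif isinstance(cond, NotNode):
        yield from _iter_predicates(cond.child)
    else:
        for c in cond.children:
            yield from _iter_predicates(c)


def _check_bindings(qom: QueryObjectModel) -> None:
    bound = set(qom.bound_variables)
    if len(bound) != 1 + len(qom.location.chain):
        raise BindingError("containment variables must be unique")
    for item in qom.selection.items:
        if item.variable not in bound:
            raise BindingError(f"unbound variable in SELECT: {item.variable!r}")
    if qom.condition is not None:
        for pred in _iter_predicates(qom.condition):
            if pred.variable not in bound:
                raise BindingError(f"unbound variable in WHERE: {pred.variable!r}")


def parse(query_text: str) -> QueryObjectModel:
    """Parse AQL text into a query object model."""
    return _Parser(query_text).parse_query()


# ---------------------------------------------------------------------------
# renderer


def _render_literal(value: Literal) -> str:
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, str):
        return "'" + value.replace("\\", "\\\\").replace("'", "\\'") + "'"
    return repr(value)


def _render_condition(cond: Condition, parent: str = "or") -> str:
    if isinstance(cond, Predicate):
        base = cond.variable + cond.path.render()
        if cond.operator == "exists":
            return f"EXISTS {base}"
        if cond.operator == "matches":
            return f"{base} MATCHES {{{', '.join(_render_literal(v) for v in cond.values)}}}"
        return f"{base} {cond.operator} {_render_literal(cond.literal)}"
    if isinstance(cond, NotNode):
        inner = _render_condition(cond.child, "not")
        if isinstance(cond.child, (AndNode, OrNode)):
            inner = f"({inner})"
        return f"NOT {inner}"
    if isinstance(cond, AndNode):
        parts = []
        for c in cond.children:
            txt = _render_condition(c, "and")
            if isinstance(c, OrNode):
                txt = f"({txt})"
            parts.append(txt)
        return " AND ".join(parts)
    parts = [_render_condition(c, "or") for c in cond.children]
    return " OR ".join(parts)


def render(qom: QueryObjectModel) -> str:
    """Canonical one-line AQL text; ``parse(render(q)) == q``."""
    sel_parts = []
    for item in qom.selection.items:
        txt = item.variable + item.path.render()
        if item.alias:
            txt += f" AS {item.alias}"
        sel_parts.append(txt)
    out = "SELECT " + ", ".join(sel_parts)
    out += f" FROM EHR {qom.location.ehr_variable}"
    for spec in qom.location.chain:
        out += f" CONTAINS {spec.rm_type} {spec.variable}"
        if spec.class_pattern != "*":
            out += f" [{spec.class_pattern}]"
    if qom.condition is not None:
        out += " WHERE " + _render_condition(qom.condition)
    return out
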