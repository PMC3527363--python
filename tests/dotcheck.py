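"""Minimal independent DOT grammar checker for the test suite.

Parses the standard DOT grammar subset (graph/digraph, subgraphs,
attribute statements, node and edge statements with quoted or bare
identifiers and [key=value, ...] lists) and returns the parsed
statements.  Raises DotSyntaxError on anything malformed, so "parses
under a DOT grammar checker" is a real check rather than a regex grep.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_TOKEN_RE = re.compile(
    r"""
    \s+
  | "(?:[^"\\]|\\.)*"          # quoted string (with escapes)
  | ->
  | --
  | [{}\[\];=,]
  | [A-Za-z0-9_.:#\-]+         # bare identifier / number
    """,
    re.VERBOSE,
)


class DotSyntaxError(Exception):
    pass


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DotSyntaxError(f"unexpected character at offset {pos}: {text[pos:pos+20]!r}")
        tok = m.group(0)
        if not tok.isspace():
            tokens.append(tok)
        pos = m.end()
    return tokens


def _unquote(tok: str) -> str:
    if tok.startswith('"'):
        return tok[1:-1].replace('\\"', '"')
    return tok


@dataclass
class NodeStmt:
    node_id: str
    attrs: dict[str, str]
    subgraph: str | None  # enclosing subgraph name, None = top level


@dataclass
class EdgeStmt:
    src: str
    dst: str
    directed: bool
    attrs: dict[str, str]
    subgraph: str | None


@dataclass
class DotGraph:
    name: str
    directed: bool
    nodes: list[NodeStmt] = field(default_factory=list)
    edges: list[EdgeStmt] = field(default_factory=list)
    subgraphs: list[str] = field(default_factory=list)

    def body_nodes(self) -> list[NodeStmt]:
        """Node statements outside any legend subgraph."""
        return [n for n in self.nodes if not (n.subgraph or "").startswith("cluster_legend")]

    def body_edges(self) -> list[EdgeStmt]:
        return [e for e in self.edges if not (e.subgraph or "").startswith("cluster_legend")]


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise DotSyntaxError("unexpected end of input")
        self.i += 1
        return tok

    def expect(self, want: str) -> None:
        tok = self.next()
        if tok != want:
            raise DotSyntaxError(f"expected {want!r}, got {tok!r}")

    def parse(self) -> DotGraph:
        kind = self.next()
        if kind not in ("graph", "digraph"):
            raise DotSyntaxError(f"expected graph/digraph, got {kind!r}")
        name = ""
        if self.peek() != "{":
            name = _unquote(self.next())
        graph = DotGraph(name=name, directed=kind == "digraph")
        self.expect("{")
        self._stmt_list(graph, None)
        if self.peek() is not None:
            raise DotSyntaxError(f"trailing tokens after graph body: {self.peek()!r}")
        return graph

    def _stmt_list(self, graph: DotGraph, subgraph: str | None) -> None:
        while True:
            tok = self.peek()
            if tok is None:
                raise DotSyntaxError("missing closing brace")
            if tok == "}":
                self.next()
                return
            self._stmt(graph, subgraph)

    def _attr_list(self) -> dict[str, str]:
        attrs: dict[str, str] = {}
        while self.peek() == "[":
            self.next()
            while self.peek() != "]":
                key = _unquote(self.next())
                self.expect("=")
                attrs[key] = _unquote(self.next())
                if self.peek() == ",":
                    self.next()
            self.expect("]")
        return attrs

    def _stmt(self, graph: DotGraph, subgraph: str | None) -> None:
        tok = self.next()
        if tok == "subgraph":
            name = ""
            if self.peek() != "{":
                name = _unquote(self.next())
            graph.subgraphs.append(name)
            self.expect("{")
            self._stmt_list(graph, name)
        elif tok in ("graph", "node", "edge"):
            self._attr_list()
            self._semi()
        else:
            ident = _unquote(tok)
            nxt = self.peek()
            if nxt == "=":  # graph-level attribute assignment
                self.next()
                self.next()
                self._semi()
            elif nxt in ("->", "--"):
                op = self.next()
                if op == "->" and not graph.directed:
                    raise DotSyntaxError("-> edge in undirected graph")
                if op == "--" and graph.directed:
                    raise DotSyntaxError("-- edge in digraph")
                dst = _unquote(self.next())
                attrs = self._attr_list()
                graph.edges.append(
                    EdgeStmt(ident, dst, op == "->", attrs, subgraph)
                )
                self._semi()
            else:
                attrs = self._attr_list()
                graph.nodes.append(NodeStmt(ident, attrs, subgraph))
                self._semi()

    def _semi(self) -> None:
        if self.peek() == ";":
            self.next()


def parse_dot(text: str) -> DotGraph:
    return _Parser(_tokenize(text)).parse()
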