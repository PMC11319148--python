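"""Pedigree handling for wheat breeding lines.

Parses Purdy-notation cross strings (``A/B``, ``A/B//C``, ``A/3/B/C//D``),
assembles a topologically ordered pedigree table, converts it to the numerator
relationship matrix A (the tabular method), and computes expected
genome-share of ancestry from a tagged set of source genotypes.

Purdy notation encodes a crossing history left-to-right: ``/`` is the first
cross, ``//`` the second, ``/3/`` the third and so on.  The string splits at
the highest-order operator present; ties at the same order split at the
rightmost occurrence (the latest cross made).  A backcross multiplier such as
``A*2/B`` expands to repeated crossing with the starred parent.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

UNKNOWN = None

__all__ = [
    "UNKNOWN",
    "PurdyParseError",
    "PedigreeCycleError",
    "CrossTree",
    "PedigreeTable",
    "parse_purdy",
    "build_pedigree",
    "nrm",
    "nrm_recursive",
    "pct_ancestry",
]


class PurdyParseError(ValueError):
    """Raised for malformed Purdy cross strings; carries the offending position."""

    def __init__(self, message: str, string: str, pos: int):
        super().__init__(f"{message} at position {pos} in {string!r}")
        self.string = string
        self.pos = pos


class PedigreeCycleError(ValueError):
    """Raised when pedigree records form a cycle (a genotype is its own ancestor)."""

    def __init__(self, cycle: Sequence[str]):
        super().__init__("pedigree cycle detected: " + " -> ".join(map(str, cycle)))
        self.cycle = list(cycle)


@dataclass(frozen=True)
class CrossTree:
    """Binary cross tree.  Leaves carry a genotype name; internal nodes a cross order."""

    name: str | None = None
    left: "CrossTree | None" = None
    right: "CrossTree | None" = None
    order: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.name is not None

    def canonical(self) -> str:
        """Deterministic serialization used for hashing synthetic cross-node ids."""
        if self.is_leaf:
            return self.name
        return f"({self.left.canonical()}|{self.right.canonical()})"

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return self.left.leaves() + self.right.leaves()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return self.name
        return f"cross({self.left!r}, {self.right!r})"


def cross(left: CrossTree, right: CrossTree, order: int | None = None) -> CrossTree:
    return CrossTree(left=left, right=right, order=order)


def leaf(name: str) -> CrossTree:
    return CrossTree(name=name)


_OP_RE = re.compile(r"/(\d+)/|//|/")


def _scan_operators(s: str) -> list[tuple[int, int, int]]:
    """Return (start, end, order) for every cross operator in ``s``."""
    ops = []
    for m in _OP_RE.finditer(s):
        if m.group(1) is not None:
            order = int(m.group(1))
            if order < 3:
                raise PurdyParseError(f"numbered operator /{order}/ must be >= 3", s, m.start())
        elif m.group(0) == "//":
            order = 2
        else:
            order = 1
        ops.append((m.start(), m.end(), order))
    return ops


_STAR_RE = re.compile(r"^(?P<core>.*?)\*(?P<k>\d+)\s*$")


def _split_star(side: str, s: str, offset: int) -> tuple[str, int]:
    """Strip a trailing ``*k`` multiplier from one side of a cross, if present."""
    m = _STAR_RE.match(side)
    if m is None:
        if "*" in side and not _OP_RE.search(side):
            raise PurdyParseError("malformed '*k' multiplier", s, offset + side.index("*"))
        return side, 1
    k = int(m.group("k"))
    if k < 1:
        raise PurdyParseError("'*k' multiplier must be >= 1", s, offset + len(m.group("core")))
    return m.group("core"), k


def parse_purdy(s: str) -> CrossTree:
    """Parse a Purdy cross string into a :class:`CrossTree`.

    The split point is the highest-order operator; ties break at the rightmost
    occurrence.  ``A*k/B`` expands to ``A/(A/.../(A/B))`` with ``k`` doses of A
    (one extra backcross per dose); ``A/B*k`` symmetrically on the right.
    """
    if not isinstance(s, str) or not s.strip():
        raise PurdyParseError("empty cross string", s or "", 0)
    s = s.strip()
    return _parse(s, s, 0)


def _parse(frag: str, full: str, offset: int) -> CrossTree:
    frag = frag.strip()
    if not frag:
        raise PurdyParseError("empty side of cross", full, offset)
    ops = _scan_operators(frag)
    if not ops:
        core, k = _split_star(frag, full, offset)
        if k > 1:
            raise PurdyParseError("'*k' multiplier without a cross", full, offset)
        return leaf(core.strip())
    top = max(o for _, _, o in ops)
    start, end, order = [op for op in ops if op[2] == top][-1]
    left_raw, right_raw = frag[:start], frag[end:]
    if not left_raw.strip() or not right_raw.strip():
        raise PurdyParseError("cross operator with an empty side", full, offset + start)
    left_core, k_left = _split_star(left_raw, full, offset)
    right_core, k_right = _split_star(right_raw, full, offset + end)
    left_tree = _parse(left_core, full, offset)
    right_tree = _parse(right_core, full, offset + end)
    # expand backcross multipliers: each extra dose is one more cross on that side
    node = cross(left_tree, right_tree, order)
    for _ in range(k_left - 1):
        node = cross(left_tree, node, order)
    for _ in range(k_right - 1):
        node = cross(node, right_tree, order)
    return node


def format_purdy(tree: CrossTree) -> str:
    """Serialize a cross tree back to a Purdy string (``/``, ``//``, ``/n/`` only)."""

    def depth(t: CrossTree) -> int:
        if t.is_leaf:
            return 0
        return 1 + max(depth(t.left), depth(t.right))

    def op(order: int) -> str:
        return {1: "/", 2: "//"}.get(order, f"/{order}/")

    def fmt(t: CrossTree) -> tuple[str, int]:
        if t.is_leaf:
            return t.name, 0
        ls, lo = fmt(t.left)
        rs, ro = fmt(t.right)
        order = max(lo, ro) + 1
        return f"{ls}{op(order)}{rs}", order

    return fmt(tree)[0]


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree records.

    ``df`` has columns genotype, parent1, parent2, purdy, source; parents of
    founders are :data:`UNKNOWN` (None).  Row order is a topological order:
    every parent precedes its offspring.
    """

    df: pd.DataFrame
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.df["genotype"])}
        if len(self._index) != len(self.df):
            dup = self.df["genotype"][self.df["genotype"].duplicated()].iloc[0]
            raise ValueError(f"duplicate genotype id {dup!r}")
        for i, (p1, p2) in enumerate(zip(self.df["parent1"], self.df["parent2"])):
            for p in (p1, p2):
                if p is not UNKNOWN and self._index.get(p, len(self.df)) >= i:
                    raise ValueError(
                        f"pedigree not topologically ordered: parent {p!r} does not "
                        f"precede offspring {self.df['genotype'].iloc[i]!r}; run build_pedigree"
                    )

    @property
    def genotypes(self) -> list[str]:
        return list(self.df["genotype"])

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, g: str) -> bool:
        return g in self._index

    def index(self, g: str) -> int:
        return self._index[g]

    def parents(self, g: str) -> tuple[str | None, str | None]:
        i = self._index[g]
        return self.df["parent1"].iloc[i], self.df["parent2"].iloc[i]

    def source(self, g: str) -> str:
        return self.df["source"].iloc[self._index[g]]

    def to_csv(self, path) -> None:
        out = self.df.copy()
        for col in ("parent1", "parent2"):
            out[col] = out[col].map(lambda v: "UNKNOWN" if v is UNKNOWN else v)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PedigreeTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("parent1", "parent2"):
            df[col] = df[col].map(lambda v: UNKNOWN if v in ("", "UNKNOWN") else v)
        if "purdy" not in df:
            df["purdy"] = ""
        if "source" not in df:
            df["source"] = ""
        return cls(df)


def _cross_node_id(tree: CrossTree) -> str:
    digest = hashlib.sha1(tree.canonical().encode()).hexdigest()[:10]
    return f"#{digest}"


def build_pedigree(
    entries: Iterable[tuple[str, str | tuple[str | None, str | None]]],
    sources: Mapping[str, str] | None = None,
    default_source: str = "",
) -> PedigreeTable:
    """Assemble a :class:`PedigreeTable` from (id, purdy-string-or-parent-pair) entries.

    Intermediate crosses in Purdy strings are materialized as synthetic records
    whose ids are deterministic hashes of the cross subtree, so repeated
    sub-crosses unify.  Parents never defined by any entry become founders.
    Unparseable Purdy strings demote the entry to a founder (the string is kept).
    """
    sources = dict(sources or {})
    graph = nx.DiGraph()
    rec: dict[str, dict] = {}

    def ensure(g: str, p1=UNKNOWN, p2=UNKNOWN, purdy: str = "") -> None:
        if g in rec and (rec[g]["parent1"] is not UNKNOWN or p1 is UNKNOWN):
            return
        rec[g] = {"genotype": g, "parent1": p1, "parent2": p2, "purdy": purdy}
        graph.add_node(g)
        for p in (p1, p2):
            if p is not UNKNOWN:
                graph.add_edge(p, g)

    def materialize(tree: CrossTree) -> str:
        if tree.is_leaf:
            ensure(tree.name)
            return tree.name
        gid = _cross_node_id(tree)
        p1 = materialize(tree.left)
        p2 = materialize(tree.right)
        ensure(gid, p1, p2, format_purdy(tree))
        return gid

    for gid, spec in entries:
        if isinstance(spec, str):
            try:
                tree = parse_purdy(spec)
            except PurdyParseError:
                ensure(gid, purdy=spec)  # unparseable: keep as founder
                continue
            if tree.is_leaf:
                # a bare name: the entry is a (possibly renamed) founder
                if tree.name != gid:
                    ensure(tree.name)
                    ensure(gid, tree.name, tree.name, spec)
                else:
                    ensure(gid, purdy=spec)
                continue
            p1 = materialize(tree.left)
            p2 = materialize(tree.right)
            ensure(gid, p1, p2, spec)
        else:
            p1, p2 = spec
            p1 = p1 if p1 not in ("", "UNKNOWN") else UNKNOWN
            p2 = p2 if p2 not in ("", "UNKNOWN") else UNKNOWN
            for p in (p1, p2):
                if p is not UNKNOWN:
                    ensure(p)
            ensure(gid, p1, p2)

    try:
        order = list(nx.lexicographical_topological_sort(graph))
    except nx.NetworkXUnfeasible:
        cyc = nx.find_cycle(graph)
        raise PedigreeCycleError([e[0] for e in cyc] + [cyc[-1][1]])

    rows = []
    for g in order:
        r = dict(rec[g])
        r["source"] = sources.get(g, default_source)
        rows.append(r)
    df = pd.DataFrame(rows, columns=["genotype", "parent1", "parent2", "purdy", "source"])
    return PedigreeTable(df)


def nrm(ped: PedigreeTable) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    Founders: ``a_ii = 1`` and unrelated.  For individual i with parents p, q
    (processed in pedigree order): ``a_ij = 0.5 (a_jp + a_jq)`` for earlier j and
    ``a_ii = 1 + 0.5 a_pq``; an unknown parent contributes 0.  Returns a
    symmetric PSD DataFrame indexed by genotype.
    """
    m = len(ped)
    A = np.zeros((m, m))
    p1s = ped.df["parent1"].to_numpy()
    p2s = ped.df["parent2"].to_numpy()
    idx = ped._index
    for i in range(m):
        p = idx.get(p1s[i], -1) if p1s[i] is not UNKNOWN else -1
        q = idx.get(p2s[i], -1) if p2s[i] is not UNKNOWN else -1
        if i > 0:
            row = np.zeros(i)
            if p >= 0:
                row += 0.5 * A[:i, p]
            if q >= 0:
                row += 0.5 * A[:i, q]
            A[:i, i] = row
            A[i, :i] = row
        A[i, i] = 1.0 + (0.5 * A[p, q] if p >= 0 and q >= 0 else 0.0)
    g = ped.genotypes
    return pd.DataFrame(A, index=g, columns=g)


def nrm_recursive(ped: PedigreeTable, i: str, j: str) -> float:
    """Additive relationship a_ij by memoized recursion (oracle for :func:`nrm`)."""
    idx = ped._index
    if i not in idx or j not in idx:
        missing = i if i not in idx else j
        raise KeyError(f"genotype {missing!r} not in pedigree")
    parents = {g: ped.parents(g) for g in ped.genotypes}

    @lru_cache(maxsize=None)
    def a(x: str, y: str) -> float:
        if idx[x] < idx[y]:
            x, y = y, x
        p, q = parents[x]
        if x == y:
            if p is UNKNOWN or q is UNKNOWN:
                return 1.0
            return 1.0 + 0.5 * a(p, q)
        tot = 0.0
        if p is not UNKNOWN:
            tot += 0.5 * a(p, y)
        if q is not UNKNOWN:
            tot += 0.5 * a(q, y)
        return tot

    return a(i, j)


def pct_ancestry(ped: PedigreeTable, g: str, sources: set[str] | frozenset[str]) -> float:
    """Expected genome share of ``g`` descending from genotypes tagged in ``sources``.

    A genotype tagged with one of the source tags contributes share 1 outright;
    otherwise its share is the mean of its parents' shares, an unknown parent
    contributing 0.  The result lies in [0, 1].
    """
    if g not in ped:
        raise KeyError(f"genotype {g!r} not in pedigree")
    tags = set(sources)

    @lru_cache(maxsize=None)
    def share(x: str) -> float:
        if ped.source(x) in tags:
            return 1.0
        p, q = ped.parents(x)
        s = 0.0
        if p is not UNKNOWN:
            s += 0.5 * share(p)
        if q is not UNKNOWN:
            s += 0.5 * share(q)
        return s

    return share(g)
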