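"""Parsimony engine: character optimization, implied weighting, tree search.

Discrete characters are optimized with Fitch set operations
(non-additive: any state change costs 1) or with the Farris interval
method (additive/ordered: a change of *k* units costs *k*).  Continuous
characters are treated as additive on their raw values.  Implied
weighting scores a tree by the concave transform ``sum_c h_c/(h_c + K)``
of per-character homoplasy ``h_c = s_c - m_c``; the complementary
Goloboff fit ``sum_c K/(h_c + K)`` is also reported.

The search is a parsimony ratchet: random-addition Wagner starting
trees, first-improvement SPR hill-climbing, and reweighting cycles that
perturb a random fraction of characters, re-search, restore the weights
and keep the result when it improves.

Internally all discrete characters are packed into per-taxon arbitrary
precision integers, one 11-bit field per (binary-recoded) character, so
a single Fitch downpass scores every discrete character at once.
Additive characters enter this fast path through cumulative binary
recoding, which preserves lengths exactly.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "Character",
    "CharacterMatrix",
    "Tree",
    "ParsimonyScore",
    "SearchConfig",
    "SearchResult",
    "char_length",
    "min_steps",
    "max_steps",
    "score_tree",
    "ratchet_search",
    "exhaustive_search",
    "strict_consensus",
    "build_combined_matrix",
]

_W = 11  # bits per packed field: 10 data bits + 1 guard bit
_DATA = (1 << 10) - 1


# ==========================================================================
# data model


@dataclass
class Character:
    """One matrix column.

    ``states`` holds one entry per taxon: a ``frozenset`` of small ints
    for discrete characters (singleton for a plain observation, larger
    for polymorphism), a float for continuous characters, or ``None``
    for missing.
    """

    states: list
    additive: bool = False
    continuous: bool = False

    def observed(self) -> list:
        return [s for s in self.states if s is not None]


@dataclass
class CharacterMatrix:
    taxa: list[str]
    characters: list[Character]
    outgroup: str | None = None

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.characters)

    def __post_init__(self):
        for j, ch in enumerate(self.characters):
            if len(ch.states) != self.ntax:
                raise ValueError(f"character {j}: wrong number of rows")
            if ch.additive and not ch.continuous:
                for s in ch.states:
                    if s is not None and not all(isinstance(v, int) for v in s):
                        raise ValueError(f"character {j}: non-integer additive state")

    @classmethod
    def from_dataframe(cls, df, state_columns=None, additive=(), outgroup=None,
                       id_column="specimen_id"):
        """Build a discrete matrix from a specimen table.

        ``state_columns`` defaults to all ``char_*`` columns; ``additive``
        is a collection of character indices (positional, 0-based).
        """
        if state_columns is None:
            state_columns = [c for c in df.columns if c.startswith("char_")]
        taxa = list(df[id_column])
        additive = set(additive)
        chars = []
        for j, col in enumerate(state_columns):
            states = [
                None if v is None or (isinstance(v, float) and math.isnan(v))
                else frozenset([int(v)])
                for v in df[col]
            ]
            chars.append(Character(states=states, additive=j in additive))
        return cls(taxa=taxa, characters=chars, outgroup=outgroup)


class Tree:
    """Unrooted binary tree over leaves ``0 .. n-1``.

    Stored as an adjacency dict; internal node ids are arbitrary ints
    ``>= n``.  Equality and hashing use the bipartition set, so two
    topologically identical trees compare equal regardless of internal
    node numbering.
    """

    def __init__(self, adj: dict[int, set[int]], n_leaves: int):
        self.adj = adj
        self.n_leaves = n_leaves

    def copy(self) -> "Tree":
        return Tree({k: set(v) for k, v in self.adj.items()}, self.n_leaves)

    # -- construction ------------------------------------------------------

    @classmethod
    def random(cls, n_leaves: int, rng: random.Random) -> "Tree":
        if n_leaves < 3:
            raise ValueError("need at least 3 leaves")
        nxt = n_leaves
        adj = {0: {nxt}, 1: {nxt}, 2: {nxt}, nxt: {0, 1, 2}}
        nxt += 1
        for leaf in range(3, n_leaves):
            edges = [(a, b) for a in adj for b in adj[a] if a < b]
            a, b = edges[rng.randrange(len(edges))]
            adj[a].discard(b)
            adj[b].discard(a)
            adj[nxt] = {a, b, leaf}
            adj[a].add(nxt)
            adj[b].add(nxt)
            adj[leaf] = {nxt}
            nxt += 1
        return cls(adj, n_leaves)

    @classmethod
    def from_newick(cls, text: str, taxa: Sequence[str]) -> "Tree":
        index = {t: i for i, t in enumerate(taxa)}
        dt = dendropy.Tree.get(data=text, schema="newick")
        dt.deroot()
        adj: dict[int, set[int]] = {}
        ids: dict = {}
        nxt = len(taxa)

        def node_id(nd):
            nonlocal nxt
            if nd in ids:
                return ids[nd]
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else nd.label
                if label not in index:
                    raise ValueError(f"unknown taxon {label!r}")
                ids[nd] = index[label]
            else:
                ids[nd] = nxt
                nxt += 1
            adj.setdefault(ids[nd], set())
            return ids[nd]

        for edge in dt.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            a, b = node_id(edge.tail_node), node_id(edge.head_node)
            adj[a].add(b)
            adj[b].add(a)
        return cls(adj, len(taxa))

    def to_newick(self, taxa: Sequence[str], root_on: str | None = None) -> str:
        """Serialize; optionally root the display on the edge to one taxon."""
        leaf = 0 if root_on is None else list(taxa).index(root_on)

        def rec(node, parent):
            kids = [nb for nb in self.adj[node] if nb != parent]
            if not kids:
                return taxa[node]
            return "(" + ",".join(rec(k, node) for k in kids) + ")"

        hub = next(iter(self.adj[leaf]))
        return f"({taxa[leaf]},{rec(hub, leaf)});"

    # -- topology ----------------------------------------------------------

    def bipartitions(self) -> frozenset[int]:
        """Non-trivial splits as canonical leaf bitmasks.

        Each internal edge is encoded by the bitmask of the leaf side not
        containing leaf 0 (so masks are comparable across trees).
        """
        n = self.n_leaves
        full = (1 << n) - 1
        masks: dict[int, int] = {}
        # iterative post-order rooted at leaf 0
        hub = next(iter(self.adj[0]))
        order = []
        stack = [(hub, 0)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        for node, parent in reversed(order):
            if node < n:
                masks[node] = 1 << node
            else:
                masks[node] = 0
                for nb in self.adj[node]:
                    if nb != parent:
                        masks[node] |= masks[nb]
        splits = set()
        for node, parent in order:
            if parent == 0 or node < n:
                continue
            m = masks[node]
            if m not in (0, full) and bin(m).count("1") >= 2 and bin(full ^ m).count("1") >= 2:
                splits.add(m if not (m & 1) else full ^ m)
        return frozenset(splits)

    def __eq__(self, other):
        return (
            isinstance(other, Tree)
            and self.n_leaves == other.n_leaves
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self):
        return hash((self.n_leaves, self.bipartitions()))


# ==========================================================================
# general per-character optimization (reference path)


def _fitch_length(tree: Tree, states: list) -> int:
    """Non-additive length by set-intersection downpass (missing = any)."""
    obs = set().union(*(s for s in states if s is not None))
    full = frozenset(obs)
    val = {}
    steps = 0
    hub = next(iter(tree.adj[0]))
    order = []
    stack = [(hub, 0)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in tree.adj[node]:
            if nb != parent:
                stack.append((nb, node))
    for node, parent in reversed(order):
        if node < tree.n_leaves:
            val[node] = states[node] if states[node] is not None else full
        else:
            kids = [nb for nb in tree.adj[node] if nb != parent]
            s = val[kids[0]]
            for k in kids[1:]:
                inter = s & val[k]
                if inter:
                    s = inter
                else:
                    s = s | val[k]
                    steps += 1
            val[node] = s
    top = states[0] if states[0] is not None else full
    root_set = val[hub]
    if not (top & root_set):
        steps += 1
    return steps


def _interval_length(tree: Tree, states: list) -> float:
    """Additive/continuous length by Farris interval downpass."""

    def leaf_iv(s):
        if s is None:
            return None
        if isinstance(s, frozenset):
            return (min(s), max(s))
        return (s, s)

    val = {}
    steps = 0.0
    hub = next(iter(tree.adj[0]))
    order = []
    stack = [(hub, 0)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in tree.adj[node]:
            if nb != parent:
                stack.append((nb, node))
    for node, parent in reversed(order):
        if node < tree.n_leaves:
            val[node] = leaf_iv(states[node])
        else:
            kids = [nb for nb in tree.adj[node] if nb != parent]
            iv = val[kids[0]]
            for k in kids[1:]:
                other = val[k]
                if iv is None:
                    iv = other
                    continue
                if other is None:
                    continue
                lo = max(iv[0], other[0])
                hi = min(iv[1], other[1])
                if lo <= hi:
                    iv = (lo, hi)
                else:
                    steps += lo - hi
                    iv = (hi, lo)
            val[node] = iv
    root_iv = val[hub]
    leaf0 = leaf_iv(states[0])
    if leaf0 is not None and root_iv is not None:
        lo = max(leaf0[0], root_iv[0])
        hi = min(leaf0[1], root_iv[1])
        if lo > hi:
            steps += lo - hi
    return steps


def char_length(tree: Tree, matrix: CharacterMatrix, index: int) -> float:
    """Minimum number of state changes for one character on a tree."""
    ch = matrix.characters[index]
    if tree.n_leaves != matrix.ntax:
        raise ValueError("tree and matrix have different taxon counts")
    if not ch.observed():
        raise ValueError(f"character {index} has no scored taxa")
    if ch.continuous or ch.additive:
        return _interval_length(tree, ch.states)
    return _fitch_length(tree, ch.states)


def min_steps(matrix: CharacterMatrix, index: int) -> float:
    """Minimum steps on any tree: states-1 (non-additive) or the span (additive)."""
    ch = matrix.characters[index]
    obs = ch.observed()
    if not obs:
        raise ValueError(f"character {index} has no scored taxa")
    if ch.continuous:
        vals = [float(v) for v in obs]
        return max(vals) - min(vals)
    if ch.additive:
        lo = min(max(s) for s in obs)
        hi = max(min(s) for s in obs)
        return max(0, hi - lo)
    # non-additive: minimal hitting set of the observed state sets, minus 1
    union = sorted(set().union(*obs))
    for size in range(1, len(union) + 1):
        for combo in itertools.combinations(union, size):
            cset = set(combo)
            if all(cset & s for s in obs):
                return size - 1
    raise AssertionError("unreachable")


def max_steps(matrix: CharacterMatrix, index: int) -> float:
    """Steps on the fully unresolved star tree (the worst topology)."""
    ch = matrix.characters[index]
    obs = ch.observed()
    if not obs:
        raise ValueError(f"character {index} has no scored taxa")
    if ch.continuous:
        vals = sorted(float(v) for v in obs)
        return min(sum(abs(v - w) for v in vals) for w in vals)
    if ch.additive:
        lo = min(min(s) for s in obs)
        hi = max(max(s) for s in obs)
        candidates = range(lo, hi + 1)
        return min(
            sum(min(abs(v - w) for v in s) for s in obs) for w in candidates
        )
    union = sorted(set().union(*obs))
    return len(obs) - max(sum(1 for s in obs if w in s) for w in union)


# ==========================================================================
# scores


@dataclass
class ParsimonyScore:
    """Per-character and ensemble parsimony statistics for one tree."""

    steps: list
    min_steps: list
    max_steps: list
    k: float

    @property
    def homoplasy(self) -> list:
        return [s - m for s, m in zip(self.steps, self.min_steps)]

    @property
    def fit_contributions(self) -> list:
        return [h / (h + self.k) for h in self.homoplasy]

    @property
    def length(self) -> float:
        total = sum(self.steps)
        return int(total) if float(total).is_integer() else total

    @property
    def implied_weights_score(self) -> float:
        """Adjusted homoplasy ``sum h/(h+K)`` (minimized by the search)."""
        return sum(self.fit_contributions)

    @property
    def goloboff_fit(self) -> float:
        """Complementary fit ``sum K/(h+K)`` (maximized form)."""
        return sum(self.k / (h + self.k) for h in self.homoplasy)

    @property
    def ci(self) -> float:
        return sum(self.min_steps) / sum(self.steps)

    @property
    def ri(self) -> float:
        sg, ss, sm = sum(self.max_steps), sum(self.steps), sum(self.min_steps)
        return (sg - ss) / (sg - sm)

    def rounded_indices(self) -> tuple[int, int]:
        """CI and RI as integer percentages, truncated as in TNT printouts."""
        return int(self.ci * 100), int(self.ri * 100)


def score_tree(tree: Tree, matrix: CharacterMatrix, k: float = 3.0) -> ParsimonyScore:
    if k <= 0:
        raise ValueError("concavity K must be positive")
    steps = [char_length(tree, matrix, j) for j in range(matrix.nchar)]
    return ParsimonyScore(
        steps=steps,
        min_steps=[min_steps(matrix, j) for j in range(matrix.nchar)],
        max_steps=[max_steps(matrix, j) for j in range(matrix.nchar)],
        k=k,
    )


# ==========================================================================
# packed fast path


class _PackedEngine:
    """Bit-parallel Fitch scorer over all discrete characters at once.

    Additive discrete characters are recoded into cumulative binary
    fields; every field occupies 11 bits (10 data + 1 guard) of one big
    Python integer per taxon.  Continuous characters are scored by the
    interval method alongside.
    """

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.n = matrix.ntax
        self.nchar = matrix.nchar
        self.char_min = [min_steps(matrix, j) for j in range(matrix.nchar)]
        fields: list[int] = []       # field index -> character index
        codes = [0] * self.n
        self.cont: list[int] = []    # continuous character indices
        for j, ch in enumerate(matrix.characters):
            if ch.continuous:
                self.cont.append(j)
                continue
            obs = ch.observed()
            if ch.additive:
                lo = min(min(s) for s in obs)
                hi = max(max(s) for s in obs)
                for t in range(1, hi - lo + 1):
                    fi = len(fields)
                    fields.append(j)
                    for i, s in enumerate(ch.states):
                        if s is None:
                            bits = 0b11
                        else:
                            bits = 0
                            for v in s:
                                bits |= 2 if (v - lo) >= t else 1
                        codes[i] |= bits << (fi * _W)
            else:
                allmask = 0
                for s in obs:
                    for v in s:
                        allmask |= 1 << v
                fi = len(fields)
                fields.append(j)
                for i, s in enumerate(ch.states):
                    if s is None:
                        bits = allmask
                    else:
                        bits = 0
                        for v in s:
                            bits |= 1 << v
                    codes[i] |= bits << (fi * _W)
        self.fields = fields
        self.codes = codes
        self.mask = 0
        self.high = 0
        for fi in range(len(fields)):
            self.mask |= _DATA << (fi * _W)
            self.high |= 1 << (fi * _W + 10)

    def _postorder(self, adj, root_leaf):
        hub = next(iter(adj[root_leaf]))
        out = []
        stack = [(hub, root_leaf)]
        while stack:
            node, parent = stack.pop()
            out.append((node, parent))
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        return out, hub

    def char_steps(self, adj) -> list:
        """Per-character steps on an unrooted binary tree (adjacency dict)."""
        n = self.n
        counts = [0.0] * self.nchar
        out, hub = self._postorder(adj, 0)
        val = {}
        codes, fields = self.codes, self.fields
        MASK, HIGH = self.mask, self.high
        for node, parent in reversed(out):
            if node < n:
                val[node] = codes[node]
                continue
            kids = [nb for nb in adj[node] if nb != parent]
            a = val[kids[0]]
            for kid in kids[1:]:
                b = val[kid]
                inter = a & b
                z = HIGH & ~(inter + MASK)
                if z:
                    inter |= (a | b) & (z - (z >> 10))
                    while z:
                        lsb = z & -z
                        counts[fields[(lsb.bit_length() - 1) // _W]] += 1
                        z ^= lsb
                a = inter
            val[node] = a
        b = val[hub]
        a = codes[0]
        inter = a & b
        z = HIGH & ~(inter + MASK)
        while z:
            lsb = z & -z
            counts[fields[(lsb.bit_length() - 1) // _W]] += 1
            z ^= lsb
        if self.cont:
            tree = Tree(adj, self.n)
            for j in self.cont:
                counts[j] = _interval_length(tree, self.matrix.characters[j].states)
        return counts

    def fit(self, adj, k: float, weights=None) -> float:
        counts = self.char_steps(adj)
        total = 0.0
        for j in range(self.nchar):
            h = counts[j] - self.char_min[j]
            if h < 0:  # partial trees during stepwise addition
                h = 0.0
            w = 1.0 if weights is None else weights[j]
            if w:
                total += w * h / (h + k)
        return total


# ==========================================================================
# search


@dataclass
class SearchConfig:
    k: float = 3.0
    iterations: int = 100
    hold: int = 100
    seed: int = 1
    perturb_fraction: float = 0.15
    n_starts: int = 4
    climb_rounds: int = 40

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("concavity K must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class SearchResult:
    trees: list
    best_score: float
    config: SearchConfig
    n_improvements: int = 0

    @property
    def best_tree(self) -> Tree:
        return self.trees[0]


def _subtree_nodes(adj, u, v):
    out = {u}
    stack = [u]
    while stack:
        w = stack.pop()
        for nb in adj[w]:
            if nb != v and nb not in out:
                out.add(nb)
                stack.append(nb)
    return out


def _prune_regraft(adj, u, v, x, y):
    nb = [w for w in adj[v] if w != u]
    p, q = nb
    adj[v].clear()
    adj[p].discard(v)
    adj[q].discard(v)
    adj[p].add(q)
    adj[q].add(p)
    adj[x].discard(y)
    adj[y].discard(x)
    adj[x].add(v)
    adj[y].add(v)
    adj[v] = {x, y, u}
    return (u, v, p, q, x, y)


def _undo_spr(adj, mv):
    u, v, p, q, x, y = mv
    adj[x].discard(v)
    adj[y].discard(v)
    adj[x].add(y)
    adj[y].add(x)
    adj[p].discard(q)
    adj[q].discard(p)
    adj[p].add(v)
    adj[q].add(v)
    adj[v] = {p, q, u}


def _spr_climb(adj, cur, scorer, rng, max_rounds=40):
    """First-improvement SPR hill climb; returns the local-optimum score."""
    for _ in range(max_rounds):
        improved = False
        edges = [(a, b) for a in adj for b in adj[a]]
        rng.shuffle(edges)
        for (u, v) in edges:
            if len(adj[v]) != 3:
                continue
            inside = _subtree_nodes(adj, u, v)
            targets = [
                (x, y)
                for x in adj
                for y in adj[x]
                if x < y and x not in inside and y not in inside
                and x != v and y != v
                and not (x in adj[v] and y in adj[v])
            ]
            rng.shuffle(targets)
            for (x, y) in targets:
                mv = _prune_regraft(adj, u, v, x, y)
                sc = scorer(adj)
                if sc < cur - 1e-12:
                    cur = sc
                    improved = True
                    break
                _undo_spr(adj, mv)
            if improved:
                break
        if not improved:
            break
    return cur


def _wagner_tree(engine: _PackedEngine, k: float, rng, weights=None):
    """Random-addition stepwise (Wagner) starting tree."""
    n = engine.n
    order = list(range(n))
    rng.shuffle(order)
    hub = 2 * n
    a, b, c = order[:3]
    adj = {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
    nxt = hub + 1
    for leaf in order[3:]:
        best = None
        edges = [(x, y) for x in adj for y in adj[x] if x < y]
        for (x, y) in edges:
            adj[x].discard(y)
            adj[y].discard(x)
            adj[nxt] = {x, y, leaf}
            adj[x].add(nxt)
            adj[y].add(nxt)
            adj[leaf] = {nxt}
            sc = _partial_fit(engine, adj, k, weights)
            if best is None or sc < best[0]:
                best = (sc, x, y)
            del adj[nxt]
            del adj[leaf]
            adj[x].discard(nxt)
            adj[y].discard(nxt)
            adj[x].add(y)
            adj[y].add(x)
        _, x, y = best
        adj[x].discard(y)
        adj[y].discard(x)
        adj[nxt] = {x, y, leaf}
        adj[x].add(nxt)
        adj[y].add(nxt)
        adj[leaf] = {nxt}
        nxt += 1
    return adj


def _partial_fit(engine, adj, k, weights=None):
    """Implied-weights fit of a partial tree (subset of leaves present)."""
    n = engine.n
    leaves = [x for x in adj if x < n]
    r0 = min(leaves)
    out = []
    stack = [(next(iter(adj[r0])), r0)]
    while stack:
        node, parent = stack.pop()
        out.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    counts = [0.0] * engine.nchar
    val = {}
    codes, fields = engine.codes, engine.fields
    MASK, HIGH = engine.mask, engine.high
    for node, parent in reversed(out):
        if node < n:
            val[node] = codes[node]
            continue
        kids = [nb for nb in adj[node] if nb != parent]
        a = val[kids[0]]
        for kid in kids[1:]:
            b = val[kid]
            inter = a & b
            z = HIGH & ~(inter + MASK)
            if z:
                inter |= (a | b) & (z - (z >> 10))
                while z:
                    lsb = z & -z
                    counts[fields[(lsb.bit_length() - 1) // _W]] += 1
                    z ^= lsb
            a = inter
        val[node] = a
    b = val[next(iter(adj[r0]))]
    inter = codes[r0] & b
    z = HIGH & ~(inter + MASK)
    while z:
        lsb = z & -z
        counts[fields[(lsb.bit_length() - 1) // _W]] += 1
        z ^= lsb
    if engine.cont:
        sub = {kk: set(vv) for kk, vv in adj.items()}
        tree = Tree(sub, n)  # interval scorer tolerates absent leaves via ids
        for j in engine.cont:
            counts[j] = _interval_length_partial(sub, engine.matrix.characters[j].states, r0)
    total = 0.0
    for j in range(engine.nchar):
        h = max(0.0, counts[j] - engine.char_min[j])
        w = 1.0 if weights is None else weights[j]
        if w:
            total += w * h / (h + k)
    return total


def _interval_length_partial(adj, states, r0):
    val = {}
    steps = 0.0
    out = []
    stack = [(next(iter(adj[r0])), r0)]
    while stack:
        node, parent = stack.pop()
        out.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    nleaf = len(states)

    def leaf_iv(s):
        if s is None:
            return None
        if isinstance(s, frozenset):
            return (min(s), max(s))
        return (s, s)

    for node, parent in reversed(out):
        if node < nleaf:
            val[node] = leaf_iv(states[node])
            continue
        kids = [nb for nb in adj[node] if nb != parent]
        iv = val[kids[0]]
        for kidn in kids[1:]:
            other = val[kidn]
            if iv is None:
                iv = other
                continue
            if other is None:
                continue
            lo, hi = max(iv[0], other[0]), min(iv[1], other[1])
            if lo <= hi:
                iv = (lo, hi)
            else:
                steps += lo - hi
                iv = (hi, lo)
        val[node] = iv
    top = leaf_iv(states[r0])
    rootv = val[next(iter(adj[r0]))]
    if top is not None and rootv is not None:
        lo, hi = max(top[0], rootv[0]), min(top[1], rootv[1])
        if lo > hi:
            steps += lo - hi
    return steps


def ratchet_search(matrix: CharacterMatrix, config: SearchConfig) -> SearchResult:
    """Parsimony ratchet under implied weighting.

    Random-addition Wagner trees are refined by first-improvement SPR;
    each ratchet cycle perturbs a random ``perturb_fraction`` of the
    characters (upweighting, occasionally deleting), climbs under the
    perturbed weights, restores them and climbs again, keeping the
    result when the implied-weights score improves.  All distinct trees
    tied at the best score are retained, up to ``hold``.
    """
    if matrix.ntax < 4:
        raise ValueError("need at least 4 taxa to search")
    rng = random.Random(config.seed)
    engine = _PackedEngine(matrix)
    k = config.k

    def scorer(adj, weights=None):
        return engine.fit(adj, k, weights)

    best = math.inf
    best_adjs: list[dict] = []
    n_improve = 0

    def consider(adj, sc):
        nonlocal best, best_adjs, n_improve
        if sc < best - 1e-9:
            best = sc
            best_adjs = [{kk: set(vv) for kk, vv in adj.items()}]
            n_improve += 1
            return True
        if abs(sc - best) <= 1e-9 and len(best_adjs) < config.hold:
            t_new = Tree({kk: set(vv) for kk, vv in adj.items()}, matrix.ntax)
            if all(Tree(a, matrix.ntax) != t_new for a in best_adjs):
                best_adjs.append(t_new.adj)
        return False

    for _ in range(config.n_starts):
        adj = _wagner_tree(engine, k, rng)
        cur = _spr_climb(adj, scorer(adj), scorer, rng, config.climb_rounds)
        consider(adj, cur)

    adj = {kk: set(vv) for kk, vv in best_adjs[0].items()}
    nchar = matrix.nchar
    for it in range(config.iterations):
        style = it % 3
        frac = config.perturb_fraction
        if style == 0:
            w = [float(rng.choice([1, 1, 1, 4, 8])) for _ in range(nchar)]
        elif style == 1:
            w = [0.0 if rng.random() < frac else 1.0 for _ in range(nchar)]
        else:
            w = [5.0 if rng.random() < frac else 1.0 for _ in range(nchar)]
        pscore = lambda a: scorer(a, w)  # noqa: E731
        _spr_climb(adj, pscore(adj), pscore, rng, max_rounds=6)
        cur = _spr_climb(adj, scorer(adj), scorer, rng, config.climb_rounds)
        if not consider(adj, cur) and (cur > best + 1e-9 or rng.random() < 0.5):
            adj = {kk: set(vv) for kk, vv in rng.choice(best_adjs).items()}

    # closure sweep: collect every distinct tree tied at the best score
    # that is one SPR move from a held tree (repeated to closure, up to
    # hold), so tie reporting does not depend on the search trajectory
    seen = {Tree(a, matrix.ntax).bipartitions() for a in best_adjs}
    queue = list(best_adjs)
    while queue and len(best_adjs) < config.hold:
        adj = {kk: set(vv) for kk, vv in queue.pop(0).items()}
        for (u, v) in [(a, b) for a in adj for b in adj[a]]:
            if len(adj[v]) != 3:
                continue
            inside = _subtree_nodes(adj, u, v)
            for x in list(adj):
                if x in inside or x == v:
                    continue
                for y in list(adj[x]):
                    if y in inside or y == v or not x < y:
                        continue
                    if x in adj[v] and y in adj[v]:
                        continue
                    mv = _prune_regraft(adj, u, v, x, y)
                    if abs(scorer(adj) - best) <= 1e-9:
                        t_new = Tree({kk: set(vv) for kk, vv in adj.items()},
                                     matrix.ntax)
                        sig = t_new.bipartitions()
                        if sig not in seen and len(best_adjs) < config.hold:
                            seen.add(sig)
                            best_adjs.append(t_new.adj)
                            queue.append(t_new.adj)
                    _undo_spr(adj, mv)

    trees = [Tree(a, matrix.ntax) for a in best_adjs]
    return SearchResult(trees=trees, best_score=best, config=config,
                        n_improvements=n_improve)


def _all_unrooted(n: int) -> Iterable[Tree]:
    """Enumerate all (2n-5)!! unrooted binary topologies; n <= 9 is sane."""
    base = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    partial = [(base, n + 1)]
    for leaf in range(3, n):
        grown = []
        for adj, nxt in partial:
            edges = [(a, b) for a in adj for b in adj[a] if a < b]
            for (a, b) in edges:
                t2 = {kk: set(vv) for kk, vv in adj.items()}
                t2[a].discard(b)
                t2[b].discard(a)
                t2[nxt] = {a, b, leaf}
                t2[a].add(nxt)
                t2[b].add(nxt)
                t2[leaf] = {nxt}
                grown.append((t2, nxt + 1))
        partial = grown
    for adj, _ in partial:
        yield Tree(adj, n)


def exhaustive_search(matrix: CharacterMatrix, k: float = 3.0):
    """Optimal implied-weights score and all optimal trees by enumeration."""
    if matrix.ntax > 9:
        raise ValueError("exhaustive search limited to 9 taxa")
    engine = _PackedEngine(matrix)
    best = math.inf
    best_trees: list[Tree] = []
    for tree in _all_unrooted(matrix.ntax):
        sc = engine.fit(tree.adj, k)
        if sc < best - 1e-9:
            best = sc
            best_trees = [tree]
        elif abs(sc - best) <= 1e-9:
            best_trees.append(tree)
    return best, best_trees


# ==========================================================================
# consensus


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the bipartitions shared by all inputs."""
    if not trees:
        raise ValueError("no trees")
    n = trees[0].n_leaves
    if any(t.n_leaves != n for t in trees):
        raise ValueError("trees have different leaf sets")
    common = set(trees[0].bipartitions())
    for t in trees[1:]:
        common &= t.bipartitions()
    # build from nested clades (all masks exclude leaf 0 by canonicalization)
    nxt = n
    root = nxt
    nxt += 1
    adj: dict[int, set[int]] = {root: set()}
    node_of = {}  # mask -> internal node
    full = (1 << n) - 1
    for mask in sorted(common, key=lambda m: bin(m).count("1")):
        node_of[mask] = nxt
        adj[nxt] = set()
        nxt += 1
    parent_mask: dict[int, int | None] = {}
    ordered = sorted(common, key=lambda m: bin(m).count("1"))
    for mask in ordered:
        par = None
        for cand in ordered:
            if cand != mask and (mask & cand) == mask:
                if par is None or bin(cand).count("1") < bin(par).count("1"):
                    par = cand
        parent_mask[mask] = par
    for mask in ordered:
        node = node_of[mask]
        up = root if parent_mask[mask] is None else node_of[parent_mask[mask]]
        adj[node].add(up)
        adj[up].add(node)
    for leaf in range(n):
        bit = 1 << leaf
        host = None
        for mask in sorted(common, key=lambda m: bin(m).count("1")):
            if mask & bit:
                host = node_of[mask]
                break
        up = root if host is None else host
        adj[leaf] = {up}
        adj[up].add(leaf)
    # suppress a degree-2 root if present
    if len(adj[root]) == 2:
        a, b = adj[root]
        adj[a].discard(root)
        adj[b].discard(root)
        adj[a].add(b)
        adj[b].add(a)
        del adj[root]
    return Tree(adj, n)


# ==========================================================================
# combined categorical + color matrices


def build_combined_matrix(
    categorical: CharacterMatrix,
    rgb_table,
    replaced_characters: Sequence[int],
    equivalent_points: Sequence[int],
) -> CharacterMatrix:
    """Replace coded color characters with continuous RGB characters.

    Drops the categorical columns in ``replaced_characters`` and appends
    three continuous additive columns (R, G, B) for every sample point in
    ``rgb_table`` (a DataFrame indexed by specimen with ``pNN_R/G/B``
    columns).  ``equivalent_points`` lists the points that stand in for
    the dropped characters and must all be present in the table.
    """
    import re as _re

    if rgb_table is None or len(rgb_table.columns) == 0:
        raise ValueError("empty RGB table")
    points = sorted(
        {int(_re.match(r"p(\d+)_", c).group(1)) for c in rgb_table.columns}
    )
    missing_pts = set(equivalent_points) - set(points)
    if missing_pts:
        raise ValueError(f"equivalent points absent from table: {sorted(missing_pts)}")
    keep = [j for j in range(categorical.nchar) if j not in set(replaced_characters)]
    chars = [categorical.characters[j] for j in keep]
    for pt in points:
        for band in "RGB":
            col = f"p{pt}_{band}"
            states = []
            for t in categorical.taxa:
                if t in rgb_table.index:
                    v = rgb_table.loc[t, col]
                    states.append(None if v is None or math.isnan(v) else float(v))
                else:
                    states.append(None)
            chars.append(Character(states=states, additive=True, continuous=True))
    return CharacterMatrix(
        taxa=list(categorical.taxa), characters=chars, outgroup=categorical.outgroup
    )
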