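"""Edit distance between merge trees.

The distance between two rooted, unordered, edge-weighted trees is the
minimal total cost of an edit path built from five operations: *shrink*
(change an edge weight; cost = absolute weight difference), *delete* /
*insert* an edge (cost = its weight) and *ghost* / *split* an order-2
vertex (cost 0).  Order-2 vertices are therefore irrelevant, and the
infimum over edit paths is realized by combinatorial *mappings*:

* a mapping is a one-to-one set of vertex pairs containing the two roots,
  preserving the ancestor relation in both directions;
* vertices outside the *kept subtree* (the union of paths from matched
  vertices to the root) are deleted/inserted at the cost of their edge;
* unmatched vertices inside the kept subtree must have exactly one kept
  child: they are ghosted for free and their edges aggregate onto the
  nearest matched descendant's chain;
* each matched pair pays the shrink cost between its ghost-aggregated
  chain weights, ``|W(a) - W'(b)|`` with ``W(a) = h(nma(a)) - h(a)``.

Three routes compute the same value: :func:`edit_distance_oracle`
exhaustively enumerates every valid mapping (definitional semantics,
small trees); the default ``dp`` solver is an exact dynamic program that
decomposes the mapping class by child subtrees; the ``milp`` solver casts
the same minimization as a 0/1 integer program (HiGHS via scipy).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import LinearConstraint, linear_sum_assignment, milp
from scipy.sparse import csr_matrix

from .errors import CapacityError, MappingError
from .mergetree import MergeTree

__all__ = [
    "Mapping",
    "total_weight",
    "mapping_cost",
    "edit_distance_oracle",
    "edit_distance",
    "canonical_form",
]


def total_weight(tree: MergeTree) -> float:
    """Sum of all edge weights of a merge tree."""
    return tree.total_weight()


def canonical_form(tree: MergeTree) -> str:
    """Sibling-permutation-invariant encoding after ghosting order-2 vertices."""
    return tree.canonical_form()


@dataclass(frozen=True)
class Mapping:
    """A cost-bearing correspondence between vertices of two merge trees."""

    pairs: frozenset[tuple[int, int]]

    def image(self) -> dict[int, int]:
        return dict(self.pairs)


# ---------------------------------------------------------------------------
# shared per-tree structure


class _Info:
    def __init__(self, t: MergeTree):
        self.tree = t
        self.n = t.n_vertices
        self.root = t.root
        self.children = t.children()
        self.w = t.weights()
        self.height = t.height
        self.parent = t.parent
        # postorder: children strictly before parents
        post: list[int] = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                post.append(v)
            else:
                stack.append((v, True))
                stack.extend((c, False) for c in self.children[v])
        self.post = post
        self.subw = np.zeros(self.n)
        self.desc: list[list[int]] = [[] for _ in range(self.n)]
        for v in post:
            d = [v]
            for c in self.children[v]:
                d.extend(self.desc[c])
                self.subw[v] += self.w[c] + self.subw[c]
            self.desc[v] = d
        self.total = float(self.w.sum())

    def ancestors(self, v: int) -> list[int]:
        """Proper ancestors, nearest first."""
        out = []
        p = self.parent[v]
        while p >= 0:
            out.append(int(p))
            p = self.parent[p]
        return out

    def is_ancestor(self, a: int, v: int) -> bool:
        p = self.parent[v]
        while p >= 0:
            if p == a:
                return True
            p = self.parent[p]
        return False


# ---------------------------------------------------------------------------
# mapping validation and cost (definitional semantics)


def _validate_side(info: _Info, matched: set[int]) -> None:
    if info.root not in matched:
        raise MappingError("roots must be matched to roots")
    # every unmatched vertex may have at most one child branch holding
    # matched vertices, so the kept subtree ghost-reduces onto the mapping
    has_matched = np.zeros(info.n, dtype=bool)
    for v in info.post:
        has_matched[v] = v in matched or any(has_matched[c] for c in info.children[v])
    for v in range(info.n):
        if v in matched:
            continue
        kept_branches = sum(bool(has_matched[c]) for c in info.children[v])
        if kept_branches >= 2:
            raise MappingError(
                f"unmatched vertex {v} branches into {kept_branches} kept subtrees; "
                "branching vertices of the kept subtree must be matched"
            )


def _aggregated_weights(info: _Info, matched: set[int]) -> dict[int, float]:
    """Ghost-aggregated chain weight of every matched non-root vertex."""
    agg = {}
    for a in matched:
        if a == info.root:
            continue
        p = info.parent[a]
        while p >= 0 and p not in matched:
            p = info.parent[p]
        if p < 0:
            raise MappingError(f"matched vertex {a} has no matched strict ancestor")
        agg[a] = float(info.height[p] - info.height[a])
    return agg


def mapping_cost(t1: MergeTree, t2: MergeTree, mapping: Mapping) -> float:
    """Cost of a valid mapping: deletions + insertions + chain shrinks.

    Raises :class:`MappingError` naming the violated constraint if the
    mapping is not one-to-one, does not pair the roots, breaks ancestry
    preservation, or leaves a branching kept-subtree vertex unmatched.
    """
    i1, i2 = _Info(t1), _Info(t2)
    pairs = sorted(mapping.pairs)
    a_side = [p[0] for p in pairs]
    b_side = [p[1] for p in pairs]
    if len(set(a_side)) != len(pairs) or len(set(b_side)) != len(pairs):
        raise MappingError("mapping is not one-to-one")
    for v, side, n in ((a_side, "first", i1.n), (b_side, "second", i2.n)):
        if any(x < 0 or x >= n for x in v):
            raise MappingError(f"mapping references an unknown vertex of the {side} tree")
    if (i1.root, i2.root) not in mapping.pairs:
        raise MappingError("roots must be matched to roots")
    for (a1, b1) in pairs:
        for (a2, b2) in pairs:
            if i1.is_ancestor(a1, a2) != i2.is_ancestor(b1, b2):
                raise MappingError(
                    f"ancestry not preserved between pairs ({a1},{b1}) and ({a2},{b2})"
                )
    m1, m2 = set(a_side), set(b_side)
    _validate_side(i1, m1)
    _validate_side(i2, m2)
    agg1 = _aggregated_weights(i1, m1)
    agg2 = _aggregated_weights(i2, m2)
    shrink = sum(
        abs(agg1[a] - agg2[b]) for a, b in pairs if a != i1.root
    )
    deleted = i1.total - sum(agg1.values())
    inserted = i2.total - sum(agg2.values())
    return float(deleted + inserted + shrink)


# ---------------------------------------------------------------------------
# exhaustive oracle


def _valid_subsets(info: _Info):
    """All matched-vertex candidate sets: contain the root, chain-valid."""
    others = [v for v in range(info.n) if v != info.root]
    for mask in range(1 << len(others)):
        s = {info.root}
        s.update(others[i] for i in range(len(others)) if mask >> i & 1)
        has_matched = np.zeros(info.n, dtype=bool)
        ok = True
        for v in info.post:
            has_matched[v] = v in s or any(has_matched[c] for c in info.children[v])
            if v not in s and sum(bool(has_matched[c]) for c in info.children[v]) >= 2:
                ok = False
                break
        if ok:
            yield s


def _skeleton(info: _Info, s: set[int]):
    """Reduced kept tree: matched vertices with nearest-matched-ancestor edges."""
    skel_children: dict[int, list[int]] = {a: [] for a in s}
    agg = _aggregated_weights(info, s)
    for a in s:
        if a == info.root:
            continue
        p = info.parent[a]
        while p not in s:
            p = info.parent[p]
        skel_children[int(p)].append(a)
    deleted = info.total - sum(agg.values())
    return skel_children, agg, deleted


def _best_iso(sk1, agg1, r1, sk2, agg2, r2):
    """Cheapest rooted-tree isomorphism between two skeletons, or None."""

    def go(a, b):
        ca, cb = sk1[a], sk2[b]
        if len(ca) != len(cb):
            return None
        best = None
        for perm in permutations(cb):
            tot, pairs, ok = 0.0, [], True
            for c, d in zip(ca, perm):
                sub = go(c, d)
                if sub is None:
                    ok = False
                    break
                tot += abs(agg1[c] - agg2[d]) + sub[0]
                pairs.extend(sub[1] + [(c, d)])
            if ok and (best is None or tot < best[0]):
                best = (tot, pairs)
        return best

    top = go(r1, r2)
    if top is None:
        return None
    return top[0], top[1] + [(r1, r2)]


def edit_distance_oracle(
    t1: MergeTree, t2: MergeTree, max_vertices: int = 9
) -> tuple[float, Mapping]:
    """Exact minimum of :func:`mapping_cost` by exhaustive enumeration.

    Enumerates every chain-valid matched set on both sides and every
    skeleton isomorphism between them.  Only feasible for small trees;
    beyond ``max_vertices`` per tree a :class:`CapacityError` directs the
    caller to :func:`edit_distance`.
    """
    if t1.n_vertices > max_vertices or t2.n_vertices > max_vertices:
        raise CapacityError(
            f"oracle enumeration is bounded at {max_vertices} vertices per tree; "
            "use edit_distance() for larger instances"
        )
    i1, i2 = _Info(t1), _Info(t2)
    best: tuple[float, list] | None = None
    skels2 = []
    for s2 in _valid_subsets(i2):
        skels2.append((len(s2),) + _skeleton(i2, s2))
    for s1 in _valid_subsets(i1):
        sk1, agg1, del1 = _skeleton(i1, s1)
        for n2, sk2, agg2, del2 in skels2:
            if n2 != len(s1):
                continue
            iso = _best_iso(sk1, agg1, i1.root, sk2, agg2, i2.root)
            if iso is None:
                continue
            cost = del1 + del2 + iso[0]
            if best is None or cost < best[0]:
                best = (cost, iso[1])
    assert best is not None  # the roots-only mapping is always valid
    return best[0], Mapping(frozenset(best[1]))


# ---------------------------------------------------------------------------
# exact dynamic program (default solver)


def _edit_distance_dp(t1: MergeTree, t2: MergeTree) -> float:
    i1, i2 = _Info(t1), _Info(t2)
    n, m = i1.n, i2.n
    BIG = 4.0 * (i1.total + i2.total + 1.0)

    # per child-context arrays: descendants, chain weight to the father,
    # off-chain deleted weight when that descendant is the kept vertex
    def context(info: _Info):
        desc_idx, pvec, dvec, totw = [], [], [], np.zeros(info.n)
        for c in range(info.n):
            if info.parent[c] < 0:
                desc_idx.append(None), pvec.append(None), dvec.append(None)
                continue
            idx = np.array(info.desc[c], dtype=np.int64)
            h_par = info.height[info.parent[c]]
            p = h_par - info.height[idx]
            tw = info.w[c] + info.subw[c]
            totw[c] = tw
            desc_idx.append(idx)
            pvec.append(p)
            dvec.append(tw - p - info.subw[idx])
        return desc_idx, pvec, dvec, totw

    d1, p1, o1, tw1 = context(i1)
    d2, p2, o2, tw2 = context(i2)

    F = np.zeros((n, m))
    for a in i1.post:
        ca = i1.children[a]
        for b in i2.post:
            cb = i2.children[b]
            if not ca or not cb:
                F[a, b] = i1.subw[a] + i2.subw[b]  # one side empty below
                continue
            nc, nd = len(ca), len(cb)
            M = np.full((nc + nd, nc + nd), BIG)
            M[nc:, nd:] = 0.0
            for i, c in enumerate(ca):
                M[i, nd + i] = tw1[c]
            for j, d in enumerate(cb):
                M[nc + j, j] = tw2[d]
            for i, c in enumerate(ca):
                for j, d in enumerate(cb):
                    blk = (
                        o1[c][:, None]
                        + o2[d][None, :]
                        + np.abs(p1[c][:, None] - p2[d][None, :])
                        + F[np.ix_(d1[c], d2[d])]
                    )
                    M[i, j] = blk.min()
            rows, cols = linear_sum_assignment(M)
            F[a, b] = M[rows, cols].sum()
    return float(F[i1.root, i2.root])


# ---------------------------------------------------------------------------
# MILP formulation


def _edit_distance_milp(t1: MergeTree, t2: MergeTree) -> float:
    i1, i2 = _Info(t1), _Info(t2)
    # decision variable per (vertex, claimed nearest-matched-ancestor) pair
    # on both sides; roots pair only with roots
    cand1 = [(a, al) for a in range(i1.n) if a != i1.root for al in i1.ancestors(a)]
    cand2 = [(b, be) for b in range(i2.n) if b != i2.root for be in i2.ancestors(b)]
    variables = []
    coef = []
    for a, al in cand1:
        pa = i1.height[al] - i1.height[a]
        for b, be in cand2:
            if (al == i1.root) != (be == i2.root):
                continue
            pb = i2.height[be] - i2.height[b]
            variables.append((a, al, b, be))
            coef.append(abs(pa - pb) - pa - pb)
    const = i1.total + i2.total
    if not variables:
        return float(const)
    nv = len(variables)
    rows, cols, vals, lo, hi = [], [], [], [], []
    r = 0

    def add_row(idx, coeffs, lb, ub):
        nonlocal r
        rows.extend([r] * len(idx))
        cols.extend(idx)
        vals.extend(coeffs)
        lo.append(lb)
        hi.append(ub)
        r += 1

    # at most one chain may run through or out of any vertex
    for info, side in ((i1, 0), (i2, 2)):
        in_subtree = [set(info.desc[u]) for u in range(info.n)]
        strictly_above = [set(info.ancestors(u)) for u in range(info.n)]
        for u in range(info.n):
            if u == info.root:
                continue
            idx = [
                k
                for k, v in enumerate(variables)
                if v[side] in in_subtree[u] and v[side + 1] in strictly_above[u]
            ]
            if idx:
                add_row(idx, [1.0] * len(idx), -np.inf, 1.0)
    # consistency: a claimed non-root ancestor pair must itself be matched
    support: dict[tuple[int, int], list[int]] = {}
    for k, (a, _, b, _) in enumerate(variables):
        support.setdefault((a, b), []).append(k)
    for k, (a, al, b, be) in enumerate(variables):
        if al == i1.root:
            continue
        sup = support.get((al, be), [])
        add_row([k] + sup, [1.0] + [-1.0] * len(sup), -np.inf, 0.0)

    A = csr_matrix((vals, (rows, cols)), shape=(r, nv))
    res = milp(
        c=np.array(coef),
        constraints=LinearConstraint(A, lo, hi),
        integrality=np.ones(nv),
        bounds=(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    return float(const + res.fun)


def edit_distance(t1: MergeTree, t2: MergeTree, solver: str = "dp") -> float:
    """Edit distance between two merge trees (exact).

    ``dp`` (default) runs the exact dynamic program; ``milp`` solves the
    equivalent 0/1 integer program; ``oracle`` exhausts all mappings
    (small trees only).  All routes agree to numerical tolerance.
    """
    if solver == "dp":
        return _edit_distance_dp(t1, t2)
    if solver == "milp":
        return _edit_distance_milp(t1, t2)
    if solver == "oracle":
        return edit_distance_oracle(t1, t2)[0]
    raise ValueError(f"unknown solver {solver!r}; choose 'dp', 'milp' or 'oracle'")
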