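"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the code path it checks: union-find instead
of graph components, recursive Newick splitting instead of dendropy, an
explicit Gotoh DP instead of the Biopython aligner, and exhaustive pair
enumeration instead of overlap-count arithmetic.
"""

from __future__ import annotations

from itertools import combinations


# ---------------------------------------------------------------- union-find
def union_find_components(edges, universe):
    parent = {x: x for x in universe}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        a, b = tuple(e)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for x in universe:
        groups.setdefault(find(x), set()).add(x)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------- local alignment (Gotoh)
def gotoh_local_score(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Best local alignment score; first gap position costs gap_open, each
    further position gap_extend (Biopython open/extend convention)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    # M: ends in match/mismatch; X: gap in b (consume a); Y: gap in a
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + sub,
                X[i - 1][j - 1] + sub,
                Y[i - 1][j - 1] + sub,
            )
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


# -------------------------------------------------------------- newick splits
def brute_force_splits(newick: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions of a Newick tree by recursive descent,
    encoded as the side not containing the smallest leaf."""
    text = newick.strip().rstrip(";")

    def parse(s: str):
        # returns (leafset, list of child leafsets at every internal node)
        if not s.startswith("("):
            label = s.split(":")[0].strip()
            return frozenset([label]), []
        # strip branch length / label after the closing paren
        depth = 0
        end = -1
        for i, ch in enumerate(s):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0:
                    end = i
                    break
        inner = s[1:end]
        parts = []
        depth = 0
        start = 0
        for i, ch in enumerate(inner):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif ch == "," and depth == 0:
                parts.append(inner[start:i])
                start = i + 1
        parts.append(inner[start:])
        leaves = frozenset()
        clades = []
        for p in parts:
            sub_leaves, sub_clades = parse(p)
            leaves |= sub_leaves
            clades.append(sub_leaves)
            clades.extend(sub_clades)
        return leaves, clades

    all_leaves, clades = parse(text)
    anchor = min(all_leaves)
    n = len(all_leaves)
    out = set()
    for clade in clades:
        side = clade if anchor not in clade else frozenset(all_leaves - clade)
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def brute_force_rf(nw1: str, nw2: str) -> tuple[int, int]:
    s1, s2 = brute_force_splits(nw1), brute_force_splits(nw2)
    return len(s1 ^ s2), len(s1) + len(s2)


# ------------------------------------------------- pairwise co-clustering diff
def brute_force_pair_disagreement(groups_a, groups_b) -> int:
    """Gene pairs co-clustered in exactly one of two partitions, by
    enumerating every unordered pair."""
    of_a = {x: i for i, g in enumerate(groups_a) for x in g}
    of_b = {x: i for i, g in enumerate(groups_b) for x in g}
    ids = sorted(of_a)
    count = 0
    for x, y in combinations(ids, 2):
        same_a = of_a[x] == of_a[y]
        same_b = of_b[x] == of_b[y]
        if same_a != same_b:
            count += 1
    return count


# ------------------------------------------------------ band classification
def integer_band_oracle(k: int, n: int, bounds=(99, 95, 15, 0), names=None) -> str:
    """Band selection with pure integer arithmetic: 100*k >= bound*n."""
    if names is None:
        names = ["First_core_99", "First_core_95", "First_core_15", "First_core_0"]
    for name, bound in zip(names, bounds):
        if 100 * k >= bound * n:
            return name
    raise AssertionError("unreachable: last bound is 0")
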