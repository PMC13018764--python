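"""Brute-force reference implementations, deliberately independent of the
package internals: they consume only the raw parent relation and IC table."""

from __future__ import annotations


def brute_closure(parents: dict[str, set[str]]) -> dict[str, set[str]]:
    """Transitive closure of the parent relation by per-node DFS."""
    out = {}
    for node in parents:
        seen: set[str] = set()
        stack = list(parents[node])
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            stack.extend(parents[p])
        out[node] = seen
    return out


def brute_min_path(parents: dict[str, set[str]], anc: str, desc: str) -> int | None:
    """Minimal number of parent edges from desc up to anc, or None."""
    if anc == desc:
        return 0
    best = None
    frontier = {desc}
    dist = 0
    visited: set[str] = set()
    while frontier:
        dist += 1
        nxt = set()
        for node in frontier:
            for p in parents[node]:
                if p == anc:
                    return dist
                if p not in visited:
                    visited.add(p)
                    nxt.add(p)
        frontier = nxt
    return best


def brute_lin(
    parents: dict[str, set[str]], ic: dict[str, float], a: str, b: str
) -> float:
    if a == b:
        return 1.0
    closure = brute_closure(parents)
    common = (closure[a] | {a}) & (closure[b] | {b})
    best = max(ic[t] for t in common)
    denom = ic[a] + ic[b]
    if denom == 0:
        return 0.0
    return min(1.0, 2.0 * best / denom)


def brute_set_similarity(
    parents: dict[str, set[str]], ic: dict[str, float], A: set[str], B: set[str]
) -> float:
    """Symmetric best-match average over exhaustive pair enumeration."""
    ab = sum(max(brute_lin(parents, ic, x, y) for y in B) for x in A) / len(A)
    ba = sum(max(brute_lin(parents, ic, x, y) for x in A) for y in B) / len(B)
    return (ab + ba) / 2.0
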