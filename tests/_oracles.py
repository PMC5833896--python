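"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own algorithms: the signature
reference builds the full depth-limited walk tree and canonicalizes by
exhaustively permuting child orderings; the p-value reference counts ranks
with a bare loop.
"""

from itertools import permutations

PREFIX = {1: "", 2: "=", 3: "#"}


def brute_force_signature(graph, root: int, height: int) -> str:
    """Reference atom signature via explicit tree expansion + permutation."""
    adj = [[] for _ in graph.atoms]
    for b in graph.bonds:
        adj[b.a].append((b.b, b.order))
        adj[b.b].append((b.a, b.order))
    elements = [a.element for a in graph.atoms]

    def expand(node, parent, depth):
        children = []
        if depth > 0:
            for nbr, order in adj[node]:
                if nbr != parent:
                    children.append((order, expand(nbr, node, depth - 1)))
        return (elements[node], children)

    def render(tree):
        el, children = tree
        if not children:
            return f"[{el}]"
        rendered = [PREFIX[order] + render(child) for order, child in children]
        best = min(permutations(rendered))  # exhaustive child-order search
        return f"[{el}]({''.join(best)})"

    return render(expand(root, None, height))


def brute_force_p_value(alpha_new: float, alphas: list) -> float:
    """Reference conformal p-value: insert-and-rank with a plain loop."""
    n_ge = 0
    for a in alphas:
        if a >= alpha_new:
            n_ge += 1
    return (n_ge + 1) / (len(alphas) + 1)
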