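"""Independent reference implementations used only as test oracles.

Each oracle is deliberately written in a different style from the package
code path it checks: the DTL oracle enumerates event histories recursively
with explicit path-loss bookkeeping (no in/out decomposition), the MCL
oracle is plain-Python matrix arithmetic, and the medoid oracle is an
exhaustive candidate scan.
"""

from __future__ import annotations

import dendropy

INF = float("inf")


# ---------------------------------------------------------------------------
# undated DTL minimum cost by direct enumeration

class OracleDTL:
    def __init__(self, species_tree: dendropy.Tree, dup: float, transfer: float,
                 loss: float, completeness: dict[str, float] | None = None):
        self.dup = dup
        self.transfer = transfer
        self.loss = loss
        comp = completeness or {}
        self.nodes = list(species_tree.preorder_node_iter())
        self.parent = {id(n): n.parent_node for n in self.nodes}
        self.children = {id(n): n.child_nodes() for n in self.nodes}
        self.leaf_of = {}
        for n in self.nodes:
            if n.is_leaf():
                self.leaf_of[n.taxon.label] = n
        self.desc = {}
        for n in species_tree.postorder_node_iter():
            s = {id(n)}
            for c in n.child_nodes():
                s |= self.desc[id(c)]
            self.desc[id(n)] = s
        self.loss_w = {id(n): loss * comp.get(n.taxon.label, 1.0)
                       if n.is_leaf() else loss for n in self.nodes}
        self._memo: dict = {}

    def _incomparable(self, x):
        out = []
        for y in self.nodes:
            if y is x:
                continue
            if id(y) in self.desc[id(x)] or id(x) in self.desc[id(y)]:
                continue
            out.append(y)
        return out

    def _loss_path(self, top, bottom):
        """Loss cost of sliding a copy from branch `top` down to branch
        `bottom`: each species node crossed loses the sibling lineage."""
        total = 0.0
        n = bottom
        while n is not top:
            p = self.parent[id(n)]
            for sib in self.children[id(p)]:
                if sib is not n:
                    total += self.loss_w[id(sib)]
            n = p
        return total

    def best_on(self, gnode, branch):
        """Min cost given one copy of `gnode`'s lineage on `branch`."""
        key = (id(gnode), id(branch))
        if key in self._memo:
            return self._memo[key]
        best = INF
        for target in self.nodes:
            if id(target) not in self.desc[id(branch)]:
                continue
            v = self._loss_path(branch, target) + self._event_at(gnode, target)
            if v < best:
                best = v
        self._memo[key] = best
        return best

    def _event_at(self, gnode, branch):
        kids = gnode.child_nodes()
        if not kids:
            genome = gnode.taxon.label.split("|", 1)[0]
            return 0.0 if self.leaf_of.get(genome) is branch else INF
        a, b = kids
        best = INF
        sp_kids = self.children[id(branch)]
        if sp_kids:
            l, r = sp_kids
            for ca, cb in ((a, b), (b, a)):
                v = self.best_on(ca, l) + self.best_on(cb, r)
                best = min(best, v)
        best = min(best, self.dup + self.best_on(a, branch)
                   + self.best_on(b, branch))
        for kept, moved in ((a, b), (b, a)):
            landings = [self.best_on(moved, z)
                        for z in self._incomparable(branch)]
            if landings:
                best = min(best, self.transfer + self.best_on(kept, branch)
                           + min(landings))
        return best

    def min_cost(self, gene_tree: dendropy.Tree) -> float:
        self._memo.clear()
        return min(self.best_on(gene_tree.seed_node, br) for br in self.nodes)


def oracle_min_cost(species_tree, gene_tree, dup, transfer, loss,
                    completeness=None) -> float:
    return OracleDTL(species_tree, dup, transfer, loss,
                     completeness).min_cost(gene_tree)


# ---------------------------------------------------------------------------
# reference Markov clustering (plain Python)

def reference_mcl_clusters(adjacency: list[list[float]], inflation: float,
                           n_iter: int = 200) -> list[set[int]]:
    n = len(adjacency)
    M = [[adjacency[i][j] for j in range(n)] for i in range(n)]

    def normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            for i in range(n):
                mat[i][j] = mat[i][j] / s
        return mat

    M = normalize(M)
    for _ in range(n_iter):
        sq = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        infl = [[sq[i][j] ** inflation if sq[i][j] > 1e-12 else 0.0
                 for j in range(n)] for i in range(n)]
        infl = normalize(infl)
        delta = max(abs(infl[i][j] - M[i][j])
                    for i in range(n) for j in range(n))
        M = infl
        if delta < 1e-8:
            break

    # union nodes connected through surviving transition mass
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if M[i][j] > 1e-6:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=min)


# ---------------------------------------------------------------------------
# exhaustive medoid

def brute_force_medoid(alignment: dict[str, str]) -> str:
    from Bio.Align import substitution_matrices
    mat = substitution_matrices.load("BLOSUM62")

    def dist(a, b):
        sab = saa = sbb = 0.0
        cols = 0
        for x, y in zip(a, b):
            if "-" in (x, y):
                continue
            cols += 1
            sab += mat[x, y]
            saa += mat[x, x]
            sbb += mat[y, y]
        if cols == 0:
            return 1.0
        return 1.0 - sab / max(saa, sbb)

    best_id, best_sum = None, None
    for cand in sorted(alignment):
        total = sum(dist(alignment[cand], alignment[other])
                    for other in alignment if other != cand)
        if best_sum is None or total < best_sum - 1e-12:
            best_id, best_sum = cand, total
    return best_id
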