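"""Independent oracles used by the test suite.

These deliberately share no code with the library's dynamic programming:
the alignment oracle enumerates every legal state path of the local model
explicitly, so Viterbi must equal the maximum and forward the log-sum over
the enumerated path scores.
"""

from __future__ import annotations

import math

import numpy as np

_T = {"MM": 0, "MI": 1, "MD": 2, "IM": 3, "II": 4, "DM": 5, "DD": 6}


def all_paths(m: int, max_consume: int):
    """Every complete local path through an M-node model.

    A path enters at any match node, moves through M/I/D states, and exits
    after a match state.  Returned as (emits, moves): ``emits`` is the
    ordered list of emitting states ``(state, node)``, ``moves`` the list
    of transitions ``(move, from_node)``.
    """
    out = []

    def rec(k, state, emits, moves):
        if state == "M":
            out.append((list(emits), list(moves)))
        if state == "M" and k < m:
            if len(emits) < max_consume:
                rec(k + 1, "M", emits + [("M", k + 1)], moves + [("MM", k)])
                rec(k, "I", emits + [("I", k)], moves + [("MI", k)])
            rec(k + 1, "D", emits, moves + [("MD", k)])
        elif state == "I":
            if len(emits) < max_consume:
                if k < m:
                    rec(k + 1, "M", emits + [("M", k + 1)], moves + [("IM", k)])
                rec(k, "I", emits + [("I", k)], moves + [("II", k)])
        elif state == "D" and k < m:
            if len(emits) < max_consume:
                rec(k + 1, "M", emits + [("M", k + 1)], moves + [("DM", k)])
            rec(k + 1, "D", emits, moves + [("DD", k)])

    for k0 in range(1, m + 1):
        rec(k0, "M", [("M", k0)], [])
    return out


def enumerate_alignment_scores(model, x: np.ndarray) -> list[float]:
    """Log-odds score (nats) of every (path, placement) on sequence x."""
    m = model.length
    with np.errstate(divide="ignore"):
        lme = np.log(model.match_emissions)
        lie = np.log(model.insert_emissions)
        ltr = np.log(model.transitions)
        lbg = np.log(model.background)
    entry = -math.log(m)
    scores = []
    for emits, moves in all_paths(m, len(x)):
        t = entry
        for move, node in moves:
            t += ltr[node - 1, _T[move]]
        c = len(emits)
        for i in range(len(x) - c + 1):
            s = t
            for j, (state, node) in enumerate(emits):
                a = x[i + j]
                if a >= 20:  # neutral symbol: log-odds 0
                    continue
                e = lme[node - 1, a] if state == "M" else lie[node - 1, a]
                s += e - lbg[a]
            scores.append(s)
    return scores


def oracle_viterbi_bits(model, x: np.ndarray) -> float:
    scores = enumerate_alignment_scores(model, x)
    best = max(scores) if scores else float("-inf")
    return best / math.log(2.0)


def oracle_forward_bits(model, x: np.ndarray) -> float:
    scores = [s for s in enumerate_alignment_scores(model, x) if s > -1e29]
    if not scores:
        return float("-inf")
    arr = np.array(scores)
    mx = arr.max()
    return (mx + math.log(np.exp(arr - mx).sum())) / math.log(2.0)


def recount_network(architectures):
    """Brute-force recount of co-occurrence edge weights over proteins."""
    edges: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for arch in architectures:
        fams = [d.family for d in arch.domains]
        for f in fams:
            totals[f] = totals.get(f, 0) + 1
        distinct = sorted(set(fams))
        for i, a in enumerate(distinct):
            for b in distinct[i + 1 :]:
                edges[(a, b)] = edges.get((a, b), 0) + 1
        for f in distinct:
            if fams.count(f) >= 2:
                edges[(f, f)] = edges.get((f, f), 0) + 1
    return edges, totals


def random_model(rng: np.random.Generator, m: int | None = None):
    """A random valid profile HMM (Dirichlet emissions/transitions)."""
    from glycoscan import ProfileHMM

    if m is None:
        m = int(rng.integers(1, 4))
    me = rng.dirichlet(np.full(20, 0.5), size=m)
    ie = rng.dirichlet(np.full(20, 2.0), size=m)
    tr = np.empty((m, 7))
    tr[:, :3] = rng.dirichlet(np.full(3, 1.0), size=m)
    tr[:, 3:5] = rng.dirichlet(np.full(2, 1.0), size=m)
    tr[:, 5:] = rng.dirichlet(np.full(2, 1.0), size=m)
    model = ProfileHMM(
        accession=f"RM{m}",
        name=f"random{m}",
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
    )
    model.validate()
    return model
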