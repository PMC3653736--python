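"""Independent oracles shared by unit and acceptance tests."""

import itertools

import numpy as np

from rnrscape.profile_engine import ProfileModel


def oracle_best_local(S, seq_idx, gap_open, gap_extend):
    """Exhaustive local-alignment score: enumerate all monotone match pairings.

    A local alignment is a set of k >= 1 matched (residue, column) pairs with
    both coordinates strictly increasing; skipping d residues or columns
    between consecutive pairs costs open + (d - 1) * extend per dimension.
    Independent of the DP implementation; exact for tiny instances.
    """
    L, n = S.shape[0], len(seq_idx)

    def gap_cost(d):
        return 0.0 if d == 0 else gap_open + (d - 1) * gap_extend

    best = 0.0
    for k in range(1, min(L, n) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.combinations(range(L), k):
                s = sum(S[c, seq_idx[r]] for r, c in zip(rows, cols))
                for (r1, c1), (r2, c2) in zip(zip(rows, cols), zip(rows[1:], cols[1:])):
                    s -= gap_cost(r2 - r1 - 1) + gap_cost(c2 - c1 - 1)
                best = max(best, s)
    return best


def random_tiny_profile(rng, L):
    S = rng.normal(0, 2.5, size=(L, 20))
    return ProfileModel(family="nrdA", S=S, gap_open=3.0, gap_extend=0.5)
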