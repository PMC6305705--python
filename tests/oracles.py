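"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately slow and simple: a textbook affine-gap
semi-global DP for alignment scores, exhaustive nearest-reference scans,
and Monte Carlo rarefaction.  None of it shares code with the package's
own paths.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def semi_global_score(
    query: str,
    ref: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Unbanded three-state affine DP; reference end gaps are free.

    ``gap_open`` is the score of the first base of a gap and
    ``gap_extend`` of each subsequent base.  State M consumes both
    sequences, X consumes only the reference (deletion), Y only the
    query (insertion).  Leading and trailing deletion runs cost zero.
    """
    nq, nr = len(query), len(ref)
    M = np.full((nq + 1, nr + 1), NEG)
    X = np.full((nq + 1, nr + 1), NEG)  # gap in query row (consumes ref)
    Y = np.full((nq + 1, nr + 1), NEG)  # gap in ref row (consumes query)
    M[0][0] = 0.0
    for j in range(1, nr + 1):
        X[0][j] = 0.0  # free leading reference overhang
    for i in range(1, nq + 1):
        Y[i][0] = gap_open + (i - 1) * gap_extend
    for i in range(1, nq + 1):
        qi = query[i - 1]
        for j in range(1, nr + 1):
            s = match if (qi == ref[j - 1] and qi != "N") else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_extend,
                Y[i][j - 1] + gap_open,
            )
            Y[i][j] = max(
                M[i - 1][j] + gap_open,
                Y[i - 1][j] + gap_extend,
                X[i - 1][j] + gap_open,
            )
    # Trailing reference overhang is free: end at any reference column,
    # having consumed the whole query outside a deletion state.
    return float(max(max(M[nq][j], Y[nq][j]) for j in range(nr + 1)))


def exhaustive_nearest(query: str, db, aligner=None) -> tuple[tuple[str, ...], float]:
    """Align against every reference; return the co-optimal id set."""
    from darkmeter.placement import align_semi_global

    best_ids: list[str] = []
    best_ident = -1.0
    for ref_id in sorted(db.tips):
        aln = align_semi_global(query, db.tips[ref_id].sequence, aligner)
        ident = aln.identity
        if ident > best_ident + 1e-12:
            best_ids, best_ident = [ref_id], ident
        elif abs(ident - best_ident) <= 1e-12:
            best_ids.append(ref_id)
    return tuple(sorted(best_ids)), best_ident


def mc_rarefaction(
    counts, depths, reps: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo subsampling rarefaction: mean and standard error."""
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=np.int64)
    means, ses = [], []
    for n in depths:
        draws = rng.multivariate_hypergeometric(counts, n, size=reps)
        richness = (draws > 0).sum(axis=1)
        means.append(richness.mean())
        ses.append(richness.std(ddof=1) / np.sqrt(reps))
    return np.asarray(means), np.asarray(ses)
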