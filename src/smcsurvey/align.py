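"""Toy Smith-Waterman local aligner for self-contained end-to-end runs.

Produces BLAST-tabular-like :class:`~smcsurvey.io.SimilarityHit` rows from a
pair of amino-acid sequences so the pipeline can be exercised without an
external search tool.  Scores use BLOSUM62 with affine gaps; the E-value is
the Karlin-Altschul approximation E = K*m*n*exp(-lambda*S) with fixed gapped
parameters (lambda = 0.267, K = 0.041), documented as an approximation —
this is a testing aid, not a database-search statistic.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from smcsurvey.io import SimilarityHit

LAMBDA = 0.267
K = 0.041
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def raw_score_to_bitscore(raw: float) -> float:
    return (LAMBDA * raw - np.log(K)) / np.log(2)


def toy_local_align(seq_a: str, seq_b: str, matrix=None,
                    gap_open: float = 11.0, gap_extend: float = 1.0
                    ) -> SimilarityHit | None:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns ``None`` when no positive-scoring local alignment exists.
    Affine gap cost: opening a gap costs ``gap_open``, each extension
    ``gap_extend`` (the first gapped residue costs gap_open + gap_extend).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    sub = _BLOSUM62 if matrix is None else matrix
    m, n = len(seq_a), len(seq_b)
    NEG = -1e9
    # H: best ending in match/mismatch; E: gap in seq_b (insertion in a);
    # F: gap in seq_a
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend,
                          E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend,
                          F[i - 1, j] - gap_extend)
            s = sub[seq_a[i - 1], seq_b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    raw = float(H.max())
    if raw <= 0.0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    end_i, end_j = i, j
    matches = 0
    ali_len = 0
    # traceback from the maximum cell
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            s = sub[seq_a[i - 1], seq_b[j - 1]]
            if H[i, j] == H[i - 1, j - 1] + s:
                matches += seq_a[i - 1] == seq_b[j - 1]
                ali_len += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ali_len += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
        else:
            ali_len += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = "H"
            i -= 1
    evalue = K * m * n * np.exp(-LAMBDA * raw)
    return SimilarityHit(
        query_id="query", subject_id="subject",
        pct_identity=100.0 * matches / ali_len if ali_len else 0.0,
        ali_len=ali_len, evalue=float(evalue),
        bitscore=float(raw_score_to_bitscore(raw)),
        q_start=i, q_end=end_i, s_start=j, s_end=end_j,
        q_len=m, s_len=n,
    )


def raw_sw_score(seq_a: str, seq_b: str, matrix=None,
                 gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Just the optimal local-alignment raw score."""
    hit = toy_local_align(seq_a, seq_b, matrix, gap_open, gap_extend)
    if hit is None:
        return 0.0
    return (hit.bitscore * np.log(2) + np.log(K)) / LAMBDA
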