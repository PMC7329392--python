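"""Independent reference implementations used only to cross-check the
package: a direct (seed, placement, position) enumeration of the repeat
scorer, a textbook Gotoh local-alignment DP, and a brute-force transitive
closure. All are plain Python, written against the definitions rather than
the optimized code paths."""

from __future__ import annotations

from Bio.Align import substitution_matrices

MIN_SCORABLE_LENGTH = 16
MIN_COHERENCE_COLS = 6


def _shift_match_vector(seq: str, d: int) -> list[bool]:
    """eq[i] = seq[i] == seq[i + d], X never matching."""
    L = len(seq)
    return [
        seq[i] == seq[i + d] and seq[i] != "X" for i in range(L - d)
    ]


def _coherent_vector(eq: list[bool], window: int, min_identity: float) -> list[bool]:
    Lc = len(eq)
    if Lc < MIN_COHERENCE_COLS:
        return [False] * Lc
    w = min(window, Lc)
    half = window // 2
    out = []
    for i in range(Lc):
        lo = max(0, min(i - half, Lc - w))
        cnt = sum(eq[lo : lo + w])
        window_ok = cnt >= min_identity * w - 1e-9
        neighbor = (i > 0 and eq[i - 1]) or (i + 1 < Lc and eq[i + 1])
        out.append(eq[i] and window_ok and neighbor)
    return out


def brute_force_repeat_votes(
    mature: str,
    seed_length: int = 40,
    coherence_window: int = 12,
    min_local_identity: float = 2 / 3,
) -> list[int]:
    """Direct enumeration of the vote definition: every seed window (stride
    1), every gapless placement with >= 1 residue of overlap except the
    self placement, one vote per coherent matched position."""
    L = len(mature)
    if L < MIN_SCORABLE_LENGTH:
        return [0] * L
    K = seed_length if L >= seed_length + 1 else max(8, L // 2)
    n_seeds = L - K + 1

    # precompute per-shift coherent-match vectors (plain python)
    valid_by_shift: dict[int, list[bool]] = {}
    for d in range(1, L):
        valid_by_shift[d] = _coherent_vector(
            _shift_match_vector(mature, d), coherence_window, min_local_identity
        )

    votes = [0] * L
    for s in range(n_seeds):  # seed source window [s, s + K)
        for p in range(-(K - 1), L):  # placement start, >= 1 overlap
            if p == s:
                continue
            d = abs(s - p)
            valid = valid_by_shift[d]
            for j in range(K):
                i = p + j  # original-sequence position under the placement
                if i < 0 or i >= L:
                    continue
                m = s + j  # the seed residue's source position
                lo = min(i, m)
                if lo < len(valid) and valid[lo]:
                    votes[i] += 1
    return votes


def gotoh_local_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Textbook affine-gap Smith-Waterman (Gotoh) best local score; a gap of
    length g costs gap_open + (g - 1) * gap_extend."""
    mat = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (deletion in b?)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = mat[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def transitive_closure_partition(ids, link_matrix) -> list[frozenset]:
    """Brute-force connected components by repeated matrix squaring of the
    reachability relation."""
    n = len(ids)
    reach = [[i == j or bool(link_matrix[i][j]) for j in range(n)] for i in range(n)]
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if not reach[i][j]:
                    if any(reach[i][k] and reach[k][j] for k in range(n)):
                        reach[i][j] = True
                        changed = True
    comps = set()
    for i in range(n):
        comps.add(frozenset(ids[j] for j in range(n) if reach[i][j]))
    return sorted(comps, key=lambda c: sorted(map(str, c))[0])
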