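"""Independent brute-force alignment oracle for the test suite.

A plain full-matrix Smith-Waterman with affine gaps (Gotoh three-state
recurrence) written without reference to the package's aligner; used only
to check scores on small instances.
"""

NEG = -(10 ** 9)


def sw_affine_score(a: str, b: str, match: int = 2, mismatch: int = 3,
                    gap_open: int = 5, gap_extend: int = 2) -> int:
    """Best local-alignment score; a gap of length L costs open + L*extend."""
    n = len(b)
    h_prev = [0] * (n + 1)
    f_prev = [NEG] * (n + 1)
    best = 0
    for i in range(1, len(a) + 1):
        h_cur = [0] * (n + 1)
        e_cur = [NEG] * (n + 1)
        f_cur = [NEG] * (n + 1)
        ai = a[i - 1]
        for j in range(1, n + 1):
            e_cur[j] = max(h_cur[j - 1] - gap_open - gap_extend,
                           e_cur[j - 1] - gap_extend)
            f_cur[j] = max(h_prev[j] - gap_open - gap_extend,
                           f_prev[j] - gap_extend)
            sub = match if ai == b[j - 1] else -mismatch
            h_cur[j] = max(0, h_prev[j - 1] + sub, e_cur[j], f_cur[j])
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev, f_prev = h_cur, f_cur
    return best


def mutate(seq: str, n_edits: int, rand) -> str:
    """Apply n random substitutions/insertions/deletions."""
    q = list(seq)
    for _ in range(n_edits):
        if not q:
            break
        op = rand.choice("sid")
        p = rand.randrange(len(q))
        if op == "s":
            q[p] = rand.choice("ACGT")
        elif op == "i":
            q.insert(p, rand.choice("ACGT"))
        else:
            del q[p]
    return "".join(q)
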