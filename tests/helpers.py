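"""Independent oracles used by the test suite.

These deliberately re-derive results with the simplest possible
algorithms (explicit dynamic programming, naive counting) so they stay
independent of the package's implementation paths.
"""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal Smith-Waterman score with affine gaps, explicit DP.

    A gap of length k costs gap_open + k * gap_extend (BLAST convention).
    """
    neg = float("-inf")
    open_cost = gap_open + gap_extend
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consuming b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def naive_metric_counts(predictions, reference_rows):
    """Naive counting oracle for the evaluation metrics.

    ``predictions``: list of (query_id, call, family or None).
    ``reference_rows``: list of (query_id, is_tf, family, evidence).
    Returns a dict of the counts the report is built from.
    """

    def norm(label):
        return " ".join((label or "").split()).casefold()

    def truthy(v):
        if isinstance(v, str):
            return v.strip().lower() in ("1", "true", "yes", "tf")
        return bool(v)

    ref = {q: (truthy(t), f, e) for q, t, f, e in reference_rows}
    predicted = [(q, fam) for q, call, fam in predictions if call != "non-TF"]
    correct_ids = set()
    counts = dict(
        predicted_tfs=0, predicted_correctly=0,
        ev_predicted=0, ev_correct=0,
        putative_predicted=0, putative_correct=0,
        tp=0, fp=0, fn=0,
    )
    counts["annotated_tfs"] = sum(1 for t, _, _ in ref.values() if t)
    for q, fam in predicted:
        counts["predicted_tfs"] += 1
        is_tf, rfam, evid = ref.get(q, (False, "", ""))
        if not is_tf:
            ok = False
        elif fam and rfam:
            ok = norm(fam) == norm(rfam)
        else:
            ok = True
        bucket = "putative" if evid.upper() == "PU" else "ev"
        counts[f"{bucket}_predicted"] += 1
        counts[f"{bucket}_correct"] += int(ok)
        counts["predicted_correctly"] += int(ok)
        if ok:
            counts["tp"] += 1
            correct_ids.add(q)
        else:
            counts["fp"] += 1
    for q, (is_tf, _, _) in ref.items():
        if is_tf and q not in correct_ids:
            counts["fn"] += 1
    return counts
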