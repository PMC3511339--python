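"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, path enumeration)
and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import itertools

from orthocis.align import AlignParams, PairwiseAlignment
from orthocis.motifs import IUPAC_SETS

GAP = "-"


# ---------------------------------------------------------------------------
# alignment: exhaustive enumeration of all global alignment paths

def _all_paths(n: int, m: int):
    def rec(i, j, path):
        if i == n and j == m:
            yield tuple(path)
            return
        if i < n and j < m:
            path.append("M")
            yield from rec(i + 1, j + 1, path)
            path.pop()
        if i < n:
            path.append("X")
            yield from rec(i + 1, j, path)
            path.pop()
        if j < m:
            path.append("Y")
            yield from rec(i, j + 1, path)
            path.pop()

    yield from rec(0, 0, [])


def affine_path_score(a: str, b: str, path, p: AlignParams) -> float:
    i = j = 0
    score = 0.0
    prev = None
    for mv in path:
        if mv == "M":
            ok = a[i] == b[j] and a[i] in "ACGT"
            score += p.match if ok else p.mismatch
            i += 1
            j += 1
        else:
            score -= p.gap_extend if prev == mv else p.gap_open
            if mv == "X":
                i += 1
            else:
                j += 1
        prev = mv
    return score


def brute_best_alignment_score(a: str, b: str, p: AlignParams) -> float:
    """Optimum over every global alignment, by full enumeration."""
    return max(
        affine_path_score(a, b, path, p) for path in _all_paths(len(a), len(b))
    )


# ---------------------------------------------------------------------------
# conservation: per-column recount and window merging

def naive_baseline_columns(aln: PairwiseAlignment) -> list[int]:
    return [k for k, ch in enumerate(aln.baseline_aligned) if ch != GAP]


def naive_window_identity(aln: PairwiseAlignment, start: int, window: int
                          ) -> float:
    """Percent identity over the column span of one baseline window
    (local frame, ignoring offsets)."""
    cols = naive_baseline_columns(aln)
    lo, hi = cols[start], cols[start + window - 1] + 1
    matches = 0
    for k in range(lo, hi):
        x, y = aln.baseline_aligned[k], aln.target_aligned[k]
        if x == y and x in "ACGT":
            matches += 1
    return 100.0 * matches / (hi - lo)


def naive_identity_profile(aln: PairwiseAlignment, window: int, step: int
                           ) -> list[tuple[int, float]]:
    n = len(aln.baseline_seq)
    return [
        (s, naive_window_identity(aln, s, window))
        for s in range(0, n - window + 1, step)
    ]


def naive_call_regions(
    aln: PairwiseAlignment,
    min_identity: float,
    min_span: int,
    window: int,
    step: int,
) -> list[tuple[int, int, float]]:
    """Merged (start, end, identity) triples, local baseline frame."""
    profile = naive_identity_profile(aln, window, step)
    ident_of = dict(profile)
    passing = [s for s, ident in profile if ident > min_identity]
    runs: list[list[int]] = []
    for s in passing:
        if runs and s <= runs[-1][-1] + window:
            runs[-1].append(s)
        else:
            runs.append([s])
    cols = naive_baseline_columns(aln)

    def span_identity(start: int, end: int) -> float:
        lo, hi = cols[start], cols[end - 1] + 1
        matches = sum(
            1
            for k in range(lo, hi)
            if aln.baseline_aligned[k] == aln.target_aligned[k]
            and aln.baseline_aligned[k] in "ACGT"
        )
        return 100.0 * matches / (hi - lo)

    out = []
    for run in runs:
        while run:
            start, end = run[0], run[-1] + window
            if end - start < min_span:
                break
            identity = span_identity(start, end)
            if identity > min_identity:
                out.append((start, end, identity))
                break
            # trim the weaker edge window, as the caller does
            if ident_of[run[0]] <= ident_of[run[-1]]:
                run = run[1:]
            else:
                run = run[:-1]
    return out


# ---------------------------------------------------------------------------
# motif scanning: per-window checks

def iupac_compatible(base: str, code: str) -> bool:
    if base == "N":
        return code == "N"
    return base in IUPAC_SETS[code]


def _revcomp_acgtn(seq: str) -> str:
    table = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(table[ch] for ch in reversed(seq))


def naive_scan_consensus(seq: str, consensus: str
                         ) -> list[tuple[int, str]]:
    """(plus-strand start, strand) of every hit of an IUPAC consensus."""
    seq = seq.upper()
    w = len(consensus)
    hits = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else _revcomp_acgtn(seq)
        for i in range(len(s) - w + 1):
            if all(iupac_compatible(s[i + k], consensus[k]) for k in range(w)):
                plus = i if strand == "+" else len(seq) - w - i
                hits.append((plus, strand))
    return sorted(hits)


def naive_scan_matrix(seq: str, counts, threshold: float
                      ) -> list[tuple[int, str, float]]:
    seq = seq.upper()
    w = len(counts)
    denom = sum(max(row) for row in counts)
    order = "ACGT"
    hits = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else _revcomp_acgtn(seq)
        for i in range(len(s) - w + 1):
            num = 0.0
            for k in range(w):
                ch = s[i + k]
                if ch in order:
                    num += counts[k][order.index(ch)]
            score = num / denom
            if score >= threshold:
                plus = i if strand == "+" else len(seq) - w - i
                hits.append((plus, strand, score))
    return sorted(hits)


# ---------------------------------------------------------------------------
# TFBS pairing: maximum-weight one-to-one matching by enumeration

def brute_matching(
    candidates: list[tuple[float, int, int]], n_base: int, n_targ: int
) -> set[tuple[int, int]]:
    """Max total-weight one-to-one matching over (weight, bi, tj) edges."""
    best_weight = -1.0
    best: set[tuple[int, int]] = set()
    edges_by_b: dict[int, list[tuple[float, int]]] = {}
    for w, bi, tj in candidates:
        edges_by_b.setdefault(bi, []).append((w, tj))
    b_ids = sorted(edges_by_b)
    # enumerate assignments of each baseline hit to a target hit or None
    choices = [edges_by_b[bi] + [(0.0, -1)] for bi in b_ids]
    for combo in itertools.product(*choices):
        used = set()
        total = 0.0
        ok = True
        picked = set()
        for (w, tj), bi in zip(combo, b_ids):
            if tj == -1:
                continue
            if tj in used:
                ok = False
                break
            used.add(tj)
            total += w
            picked.add((bi, tj))
        if ok and total > best_weight:
            best_weight = total
            best = picked
    return best


# ---------------------------------------------------------------------------
# random gapped alignments (for property tests)

def random_alignment(rng, min_baseline: int = 1, max_cols: int = 60,
                     p_gap: float = 0.15) -> PairwiseAlignment:
    """A random valid alignment (no dual-gap columns) with at least
    ``min_baseline`` baseline residues."""
    bases = "ACGT"
    while True:
        ncols = int(rng.integers(min_baseline, max_cols + 1))
        b_chars, t_chars = [], []
        for _ in range(ncols):
            r = rng.random()
            if r < p_gap:
                b_chars.append(GAP)
                t_chars.append(bases[rng.integers(0, 4)])
            elif r < 2 * p_gap:
                b_chars.append(bases[rng.integers(0, 4)])
                t_chars.append(GAP)
            else:
                x = bases[rng.integers(0, 4)]
                b_chars.append(x)
                t_chars.append(
                    x if rng.random() < 0.6 else bases[rng.integers(0, 4)]
                )
        baseline = "".join(b_chars)
        target = "".join(t_chars)
        if (len(baseline.replace(GAP, "")) >= min_baseline
                and len(target.replace(GAP, "")) >= 1):
            return PairwiseAlignment(
                baseline_name="baseline", target_name="target",
                baseline_aligned=baseline, target_aligned=target,
            )
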