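"""Independent brute-force oracles used only by the test suite.

These deliberately share no code path with the package: the motif
oracle enumerates complete element strings and slides them, rather than
extending tilings along the sequence; the duplex oracle tries every
interval pair by explicit reverse-complement comparison; the pairing
oracle rebuilds the bracket pair table by stack simulation.  A tiny
Nussinov-style folder (maximum base pairs, minimum loop 3) fabricates
plausible dot-bracket strings for structure tests.
"""

from __future__ import annotations

import functools

A_SITE = set("A")
R_SITE = set("AG")
N_SITE = set("ACGU0")

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def arn_ok(t: str) -> bool:
    return len(t) == 3 and t[0] in A_SITE and t[1] in R_SITE and t[2] in N_SITE


# ---------------------------------------------------------------------------
# layout enumeration oracle: all element strings over {A, N, g}
# ---------------------------------------------------------------------------

def brute_force_layouts(n_arn: int, n_nf: int, n_gaps: int) -> set[str]:
    """All valid element strings with exactly the given counts, built by
    exhaustive string generation + filtering."""
    total = n_arn + n_nf + n_gaps
    out: set[str] = set()

    def rec(s: str, a: int, f: int, g: int) -> None:
        if len(s) == total:
            if a == n_arn and f == n_nf and g == n_gaps:
                if s[0] == "A" and s[-1] == "A" and "NN" not in s and "gg" not in s:
                    out.add(s)
            return
        rec(s + "A", a + 1, f, g)
        rec(s + "N", a, f + 1, g)
        rec(s + "g", a, f, g + 1)

    rec("", 0, 0, 0)
    return out


# ---------------------------------------------------------------------------
# motif-match oracle: slide every legal layout over the sequence
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _all_layouts(n_arn_min: int, max_nf: int, max_gaps: int, window_nt: int):
    layouts = []
    max_arn = window_nt // 3
    for a in range(n_arn_min, max_arn + 1):
        for f in range(max_nf + 1):
            for g in range(max_gaps + 1):
                for s in brute_force_layouts(a, f, g):
                    span = 3 * (a + f) + g
                    if span <= window_nt:
                        layouts.append((s, span))
    return layouts


def _layout_fits(layout: str, res: str, pos0: int) -> bool:
    """Check a layout string at 0-based position by direct tiling."""
    cur = pos0
    for ch in layout:
        if ch == "g":
            cur += 1
        else:
            t = res[cur : cur + 3]
            if ch == "A" and not arn_ok(t):
                return False
            cur += 3
    return True


def brute_force_matches(
    residues: str,
    n_arn_min: int = 4,
    max_nf: int = 2,
    max_gaps: int = 2,
    window_nt: int = 20,
) -> set[tuple[int, int]]:
    """Maximal match intervals (local 1-based inclusive) by exhaustive
    layout sliding."""
    n = len(residues)
    layouts = _all_layouts(n_arn_min, max_nf, max_gaps, window_nt)
    hits: set[tuple[int, int]] = set()
    arn_at = [arn_ok(residues[i : i + 3]) for i in range(n)]
    for pos0 in range(n):
        if pos0 + 2 >= n or not arn_at[pos0]:
            continue  # matches open with an ARN triplet
        for layout, span in layouts:
            if pos0 + span > n:
                continue
            if _layout_fits(layout, residues, pos0):
                hits.add((pos0 + 1, pos0 + span))
    return {
        iv
        for iv in hits
        if not any(
            o != iv and o[0] <= iv[0] and o[1] >= iv[1] for o in hits
        )
    }


# ---------------------------------------------------------------------------
# duplex oracle: every interval pair, explicit reverse-complement test
# ---------------------------------------------------------------------------

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(s: str) -> str:
    return "".join(_COMP.get(c, "?") for c in reversed(s))


def brute_force_perfect_duplexes(s: str, m: str, min_len: int = 7):
    """Maximal perfect duplexes as (s_start0, m_start0, length)."""
    hits = set()
    for ln in range(min_len, min(len(s), len(m)) + 1):
        for i in range(len(s) - ln + 1):
            for j in range(len(m) - ln + 1):
                if s[i : i + ln] == _revcomp(m[j : j + ln]):
                    hits.add((i, j, ln))
    # keep only non-extendable duplexes
    maximal = set()
    for i, j, ln in hits:
        grown = (i - 1, j, ln + 1) in hits or (i, j - 1, ln + 1) in hits
        if not grown:
            maximal.add((i, j, ln))
    return maximal


def brute_force_bulged_duplexes(s: str, m: str):
    """All 6+gap+2 / 2+gap+6 duplexes with a single one-nucleotide bulge,
    as (s_start0, s_len, m_start0, m_len, bulge_strand)."""
    hits = set()
    for seg1, seg2 in ((6, 2), (2, 6)):
        # bulge on sRNA: sRNA = seg1 + 1 + seg2, mRNA = seg1 + seg2
        for i in range(len(s) - (seg1 + seg2 + 1) + 1):
            p1 = s[i : i + seg1]
            p2 = s[i + seg1 + 1 : i + seg1 + 1 + seg2]
            for j in range(len(m) - (seg1 + seg2) + 1):
                mm = m[j : j + seg1 + seg2]
                if mm == _revcomp(p1 + p2):
                    hits.add((i, seg1 + seg2 + 1, j, seg1 + seg2, "srna"))
        # bulge on mRNA: walking the mRNA 3'->5', the bulge sits after
        # seg1 pairs, i.e. between the 3' part and 5' part of the mRNA
        for i in range(len(s) - (seg1 + seg2) + 1):
            ss = s[i : i + seg1 + seg2]
            for j in range(len(m) - (seg1 + seg2 + 1) + 1):
                m3 = m[j + seg2 + 1 : j + seg2 + 1 + seg1]  # pairs first seg1
                m5 = m[j : j + seg2]  # pairs final seg2
                if ss == _revcomp(m5 + m3):
                    hits.add((i, seg1 + seg2, j, seg1 + seg2 + 1, "mrna"))
    return hits


# ---------------------------------------------------------------------------
# structure oracles
# ---------------------------------------------------------------------------

def pairing_table(brackets: str) -> dict[int, int]:
    stack, pairs = [], {}
    for i, ch in enumerate(brackets, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    return pairs


def nussinov(seq: str, min_loop: int = 3) -> str:
    """Maximum base-pair dot-bracket (Watson-Crick only) — used solely to
    fabricate plausible test structures."""
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in WC:
                    left = dp[i][k - 1] if k > i else 0
                    best = max(best, left + 1 + dp[k + 1][j - 1])
            dp[i][j] = best
    out = ["."] * n

    def trace(i: int, j: int) -> None:
        if i >= j:
            return
        if dp[i][j] == dp[i][j - 1]:
            trace(i, j - 1)
            return
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in WC:
                left = dp[i][k - 1] if k > i else 0
                if left + 1 + dp[k + 1][j - 1] == dp[i][j]:
                    out[k], out[j] = "(", ")"
                    trace(i, k - 1)
                    trace(k + 1, j - 1)
                    return

    trace(0, n - 1)
    return "".join(out)
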