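"""Independent brute-force oracles used to check the package implementations.

Everything here is written as direct exhaustive enumeration of the stated
rules, deliberately sharing no code with the package.
"""

from itertools import combinations

BASIC = set("KR")
HP = set("HP")
PHI = set("LIVFM")


def pat4_starts(seq: str) -> list[int]:
    """1-based starts of 4-mers: all basic, or exactly 3 basic + one H/P."""
    out = []
    for i in range(len(seq) - 3):
        w = seq[i : i + 4]
        nb = sum(c in BASIC for c in w)
        nh = sum(c in HP for c in w)
        if nb == 4 or (nb == 3 and nh == 1):
            out.append(i + 1)
    return out


def pat7_starts(seq: str) -> list[int]:
    """1-based starts of P-anchored 7-mers holding a basic-rich 4-mer at offset 1-3."""
    out = []
    for i in range(len(seq) - 6):
        w = seq[i : i + 7]
        if w[0] != "P":
            continue
        if any(sum(c in BASIC for c in w[off : off + 4]) >= 3 for off in (1, 2, 3)):
            out.append(i + 1)
    return out


def bipartite_starts(seq: str) -> list[int]:
    """1-based starts of 17-mers: 2 basic, 10 spacer, >=3 of final 5 basic."""
    out = []
    for i in range(len(seq) - 16):
        w = seq[i : i + 17]
        if w[0] in BASIC and w[1] in BASIC and sum(c in BASIC for c in w[12:17]) >= 3:
            out.append(i + 1)
    return out


def nes_positive_bruteforce(track, window=15, min_residues=3, threshold=0.5) -> bool:
    """Check every window of `window` consecutive positions directly."""
    n = len(track)
    contrib = [i for i in range(n) if track[i] > threshold]
    for start in range(n):
        end = min(start + window, n)
        if sum(1 for i in contrib if start <= i < end) >= min_residues:
            return True
    return False


def nes_anchor_positions(seq: str) -> set[int]:
    """0-based Phi anchor positions of Phi-x(2,3)-Phi-x(2,3)-Phi-x-Phi matches."""
    n = len(seq)
    anchors = set()
    for i in range(n):
        for g1 in (2, 3):
            for g2 in (2, 3):
                p2 = i + 1 + g1
                p3 = p2 + 1 + g2
                p4 = p3 + 2
                if p4 < n and all(seq[p] in PHI for p in (i, p2, p3, p4)):
                    anchors.update((i, p2, p3, p4))
    return anchors


def hypergeom_upper_tail_enum(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-universe with K successes."""
    universe = range(N)
    successes = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if sum(1 for x in draw if x in successes) >= k:
            hits += 1
    return hits / total if total else 1.0
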