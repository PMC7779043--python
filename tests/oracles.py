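"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with different algorithms from the
implementation: a per-position ORF scanner, a quadratic Gotoh local-alignment
DP, a regex-based tryptic digestion, and a hardcoded monoisotopic residue
mass table.
"""

from __future__ import annotations

import re

from Bio.Align import substitution_matrices

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq: str, min_codons: int = 30,
                     starts: frozenset = frozenset({"ATG"})) -> set[tuple[int, int]]:
    """Test every position as a start; per (frame, stop) keep the 5'-most."""
    seq = seq.upper()
    candidates = []
    for pos in range(len(seq) - 2):
        codon = seq[pos:pos + 3]
        if codon not in starts or "N" in codon:
            continue
        stop_end = None
        for q in range(pos + 3, len(seq) - 2, 3):
            c = seq[q:q + 3]
            if "N" in c:
                continue
            if c in STOPS:
                stop_end = q + 3
                break
        if stop_end is None:
            continue
        if (stop_end - 3 - pos) // 3 >= min_codons:
            candidates.append((pos, stop_end))
    best: dict[tuple[int, int], int] = {}
    for pos, stop_end in candidates:
        key = (pos % 3, stop_end)
        if key not in best or pos < best[key]:
            # 5'-most start must not have an intervening in-frame stop,
            # which the shared stop_end already guarantees
            best[key] = pos
    return {(pos, stop_end) for (_, stop_end), pos in best.items()}


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 12,
                      gap_extend: int = 1) -> float:
    """Quadratic Smith-Waterman/Gotoh best local score; affine gap of
    length k costs gap_open + (k-1)*gap_extend (= BLAST's 11 + k)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    best = 0.0
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)
    for i in range(1, n + 1):
        h_row = [0.0] * (m + 1)
        e_row = [neg] * (m + 1)
        f = neg
        for j in range(1, m + 1):
            e_row[j] = max(h_prev[j] - gap_open, e_prev[j] - gap_extend)
            f = max(h_row[j - 1] - gap_open, f - gap_extend)
            diag = h_prev[j - 1] + _BLOSUM62[a[i - 1]][b[j - 1]]
            h_row[j] = max(0.0, diag, e_row[j], f)
            best = max(best, h_row[j])
        h_prev, e_prev = h_row, e_row
    return best


_TRYPSIN_SITE = re.compile(r"(?<=[KR])(?![P])")


def regex_digest(protein: str, missed_cleavages: int = 0) -> set[tuple[int, str]]:
    """Cut positions by lookbehind/lookahead regex; expand missed cleavages."""
    cuts = [0] + [m.start() for m in _TRYPSIN_SITE.finditer(protein)
                  if 0 < m.start() < len(protein)] + [len(protein)]
    out = set()
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            out.add((cuts[i], protein[cuts[i]:cuts[j]]))
    return out


# standard monoisotopic residue masses (Da), plus water for the free peptide
MONO_RESIDUE = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MONO = 18.0105646863


def table_mass(peptide: str) -> float:
    return sum(MONO_RESIDUE[aa] for aa in peptide) + WATER_MONO


def random_transcript(rng, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
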