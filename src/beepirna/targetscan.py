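"""piRNA target prediction by antisense complementarity.

piRNAs are assumed to bind mRNA targets in a miRNA-like, near-contiguous
antisense duplex. A candidate site is scored with a plant-miRNA-style penalty
scheme: each mismatch costs 1.0, each G:U wobble 0.5, each gap 1.0, penalties
doubled inside the core region (piRNA positions 2-13 from the 5' end), and a
site is reported when its total penalty is at most max_score (default 4.0).
Alignments are banded to at most 2 gaps in total, found with a gap-count
limited dynamic program that is vectorised across transcript positions.

Binding free energy of a reported duplex is estimated with a simplified
nearest-neighbor model at 37 degrees C: a duplex initiation term, Turner-2004
Watson-Crick stack free energies summed over consecutive paired positions
(wobble-containing stacks use fixed representative values), fixed penalties
for internal defects (mismatch or gap columns), and a terminal A:U / G:U end
penalty. Target-binding relationships are finally screened at a free energy
strictly below -15 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import as_dna, as_rna

CORE_REGION = (2, 13)  # piRNA positions (1-based, 5' end) with doubled penalties

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}

# pair class of (piRNA base, target base): 0 match, 1 wobble, 2 mismatch
_PAIR_CLASS = np.full((4, 4), 2, dtype=int)
for _p, _t in _WC:
    _PAIR_CLASS[_BASE_INDEX[_p], _BASE_INDEX[_t]] = 0
for _p, _t in _GU:
    _PAIR_CLASS[_BASE_INDEX[_p], _BASE_INDEX[_t]] = 1


@dataclass
class ScoringParams:
    """Penalty constants of the complementarity score."""

    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 1.0
    core_region: tuple[int, int] = CORE_REGION
    core_multiplier: float = 2.0
    max_gaps: int = 2
    max_score: float = 4.0
    energy_gate: float = -15.0  # strict less-than

    def __post_init__(self):
        if min(self.mismatch_penalty, self.gu_penalty, self.gap_penalty) < 0:
            raise ValueError("penalties must be non-negative")

    def weight(self, position: int) -> float:
        lo, hi = self.core_region
        return self.core_multiplier if lo <= position <= hi else 1.0


# Turner-2004 Watson-Crick RNA/RNA stack free energies at 37 C (kcal/mol),
# keyed by (top dinucleotide 5'->3', bottom dinucleotide 3'->5'). The ten
# canonical entries; all sixteen orderings follow by the dyad symmetry
# dG(WX/YZ) = dG(ZY/XW).
_WC_STACKS = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}

_RNA_PAIRS = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
_WOBBLE = {("G", "U"), ("U", "G")}


def _full_stack_table() -> dict[tuple[str, str], float]:
    """All ordered WC/GU dinucleotide stacks.

    Wobble-containing stacks carry fixed representative values (-1.30 with one
    wobble pair, +0.50 with two) in place of the full Turner wobble tables.
    """
    table: dict[tuple[str, str], float] = {}
    for p1, q1 in _RNA_PAIRS:
        for p2, q2 in _RNA_PAIRS:
            key = (p1 + p2, q1 + q2)
            n_wobble = ((p1, q1) in _WOBBLE) + ((p2, q2) in _WOBBLE)
            if n_wobble == 0:
                val = _WC_STACKS.get(key)
                if val is None:
                    val = _WC_STACKS[(key[1][::-1], key[0][::-1])]
            elif n_wobble == 1:
                val = -1.30
            else:
                val = 0.50
            table[key] = val
    return table


@dataclass
class NNParams:
    """Nearest-neighbor duplex free-energy parameters (kcal/mol, 37 C)."""

    stacks: dict[tuple[str, str], float] = field(default_factory=_full_stack_table)
    initiation: float = 4.09
    defect_penalty: float = 1.0  # per internal mismatch/gap column
    terminal_au_penalty: float = 0.45  # per A:U or G:U closing pair

    def stack(self, top: str, bottom: str) -> float:
        return self.stacks[(as_rna(top), as_rna(bottom))]


@dataclass
class DuplexHit:
    """A piRNA binding site on a transcript.

    The site interval is 0-based half-open on the transcript. `pirna_aln` is
    the piRNA 5'->3' with gap dashes; `target_aln` is the site read 3'->5' so
    the two strings line up column by column; `pairing` marks each column as
    '|' (Watson-Crick), 'o' (G:U), '.' (mismatch), or '-' (gap).
    """

    pirna_id: str
    transcript_id: str
    start: int
    end: int
    penalty_score: float
    delta_g: float
    pairing: str
    pirna_aln: str
    target_aln: str


class PairingConsistencyError(ValueError):
    """Pairing string does not agree with the aligned duplex sequences."""


def _check_alignment(pairing: str, pirna_aln: str, target_aln: str) -> None:
    if not (len(pairing) == len(pirna_aln) == len(target_aln)):
        raise PairingConsistencyError("pairing and aligned sequences differ in length")
    for sym, p, t in zip(pairing, pirna_aln, target_aln):
        if sym == "-":
            if p != "-" and t != "-":
                raise PairingConsistencyError("gap column without a gap character")
            continue
        if p == "-" or t == "-":
            raise PairingConsistencyError("gap character in a non-gap column")
        cls = _PAIR_CLASS[_BASE_INDEX[p], _BASE_INDEX[t]]
        expect = {0: "|", 1: "o", 2: "."}[cls]
        if sym != expect:
            raise PairingConsistencyError(
                f"column {p}/{t} labelled {sym!r}, expected {expect!r}"
            )


def duplex_energy(pairing: str, pirna_aln: str, target_aln: str, nn: NNParams | None = None) -> float:
    """Nearest-neighbor free energy (kcal/mol) of an aligned duplex.

    dG = initiation + sum of stack energies over consecutive paired columns
    + defect_penalty per internal unpaired column + terminal end penalties.
    Defects outside the first/last paired column do not form part of the
    duplex and are ignored.
    """
    nn = nn or NNParams()
    pirna_aln = as_dna(pirna_aln).replace("U", "T")
    target_aln = as_dna(target_aln)
    _check_alignment(pairing, pirna_aln, target_aln)
    paired = [i for i, s in enumerate(pairing) if s in "|o"]
    dg = nn.initiation
    if not paired:
        return dg
    first, last = paired[0], paired[-1]
    dg += nn.defect_penalty * sum(
        1 for i in range(first, last + 1) if pairing[i] not in "|o"
    )
    for a, b in zip(paired, paired[1:]):
        if b == a + 1:
            dg += nn.stack(pirna_aln[a] + pirna_aln[b], target_aln[a] + target_aln[b])
    for i in (first, last):
        pair = (as_rna(pirna_aln[i]), as_rna(target_aln[i]))
        if "A" in pair or pair in {("G", "U"), ("U", "G")}:
            dg += nn.terminal_au_penalty
    return float(round(dg, 10))


def _substitution_rows(pirna: str, rev_codes: np.ndarray, params: ScoringParams) -> np.ndarray:
    """Penalty of pairing piRNA position i (row) with each reversed-target base."""
    pen = np.array([0.0, params.gu_penalty, params.mismatch_penalty])
    L = len(pirna)
    rows = np.empty((L, len(rev_codes)))
    for i in range(L):
        cls = _PAIR_CLASS[_BASE_INDEX[pirna[i]], rev_codes]
        rows[i] = pen[cls] * params.weight(i + 1)
    return rows


def _banded_dp(pirna: str, rev_target: str, params: ScoringParams) -> np.ndarray:
    """Gap-count-limited semi-global DP.

    Aligns the full piRNA (5'->3') against the reversed transcript, start
    free, gaps <= max_gaps. Returns D of shape (gaps+1, L+1, n+1) where
    D[g, i, j] is the minimal penalty of aligning pirna[:i] with an alignment
    using exactly <= g gaps that ends at reversed-target position j.
    """
    L, n = len(pirna), len(rev_target)
    G = params.max_gaps
    rev_codes = np.array([_BASE_INDEX[b] for b in rev_target], dtype=int)
    sub = _substitution_rows(pirna, rev_codes, params)
    INF = np.inf
    D = np.full((G + 1, L + 1, n + 1), INF)
    D[:, 0, :] = 0.0
    for g in range(G + 1):
        for i in range(1, L + 1):
            diag = D[g, i - 1, :-1] + sub[i - 1]
            best = np.full(n + 1, INF)
            best[1:] = diag
            if g > 0:
                w_del = params.gap_penalty * params.weight(i)
                best = np.minimum(best, D[g - 1, i - 1, :] + w_del)
                w_ins = params.gap_penalty * params.weight(min(i + 1, L))
                ins = D[g - 1, i, :-1] + w_ins
                best[1:] = np.minimum(best[1:], ins)
            D[g, i, :] = best
    return D


def _traceback(D, pirna, rev_target, params, g, j):
    """Recover one optimal alignment ending at reversed-target position j."""
    i = len(pirna)
    cols_p, cols_t = [], []
    eps = 1e-9
    while i > 0:
        val = D[g, i, j]
        rev_codes = _BASE_INDEX[rev_target[j - 1]] if j > 0 else None
        if j > 0:
            cls = _PAIR_CLASS[_BASE_INDEX[pirna[i - 1]], rev_codes]
            pen = [0.0, params.gu_penalty, params.mismatch_penalty][cls] * params.weight(i)
            if abs(D[g, i - 1, j - 1] + pen - val) < eps:
                cols_p.append(pirna[i - 1])
                cols_t.append(rev_target[j - 1])
                i, j = i - 1, j - 1
                continue
        if g > 0:
            w_del = params.gap_penalty * params.weight(i)
            if abs(D[g - 1, i - 1, j] + w_del - val) < eps:
                cols_p.append(pirna[i - 1])
                cols_t.append("-")
                i, g = i - 1, g - 1
                continue
            w_ins = params.gap_penalty * params.weight(min(i + 1, len(pirna)))
            if j > 0 and abs(D[g - 1, i, j - 1] + w_ins - val) < eps:
                cols_p.append("-")
                cols_t.append(rev_target[j - 1])
                g, j = g - 1, j - 1
                continue
        raise AssertionError("traceback failed")  # pragma: no cover
    cols_p.reverse()
    cols_t.reverse()
    return "".join(cols_p), "".join(cols_t), j  # j = alignment start in rev coords


def _pairing_string(pirna_aln: str, target_aln: str) -> str:
    out = []
    for p, t in zip(pirna_aln, target_aln):
        if p == "-" or t == "-":
            out.append("-")
        else:
            out.append("|o."[_PAIR_CLASS[_BASE_INDEX[p], _BASE_INDEX[t]]])
    return "".join(out)


def scan_targets(
    pirna_seq: str,
    transcripts: Mapping[str, str],
    params: ScoringParams | None = None,
    nn: NNParams | None = None,
    pirna_name: str | None = None,
) -> list[DuplexHit]:
    """Scan every transcript for antisense binding sites of one piRNA.

    Emits one hit per site region with penalty_score <= max_score; among
    overlapping candidate alignments the lowest-score (ties: leftmost) one is
    kept. Site coordinates are on the forward transcript.
    """
    params = params or ScoringParams()
    nn = nn or NNParams()
    pirna_seq = as_dna(pirna_seq)
    if len(pirna_seq) < 18:
        raise ValueError("piRNA must be at least 18 nt")
    if set(pirna_seq) - set("ACGT"):
        raise ValueError("non-nucleotide characters in piRNA sequence")
    name = pirna_name or pirna_seq
    hits: list[DuplexHit] = []
    for tid in transcripts:
        tseq = as_dna(transcripts[tid])
        if set(tseq) - set("ACGT"):
            raise ValueError(f"non-nucleotide characters in transcript {tid!r}")
        if len(tseq) < 1:
            continue
        rev = tseq[::-1]
        D = _banded_dp(pirna_seq, rev, params)
        L, n = len(pirna_seq), len(rev)
        ends = np.min(D[:, L, :], axis=0)
        cand_j = np.nonzero(ends <= params.max_score + 1e-9)[0]
        cands = []
        for j in cand_j:
            g = int(np.argmin(D[:, L, j]))
            p_aln, t_aln, j0 = _traceback(D, pirna_seq, rev, params, g, int(j))
            # reversed coords [j0, j) -> forward transcript interval
            start, end = n - int(j), n - j0
            cands.append((start, end, float(ends[j]), p_aln, t_aln))
        # cluster overlapping candidate sites; keep best (score, then leftmost)
        cands.sort(key=lambda c: (c[0], c[1]))
        clusters: list[list] = []
        for c in cands:
            if clusters and c[0] < clusters[-1][-1][1]:
                clusters[-1].append(c)
            else:
                clusters.append([c])
        for cluster in clusters:
            start, end, score, p_aln, t_aln = min(
                cluster, key=lambda c: (round(c[2], 9), c[0], c[1])
            )
            pairing = _pairing_string(p_aln, t_aln)
            dg = duplex_energy(pairing, p_aln, t_aln, nn)
            hits.append(
                DuplexHit(
                    pirna_id=name,
                    transcript_id=tid,
                    start=start,
                    end=end,
                    penalty_score=round(score, 9),
                    delta_g=dg,
                    pairing=pairing,
                    pirna_aln=p_aln,
                    target_aln=t_aln,
                )
            )
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.penalty_score))
    return hits


def scan_many(
    pirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    params: ScoringParams | None = None,
    nn: NNParams | None = None,
) -> list[DuplexHit]:
    """scan_targets over a set of named piRNAs."""
    out: list[DuplexHit] = []
    for name in pirnas:
        out.extend(scan_targets(pirnas[name], transcripts, params, nn, pirna_name=name))
    return out


def gate_targets(hits: Sequence[DuplexHit], energy_gate: float = -15.0):
    """Screen binding relationships at delta_g strictly below the gate.

    Returns (retained hits, per-piRNA target table with deduplicated gene
    counts).
    """
    retained = [h for h in hits if h.delta_g < energy_gate]
    genes: dict[str, set[str]] = {}
    for h in retained:
        genes.setdefault(h.pirna_id, set()).add(h.transcript_id)
    table = pd.DataFrame(
        [
            {"pirna_id": p, "n_target_genes": len(g), "target_genes": ",".join(sorted(g))}
            for p, g in sorted(genes.items())
        ],
        columns=["pirna_id", "n_target_genes", "target_genes"],
    )
    return retained, table


def hits_frame(hits: Sequence[DuplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pirna_id": h.pirna_id,
                "transcript_id": h.transcript_id,
                "start": h.start,
                "end": h.end,
                "penalty_score": h.penalty_score,
                "delta_g": h.delta_g,
                "pairing": h.pairing,
            }
            for h in hits
        ],
        columns=[
            "pirna_id", "transcript_id", "start", "end",
            "penalty_score", "delta_g", "pairing",
        ],
    )
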