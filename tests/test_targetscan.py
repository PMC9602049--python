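"""Complementarity scanning, duplex energetics, and the -15 kcal/mol gate."""

import numpy as np
import pytest

from beepirna.io import revcomp
from beepirna.targetscan import (
    DuplexHit,
    NNParams,
    PairingConsistencyError,
    ScoringParams,
    duplex_energy,
    gate_targets,
    scan_targets,
)
from oracles import enumerate_best_alignment


def random_pirna(rng, length=26):
    return "".join(rng.choice(list("ACGT"), size=length))


def embed(rng, insert, flank=60):
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return left + insert + right, flank


class TestScanning:
    def test_perfect_complement_scores_zero(self, rng):
        p = random_pirna(rng)
        tx, start = embed(rng, revcomp(p))
        [hit] = scan_targets(p, {"t": tx})
        assert hit.penalty_score == 0
        assert (hit.start, hit.end) == (start, start + len(p))
        assert set(hit.pairing) == {"|"}

    def test_two_core_mismatches_score_four(self, rng):
        p = random_pirna(rng)
        site = list(revcomp(p))
        # piRNA positions 5 and 9 (core) pair with site positions len-5, len-9
        for k in (5, 9):
            j = len(site) - k
            bad = next(b for b in "ACGT" if b not in _pairing_partners(p[k - 1]))
            site[j] = bad
        tx, start = embed(rng, "".join(site))
        hits = [h for h in scan_targets(p, {"t": tx}) if h.start == start]
        assert hits and hits[0].penalty_score == pytest.approx(4.0)

    def test_single_wobble_outside_core_scores_half(self, rng):
        rng = np.random.default_rng(8)
        p = random_pirna(rng)
        k = 20  # outside the 2-13 core
        if p[k - 1] not in "GT":
            p = p[: k - 1] + "G" + p[k:]
        site = list(revcomp(p))
        j = len(site) - k
        site[j] = "T" if p[k - 1] == "G" else "G"  # wobble partner
        tx, start = embed(rng, "".join(site))
        hits = [h for h in scan_targets(p, {"t": tx}) if h.start == start]
        assert hits and hits[0].penalty_score == pytest.approx(0.5)
        assert hits[0].pairing.count("o") == 1

    def test_wobble_inside_core_is_doubled(self, rng):
        rng = np.random.default_rng(9)
        p = random_pirna(rng)
        k = 6
        p = p[: k - 1] + "G" + p[k:]
        site = list(revcomp(p))
        site[len(site) - k] = "T"
        tx, start = embed(rng, "".join(site))
        hits = [h for h in scan_targets(p, {"t": tx}) if h.start == start]
        assert hits and hits[0].penalty_score == pytest.approx(1.0)

    def test_score_above_cutoff_not_reported(self, rng):
        p = random_pirna(rng)
        site = list(revcomp(p))
        for k in (3, 5, 7):  # 3 core mismatches -> penalty 6 > 4
            j = len(site) - k
            site[j] = next(b for b in "ACGT" if b not in _pairing_partners(p[k - 1]))
        tx, start = embed(rng, "".join(site))
        assert [h for h in scan_targets(p, {"t": tx}) if h.start == start] == []

    def test_rejects_short_or_invalid_input(self):
        with pytest.raises(ValueError, match="18"):
            scan_targets("ACGT", {"t": "ACGT" * 20})
        with pytest.raises(ValueError, match="non-nucleotide"):
            scan_targets("A" * 24, {"t": "ACGTN" * 10})

    def test_matches_exhaustive_enumeration_on_short_transcripts(self):
        """Best banded antisense alignment agrees with plain recursion."""
        params = ScoringParams()
        rng = np.random.default_rng(123)
        n_checked = 0
        for trial in range(100):
            L = int(rng.integers(20, 29))
            p = random_pirna(rng, L)
            n = int(rng.integers(L, 61))
            if rng.random() < 0.5:
                tx = "".join(rng.choice(list("ACGT"), size=n))
            else:  # bias toward hits: plant a lightly mutated site
                site = list(revcomp(p))
                for _ in range(int(rng.integers(0, 4))):
                    site[int(rng.integers(0, len(site)))] = str(rng.choice(list("ACGT")))
                pad = max(0, n - len(site))
                tx = "".join(rng.choice(list("ACGT"), size=pad // 2)) + "".join(site) + \
                     "".join(rng.choice(list("ACGT"), size=pad - pad // 2))
            best = enumerate_best_alignment(p, tx, params)
            hits = scan_targets(p, {"t": tx}, params)
            if best is None:
                assert hits == []
                continue
            n_checked += 1
            assert hits, (trial, best)
            top = min(hits, key=lambda h: (round(h.penalty_score, 9), h.start, h.end))
            assert top.penalty_score == pytest.approx(best[0], abs=1e-9), trial
            # site agreement: the reported site overlaps the enumerated one
            s, e = best[1]
            assert top.start < e and s < top.end, (trial, best, (top.start, top.end))
        assert n_checked >= 30

    def test_duplex_symmetry_under_joint_reverse_complement(self, rng):
        """scan(revcomp(p), revcomp(T)) mirrors scan(p, T)."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            p = random_pirna(r)
            tx, _ = embed(r, revcomp(p))
            fwd = scan_targets(p, {"t": tx})
            mir = scan_targets(revcomp(p), {"t": revcomp(tx)})
            n = len(tx)
            fwd_sites = {(n - h.end, n - h.start, h.penalty_score) for h in fwd
                         if h.penalty_score == 0}
            mir_sites = {(h.start, h.end, h.penalty_score) for h in mir
                         if h.penalty_score == 0}
            assert fwd_sites == mir_sites and fwd_sites


def _pairing_partners(base):
    return {"A": "T", "C": "G", "G": "CT", "T": "AG"}[base]


class TestDuplexEnergy:
    def test_no_paired_positions_gives_initiation_only(self):
        nn = NNParams()
        assert duplex_energy("....", "AAAA", "CCCC", nn) == pytest.approx(nn.initiation)

    def test_toy_duplex_hand_sum(self):
        # 5'-GCGC-3' / 3'-CGCG-5': stacks GC/CG, CG/GC, GC/CG + initiation
        nn = NNParams()
        want = (
            nn.initiation
            + nn.stacks[("GC", "CG")]
            + nn.stacks[("CG", "GC")]
            + nn.stacks[("GC", "CG")]
        )
        assert duplex_energy("||||", "GCGC", "CGCG", nn) == pytest.approx(want, abs=1e-9)

    def test_au_duplex_hand_sum_includes_end_penalties(self):
        # 5'-AAAA-3' / 3'-TTTT-5': three AA/UU stacks, two A:U ends
        nn = NNParams()
        want = nn.initiation + 3 * nn.stacks[("AA", "UU")] + 2 * nn.terminal_au_penalty
        assert duplex_energy("||||", "AAAA", "TTTT", nn) == pytest.approx(want, abs=1e-9)

    def test_mixed_duplex_with_internal_mismatch_hand_sum(self):
        # 5'-GGAC-3' / 3'-CCAG-5': pairing ||.| breaks the helix at column 3
        nn = NNParams()
        want = (
            nn.initiation
            + nn.stacks[("GG", "CC")]
            + nn.defect_penalty
        )
        assert duplex_energy("||.|", "GGAC", "CCAG", nn) == pytest.approx(want, abs=1e-9)

    def test_internal_mismatch_strictly_destabilises(self, rng):
        nn = NNParams()
        for _ in range(20):
            p = random_pirna(rng, int(rng.integers(20, 31)))
            t = revcomp(p)[::-1]  # column-aligned complement (3'->5')
            perfect = duplex_energy("|" * len(p), p, t, nn)
            j = int(rng.integers(1, len(p) - 1))
            bad = next(b for b in "ACGT" if b not in _pairing_partners(p[j]))
            t2 = t[:j] + bad + t[j + 1 :]
            pairing = "|" * j + "." + "|" * (len(p) - j - 1)
            assert duplex_energy(pairing, p, t2, nn) > perfect

    def test_inconsistent_pairing_rejected(self):
        with pytest.raises(PairingConsistencyError):
            duplex_energy("||", "AC", "TC")  # C:C labelled as a match
        with pytest.raises(PairingConsistencyError):
            duplex_energy("|||", "AC", "TG")  # length mismatch

    def test_stack_table_covers_all_wc_gu_stacks(self):
        nn = NNParams()
        pairs = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
        for p1, q1 in pairs:
            for p2, q2 in pairs:
                assert np.isfinite(nn.stacks[(p1 + p2, q1 + q2)])
        # dyad symmetry of the table
        for (top, bot), val in nn.stacks.items():
            assert nn.stacks[(bot[::-1], top[::-1])] == val


class TestGate:
    def _hit(self, dg, pid="p", gene="g"):
        return DuplexHit(pid, gene, 0, 24, 0.0, dg, "|" * 24, "A" * 24, "T" * 24)

    def test_gate_is_strictly_less_than(self):
        kept, _ = gate_targets([self._hit(-15.0), self._hit(-15.01, gene="h")], -15.0)
        assert [h.delta_g for h in kept] == [-15.01]

    def test_gene_deduplication_and_counts(self):
        hits = [self._hit(-20, gene="g1"), self._hit(-18, gene="g1"), self._hit(-22, gene="g2")]
        _, table = gate_targets(hits, -15.0)
        assert table.iloc[0]["n_target_genes"] == 2

    def test_empty_input_gives_empty_table(self):
        kept, table = gate_targets([], -15.0)
        assert kept == [] and table.empty

    def test_perfect_sites_of_24nt_or_more_pass_gate(self, rng):
        params = ScoringParams()
        for length in (24, 28, 33):
            for _ in range(5):
                p = random_pirna(rng, length)
                tx, start = embed(rng, revcomp(p))
                hits = [h for h in scan_targets(p, {"t": tx}) if h.penalty_score == 0]
                assert hits and all(h.delta_g < params.energy_gate for h in hits)
        # even the weakest-stacking 24-mer clears the gate
        p = "A" * 24
        [hit] = scan_targets(p, {"t": revcomp(p)})
        assert hit.delta_g < params.energy_gate
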