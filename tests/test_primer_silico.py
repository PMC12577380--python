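"""Degenerate-primer matching against an exhaustive enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cprkit.errors import ValidationError
from cprkit.io_formats import TAXONOMY_RANKS
from cprkit.primer_silico import (
    BAKT341F,
    BAKT785R,
    IUPAC_MASKS,
    PrimerSpec,
    best_primer_alignment,
    coverage_by_class,
    iupac_compatible,
    reverse_complement,
    sequence_amplifiable,
)
from cprkit.synthetic import PrimerSiteDesign, SynthConfig, simulate_reference_db

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_alignment(primer: str, target: str, budget: int):
    """Independent pure-python enumeration of every offset's mismatches."""
    L = len(primer)
    best = None  # (matched, mismatches, position)
    global_best = None
    for off in range(len(target) - L + 1):
        window = target[off : off + L]
        mism = sum(
            1
            for p, t in zip(primer, window)
            if not (set(IUPAC_SETS[p]) & set(IUPAC_SETS[t]))
        )
        anchor = all(
            t in "ACGT" and t in IUPAC_SETS[p]
            for p, t in zip(primer[-2:], window[-2:])
        )
        if global_best is None or mism < global_best[0]:
            global_best = (mism, off)
        if mism <= budget and anchor:
            if best is None or mism < best[0]:
                best = (mism, off)
    if best is not None:
        return True, best[0], best[1]
    return False, global_best[0], global_best[1]


class TestIupacCompatible:
    @pytest.mark.parametrize(
        "p,t,expected",
        [("N", "G", True), ("W", "C", False), ("R", "R", True), ("U", "T", True)],
    )
    def test_set_intersection(self, p, t, expected):
        assert iupac_compatible(p, t) is expected

    def test_non_iupac_code_rejected(self):
        with pytest.raises(ValidationError):
            iupac_compatible("X", "A")


class TestBestAlignment:
    def test_perfect_site_located(self):
        res = best_primer_alignment(PrimerSpec("p", "ACGT"), "TTACGTTT")
        assert res.matched and res.mismatches == 0 and res.position == 2

    def test_three_prime_mismatch_fails_despite_budget(self):
        # one mismatch total, but it sits in the 3'-terminal dinucleotide
        res = best_primer_alignment(PrimerSpec("p", "ACGT"), "TTACGATT")
        assert not res.matched
        assert res.mismatches == 1

    def test_three_internal_mismatches_exceed_budget(self):
        primer = PrimerSpec("p", "ACGTACGT")
        target = "TT" + "TACTACGT" + "TT"  # 3 mismatches, intact 3' end
        res = best_primer_alignment(primer, target)
        assert not res.matched

    def test_ambiguous_target_base_breaks_three_prime_anchor(self):
        # N in the target matches by set intersection but is not a concrete
        # base, so extension from the 3' dinucleotide is not credited
        res = best_primer_alignment(PrimerSpec("p", "ACGT"), "TTACGNTT")
        assert not res.matched

    def test_oracle_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        codes = list(IUPAC_MASKS)
        concrete = "ACGT"
        for _ in range(300):
            plen = int(rng.integers(6, 18))
            primer = "".join(
                rng.choice(codes if rng.random() < 0.3 else list(concrete))
                for _ in range(plen)
            )
            target = "".join(rng.choice(list(concrete + "N"), size=rng.integers(plen, 80)))
            budget = int(rng.integers(0, 4))
            res = best_primer_alignment(PrimerSpec("p", primer), target, budget=budget)
            exp = oracle_alignment(primer.upper(), target, budget)
            assert (res.matched, res.mismatches, res.position) == exp


class TestSequenceAmplifiable:
    FWD = PrimerSpec("fwd", "ACGTACGTAC")
    REV = PrimerSpec("rev", "TTGGCCAATT", "reverse")

    def build(self, fwd_site, rev_rc, gap=380):
        rng = np.random.default_rng(7)
        insert = "".join(rng.choice(list("ACGT"), size=gap))
        return "TTTTTTTTTT" + fwd_site + insert + rev_rc + "TTTTTTTTTT"

    def test_planted_pair_detected_with_amplicon_length(self):
        target = self.build(self.FWD.sequence, reverse_complement(self.REV.sequence))
        ok, diag = sequence_amplifiable(self.FWD, self.REV, target)
        assert ok
        assert diag["amplicon_length"] == 10 + 380 + 10

    def test_reverse_site_upstream_fails(self):
        rng = np.random.default_rng(8)
        insert = "".join(rng.choice(list("ACGT"), size=300))
        target = (
            "TTTT" + reverse_complement(self.REV.sequence) + insert + self.FWD.sequence + "TTTT"
        )
        ok, _ = sequence_amplifiable(self.FWD, self.REV, target)
        assert not ok

    def test_reverse_site_with_three_mismatches_fails(self):
        rev_rc = list(reverse_complement(self.REV.sequence))
        for i in (3, 4, 5):  # internal: away from the rev primer's 3' anchor
            rev_rc[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[rev_rc[i]]
        target = self.build(self.FWD.sequence, "".join(rev_rc))
        ok, _ = sequence_amplifiable(self.FWD, self.REV, target)
        assert not ok

    def test_amplicon_length_bounds_enforced(self):
        target = self.build(self.FWD.sequence, reverse_complement(self.REV.sequence), gap=30)
        ok, _ = sequence_amplifiable(
            self.FWD, self.REV, target, amplicon_bounds=(100, 2000)
        )
        assert not ok


class TestCoverage:
    def test_planted_design_recovered_exactly(self):
        cfg = SynthConfig(
            seed=6, primer_design={"ABY1": PrimerSiteDesign(9, 0, 1, 0)}
        )
        seqs, tax, truth = simulate_reference_db(cfg)
        cov = coverage_by_class(seqs, tax, BAKT341F, BAKT785R)
        assert cov.iloc[0]["coverage"] == pytest.approx(0.9)
        # per-sequence decisions match the planted amplifiability flags
        for seq_id, seq in seqs.items():
            ok, _ = sequence_amplifiable(BAKT341F, BAKT785R, seq)
            assert ok == truth.amplifiable[seq_id]

    def test_budget_monotonicity(self):
        cfg = SynthConfig(
            seed=13,
            primer_design={c: PrimerSiteDesign(3, 3, 2, 2) for c in ("ABY1", "Parcubacteria")},
        )
        seqs, tax, _ = simulate_reference_db(cfg)
        prev = None
        for budget in (0, 1, 2, 3, 4):
            cov = coverage_by_class(seqs, tax, BAKT341F, BAKT785R, budget=budget)
            current = cov.set_index("taxon_class")["coverage"]
            if prev is not None:
                assert (current >= prev - 1e-12).all()
            prev = current

    def test_strand_symmetry(self):
        cfg = SynthConfig(seed=21, primer_design={"ABY1": PrimerSiteDesign(4, 2, 2, 2)})
        seqs, tax, _ = simulate_reference_db(cfg)
        fwd, rev = BAKT341F, BAKT785R
        flipped = {k: reverse_complement(v) for k, v in seqs.items()}
        swapped_fwd = PrimerSpec("rev_as_fwd", rev.sequence, "forward")
        swapped_rev = PrimerSpec("fwd_as_rev", fwd.sequence, "reverse")
        a = coverage_by_class(seqs, tax, fwd, rev)
        b = coverage_by_class(flipped, tax, swapped_fwd, swapped_rev)
        assert a["coverage"].tolist() == b["coverage"].tolist()
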