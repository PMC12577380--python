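"""In-silico PCR with IUPAC-degenerate primers.

A primer matches a target site when, at some ungapped offset, the
number of incompatible positions is within the mismatch budget
(default 2) and the two 3'-terminal primer positions pair perfectly —
polymerase extension requires true base pairing, so at those two
positions the target base must additionally be a concrete A/C/G/T
inside the primer base's degeneracy set. Elsewhere, degenerate codes
match by nucleotide-set intersection. Alignment is ungapped (only
mismatches are counted, never indels) and U is treated as T.

Coordinates are 0-based half-open internally; reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import TaxonomyTable

#: nucleotide bitmasks: A=1, C=2, G=4, T=8
IUPAC_MASKS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}
_CONCRETE = {"A", "C", "G", "T", "U"}

IUPAC_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN"
)


@dataclass(frozen=True)
class PrimerSpec:
    """A (possibly degenerate) PCR primer, written 5'->3' as synthesized."""

    name: str
    sequence: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set(IUPAC_MASKS)
        if bad:
            raise ValidationError(
                f"primer {self.name}: non-IUPAC characters {sorted(bad)}"
            )
        if len(seq) < 4:
            raise ValidationError(f"primer {self.name}: length must be >= 4")
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(f"primer {self.name}: bad orientation")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


# primer pairs used for amplicon sequencing and total-16S qPCR in
# groundwater enrichment workflows
BAKT341F = PrimerSpec("Bakt341F", "CCTACGGGNGGCWGCAG", "forward")
BAKT785R = PrimerSpec("Bakt785R", "GACTACHVGGGTATCTAATCC", "reverse")
BAC8FMOD = PrimerSpec("Bac8Fmod", "AGAGTTTGATYMTGGCTCAG", "forward")
BAC338RABC = PrimerSpec("Bac338Rabc", "GCWGCCWCCCGTAGGWGT", "reverse")


@dataclass(frozen=True)
class PrimerMatchResult:
    """Best placement of one primer on one target strand."""

    primer_name: str
    matched: bool
    mismatches: int
    position: int  # 0-based offset of the primer 5' end, -1 if target too short
    three_prime_intact: bool
    sequence_id: str | None = None


def iupac_compatible(primer_base: str, target_base: str) -> bool:
    """True iff the two codes' nucleotide sets intersect (U == T)."""
    try:
        pm = IUPAC_MASKS[primer_base.upper()]
        tm = IUPAC_MASKS[target_base.upper()]
    except KeyError as exc:
        raise ValidationError(f"non-IUPAC nucleotide code {exc.args[0]!r}") from exc
    return bool(pm & tm)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (U handled as T)."""
    return seq.upper().translate(IUPAC_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([IUPAC_MASKS[b] for b in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValidationError(f"non-IUPAC nucleotide code {exc.args[0]!r}") from exc


def _scan(
    primer: PrimerSpec, target: str, anchor_end: str = "right"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset mismatch counts and 3'-anchor flags for every placement.

    ``anchor_end`` names where the primer's 3'-terminal dinucleotide
    falls in the window: "right" for a primer given on the target
    strand, "left" for a reverse primer matched as its reverse
    complement (reverse-complementing puts its 3' end first).
    """
    p = _encode(primer.sequence)
    t = _encode(target)
    L = len(p)
    if len(t) < L:
        raise ValidationError(
            f"target shorter than primer {primer.name} ({len(t)} < {L})"
        )
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    compat = (windows & p[None, :]) != 0
    mismatches = (~compat).sum(axis=1)
    # 3' anchor: the terminal two primer positions compatible AND the
    # target base there a concrete A/C/G/T
    concrete = np.array([b in "ACGT" for b in target.upper()], dtype=bool)
    cw = np.lib.stride_tricks.sliding_window_view(concrete, L)
    sl = slice(-2, None) if anchor_end == "right" else slice(None, 2)
    anchor = compat[:, sl].all(axis=1) & cw[:, sl].all(axis=1)
    return mismatches, anchor


def best_primer_alignment(
    primer: PrimerSpec,
    target: str,
    *,
    budget: int = 2,
    sequence_id: str | None = None,
) -> PrimerMatchResult:
    """Best ungapped placement of a primer on the given target strand.

    Valid candidates have at most ``budget`` mismatches and an intact
    two-base 3' anchor; among them the fewest-mismatch (leftmost on
    ties) placement is returned. With no valid candidate the result is
    unmatched and carries the global minimum-mismatch diagnostics.
    """
    mismatches, anchor = _scan(primer, target)
    valid = (mismatches <= budget) & anchor
    if valid.any():
        mm = np.where(valid, mismatches, np.iinfo(np.int64).max)
        pos = int(np.argmin(mm))
        return PrimerMatchResult(
            primer_name=primer.name,
            matched=True,
            mismatches=int(mismatches[pos]),
            position=pos,
            three_prime_intact=True,
            sequence_id=sequence_id,
        )
    pos = int(np.argmin(mismatches))
    return PrimerMatchResult(
        primer_name=primer.name,
        matched=False,
        mismatches=int(mismatches[pos]),
        position=pos,
        three_prime_intact=bool(anchor[pos]),
        sequence_id=sequence_id,
    )


def _valid_offsets(
    primer: PrimerSpec, target: str, budget: int, anchor_end: str = "right"
) -> np.ndarray:
    mismatches, anchor = _scan(primer, target, anchor_end)
    return np.nonzero((mismatches <= budget) & anchor)[0]


def sequence_amplifiable(
    fwd: PrimerSpec,
    rev: PrimerSpec,
    target: str,
    *,
    budget: int = 2,
    amplicon_bounds: tuple[int, int] = (50, 2000),
) -> tuple[bool, dict]:
    """Decide whether a primer pair amplifies a target sequence.

    The forward primer is matched on the given strand and the reverse
    primer as its reverse complement downstream of the forward site; an
    amplicon (forward 5' end to the 3' end of the reverse site) must
    fall within ``amplicon_bounds``. Every valid placement pair is
    considered.
    """
    lo, hi = amplicon_bounds
    rev_rc = PrimerSpec(rev.name + "_rc", reverse_complement(rev.sequence), "forward")
    diagnostics: dict = {"fwd_match": False, "rev_match": False, "amplicon_length": None}
    if len(target) < len(fwd) or len(target) < len(rev_rc):
        return False, diagnostics
    f_off = _valid_offsets(fwd, target, budget)
    diagnostics["fwd_match"] = bool(len(f_off))
    if not len(f_off):
        return False, diagnostics
    r_off = _valid_offsets(rev_rc, target, budget, anchor_end="left")
    diagnostics["rev_match"] = bool(len(r_off))
    if not len(r_off):
        return False, diagnostics
    Lr = len(rev_rc)
    for f in f_off:
        downstream = r_off[r_off >= f + len(fwd)]
        for r in downstream:
            amplicon = int(r) + Lr - int(f)
            if lo <= amplicon <= hi:
                diagnostics["amplicon_length"] = amplicon
                return True, diagnostics
    return False, diagnostics


def coverage_by_class(
    seqs: Mapping[str, str],
    taxonomy: TaxonomyTable,
    fwd: PrimerSpec,
    rev: PrimerSpec,
    *,
    budget: int = 2,
    amplicon_bounds: tuple[int, int] = (50, 2000),
    rank: str = "class",
) -> pd.DataFrame:
    """Per-class fraction of reference sequences the primer pair amplifies.

    Returns a frame with columns taxon_class, n_sequences, n_amplifiable
    and coverage; classes without sequences are simply absent.
    """
    missing = [s for s in seqs if s not in taxonomy.data.index]
    if missing:
        raise ValidationError(f"sequences without taxonomy: {sorted(missing)[:5]}")
    tallies: dict[str, list[int]] = {}
    for seq_id, seq in seqs.items():
        cls = taxonomy.rank_of(seq_id, rank)
        ok, _ = sequence_amplifiable(
            fwd, rev, seq, budget=budget, amplicon_bounds=amplicon_bounds
        )
        n, amp = tallies.get(cls, [0, 0])
        tallies[cls] = [n + 1, amp + int(ok)]
    rows = [
        {
            "taxon_class": cls,
            "n_sequences": n,
            "n_amplifiable": amp,
            "coverage": amp / n,
        }
        for cls, (n, amp) in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["taxon_class", "n_sequences", "n_amplifiable", "coverage"])


def with_orientation(primer: PrimerSpec, orientation: str) -> PrimerSpec:
    return replace(primer, orientation=orientation)
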