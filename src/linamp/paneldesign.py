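"""Hybrid-primer panel design and validation for targeted linear amplification.

A targeted panel is a set of hybrid primers, one per gene: a 14-18 nt
gene-specific 3' sequence fused to a universal 14 nt handle.  The specific
part anneals to the first-strand cDNA so that extension runs toward the
transcript 3' end, where the bead barcode and UMI sit; the amplicon (primer
3' end to the poly(A) junction) must span 500-1000 nt so every product
carries the barcode and UMI.  This module screens candidate primers by
melting temperature and GC content, scores primer-primer cross-dimers, and
enforces the multiplex capacity rule (at most 300 targets per reaction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignInfeasibleError, ValidationError

__all__ = [
    "HybridPrimer",
    "GenePanel",
    "DesignFailure",
    "PanelValidationReport",
    "melting_temp",
    "gc_fraction",
    "reverse_complement",
    "design_hybrid_primer",
    "cross_dimer_score",
    "validate_panel",
    "random_panel",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SPECIFIC_LENGTH_RANGE = (14, 18)
HANDLE_LENGTH = 14
AMPLICON_RANGE = (500, 1000)
MAX_PLEX = 300


def _check_acgt(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValidationError(f"{what} is empty")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(f"{what} contains non-ACGT characters: {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    _check_acgt(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def melting_temp(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees Celsius.

    Deterministic and additive over concatenation; the conventional quick
    estimate for short oligos.  Nearest-neighbor thermodynamics would be a
    drop-in refinement but is not needed for the rule-based screens here.
    """
    _check_acgt(seq, "primer sequence")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return float(2 * at + 4 * gc)


def gc_fraction(seq: str) -> float:
    _check_acgt(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class HybridPrimer:
    """One gene's hybrid primer: specific 3' part plus the shared handle.

    ``target_position`` is the 1-based position of the primer 3' end on the
    transcript, counting from the transcript 5' end (mRNA sense).
    """

    gene_id: str
    specific_seq: str
    handle_seq: str
    target_position: int
    tm_celsius: float = float("nan")
    gc_fraction: float = float("nan")

    def __post_init__(self):
        _check_acgt(self.specific_seq, f"specific_seq of {self.gene_id}")
        _check_acgt(self.handle_seq, f"handle_seq of {self.gene_id}")

    def validate(self) -> list[str]:
        """Return human-readable constraint violations (empty when compliant)."""
        problems = []
        lo, hi = SPECIFIC_LENGTH_RANGE
        if not lo <= len(self.specific_seq) <= hi:
            problems.append(
                f"{self.gene_id}: specific sequence length {len(self.specific_seq)} "
                f"outside [{lo}, {hi}]"
            )
        if len(self.handle_seq) != HANDLE_LENGTH:
            problems.append(
                f"{self.gene_id}: handle length {len(self.handle_seq)} != {HANDLE_LENGTH}"
            )
        return problems


@dataclass
class GenePanel:
    """An ordered multiplex of hybrid primers sharing one handle.

    One primer per gene; negative-control entries target transcripts absent
    from the sample, so any signal on them measures off-target priming.
    """

    primers: list[HybridPrimer]
    negative_controls: frozenset[str] = frozenset()

    def __post_init__(self):
        self.negative_controls = frozenset(self.negative_controls)
        seen = set()
        for p in self.primers:
            if p.gene_id in seen:
                raise ValidationError(f"duplicate primer for gene {p.gene_id!r}")
            seen.add(p.gene_id)
        unknown = self.negative_controls - seen
        if unknown:
            raise ValidationError(f"negative controls not in panel: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.primers)

    @property
    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.primers]

    @property
    def handle_seq(self) -> str:
        return self.primers[0].handle_seq if self.primers else ""

    def is_negative_control(self, gene_id: str) -> bool:
        return gene_id in self.negative_controls

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [p.gene_id for p in self.primers],
                "specific_seq": [p.specific_seq for p in self.primers],
                "handle_seq": [p.handle_seq for p in self.primers],
                "target_position": [p.target_position for p in self.primers],
                "is_negative_control": [
                    p.gene_id in self.negative_controls for p in self.primers
                ],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenePanel":
        primers = [
            HybridPrimer(
                gene_id=str(r.gene_id),
                specific_seq=str(r.specific_seq),
                handle_seq=str(r.handle_seq),
                target_position=int(r.target_position),
                tm_celsius=melting_temp(str(r.specific_seq)),
                gc_fraction=gc_fraction(str(r.specific_seq)),
            )
            for r in df.itertuples(index=False)
        ]
        negs = frozenset(df.loc[df["is_negative_control"].astype(bool), "gene_id"].astype(str))
        return cls(primers=primers, negative_controls=negs)


@dataclass
class DesignFailure:
    """Why no primer could be returned for a transcript: per-constraint tallies."""

    gene_id: str
    n_candidates: int
    eliminated_by: dict[str, int]

    @property
    def limiting_constraint(self) -> str:
        return max(self.eliminated_by, key=self.eliminated_by.get)

    def __str__(self) -> str:
        parts = ", ".join(f"{k}={v}" for k, v in sorted(self.eliminated_by.items()))
        return (
            f"no primer for {self.gene_id}: {self.n_candidates} candidates screened, "
            f"eliminated by {parts}"
        )


def design_hybrid_primer(
    transcript_seq: str,
    handle_seq: str,
    gene_id: str = "gene",
    *,
    length_range: tuple[int, int] = SPECIFIC_LENGTH_RANGE,
    tm_window: tuple[float, float] = (40.0, 64.0),
    gc_window: tuple[float, float] = (0.4, 0.6),
    amplicon_range: tuple[int, int] = AMPLICON_RANGE,
) -> HybridPrimer | DesignFailure:
    """Pick a specific primer so the extension product spans ``amplicon_range`` nt.

    ``transcript_seq`` is the mRNA sense strand, 5'->3'.  The primer equals the
    transcript subsequence ending at the chosen 3'-end position P (1-based); its
    extension product toward the poly(A) junction has length L - P + 1, which
    must fall in ``amplicon_range`` so the product reaches the barcode/UMI.
    Candidates are scanned from the shortest feasible amplicon outward, lengths
    tried mid-window first; the first candidate passing the Tm and GC windows is
    returned.  When all candidates fail a soft screen, a :class:`DesignFailure`
    tallies which constraint removed them.

    Raises :class:`DesignInfeasibleError` when no position satisfies the hard
    geometry (transcript too short for the minimum amplicon plus a primer).
    """
    _check_acgt(transcript_seq, "transcript")
    _check_acgt(handle_seq, "handle")
    if len(handle_seq) != HANDLE_LENGTH:
        raise ValidationError(f"handle length {len(handle_seq)} != {HANDLE_LENGTH}")
    min_len, max_len = length_range
    min_amp, max_amp = amplicon_range
    L = len(transcript_seq)
    # P must leave >= min_len bases upstream and an amplicon in range downstream.
    p_hi = L - min_amp + 1
    p_lo = max(min_len, L - max_amp + 1)
    if p_hi < p_lo:
        raise DesignInfeasibleError(
            f"{gene_id}: transcript length {L} admits no primer position with an "
            f"amplicon in [{min_amp}, {max_amp}]"
        )
    # mid-window lengths first: 16, 15, 17, 14, 18 for the default 14-18 window
    lengths = sorted(range(min_len, max_len + 1), key=lambda k: (abs(2 * k - min_len - max_len), k))
    eliminated = {"tm": 0, "gc": 0}
    n_candidates = 0
    for pos in range(p_hi, p_lo - 1, -1):
        for k in lengths:
            if k > pos:
                continue
            n_candidates += 1
            seq = transcript_seq[pos - k : pos]
            gc = gc_fraction(seq)
            if not gc_window[0] <= gc <= gc_window[1]:
                eliminated["gc"] += 1
                continue
            tm = melting_temp(seq)
            if not tm_window[0] <= tm <= tm_window[1]:
                eliminated["tm"] += 1
                continue
            return HybridPrimer(
                gene_id=gene_id,
                specific_seq=seq,
                handle_seq=handle_seq,
                target_position=pos,
                tm_celsius=tm,
                gc_fraction=gc,
            )
    return DesignFailure(gene_id=gene_id, n_candidates=n_candidates, eliminated_by=eliminated)


def cross_dimer_score(seq_a: str, seq_b: str) -> int:
    """Longest contiguous Watson-Crick complementary run over all ungapped
    antiparallel alignments of two primers.

    The score is symmetric and bounded by ``min(len(a), len(b))``; it is a fast
    rule-based proxy for dimer propensity, not a free-energy model.
    """
    _check_acgt(seq_a, "seq_a")
    _check_acgt(seq_b, "seq_b")
    # align a (5'->3') against b read 3'->5'; position i of a faces b3[i - shift]
    b3 = seq_b[::-1]
    na, nb = len(seq_a), len(b3)
    best = 0
    for shift in range(-(nb - 1), na):
        run = 0
        lo = max(0, shift)
        hi = min(na, nb + shift)
        for i in range(lo, hi):
            if _COMPLEMENT[seq_a[i]] == b3[i - shift]:
                run += 1
                if run > best:
                    best = run
            else:
                run = 0
    return best


@dataclass
class PanelValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_panel(
    panel: GenePanel, max_plex: int = MAX_PLEX, max_dimer: int = 12
) -> PanelValidationReport:
    """Check multiplex capacity, primer geometry, handle uniformity and dimers.

    Violations are report content, never exceptions: size above ``max_plex``
    (300-target single-reaction capacity), specific length outside 14-18,
    handle mismatches, and any pairwise cross-dimer score above ``max_dimer``,
    including each primer screened against the shared handle.
    """
    violations: list[str] = []
    if len(panel) > max_plex:
        violations.append(f"panel size {len(panel)} exceeds single-reaction capacity {max_plex}")
    handle = panel.handle_seq
    for p in panel.primers:
        violations.extend(p.validate())
        if p.handle_seq != handle:
            violations.append(f"{p.gene_id}: handle differs from the shared handle")
    primers = panel.primers
    for i in range(len(primers)):
        s = cross_dimer_score(primers[i].specific_seq, handle)
        if s > max_dimer:
            violations.append(
                f"{primers[i].gene_id} vs handle: cross-dimer score {s} > {max_dimer}"
            )
        for j in range(i + 1, len(primers)):
            s = cross_dimer_score(primers[i].specific_seq, primers[j].specific_seq)
            if s > max_dimer:
                violations.append(
                    f"{primers[i].gene_id} vs {primers[j].gene_id}: "
                    f"cross-dimer score {s} > {max_dimer}"
                )
    return PanelValidationReport(passed=not violations, violations=violations)


DEFAULT_HANDLE = "ACACGACGCTCTTC"  # universal 14-mer handle used by the simulators


def random_panel(
    gene_ids: Sequence[str],
    negative_controls: Iterable[str] = (),
    handle_seq: str = DEFAULT_HANDLE,
    seed: int = 0,
    max_dimer: int | None = 12,
    max_tries: int = 200,
) -> GenePanel:
    """Generate a synthetic compliant panel for simulation studies.

    Specific sequences are random 14-18-mers inside a 40-60% GC window; when
    ``max_dimer`` is set, candidates are greedily rejected against the handle
    and all previously accepted primers, so the returned panel passes
    :func:`validate_panel` at that threshold.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list[HybridPrimer] = []
    for g in gene_ids:
        ok = None
        for _ in range(max_tries):
            k = int(rng.integers(SPECIFIC_LENGTH_RANGE[0], SPECIFIC_LENGTH_RANGE[1] + 1))
            seq = "".join(bases[rng.integers(0, 4, size=k)])
            if not 0.4 <= gc_fraction(seq) <= 0.6:
                continue
            if max_dimer is not None:
                if cross_dimer_score(seq, handle_seq) > max_dimer:
                    continue
                if cross_dimer_score(seq, seq) > max_dimer:
                    continue
                if any(cross_dimer_score(seq, a.specific_seq) > max_dimer for a in accepted):
                    continue
            ok = seq
            break
        if ok is None:
            raise DesignInfeasibleError(
                f"could not draw a compliant primer for {g} in {max_tries} tries"
            )
        accepted.append(
            HybridPrimer(
                gene_id=str(g),
                specific_seq=ok,
                handle_seq=handle_seq,
                target_position=600,
                tm_celsius=melting_temp(ok),
                gc_fraction=gc_fraction(ok),
            )
        )
    return GenePanel(primers=accepted, negative_controls=frozenset(map(str, negative_controls)))
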