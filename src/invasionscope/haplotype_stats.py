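"""Haplotype collapsing and sampling-sufficiency statistics.

Mitochondrial (COI) sequences from an outbreak are collapsed into haplotypes
(exact sequence matches), and two closed-form results guide sampling design:

* the coalescent probability that a sample of size ``n`` has captured every
  haplotype segregating in the population,

      p = (n - 1) / (n + 1),

  so e.g. 39 sequences suffice for p = 0.95; and

* the minimum sample size needed to detect (or confidently exclude) a
  haplotype of population frequency ``p`` at confidence ``beta``,

      n = ln(1 - beta) / ln(1 - p).

An iterative procedure re-evaluates the detection sample size as sequences
accrue, using the running frequency of the rarest observed haplotype — the
field workflow for deciding when to stop sequencing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AlignedSequence",
    "HaplotypeTable",
    "SufficiencyResult",
    "SufficiencyTrace",
    "collapse_haplotypes",
    "pairwise_differences",
    "prob_all_haplotypes_sampled",
    "min_n_for_prob",
    "min_detection_sample_size",
    "iterative_sufficiency",
    "format_percent",
]

_UNAMBIGUOUS = frozenset("ACGT")
_ALLOWED = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised on malformed or inconsistent alignments."""


@dataclass(frozen=True)
class AlignedSequence:
    """One aligned DNA sequence (IUPAC codes and '-' gaps allowed)."""

    seq_id: str
    residues: str
    locality: str | None = None
    group: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise AlignmentError(
                f"sequence {self.seq_id!r}: unexpected symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _check_equal_lengths(seqs: Sequence[AlignedSequence]) -> int:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        offenders = sorted({s.seq_id for s in seqs if len(s) != len(seqs[0])})
        raise AlignmentError(
            f"unequal sequence lengths {sorted(lengths)}; offending ids "
            f"(vs first): {offenders}"
        )
    return lengths.pop()


def _haplotype_label(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA', ... (spreadsheet-style)."""
    label = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


@dataclass
class HaplotypeEntry:
    haplotype_id: str
    sequence: str
    count: int
    frequency: float
    members: list[str] = field(default_factory=list)
    per_locality_counts: dict[str, int] = field(default_factory=dict)


class HaplotypeTable:
    """Haplotype -> count/frequency table, labels assigned in input order."""

    def __init__(self, entries: list[HaplotypeEntry]):
        self.entries = entries
        total = sum(e.count for e in entries)
        if total == 0:
            raise AlignmentError("empty haplotype table")
        assert abs(sum(e.frequency for e in entries) - 1.0) < 1e-9
        self.total = total

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, haplotype_id: str) -> HaplotypeEntry:
        for e in self.entries:
            if e.haplotype_id == haplotype_id:
                return e
        raise KeyError(haplotype_id)

    @property
    def counts(self) -> dict[str, int]:
        return {e.haplotype_id: e.count for e in self.entries}

    @property
    def frequencies(self) -> dict[str, float]:
        return {e.haplotype_id: e.frequency for e in self.entries}

    def formatted_frequencies(self, ndigits: int = 1, mode: str = "round") -> dict[str, float]:
        """Percent frequencies at the given precision ('round' or 'truncate')."""
        return {
            e.haplotype_id: format_percent(100.0 * e.frequency, ndigits, mode)
            for e in self.entries
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": [e.haplotype_id for e in self.entries],
                "count": [e.count for e in self.entries],
                "frequency": [e.frequency for e in self.entries],
            }
        )


def format_percent(value: float, ndigits: int = 1, mode: str = "round") -> float:
    """Round or truncate a percentage to ``ndigits`` decimals.

    Truncation matters when matching report-style figures computed by
    dropping (not rounding) trailing digits, e.g. 10/18 -> 55.5 %.
    """
    if mode == "round":
        return round(value, ndigits)
    if mode == "truncate":
        factor = 10 ** ndigits
        return math.floor(value * factor + 1e-9) / factor
    raise ValueError(f"mode must be 'round' or 'truncate', got {mode!r}")


def collapse_haplotypes(alignment: Sequence[AlignedSequence]) -> HaplotypeTable:
    """Group identical sequences (exact string match after uppercasing).

    Ambiguity codes are part of identity: an N-bearing sequence is its own
    haplotype unless identical to another.  Labels A, B, ... are assigned by
    first occurrence in input order; per-locality tallies are kept when
    localities are present.
    """
    if not alignment:
        raise AlignmentError("empty alignment")
    _check_equal_lengths(alignment)
    order: dict[str, HaplotypeEntry] = {}
    for seq in alignment:
        entry = order.get(seq.residues)
        if entry is None:
            entry = HaplotypeEntry(
                haplotype_id=_haplotype_label(len(order)),
                sequence=seq.residues, count=0, frequency=0.0,
            )
            order[seq.residues] = entry
        entry.count += 1
        entry.members.append(seq.seq_id)
        if seq.locality is not None:
            entry.per_locality_counts[seq.locality] = (
                entry.per_locality_counts.get(seq.locality, 0) + 1
            )
    total = len(alignment)
    entries = list(order.values())
    for e in entries:
        e.frequency = e.count / total
    return HaplotypeTable(entries)


def pairwise_differences(a: AlignedSequence, b: AlignedSequence) -> tuple[int, int]:
    """(differing sites, compared sites) under pairwise deletion.

    Only sites where *both* residues are unambiguous bases (A/C/G/T) are
    compared; gaps and ambiguity codes are deleted pairwise.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"sequences {a.seq_id!r} ({len(a)} bp) and {b.seq_id!r} ({len(b)} bp) "
            f"have unequal lengths"
        )
    diff = compared = 0
    for x, y in zip(a.residues, b.residues):
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS:
            compared += 1
            if x != y:
                diff += 1
    return diff, compared


# ---------------------------------------------------------------------------
# sampling sufficiency

def prob_all_haplotypes_sampled(n: int) -> float:
    """Coalescent probability that ``n`` sequences capture all haplotypes.

    p = (n - 1) / (n + 1); p(1) = 0, p -> 1 as n grows.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    return (n - 1) / (n + 1)


def min_n_for_prob(p_target: float) -> int:
    """Smallest n with (n - 1)/(n + 1) >= p_target (e.g. 0.95 -> 39)."""
    if not 0 <= p_target < 1:
        raise ValueError(f"target probability must be in [0, 1), got {p_target}")
    n = max(1, math.ceil((1 + p_target) / (1 - p_target) - 1e-9))
    while prob_all_haplotypes_sampled(n) < p_target:  # guard float division error
        n += 1
    while n > 1 and prob_all_haplotypes_sampled(n - 1) >= p_target:
        n -= 1
    return n


def min_detection_sample_size(p_freq: float, beta: float, ceil: bool = False) -> float:
    """Minimum sample size to detect a haplotype of frequency ``p_freq``.

    n = ln(1 - beta) / ln(1 - p_freq); a positive real (use ``ceil=True`` for
    the next integer).  ``beta`` is the desired confidence of detecting at
    least one copy.
    """
    if not 0 < p_freq < 1:
        raise ValueError(f"haplotype frequency must be in (0, 1), got {p_freq}")
    if not 0 < beta < 1:
        raise ValueError(f"confidence must be in (0, 1), got {beta}")
    n = math.log(1 - beta) / math.log(1 - p_freq)
    return math.ceil(n) if ceil else n


@dataclass(frozen=True)
class SufficiencyResult:
    """One step of the iterative sufficiency trace."""

    n: int
    p_all_sampled: float
    rare_frequency: float | None
    beta: float
    n_min_detect: float | None  # None when only one haplotype observed so far

    @property
    def computable(self) -> bool:
        return self.n_min_detect is not None


class SufficiencyTrace:
    """Trace of per-step sufficiency statistics as samples accrue."""

    def __init__(self, steps: list[SufficiencyResult]):
        self.steps = steps

    def __len__(self) -> int:
        return len(self.steps)

    def __getitem__(self, i: int) -> SufficiencyResult:
        return self.steps[i]

    @property
    def final(self) -> SufficiencyResult:
        return self.steps[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [s.n for s in self.steps],
                "p_all_sampled": [s.p_all_sampled for s in self.steps],
                "rare_frequency": [s.rare_frequency for s in self.steps],
                "n_min_detect": [s.n_min_detect for s in self.steps],
            }
        )


def iterative_sufficiency(
    samples: Iterable[str], beta: float = 0.95
) -> SufficiencyTrace:
    """Re-evaluate the detection sample size after each new sequence.

    Processes haplotype labels in sampling order; after each sample, observed
    frequencies are updated, ``p`` is set to the rarest observed haplotype's
    frequency, and the detection formula is evaluated.  Steps where only one
    haplotype has been observed (p = 1, formula undefined) are recorded as
    not computable.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("iterative sufficiency needs at least 2 samples")
    counts: dict[str, int] = {}
    steps: list[SufficiencyResult] = []
    for i, label in enumerate(samples, start=1):
        counts[label] = counts.get(label, 0) + 1
        if len(counts) >= 2:
            rare = min(counts.values()) / i
            n_min = min_detection_sample_size(rare, beta)
        else:
            rare, n_min = None, None
        steps.append(
            SufficiencyResult(
                n=i,
                p_all_sampled=prob_all_haplotypes_sampled(i),
                rare_frequency=rare,
                beta=beta,
                n_min_detect=n_min,
            )
        )
    return SufficiencyTrace(steps)
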