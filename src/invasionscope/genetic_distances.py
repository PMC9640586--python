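"""Uncorrected p-distances within and between sequence groups.

The p-distance between two aligned sequences is the proportion of compared
sites at which they differ, with pairwise deletion of gaps and ambiguity
codes (the convention of MEGA's "p-distance" with pairwise deletion).  For a
set of named groups (species, lineages), the module computes the mean
within-group distance (the diagonal; "n.c." for singleton groups) and the
mean between-group distance for every pair, with standard errors obtained by
bootstrap over alignment sites — the standard barcoding-table layout used to
weigh intra- vs inter-specific divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotype_stats import AlignedSequence, AlignmentError, _check_equal_lengths, format_percent

__all__ = [
    "GroupDistanceMatrix",
    "p_distance",
    "group_distance_matrix",
    "matrix_summaries",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(seqs: Sequence[AlignedSequence]) -> tuple[np.ndarray, np.ndarray]:
    """(n, L) uint8 residue matrix and boolean matrix of unambiguous sites."""
    length = _check_equal_lengths(seqs)
    arr = np.frombuffer("".join(s.residues for s in seqs).encode("ascii"), np.uint8)
    arr = arr.reshape(len(seqs), length)
    valid = np.isin(arr, _BASES)
    return arr, valid


def p_distance(a: AlignedSequence, b: AlignedSequence) -> float:
    """Proportion of differing sites among pairwise-comparable sites, in [0, 1]."""
    arr, valid = _encode([a, b])
    both = valid[0] & valid[1]
    compared = int(both.sum())
    if compared == 0:
        raise AlignmentError(
            f"no comparable sites between {a.seq_id!r} and {b.seq_id!r} "
            f"after pairwise deletion"
        )
    return float((arr[0, both] != arr[1, both]).sum() / compared)


@dataclass
class GroupDistanceMatrix:
    """Group-wise mean p-distances (percent) with bootstrap standard errors.

    ``between[i, j]`` (i != j, symmetric) is the mean distance over all
    cross-group sequence pairs; ``within[i]`` the mean over intra-group
    pairs, NaN ("n.c.", not calculable) for groups with fewer than two
    sequences.  SEs are on the same percent scale as the distances.
    """

    group_names: list[str]
    between: np.ndarray
    between_se: np.ndarray
    within: np.ndarray
    within_se: np.ndarray

    def __post_init__(self):
        k = len(self.group_names)
        for name in ("between", "between_se", "within", "within_se"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if self.between.shape != (k, k) or self.within.shape != (k,):
            raise ValueError("matrix shapes inconsistent with group_names")

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def between_pairs(self):
        """Yield (name_i, name_j, distance, se) over the lower triangle."""
        for i in range(self.n_groups):
            for j in range(i):
                yield (
                    self.group_names[i], self.group_names[j],
                    float(self.between[i, j]), float(self.between_se[i, j]),
                )

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        """Lower-triangle table in the conventional layout: between-group
        distances below the diagonal, within-group on the diagonal, and the
        literal "n.c." for non-calculable entries."""
        k = self.n_groups
        data = []
        for i in range(k):
            row = []
            for j in range(k):
                if j < i:
                    row.append(f"{self.between[i, j]:.{ndigits}f}")
                elif j == i:
                    row.append(
                        "n.c." if np.isnan(self.within[i]) else f"{self.within[i]:.{ndigits}f}"
                    )
                else:
                    row.append("")
            data.append(row)
        return pd.DataFrame(data, index=self.group_names, columns=self.group_names)


def group_distance_matrix(
    alignment: Sequence[AlignedSequence],
    group_map: Mapping[str, str] | None = None,
    bootstrap_reps: int = 500,
    seed: int = 0,
) -> GroupDistanceMatrix:
    """Mean within/between-group p-distances with site-bootstrap SEs.

    Groups come from ``group_map`` (seq_id -> group) or, if omitted, from
    each sequence's ``group`` attribute.  SEs: alignment columns are
    resampled with replacement ``bootstrap_reps`` times, the matrix is
    recomputed per replicate, and the SE is the standard deviation across
    replicates (seeded, reproducible).  Distances are reported in percent.
    """
    if not alignment:
        raise AlignmentError("empty alignment")
    if group_map is None:
        group_map = {s.seq_id: s.group for s in alignment}
    groups_of = []
    for s in alignment:
        g = group_map.get(s.seq_id)
        if g is None:
            raise AlignmentError(f"sequence {s.seq_id!r} has no group assignment")
        groups_of.append(g)
    names = list(dict.fromkeys(groups_of))  # first-appearance order
    if len(names) < 2:
        raise AlignmentError("need at least 2 groups")
    gidx = {g: i for i, g in enumerate(names)}
    arr, valid = _encode(alignment)
    n, length = arr.shape

    # All unordered sequence pairs with per-site difference/comparability masks.
    pair_cells: list[tuple[int, int]] = []  # (gi, gj) cell for each pair (gi >= gj)
    ii, jj = np.triu_indices(n, k=1)
    diff = (arr[ii] != arr[jj]) & valid[ii] & valid[jj]
    comp = valid[ii] & valid[jj]
    for a, b in zip(ii, jj):
        gi, gj = gidx[groups_of[a]], gidx[groups_of[b]]
        pair_cells.append((max(gi, gj), min(gi, gj)))
    cells = np.array(pair_cells)

    def matrices(site_idx: np.ndarray | slice):
        d = diff[:, site_idx].sum(axis=1)
        c = comp[:, site_idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pd_pairs = np.where(c > 0, d / np.maximum(c, 1), np.nan)
        k = len(names)
        between = np.full((k, k), np.nan)
        within = np.full(k, np.nan)
        for i in range(k):
            wi = (cells[:, 0] == i) & (cells[:, 1] == i)
            if wi.any():
                within[i] = np.nanmean(pd_pairs[wi])
            for j in range(i):
                bi = (cells[:, 0] == i) & (cells[:, 1] == j)
                if bi.any():
                    between[i, j] = between[j, i] = np.nanmean(pd_pairs[bi])
        return between * 100.0, within * 100.0

    between, within = matrices(slice(None))

    rng = np.random.default_rng(seed)
    k = len(names)
    boot_between = np.empty((bootstrap_reps, k, k))
    boot_within = np.empty((bootstrap_reps, k))
    for r in range(bootstrap_reps):
        idx = rng.integers(0, length, size=length)
        boot_between[r], boot_within[r] = matrices(idx)
    with warnings.catch_warnings():
        # cells with no pairs are all-NaN across replicates; they stay NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        between_se = np.nanstd(boot_between, axis=0, ddof=1)
        within_se = np.nanstd(boot_within, axis=0, ddof=1)
    between_se[np.isnan(between)] = np.nan
    within_se[np.isnan(within)] = np.nan

    return GroupDistanceMatrix(names, between, between_se, within, within_se)


def matrix_summaries(
    m: GroupDistanceMatrix, ndigits: int = 1, mode: str = "truncate"
) -> dict:
    """Aggregate the matrix: mean/max/min between (with pairs), mean/max/min
    within (with groups); "n.c." diagonal entries are excluded.

    ``mode`` ('truncate' or 'round') controls the displayed aggregates; raw
    full-precision values are always included under ``*_raw`` keys.  Each of
    the between-group pairs is weighted equally (not by pair counts).
    """
    pairs = list(m.between_pairs())
    if not pairs:
        raise ValueError("no between-group entries to summarise")
    values = np.array([p[2] for p in pairs])
    mean_between = float(values.mean())
    i_max, i_min = int(values.argmax()), int(values.argmin())

    within_vals = [
        (m.group_names[i], float(m.within[i]))
        for i in range(m.n_groups)
        if not np.isnan(m.within[i])
    ]
    out = {
        "mean_between_raw": mean_between,
        "mean_between": format_percent(mean_between, ndigits, mode),
        "max_between": (pairs[i_max][0], pairs[i_max][1], float(values[i_max])),
        "min_between": (pairs[i_min][0], pairs[i_min][1], float(values[i_min])),
        "n_between_pairs": len(pairs),
    }
    if within_vals:
        wv = np.array([v for _, v in within_vals])
        mean_within = float(wv.mean())
        out.update(
            {
                "mean_within_raw": mean_within,
                "mean_within": format_percent(mean_within, ndigits + 1, mode),
                "max_within": within_vals[int(wv.argmax())],
                "min_within": within_vals[int(wv.argmin())],
                "n_within_groups": len(within_vals),
            }
        )
    return out
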