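"""Panel alignment and per-site conservation/discrimination profiling.

The workflow mirrors how diagnostic markers are found in practice for
panels of near-identical genomes (>93% identity): every record is
globally aligned to a designated reference with a banded affine-gap
aligner, the pairwise alignments are merged center-star style onto
reference columns, and each column is scored for being invariant within
the target species while differing from every record of the other
species.  Runs of such fully diagnostic columns become candidate
windows for primer design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from . import _banded
from .seq_io import GenomeRecord, SpeciesPanel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default alignment scores: match, mismatch, gap open, gap extend
DEFAULT_SCORES = (1.0, -1.0, -4.0, -1.0)


class AlignmentError(ValueError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid DNA character(s) {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A banded global alignment and its percent identity.

    Identity uses the alignment-length convention: matches divided by
    all aligned columns, gap columns included in the denominator.
    """

    aligned_a: str
    aligned_b: str
    score: float
    band_width: int

    @property
    def identity_pct(self) -> float:
        cols = len(self.aligned_a)
        matches = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )
        return 100.0 * matches / cols


def default_band(a: str, b: str) -> int:
    return max(200, 2 * abs(len(a) - len(b)))


def global_align(
    a: str,
    b: str,
    band: int | None = None,
    scores: tuple[float, float, float, float] = DEFAULT_SCORES,
) -> PairwiseAlignment:
    """Banded global alignment with affine gaps.

    A gap of length L costs ``open + L * extend`` (defaults 4 + L).  The
    band is a half-width on the diagonal offset; it must be at least the
    length difference of the two sequences so the corner is reachable.
    For short sequences (band covering the whole matrix) the result is
    exactly the unbanded optimum.
    """
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    if band is None:
        band = default_band(a, b)
    if band < abs(len(a) - len(b)):
        raise AlignmentError(
            f"band {band} cannot connect the alignment corners; "
            f"use band >= {abs(len(a) - len(b))}"
        )
    match, mismatch, gap_open, gap_extend = scores
    score, ptrM, ptrX, ptrY, endmat = _banded.banded_affine(
        _encode(a), _encode(b), band, match, mismatch, gap_open, gap_extend
    )
    aligned_a, aligned_b = _banded.traceback(a, b, band, ptrM, ptrX, ptrY, endmat)
    return PairwiseAlignment(aligned_a, aligned_b, float(score), band)


@dataclass
class MultipleAlignment:
    """Center-star alignment projected onto reference columns.

    Every row has exactly one character per reference position
    (insertions relative to the reference are dropped from profiling but
    counted in ``insertion_counts``).  ``col_to_ref`` is therefore the
    identity mapping; it is kept explicit for downstream consumers.
    """

    reference_id: str
    rows: dict[str, str]
    insertion_counts: dict[str, int] = field(default_factory=dict)

    @property
    def column_count(self) -> int:
        return len(self.rows[self.reference_id])

    @property
    def col_to_ref(self) -> np.ndarray:
        return np.arange(self.column_count)


def build_msa(
    panel: SpeciesPanel,
    reference_id: str,
    band: int | None = None,
    min_identity: float = 85.0,
) -> MultipleAlignment:
    """Align every panel record to the reference and merge by reference
    columns (center-star).  Deterministic for fixed input.

    Records below *min_identity* percent identity to the reference are
    rejected by name: the profiling model assumes near-identical panels.
    """
    reference = panel[reference_id]
    rows: dict[str, str] = {}
    insertions: dict[str, int] = {}
    for rec in panel.records:
        if rec.id == reference_id:
            rows[rec.id] = reference.sequence
            insertions[rec.id] = 0
            continue
        aln = global_align(reference.sequence, rec.sequence, band=band)
        if aln.identity_pct < min_identity:
            raise AlignmentError(
                f"record {rec.id!r} is only {aln.identity_pct:.1f}% identical "
                f"to reference {reference_id!r} (floor {min_identity}%)"
            )
        projected: list[str] = []
        n_ins = 0
        for ref_ch, rec_ch in zip(aln.aligned_a, aln.aligned_b):
            if ref_ch == "-":
                n_ins += 1
                continue
            projected.append(rec_ch)
        rows[rec.id] = "".join(projected)
        insertions[rec.id] = n_ins
    return MultipleAlignment(reference_id, rows, insertions)


@dataclass
class SiteProfile:
    """Per-column conservation and discrimination flags for one target.

    ``target_base[c]`` is the single base shared by every target-species
    row at column c (empty string when the target is polymorphic, gapped
    or ambiguous there, in which case the column can never be
    diagnostic).  ``discriminating[c]`` is the set of non-target species
    whose every row differs from the target base at c; a column is fully
    diagnostic when that set covers all non-target species.
    """

    target_species: str
    species: list[str]
    target_base: list[str]
    target_invariant: np.ndarray
    discriminating: list[frozenset[str]]

    @property
    def nontarget_species(self) -> frozenset[str]:
        return frozenset(s for s in self.species if s != self.target_species)

    @cached_property
    def diagnostic_mask(self) -> np.ndarray:
        """Boolean mask of columns diagnostic against *all* non-target
        species."""
        others = self.nontarget_species
        if not others:  # nothing to discriminate against
            return np.zeros(len(self.target_base), dtype=bool)
        return np.array(
            [
                bool(inv) and disc == others
                for inv, disc in zip(self.target_invariant, self.discriminating)
            ]
        )

    @cached_property
    def diagnostic_columns(self) -> np.ndarray:
        return np.flatnonzero(self.diagnostic_mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(len(self.target_base)),
                "ref_pos": np.arange(len(self.target_base)),
                "target_base": self.target_base,
                "invariant": self.target_invariant.astype(int),
                "discriminates": [
                    ",".join(sorted(d)) for d in self.discriminating
                ],
                "diagnostic": self.diagnostic_mask.astype(int),
            }
        )


_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "": ""}


def mirror_profile(profile: SiteProfile) -> SiteProfile:
    """The same profile expressed on the reverse-complement reference
    (column order reversed, target bases complemented)."""
    return SiteProfile(
        target_species=profile.target_species,
        species=list(profile.species),
        target_base=[_BASE_COMPLEMENT[b] for b in reversed(profile.target_base)],
        target_invariant=profile.target_invariant[::-1].copy(),
        discriminating=list(reversed(profile.discriminating)),
    )


def site_profile(
    msa: MultipleAlignment, panel: SpeciesPanel, target: str
) -> SiteProfile:
    """Flag, per alignment column, target invariance and which non-target
    species are fully distinguishable there.

    A non-target species counts as discriminated at a column when none
    of its rows equals the target base — it may be polymorphic, as long
    as it never matches.  Gaps and Ns never match anything, including
    themselves.
    """
    species_by_id = panel.species_of
    if target not in species_by_id.values():
        raise ValueError(f"unknown target species {target!r}")
    ncol = msa.column_count
    ids_by_species: dict[str, list[str]] = {}
    for rid, sp in species_by_id.items():
        if rid in msa.rows:
            ids_by_species.setdefault(sp, []).append(rid)
    target_rows = [msa.rows[rid] for rid in ids_by_species[target]]
    other_species = sorted(s for s in ids_by_species if s != target)

    target_base: list[str] = []
    invariant = np.zeros(ncol, dtype=bool)
    discriminating: list[frozenset[str]] = []
    for c in range(ncol):
        bases = {row[c] for row in target_rows}
        if len(bases) == 1 and bases <= set("ACGT"):
            tb = next(iter(bases))
            target_base.append(tb)
            invariant[c] = True
            disc = frozenset(
                sp
                for sp in other_species
                if all(msa.rows[rid][c] != tb for rid in ids_by_species[sp])
            )
            discriminating.append(disc)
        else:
            target_base.append("")
            discriminating.append(frozenset())
    return SiteProfile(
        target_species=target,
        species=sorted(ids_by_species),
        target_base=target_base,
        target_invariant=invariant,
        discriminating=discriminating,
    )


@dataclass(frozen=True)
class DiagnosticWindow:
    """A reference interval bundling fully diagnostic columns."""

    start: int
    end: int
    diagnostic_columns: tuple[int, ...]
    score: int

    def __post_init__(self) -> None:
        assert self.start < self.end
        assert all(self.start <= c < self.end for c in self.diagnostic_columns)


def find_windows(
    profile: SiteProfile, min_sites: int = 3, window_len: int = 500
) -> list[DiagnosticWindow]:
    """Maximal clusters of fully diagnostic columns spanning at most
    *window_len* bases and holding at least *min_sites* of them, sorted
    by site count (descending) then start (ascending)."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    if window_len < 50:
        raise ValueError("window_len must be >= 50")
    cols = profile.diagnostic_columns
    windows: list[DiagnosticWindow] = []
    prev_j = -1
    for i in range(len(cols)):
        j = i
        while j + 1 < len(cols) and cols[j + 1] - cols[i] < window_len:
            j += 1
        if j <= prev_j:  # contained in the previous maximal window
            continue
        prev_j = j
        count = j - i + 1
        if count >= min_sites:
            members = tuple(int(c) for c in cols[i : j + 1])
            windows.append(
                DiagnosticWindow(
                    start=members[0],
                    end=members[-1] + 1,
                    diagnostic_columns=members,
                    score=count,
                )
            )
    windows.sort(key=lambda w: (-w.score, w.start))
    return windows
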