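"""Seeded synthetic panels of AT-rich, near-identical circular genomes.

The generator emulates the data regime diagnostic LAMP markers are
mined from: a star phylogeny of species radiating from a shared
ancestral mitogenome by independent substitutions (no indels by
default), low intra-species polymorphism, ~80% AT composition, and a
handful of *planted* fully diagnostic sites per target species whose
positions are returned as ground truth.

Two guarantees make the truth table exact rather than approximate:

* planted positions are excluded from polymorphism in every record, and
  every non-target species is forced to a different base there;
* species-level substitutions that would *accidentally* create a fully
  diagnostic column for a species with a planted window are neutralised
  by copying the target base into one other species, so the set of
  diagnostic columns recovered by profiling equals the planted set.

Everything is a pure function of the spec (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seq_io import (
    GenomeRecord,
    SpeciesPanel,
    write_fasta,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = _BASES


@dataclass(frozen=True)
class PlantedWindow:
    """Request for a block of diagnostic sites for one species.

    ``n_sites`` sites are laid out as two tight clusters (a run of
    ``ceil(n/2)`` at ``position`` and the rest ending ``span`` bases
    later) so that designed outer primers can terminate on them at both
    ends of a LAMP amplicon."""

    species: str
    position: int
    n_sites: int = 6
    span: int = 190

    @property
    def site_positions(self) -> tuple[int, ...]:
        left = (self.n_sites + 1) // 2
        right = self.n_sites - left
        sites = [self.position + t for t in range(left)]
        sites += [self.position + self.span - t for t in range(right)][::-1]
        return tuple(sites)


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Parameters of one synthetic panel draw."""

    n_species: int = 7
    records_per_species: int | Sequence[int] = 1
    genome_length: int = 15000
    at_fraction: float = 0.80
    interspecies_divergence: float | Sequence[float] = 0.02
    intraspecies_polymorphism: float = 0.002
    planted_windows: tuple[PlantedWindow, ...] = ()
    circular: bool = True
    seed: int = 0
    species_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for d in np.atleast_1d(np.asarray(self.interspecies_divergence, dtype=float)):
            if not 0 < d < 0.25:
                raise ValueError("divergence must be in (0, 0.25)")
        if self.intraspecies_polymorphism >= float(
            np.min(np.atleast_1d(np.asarray(self.interspecies_divergence)))
        ):
            raise ValueError("polymorphism must be below divergence")
        taken: set[int] = set()
        for w in self.planted_windows:
            sites = w.site_positions
            if min(sites) < 0 or max(sites) >= self.genome_length:
                raise ValueError(f"planted window for {w.species} outside genome")
            if taken & set(range(w.position, w.position + w.span + 1)):
                raise ValueError("planted windows overlap")
            taken |= set(range(w.position, w.position + w.span + 1))

    @property
    def names(self) -> tuple[str, ...]:
        if self.species_names is not None:
            return self.species_names
        return tuple(f"sp{i + 1}" for i in range(self.n_species))

    @property
    def divergences(self) -> np.ndarray:
        d = np.asarray(self.interspecies_divergence, dtype=float)
        if d.ndim == 0:
            return np.full(self.n_species, float(d))
        return d

    @property
    def copies(self) -> tuple[int, ...]:
        c = self.records_per_species
        if isinstance(c, int):
            return (c,) * self.n_species
        return tuple(c)


@dataclass(frozen=True)
class PlantedTruth:
    """Realized diagnostic sites for one planted window."""

    species: str
    positions: tuple[int, ...]
    target_bases: tuple[str, ...]
    other_bases: dict  # species -> tuple of bases at each position


@dataclass(frozen=True)
class PanelTruth:
    windows: tuple[PlantedTruth, ...]

    def positions_for(self, species: str) -> tuple[int, ...]:
        out: list[int] = []
        for w in self.windows:
            if w.species == species:
                out.extend(w.positions)
        return tuple(sorted(out))

    def to_json_obj(self) -> list[dict]:
        return [
            {
                "species": w.species,
                "positions": list(w.positions),
                "target_bases": list(w.target_bases),
                "other_bases": {k: list(v) for k, v in w.other_bases.items()},
            }
            for w in self.windows
        ]


def _mutate(rng: np.random.Generator, arr: np.ndarray, positions: np.ndarray) -> None:
    """Substitute each position with a uniformly chosen different base."""
    shift = rng.integers(1, 4, size=positions.size)
    idx = np.searchsorted(_BASES, arr[positions])
    arr[positions] = _BASES[(idx + shift) % 4]


def simulate_panel(spec: SyntheticPanelSpec) -> tuple[SpeciesPanel, PanelTruth]:
    """Draw a panel and its ground-truth diagnostic sites."""
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    n = spec.n_species
    at = spec.at_fraction
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    ancestral = rng.choice(_BASES, size=L, p=probs)

    consensus = np.tile(ancestral, (n, 1))
    for i, d in enumerate(spec.divergences):
        mask = rng.random(L) < d
        _mutate(rng, consensus[i], np.flatnonzero(mask))

    names = list(spec.names)
    sp_index = {s: i for i, s in enumerate(names)}
    planted_positions: dict[str, set[int]] = {s: set() for s in names}
    all_planted: set[int] = set()

    # force planted sites: the target keeps its base and every other
    # species is set to one shared different base, so the column is
    # fully diagnostic for the owner and for nobody else
    for w in spec.planted_windows:
        ti = sp_index[w.species]
        for pos in w.site_positions:
            tb = consensus[ti, pos]
            idx = int(np.searchsorted(_BASES, tb))
            other = _BASES[(idx + int(rng.integers(1, 4))) % 4]
            for j in range(n):
                if j != ti:
                    consensus[j, pos] = other
            planted_positions[w.species].add(pos)
            all_planted.add(pos)

    # neutralise accidental fully diagnostic columns for planted species
    # by copying the target base into one sink species; sinks are drawn
    # from species without planted windows so that the identity
    # structure among the marker-carrying species stays undistorted
    planted_species = [w.species for w in spec.planted_windows]
    used_sinks: dict[int, set[int]] = {}
    for _ in range(12):
        dirty = False
        for s in planted_species:
            ti = sp_index[s]
            others = [j for j in range(n) if j != ti]
            pool = [j for j in others if names[j] not in planted_species] or others
            diff = (consensus[others] != consensus[ti]).all(axis=0)
            accidental = np.flatnonzero(diff)
            accidental = [c for c in accidental if c not in planted_positions[s]]
            if accidental:
                dirty = True
                for c in accidental:
                    # one sink per species per column: a later fix must
                    # never overwrite an earlier one, or two species
                    # unique at the same column can ping-pong forever
                    taken = used_sinks.setdefault(int(c), set())
                    free_pool = [j for j in pool if j not in taken]
                    if free_pool:
                        j = free_pool[int(rng.integers(len(free_pool)))]
                        taken.add(j)
                        consensus[j, c] = consensus[ti, c]
                    else:
                        # sinks exhausted (up to four planted species can
                        # hold four distinct bases at one column): merge
                        # the target onto an existing base instead — this
                        # removes its uniqueness and can never create a
                        # new unique base, so it is terminal
                        consensus[ti, c] = consensus[pool[0], c]
        if not dirty:
            break
    else:
        raise RuntimeError("accidental-diagnostic cleanup did not converge")

    # materialise records; polymorphism on disjoint non-planted positions
    free = np.array(sorted(set(range(L)) - all_planted))
    records: list[GenomeRecord] = []
    for i, s in enumerate(names):
        m = spec.copies[i]
        n_poly = rng.binomial(free.size, spec.intraspecies_polymorphism, size=m)
        if m == 1:
            n_poly[:] = 0  # a lone record has no within-species variation
        total = int(n_poly.sum())
        chosen = (
            rng.choice(free, size=total, replace=False)
            if total
            else np.empty(0, dtype=int)
        )
        offset = 0
        for k in range(m):
            arr = consensus[i].copy()
            take = chosen[offset : offset + n_poly[k]]
            offset += int(n_poly[k])
            if take.size:
                _mutate(rng, arr, take)
            records.append(
                GenomeRecord(
                    id=f"{s}_{k + 1}",
                    species=s,
                    sequence=arr.tobytes().decode("ascii"),
                    circular=spec.circular,
                )
            )

    truths = []
    for w in spec.planted_windows:
        ti = sp_index[w.species]
        pos = w.site_positions
        truths.append(
            PlantedTruth(
                species=w.species,
                positions=pos,
                target_bases=tuple(chr(consensus[ti, p]) for p in pos),
                other_bases={
                    s: tuple(chr(consensus[sp_index[s], p]) for p in pos)
                    for s in names
                    if s != w.species
                },
            )
        )
    return SpeciesPanel(records), PanelTruth(tuple(truths))


#: canonical 7-species panel emulating the identity structure of the
#: Spodoptera study system: a reference-like species at ~93.3-94.7%
#: identity to everything else, one near-identical pair at ~98.2%, and
#: three more distant relatives standing in for the non-target moths.
CANONICAL_NAMES = (
    "BAW_like", "FAW_like", "TCW_like", "ACL_like",
    "CBW_like", "TM_like", "RAW_like",
)
CANONICAL_DIVERGENCES = (0.047, 0.0119, 0.0081, 0.0081, 0.020, 0.022, 0.018)
CANONICAL_SEED = 883


def canonical_spec(seed: int = CANONICAL_SEED) -> SyntheticPanelSpec:
    """The canonical test panel: four target species with planted
    diagnostic windows (two records each), three outgroup species."""
    return SyntheticPanelSpec(
        n_species=7,
        records_per_species=(2, 2, 2, 2, 1, 1, 1),
        genome_length=15000,
        at_fraction=0.80,
        interspecies_divergence=CANONICAL_DIVERGENCES,
        intraspecies_polymorphism=0.002,
        planted_windows=(
            PlantedWindow("BAW_like", 1000),
            PlantedWindow("FAW_like", 3000),
            PlantedWindow("TCW_like", 5000),
            PlantedWindow("ACL_like", 7000),
        ),
        circular=True,
        seed=seed,
        species_names=CANONICAL_NAMES,
    )


def make_fixture_suite(outdir: str | Path, seed: int = CANONICAL_SEED) -> dict:
    """Write the canonical panel FASTA, its truth JSON and a copy of the
    bundled published primer table into *outdir*; returns the paths."""
    from .seq_io import bundled_primer_table, write_primer_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_panel(canonical_spec(seed))
    fasta = outdir / "canonical_panel.fasta"
    write_fasta(panel, fasta)
    truth_path = outdir / "canonical_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.to_json_obj(), fh, indent=2)
        fh.write("\n")
    primers = outdir / "published_primers.tsv"
    write_primer_table(bundled_primer_table(), primers)
    return {"fasta": fasta, "truth": truth_path, "primers": primers}
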