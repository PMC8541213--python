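"""Reading and writing the toolkit's external formats.

Genome panels travel as multi-FASTA with ``id|species`` headers (or a
sidecar TSV mapping ids to species), primer tables as a TSV dialect with
optional annotation columns, diagnostic windows as BED6, and reports as
JSON.  GenBank flat files are only consumed for feature counting.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

#: primer role vocabulary; order matters for suffix inference (FIP before F3
#: so that e.g. ``BAW_5FIP`` is not mistaken for an F3).
ROLE_SUFFIXES = ("FIP", "BIP", "F3", "B3", "LF", "LB")
UNIVERSAL_NAMES = frozenset({"LCO1490", "HCO2198"})


class SeqIOError(ValueError):
    """Raised on malformed panel, primer-table or GenBank input."""


def _clean_sequence(raw: str, context: str) -> str:
    seq = str(raw).strip().upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise SeqIOError(
                f"{context}: non-DNA character {ch!r} at position {pos}"
            )
    if not seq:
        raise SeqIOError(f"{context}: empty sequence")
    return seq


@dataclass(frozen=True)
class GenomeRecord:
    """A labeled genome sequence, circular by default (mitogenomes)."""

    id: str
    species: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _clean_sequence(self.sequence, f"record {self.id}")
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SpeciesPanel:
    """A collection of genome records grouped by species label."""

    records: list[GenomeRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SeqIOError(f"duplicate record id {rec.id!r} in panel")
            seen.add(rec.id)
        if not self.records:
            raise SeqIOError("panel contains no records")

    @property
    def species_of(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records}

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.species not in out:
                out.append(r.species)
        return out

    def records_for(self, species: str) -> list[GenomeRecord]:
        return [r for r in self.records if r.species == species]

    def __getitem__(self, record_id: str) -> GenomeRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PrimerTableRow:
    """One row of the primer-table dialect.

    ``specific_positions`` are 0-based indices into ``sequence`` flagged as
    species-diagnostic; ``padded_5prime_count`` counts non-genomic 5' bases
    added for melting-temperature adjustment (``None`` when unknown).
    """

    purpose: str
    name: str
    sequence: str
    role: str
    specific_positions: tuple[int, ...] = field(default_factory=tuple)
    padded_5prime_count: int | None = 0


def infer_role(name: str) -> str:
    """Infer a primer role from its name suffix (``universal`` for the
    mtCO1 barcode pair)."""
    if name in UNIVERSAL_NAMES:
        return "universal"
    upper = name.upper()
    for suffix in ROLE_SUFFIXES:
        if upper.endswith(suffix):
            return suffix
    raise SeqIOError(f"cannot infer primer role from name {name!r}")


def read_fasta(
    path: str | Path,
    species_map: Mapping[str, str] | str | Path | None = None,
    circular: bool = True,
) -> SpeciesPanel:
    """Read a multi-FASTA panel.

    Headers are parsed as ``id|species``; records whose header lacks a
    species label must be covered by *species_map* (a mapping or a
    two-column TSV of ``id<TAB>species``).
    """
    path = Path(path)
    if species_map is not None and not isinstance(species_map, Mapping):
        species_map = read_species_map(species_map)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, sep, species = rec.id.partition("|")
        if not sep or not species:
            if species_map and rec_id in species_map:
                species = species_map[rec_id]
            else:
                raise SeqIOError(
                    f"record {rec_id!r}: header lacks '|species' and no "
                    "species mapping covers it"
                )
        records.append(
            GenomeRecord(rec_id, species, str(rec.seq), circular=circular)
        )
    if not records:
        raise SeqIOError(f"{path}: no FASTA records found")
    return SpeciesPanel(records)


def write_fasta(panel: SpeciesPanel, path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.species}", description="")
        for r in panel.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_species_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "species"])
    return dict(zip(df["id"].astype(str), df["species"].astype(str)))


def read_primer_table(path: str | Path) -> list[PrimerTableRow]:
    """Read the primer TSV dialect (columns: purpose, name, sequence,
    optional specific_positions and padded_5prime_count)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        warnings.warn(f"{path}: empty primer table", stacklevel=2)
        return []
    required = {"purpose", "name", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise SeqIOError(f"{path}: missing columns {sorted(missing)}")
    rows: list[PrimerTableRow] = []
    for _, r in df.iterrows():
        name = str(r["name"]).strip()
        seq = _clean_sequence(r["sequence"], f"primer {name}")
        if "N" in seq:
            raise SeqIOError(f"primer {name}: N not allowed in primers")
        spec_raw = r.get("specific_positions")
        positions: tuple[int, ...] = ()
        if isinstance(spec_raw, str) and spec_raw.strip():
            positions = tuple(int(x) for x in spec_raw.split(","))
            if any(p < 0 or p >= len(seq) for p in positions):
                raise SeqIOError(f"primer {name}: specific position out of range")
        pad_raw = r.get("padded_5prime_count")
        padded = (
            int(pad_raw)
            if isinstance(pad_raw, str) and pad_raw.strip()
            else None
        )
        rows.append(
            PrimerTableRow(
                purpose=str(r["purpose"]).strip(),
                name=name,
                sequence=seq,
                role=infer_role(name),
                specific_positions=positions,
                padded_5prime_count=padded,
            )
        )
    return rows


def write_primer_table(rows: Sequence[PrimerTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "purpose": [r.purpose for r in rows],
            "name": [r.name for r in rows],
            "sequence": [r.sequence for r in rows],
            "specific_positions": [
                ",".join(map(str, r.specific_positions)) for r in rows
            ],
            "padded_5prime_count": [
                "" if r.padded_5prime_count is None else r.padded_5prime_count
                for r in rows
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def bundled_primer_table() -> list[PrimerTableRow]:
    """The published diagnostic primer set bundled with the package
    (24 LAMP primers for four target species plus the universal mtCO1
    PCR pair)."""
    ref = resources.files("lampdiag.data") / "table1_primers.tsv"
    with resources.as_file(ref) as p:
        return read_primer_table(p)


def count_genbank_features(path: str | Path, kind: str) -> int:
    """Count features of a kind (``CDS``, ``tRNA``, ``rRNA``...) across all
    records of a GenBank flat file."""
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Bio raises assorted parse errors
        raise SeqIOError(f"{path}: unparseable GenBank file: {exc}") from exc
    if not records:
        raise SeqIOError(f"{path}: no GenBank records found")
    return sum(
        1 for rec in records for f in rec.features if f.type == kind
    )


def write_bed(
    windows: Iterable,
    path: str | Path,
    chrom: str,
    name_prefix: str = "window",
) -> None:
    """Export diagnostic windows as BED6 (score = diagnostic-site count)."""
    with open(path, "w") as fh:
        for i, w in enumerate(windows, 1):
            fh.write(
                f"{chrom}\t{w.start}\t{w.end}\t{name_prefix}{i}\t{w.score}\t+\n"
            )


def write_json_report(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
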