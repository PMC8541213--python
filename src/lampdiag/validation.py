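"""Optional validation against the two published reference mitogenomes.

The *S. litura* (MZ603870) and *S. exigua* (MT702982) records are not
redistributable with the package; users who want to reproduce the
sequence-derived numbers of the source study fetch the two GenBank flat
files themselves and point this module (or ``lampdiag validate``) at
them.  Expected values:

* record lengths 15,378 bp (MZ603870) and 15,361 bp (MT702982);
* 13 CDS and 22 tRNA features in MZ603870;
* banded global alignment identity of the two genomes 94.21 ± 0.5
  percentage points (alignment-length denominator);
* the published TCW set-3 F3/B3 pair yields exactly one in-silico PCR
  amplicon of at most 500 bp on MZ603870, and the BAW set-5 pair does
  the same on MT702982.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .insilico import BindingModel, predict_pcr
from .panel_profile import global_align
from .seq_io import GenomeRecord, bundled_primer_table, count_genbank_features

EXPECTED_LENGTHS = {"MZ603870": 15378, "MT702982": 15361}
EXPECTED_FEATURES = {"CDS": 13, "tRNA": 22}
EXPECTED_IDENTITY_PCT = 94.21
IDENTITY_TOL = 0.5


@dataclass
class AccessionCheck:
    name: str
    ok: bool
    observed: object
    expected: object


def _load_genome(path: str | Path, accession: str, species: str) -> GenomeRecord:
    rec = next(SeqIO.parse(str(path), "genbank"))
    return GenomeRecord(accession, species, str(rec.seq), circular=True)


def validate_accessions(
    litura_gb: str | Path, exigua_gb: str | Path
) -> list[AccessionCheck]:
    """Run all accession-dependent checks on locally supplied GenBank
    files for MZ603870 (*S. litura*) and MT702982 (*S. exigua*)."""
    checks: list[AccessionCheck] = []
    litura = _load_genome(litura_gb, "MZ603870", "TCW")
    exigua = _load_genome(exigua_gb, "MT702982", "BAW")

    for rec in (litura, exigua):
        exp = EXPECTED_LENGTHS[rec.id]
        checks.append(
            AccessionCheck(f"length[{rec.id}]", len(rec) == exp, len(rec), exp)
        )
    for kind, exp in EXPECTED_FEATURES.items():
        obs = count_genbank_features(litura_gb, kind)
        checks.append(AccessionCheck(f"{kind}[MZ603870]", obs == exp, obs, exp))

    aln = global_align(exigua.sequence, litura.sequence)
    ident = aln.identity_pct
    checks.append(
        AccessionCheck(
            "identity[MT702982 vs MZ603870]",
            abs(ident - EXPECTED_IDENTITY_PCT) <= IDENTITY_TOL,
            round(ident, 2),
            f"{EXPECTED_IDENTITY_PCT} ± {IDENTITY_TOL}",
        )
    )

    primers = {r.name: r.sequence for r in bundled_primer_table()}
    model = BindingModel()
    for label, genome, f3, b3 in (
        ("TCW_set3_pcr[MZ603870]", litura, "TCW_3F3", "TCW_3B3"),
        ("BAW_set5_pcr[MT702982]", exigua, "BAW_5F3", "BAW_5B3"),
    ):
        amps = predict_pcr(primers[f3], primers[b3], genome, model, max_len=500)
        checks.append(
            AccessionCheck(label, len(amps) == 1, [a.length for a in amps], "1 amplicon <= 500 bp")
        )
    return checks
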