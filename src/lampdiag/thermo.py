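"""Primer physical properties: nearest-neighbor melting temperature, GC
fraction and a simple self-complementarity screen.

Tm uses the unified nearest-neighbor parameter set with a sodium-based
entropy salt correction, evaluated through Biopython's ``MeltingTemp``
machinery.  The defaults (50 mM monovalent salt, 250 nM primer) are the
conventional desk values for primer design; AT-rich mitochondrial
primers land in the high-40s to high-50s °C under this model, which is
why practitioners pad 5' G bases to lift marginal primers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.SeqUtils import MeltingTemp as _mt

from .panel_profile import revcomp

_NN_TABLES = {
    "unified": _mt.DNA_NN3,  # Allawi & SantaLucia unified parameters
    "breslauer": _mt.DNA_NN1,
    "sugimoto": _mt.DNA_NN2,
    "santalucia2004": _mt.DNA_NN4,
}


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for Tm evaluation (molar units)."""

    monovalent: float = 0.050
    primer_conc: float = 0.25e-6
    nn_set: str = "unified"

    def __post_init__(self) -> None:
        if self.monovalent <= 0 or self.primer_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.nn_set not in _NN_TABLES:
            raise ValueError(
                f"unknown NN set {self.nn_set!r}; choose from {sorted(_NN_TABLES)}"
            )


DEFAULT_CONDITIONS = ThermoConditions()


@lru_cache(maxsize=1 << 16)
def melting_temperature(
    seq: str, cond: ThermoConditions = DEFAULT_CONDITIONS
) -> float:
    """Nearest-neighbor duplex Tm in °C.

    Requires at least 8 unambiguous bases: shorter oligos are outside
    the model's sensible range, and N has no stacking parameters.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError(f"sequence too short for NN Tm ({len(seq)} < 8 nt)")
    if set(seq) - set("ACGT"):
        raise ValueError("Tm undefined for sequences with non-ACGT characters")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_NN_TABLES[cond.nn_set],
            Na=cond.monovalent * 1e3,
            dnac1=cond.primer_conc * 1e9,
            dnac2=0,
            saltcorr=5,
        )
    )


def gc_fraction(seq: str) -> float:
    """(G+C) / length, in [0, 1]."""
    seq = seq.upper()
    if not seq:
        raise ValueError("gc_fraction of empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


@lru_cache(maxsize=1 << 16)
def max_self_complementary_run(seq: str) -> int:
    """Length of the longest substring whose reverse complement also
    occurs in the sequence (a proxy for hairpin/self-dimer potential)."""
    seq = seq.upper()
    n = len(seq)
    for k in range(n, 2, -1):
        subs = {seq[i : i + k] for i in range(n - k + 1)}
        if any(revcomp(s) in subs for s in subs):
            return k
    return 0


def passes_structure_screen(seq: str, max_run: int = 5) -> bool:
    """Reject primers with a self-complementary run longer than
    *max_run* bases (default: runs of >= 6 fail)."""
    return max_self_complementary_run(seq) <= max_run
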