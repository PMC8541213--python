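"""In-silico PCR and LAMP prediction with a 3'-anchored mismatch model.

Binding is modeled as mismatch counting with a mandatory exact match in
the primer's 3'-terminal window — the biologically critical region for
polymerase extension, and the place where diagnostic sites are put by
the designer.  This deliberately reproduces the qualitative rule that
two or more species-specific 3' nucleotides confer specificity while a
single internal difference may still cross-react; it is not a
thermodynamic duplex model.

Circular templates are searched over a virtually doubled sequence, so
sites and amplicons straddling the origin are found and every verdict
is invariant under rotation of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designer import LampPrimerSet, Primer
from .panel_profile import revcomp
from .seq_io import GenomeRecord, SpeciesPanel


@dataclass(frozen=True)
class BindingModel:
    """Mismatch-tolerance model for primer annealing."""

    exact_3prime: int = 2
    max_mismatches: int = 2
    min_length: int = 15

    def __post_init__(self) -> None:
        if self.exact_3prime < 1:
            raise ValueError("exact_3prime must be >= 1")


DEFAULT_MODEL = BindingModel()


@dataclass(frozen=True)
class BindingSite:
    """One predicted annealing site.

    ``position`` is the genome coordinate of the primer's 3'-terminal
    base; ``footprint_start`` the leftmost genome coordinate of the
    duplex.  ``mismatch_positions`` are primer-relative (0 = 5' end).
    """

    genome_id: str
    position: int
    strand: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    footprint_start: int


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    length: int


@dataclass
class AmplificationCall:
    """Combined PCR/LAMP verdict for one primer set on one genome."""

    genome_id: str
    pcr_positive: bool
    pcr_amplicons: list[Amplicon]
    lamp_positive: bool
    missing_or_misordered: list[str] = field(default_factory=list)
    loop_risk: bool = False
    loop_binders: list[str] = field(default_factory=list)

    @property
    def cell(self) -> str:
        """Matrix cell notation: '+', '-', or '-!loop'."""
        if self.lamp_positive:
            return "+"
        return "-!loop" if self.loop_risk else "-"


def _as_sequence(primer: Primer | str) -> str:
    if isinstance(primer, Primer):
        return primer.genomic_sequence
    return str(primer).upper()


def _scan(genome_seq: str, query: str, circular: bool):
    """Mismatch counts of *query* against every window of the genome
    (doubled when circular); returns (mismatch matrix row count array,
    per-window boolean of each query offset matching)."""
    L = len(query)
    gg = genome_seq + (genome_seq[: L - 1] if circular else "")
    if len(gg) < L:
        return None, None, 0
    arr = np.frombuffer(gg.encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    nwin = len(gg) - L + 1
    mism = np.zeros(nwin, dtype=np.int32)
    per_offset = np.empty((L, nwin), dtype=bool)
    for k in range(L):
        neq = arr[k : k + nwin] != q[k]
        per_offset[k] = neq
        mism += neq
    return mism, per_offset, nwin


def find_binding_sites(
    primer: Primer | str,
    genome: GenomeRecord,
    model: BindingModel = DEFAULT_MODEL,
) -> list[BindingSite]:
    """All annealing sites of *primer* on both strands of *genome*.

    A site requires an exact match over the primer's 3'-terminal
    ``model.exact_3prime`` bases and at most ``model.max_mismatches``
    mismatches overall.  Non-genomic 5' padding bases of designed
    primers are excluded from the duplex.
    """
    seq = _as_sequence(primer)
    if len(seq) < model.min_length:
        raise ValueError(
            f"primer ({len(seq)} nt) shorter than model minimum {model.min_length}"
        )
    g = genome.sequence
    N = len(g)
    e = model.exact_3prime
    sites: list[BindingSite] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        mism, per_offset, nwin = _scan(g, query, genome.circular)
        if mism is None:
            continue
        L = len(query)
        # primer 3'-terminal window: last offsets for '+', first for '-'
        if strand == "+":
            three_prime = per_offset[L - e :].any(axis=0)
        else:
            three_prime = per_offset[:e].any(axis=0)
        ok = (mism <= model.max_mismatches) & ~three_prime
        starts = np.flatnonzero(ok)
        for s in starts:
            if s >= N:  # duplicate of a wrapped site
                continue
            offsets = np.flatnonzero(per_offset[:, s])
            if strand == "+":
                mpos = tuple(int(o) for o in offsets)
                pos3 = (s + L - 1) % N
            else:
                mpos = tuple(sorted(int(L - 1 - o) for o in offsets))
                pos3 = int(s)
            sites.append(
                BindingSite(
                    genome_id=genome.id,
                    position=int(pos3),
                    strand=strand,
                    mismatch_count=int(mism[s]),
                    mismatch_positions=mpos,
                    footprint_start=int(s),
                )
            )
    sites.sort(key=lambda b: (b.footprint_start, b.strand))
    return sites


def predict_pcr(
    f3: Primer | str,
    b3: Primer | str,
    genome: GenomeRecord,
    model: BindingModel = DEFAULT_MODEL,
    max_len: int = 2000,
) -> list[Amplicon]:
    """Convergent amplicons of a primer pair, 5'-to-5' inclusive length.

    Both assignment orientations are considered (either primer may act
    as the forward one), matching how a pair behaves in a reaction.
    """
    fa = _as_sequence(f3)
    fb = _as_sequence(b3)
    sites_a = find_binding_sites(fa, genome, model)
    sites_b = find_binding_sites(fb, genome, model)
    N = len(genome.sequence)
    out: set[tuple[int, int]] = set()
    for fwd_sites, rev_sites, rev_len in (
        (sites_a, sites_b, len(fb)),
        (sites_b, sites_a, len(fa)),
    ):
        for fs in fwd_sites:
            if fs.strand != "+":
                continue
            five_f = fs.footprint_start
            for rs in rev_sites:
                if rs.strand != "-":
                    continue
                five_r = rs.footprint_start + rev_len - 1
                delta = five_r - five_f
                if genome.circular:
                    delta %= N
                elif delta < 0:
                    continue
                length = delta + 1
                if length <= max_len:
                    out.add((five_f, length))
    return sorted(
        Amplicon(start=s, end=s + ln, length=ln) for s, ln in out
    )


#: annealing orientation of each LAMP region part on the template that
#: carries F3..B3 left to right on its forward strand
_ROLE_ORIENT = {
    "F3": "+", "F2": "+", "F1c": "-", "B1": "+", "B2c": "-", "B3": "-",
    "LF": "-", "LB": "+",
}
_CORE_ORDER = ("F3", "F2", "F1c", "B1", "B2c", "B3")


def _core_geometry(
    parts: dict[str, str],
    genome: GenomeRecord,
    model: BindingModel,
    max_product: int,
) -> tuple[bool, list[str]]:
    """Check the six core regions bind with dumbbell-compatible order
    and strand within *max_product* on this template orientation."""
    footprints: dict[str, list[int]] = {}
    missing: list[str] = []
    for role in _CORE_ORDER:
        seq = parts[role]
        want = _ROLE_ORIENT[role]
        sites = [
            s for s in find_binding_sites(seq, genome, model) if s.strand == want
        ]
        if not sites:
            missing.append(role)
        footprints[role] = [s.footprint_start for s in sites]
    if missing:
        return False, missing
    N = len(genome.sequence)
    lengths = {role: len(parts[role]) for role in _CORE_ORDER}
    for s0 in footprints["F3"]:
        cursor = lengths["F3"]  # relative end of previous region
        ok = True
        for role in _CORE_ORDER[1:]:
            rels = []
            for s in footprints[role]:
                rel = (s - s0) % N if genome.circular else s - s0
                if rel >= cursor:
                    rels.append(rel)
            if not rels:
                ok = False
                break
            best = min(rels)
            cursor = best + lengths[role]
            if cursor > max_product:
                ok = False
                break
        if ok:
            return True, []
    return False, ["geometry"]


def predict_lamp(
    lamp_set: LampPrimerSet,
    genome: GenomeRecord,
    model: BindingModel = DEFAULT_MODEL,
    max_product: int = 500,
) -> AmplificationCall:
    """Amplification verdict of a six-primer set on one genome.

    Positive iff all six core regions (FIP/BIP decomposed into their
    parts) bind with correct strands and ordering within *max_product*;
    the template is checked in both orientations.  Loop primers never
    make a call positive — when one binds a genome whose core call is
    negative it only raises ``loop_risk``, reflecting the non-specific
    amplification loop primers are known to cause in close relatives.
    """
    core = lamp_set.core_primers()
    parts = {role: p.genomic_sequence for role, p in core.items()}
    positive, missing = _lamp_parts_call(parts, genome, model, max_product)

    loop_binders: list[str] = []
    for role, p in (("LF", lamp_set.lf), ("LB", lamp_set.lb)):
        if p is None:
            continue
        if find_binding_sites(p, genome, model):
            loop_binders.append(role)
    amps = predict_pcr(lamp_set.f3, lamp_set.b3, genome, model, max_len=max_product)
    return AmplificationCall(
        genome_id=genome.id,
        pcr_positive=bool(amps),
        pcr_amplicons=amps,
        lamp_positive=positive,
        missing_or_misordered=missing,
        loop_risk=bool(loop_binders) and not positive,
        loop_binders=loop_binders,
    )


def _lamp_parts_call(
    parts: dict[str, str],
    genome: GenomeRecord,
    model: BindingModel,
    max_product: int,
) -> tuple[bool, list[str]]:
    for role in _CORE_ORDER:
        if role not in parts or not parts[role]:
            raise ValueError(f"LAMP set is missing core role {role}")
    positive, missing = _core_geometry(parts, genome, model, max_product)
    if positive:
        return True, []
    flipped = GenomeRecord(
        genome.id, genome.species, revcomp(genome.sequence), genome.circular
    )
    positive_rc, missing_rc = _core_geometry(parts, flipped, model, max_product)
    if positive_rc:
        return True, []
    return False, missing if len(missing) <= len(missing_rc) else missing_rc


def predict_lamp_components(
    components: dict[str, str],
    genome: GenomeRecord,
    model: BindingModel = DEFAULT_MODEL,
    max_product: int = 500,
    min_part: int = 15,
) -> AmplificationCall:
    """Verdict from assembled primers (F3, B3, FIP, BIP, optional
    LF/LB) when the FIP/BIP split points are unknown, e.g. primers read
    from a published table.  Every admissible split of FIP into
    F1c|F2 and BIP into B1|B2c is tried; the call is positive when any
    split satisfies the core geometry.
    """
    for role in ("F3", "B3", "FIP", "BIP"):
        if role not in components:
            raise ValueError(f"missing component {role}")
    fip = components["FIP"].upper()
    bip = components["BIP"].upper()
    base = {"F3": components["F3"].upper(), "B3": components["B3"].upper()}
    positive = False
    missing: list[str] = ["FIP", "BIP"]
    for i in range(min_part, len(fip) - min_part + 1):
        for j in range(min_part, len(bip) - min_part + 1):
            parts = dict(
                base, F1c=fip[:i], F2=fip[i:], B1=bip[:j], B2c=bip[j:]
            )
            pos, miss = _lamp_parts_call(parts, genome, model, max_product)
            if pos:
                positive = True
                missing = []
                break
            if len(miss) < len(missing):
                missing = miss
        if positive:
            break
    loop_binders = [
        role
        for role in ("LF", "LB")
        if components.get(role)
        and find_binding_sites(components[role], genome, model)
    ]
    amps = predict_pcr(
        components["F3"], components["B3"], genome, model, max_len=max_product
    )
    return AmplificationCall(
        genome_id=genome.id,
        pcr_positive=bool(amps),
        pcr_amplicons=amps,
        lamp_positive=positive,
        missing_or_misordered=missing,
        loop_risk=bool(loop_binders) and not positive,
        loop_binders=loop_binders,
    )


@dataclass
class SpecificityMatrix:
    """Calls of every set against every panel genome."""

    set_names: list[str]
    set_targets: dict[str, str]
    calls: dict[tuple[str, str], AmplificationCall]
    panel: SpeciesPanel

    @property
    def diagonal_ok(self) -> bool:
        """True when every set is positive on every genome of its own
        target species and negative on all others."""
        for name in self.set_names:
            target = self.set_targets[name]
            for rec in self.panel.records:
                call = self.calls[(name, rec.id)]
                if (rec.species == target) != call.lamp_positive:
                    return False
        return True

    @property
    def off_target(self) -> list[tuple[str, str]]:
        return [
            (name, rec.id)
            for name in self.set_names
            for rec in self.panel.records
            if rec.species != self.set_targets[name]
            and self.calls[(name, rec.id)].lamp_positive
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                rec.id: [
                    self.calls[(name, rec.id)].cell for name in self.set_names
                ]
                for rec in self.panel.records
            },
            index=self.set_names,
        )


def specificity_matrix(
    sets: list[LampPrimerSet],
    panel: SpeciesPanel,
    model: BindingModel = DEFAULT_MODEL,
    max_product: int = 500,
) -> SpecificityMatrix:
    """Cross-species verdict matrix (rows = sets, columns = genomes)."""
    calls: dict[tuple[str, str], AmplificationCall] = {}
    names: list[str] = []
    targets: dict[str, str] = {}
    for s in sets:
        name = s.name or f"{s.target_species}_set"
        names.append(name)
        targets[name] = s.target_species
        for rec in panel.records:
            calls[(name, rec.id)] = predict_lamp(s, rec, model, max_product)
    return SpecificityMatrix(names, targets, calls, panel)
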