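"""Enumeration and ranking of species-specific LAMP primer sets.

A LAMP set recognizes six regions laid out on the reference as

    F3 > F2 > (LF) > F1 > B1 > (LB) > B2 > B3

with F-side priming primers (F3, F2) on the forward strand and B-side
priming primers (B3, B2) on the reverse strand.  The inner primers are
concatenations: FIP = F1c + F2 and BIP = B1 + B2c, where F1c and B2c
are reverse complements of the forward-strand F1/B2 regions and B1 is
the forward-strand B1 region itself.

Species specificity is enforced where it matters for discrimination:
the outer primers F3 and B3 must carry diagnostic sites in their
3'-terminal window (two or more by default; a single terminal site is
accepted only as a fallback when no two-site candidate exists anywhere,
mirroring how real marker panels occasionally have to settle for one).

Default physical constraints are calibrated to envelope a published
Spodoptera diagnostic set designed on ~80% AT mitochondrial genomes:
such primers run long (up to 30 nt), AT-rich (GC as low as 0.11) and
cool (outer Tm ~51-57 °C under the unified NN model), so conventional
PrimerExplorer windows would reject all of them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from .panel_profile import (
    DiagnosticWindow,
    SiteProfile,
    build_msa,
    find_windows,
    revcomp,
    site_profile,
)
from .seq_io import GenomeRecord, SpeciesPanel
from .thermo import (
    DEFAULT_CONDITIONS,
    ThermoConditions,
    gc_fraction,
    max_self_complementary_run,
    melting_temperature,
)

logger = logging.getLogger(__name__)

#: genomic roles on the forward strand; all others anneal reverse
PLUS_ROLES = frozenset({"F3", "F2", "B1", "LB"})
MINUS_ROLES = frozenset({"F1c", "B2c", "B3", "LF"})
GENOMIC_ROLES = PLUS_ROLES | MINUS_ROLES
CORE_ROLES = ("F3", "F2", "F1c", "B1", "B2c", "B3")


@dataclass(frozen=True)
class Primer:
    """A primer (or inner-primer part) with optional reference placement.

    ``ref_start``/``ref_end`` are 0-based half-open on the reference;
    ``padded_5prime`` counts non-genomic 5' G/C bases prepended for Tm
    adjustment (they are part of ``sequence`` but not of the genomic
    footprint).
    """

    name: str
    role: str
    sequence: str
    ref_start: int | None = None
    ref_end: int | None = None
    strand: str | None = None
    padded_5prime: int = 0

    @property
    def genomic_sequence(self) -> str:
        return self.sequence[self.padded_5prime :]

    @property
    def three_prime_ref(self) -> int:
        """Reference coordinate of the 3'-terminal base."""
        if self.ref_start is None or self.ref_end is None:
            raise ValueError(f"primer {self.name} has no reference coordinates")
        return self.ref_end - 1 if self.strand == "+" else self.ref_start

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LampPrimerSet:
    """A complete six-region LAMP set (loop primers optional)."""

    target_species: str
    f3: Primer
    f2: Primer
    f1c: Primer
    b1: Primer
    b2c: Primer
    b3: Primer
    lf: Primer | None = None
    lb: Primer | None = None
    name: str = ""

    @property
    def fip(self) -> Primer:
        return assemble_inner(self.f1c, self.f2)

    @property
    def bip(self) -> Primer:
        return assemble_inner(self.b1, self.b2c)

    @property
    def product_span(self) -> int:
        """F3 start through B3 end on the reference (outer PCR product)."""
        return self.b3.ref_end - self.f3.ref_start

    def core_primers(self) -> dict[str, Primer]:
        return {
            "F3": self.f3,
            "F2": self.f2,
            "F1c": self.f1c,
            "B1": self.b1,
            "B2c": self.b2c,
            "B3": self.b3,
        }

    def all_primers(self) -> dict[str, Primer]:
        out = self.core_primers()
        if self.lf is not None:
            out["LF"] = self.lf
        if self.lb is not None:
            out["LB"] = self.lb
        return out


@dataclass(frozen=True)
class DesignConstraints:
    """Physical and geometric bounds for candidate primers and sets.

    ``inner_span`` bounds the distance from the F2 start to the B2 end
    (the region copied into the dumbbell); ``max_product`` caps the
    outer F3→B3 span so the confirmation PCR stays fast.
    """

    length: dict = field(
        default_factory=lambda: {
            "F3": (18, 30), "B3": (18, 30),
            "F2": (18, 28), "B2c": (18, 28),
            "F1c": (18, 28), "B1": (18, 28),
            "LF": (18, 30), "LB": (18, 30),
        }
    )
    tm: dict = field(
        default_factory=lambda: {
            "F3": (46.0, 63.0), "B3": (46.0, 63.0),
            "F2": (46.0, 63.0), "B2c": (46.0, 63.0),
            "F1c": (46.0, 66.0), "B1": (46.0, 66.0),
            "LF": (43.0, 60.0), "LB": (43.0, 60.0),
        }
    )
    tm_target: dict = field(
        default_factory=lambda: {
            "F3": 55.0, "B3": 55.0, "F2": 55.0, "B2c": 55.0,
            "F1c": 58.0, "B1": 58.0, "LF": 52.0, "LB": 52.0,
        }
    )
    gc: tuple[float, float] = (0.02, 0.60)
    f3_f2_gap: tuple[int, int] = (0, 40)
    inner_span: tuple[int, int] = (120, 260)
    max_product: int = 500
    min_specific_3prime: int = 2
    specific_3prime_window: int = 3
    allow_padding: bool = True
    max_padding: int = 3
    max_self_comp_run: int = 16
    #: primers are placed where the target species shows no
    #: within-species variation: the 3'-terminal bases must be
    #: target-invariant columns and at most ``max_variable_columns``
    #: variable columns are tolerated in the whole footprint (so every
    #: intra-species variant still binds under the mismatch model)
    invariant_3prime: int = 4
    max_variable_columns: int = 2


class DesignError(ValueError):
    pass


def specific_3prime_count(
    primer: Primer, profile: SiteProfile, window: int = 3
) -> int:
    """Number of fully diagnostic columns within the primer's 3'-terminal
    *window* bases, respecting strand orientation."""
    if primer.ref_start is None or primer.strand is None:
        raise DesignError(f"primer {primer.name} is not mapped to the reference")
    mask = profile.diagnostic_mask
    if primer.strand == "+":
        lo, hi = primer.ref_end - window, primer.ref_end
    else:
        lo, hi = primer.ref_start, primer.ref_start + window
    lo = max(lo, 0)
    hi = min(hi, len(mask))
    return int(mask[lo:hi].sum())


def pad_5prime(
    primer: Primer,
    target_tm: float,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
    max_padding: int = 3,
) -> tuple[Primer, bool]:
    """Prepend the minimal number of 5' G bases (at most *max_padding*)
    needed to reach *target_tm*.

    Returns ``(primer, reached)``; the primer is returned unchanged with
    ``reached=False`` when even full padding falls short.
    """
    for g in range(max_padding + 1):
        seq = "G" * g + primer.sequence
        if melting_temperature(seq, cond) >= target_tm:
            if g == 0:
                return primer, True
            return (
                replace(
                    primer,
                    sequence=seq,
                    padded_5prime=primer.padded_5prime + g,
                ),
                True,
            )
    return primer, False


def assemble_inner(outer_c: Primer, inner: Primer) -> Primer:
    """Concatenate inner-primer parts: F1c+F2 → FIP, B1+B2c → BIP."""
    pair = (outer_c.role, inner.role)
    if pair == ("F1c", "F2"):
        role = "FIP"
    elif pair == ("B1", "B2c"):
        role = "BIP"
    else:
        raise DesignError(f"cannot assemble inner primer from roles {pair}")
    return Primer(
        name=f"{outer_c.name}+{inner.name}",
        role=role,
        sequence=outer_c.sequence + inner.sequence,
        padded_5prime=outer_c.padded_5prime,
    )


def _role_primer(
    reference: GenomeRecord, role: str, start: int, end: int
) -> Primer:
    region = reference.sequence[start:end]
    strand = "+" if role in PLUS_ROLES else "-"
    seq = region if strand == "+" else revcomp(region)
    return Primer(
        name=f"{role}_{start}",
        role=role,
        sequence=seq,
        ref_start=start,
        ref_end=end,
        strand=strand,
    )


def enumerate_role_candidates(
    reference: GenomeRecord,
    profile: SiteProfile,
    window: DiagnosticWindow,
    role: str,
    constraints: DesignConstraints = DesignConstraints(),
    cond: ThermoConditions = DEFAULT_CONDITIONS,
    region: tuple[int, int] | None = None,
) -> list[Primer]:
    """All primers of *role* inside the window (or an explicit region)
    passing length, Tm, GC and self-structure screens; F3/B3 candidates
    additionally need ``min_specific_3prime`` diagnostic 3' bases."""
    if role not in GENOMIC_ROLES:
        raise DesignError(f"role {role!r} is not a genomic role")
    lo, hi = region if region is not None else (window.start, window.end)
    lo = max(0, lo)
    hi = min(len(reference.sequence), hi)
    len_lo, len_hi = constraints.length[role]
    tm_lo, tm_hi = constraints.tm[role]
    invariant = profile.target_invariant
    strand = "+" if role in PLUS_ROLES else "-"
    out: list[Primer] = []
    for start in range(lo, hi):
        for length in range(len_lo, len_hi + 1):
            end = start + length
            if end > hi:
                break
            region_seq = reference.sequence[start:end]
            if "N" in region_seq:
                continue
            variable = ~invariant[start:end]
            if variable.sum() > constraints.max_variable_columns:
                continue
            k = constraints.invariant_3prime
            tail = variable[-k:] if strand == "+" else variable[:k]
            if tail.any():
                continue
            g = gc_fraction(region_seq)
            if not (constraints.gc[0] <= g <= constraints.gc[1]):
                continue
            primer = _role_primer(reference, role, start, end)
            if role in ("F3", "B3"):
                nspec = specific_3prime_count(
                    primer, profile, constraints.specific_3prime_window
                )
                if nspec < constraints.min_specific_3prime:
                    continue
            tm = melting_temperature(primer.sequence, cond)
            if not (tm_lo <= tm <= tm_hi):
                if constraints.allow_padding and tm < tm_lo:
                    primer, reached = pad_5prime(
                        primer, tm_lo, cond, constraints.max_padding
                    )
                    if not reached:
                        continue
                    if melting_temperature(primer.sequence, cond) > tm_hi:
                        continue
                else:
                    continue
            if max_self_complementary_run(primer.sequence) > constraints.max_self_comp_run:
                continue
            out.append(primer)
    return out


def _tm_closeness(primers: dict[str, Primer], constraints, cond) -> float:
    return sum(
        abs(melting_temperature(p.sequence, cond) - constraints.tm_target[role])
        for role, p in primers.items()
        if role in constraints.tm_target
    )


def validate_set(
    s: LampPrimerSet,
    constraints: DesignConstraints,
    profile: SiteProfile | None = None,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
) -> list[str]:
    """Independent constraint check; returns a list of violations
    (empty when the set is fully compliant)."""
    problems: list[str] = []
    primers = s.all_primers()
    for role, p in primers.items():
        lo, hi = constraints.length[role]
        if not (lo <= len(p.genomic_sequence) <= hi):
            problems.append(f"{role}: genomic length {len(p.genomic_sequence)} outside [{lo},{hi}]")
        tm = melting_temperature(p.sequence, cond)
        tlo, thi = constraints.tm[role]
        if not (tlo <= tm <= thi):
            problems.append(f"{role}: Tm {tm:.1f} outside [{tlo},{thi}]")
        g = gc_fraction(p.genomic_sequence)
        if not (constraints.gc[0] <= g <= constraints.gc[1]):
            problems.append(f"{role}: GC {g:.2f} outside {constraints.gc}")
        if max_self_complementary_run(p.sequence) > constraints.max_self_comp_run:
            problems.append(f"{role}: self-complementary run too long")
    order = [s.f3, s.f2, s.f1c, s.b1, s.b2c, s.b3]
    for left, right in zip(order, order[1:]):
        if left.ref_end > right.ref_start:
            problems.append(
                f"ordering violated: {left.role} ends {left.ref_end} after "
                f"{right.role} starts {right.ref_start}"
            )
    if s.lf is not None and not (
        s.f2.ref_end <= s.lf.ref_start and s.lf.ref_end <= s.f1c.ref_start
    ):
        problems.append("LF not between F2 and F1")
    if s.lb is not None and not (
        s.b1.ref_end <= s.lb.ref_start and s.lb.ref_end <= s.b2c.ref_start
    ):
        problems.append("LB not between B1 and B2")
    gap = s.f2.ref_start - s.f3.ref_end
    if not (constraints.f3_f2_gap[0] <= gap <= constraints.f3_f2_gap[1]):
        problems.append(f"F3-F2 gap {gap} outside {constraints.f3_f2_gap}")
    inner = s.b2c.ref_end - s.f2.ref_start
    if not (constraints.inner_span[0] <= inner <= constraints.inner_span[1]):
        problems.append(f"inner span {inner} outside {constraints.inner_span}")
    if s.product_span > constraints.max_product:
        problems.append(f"product span {s.product_span} > {constraints.max_product}")
    if profile is not None:
        for p in (s.f3, s.b3):
            n = specific_3prime_count(p, profile, constraints.specific_3prime_window)
            if n < constraints.min_specific_3prime:
                problems.append(
                    f"{p.role}: only {n} diagnostic 3' site(s), "
                    f"need {constraints.min_specific_3prime}"
                )
    return problems


def design_sets(
    panel: SpeciesPanel,
    target: str,
    constraints: DesignConstraints = DesignConstraints(),
    top_k: int = 5,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
    reference_id: str | None = None,
    min_sites: int = 3,
) -> list[LampPrimerSet]:
    """Design ranked species-specific LAMP sets for *target*.

    Deterministic: candidates are enumerated in coordinate order and
    ranked by (diagnostic 3'
    sites on F3+B3 descending, summed Tm distance from role targets
    ascending, product span ascending, F3 start).  When no
    F3/B3 candidate carries the required number of diagnostic 3' sites
    the requirement is relaxed to a single terminal site before giving
    up, mirroring markers that have to settle for one specific base.
    """
    if target not in panel.species:
        raise DesignError(f"target species {target!r} not in panel")
    if len(panel.species) < 2:
        logger.info("panel has no non-target species; nothing to discriminate")
        return []
    if reference_id is None:
        reference_id = min(r.id for r in panel.records_for(target))
    reference = panel[reference_id]
    msa = build_msa(panel, reference_id)
    profile = site_profile(msa, panel, target)
    windows = find_windows(profile, min_sites=min_sites, window_len=constraints.max_product)
    if not windows:
        logger.info("no diagnostic window found for %s", target)
        return []
    results: list[tuple[tuple, LampPrimerSet]] = []
    for relax in (False, True):
        active = constraints
        if relax:
            if results or constraints.min_specific_3prime <= 1:
                break
            active = replace(constraints, min_specific_3prime=1)
            logger.info(
                "no set with >=%d diagnostic 3' sites for %s; retrying with 1",
                constraints.min_specific_3prime, target,
            )
        for window in windows[:3]:
            results.extend(
                _design_in_window(reference, profile, window, active, cond, target)
            )
    results.sort(key=lambda t: t[0])
    out = []
    for rank, (_, s) in enumerate(results[:top_k], 1):
        out.append(replace(s, name=f"{target}_set{rank}"))
    return out


def _candidate_arrays(cands, constraints, cond):
    import numpy as np

    starts = np.array([p.ref_start for p in cands], dtype=np.int64)
    ends = np.array([p.ref_end for p in cands], dtype=np.int64)
    closeness = np.array(
        [
            abs(melting_temperature(p.sequence, cond) - constraints.tm_target[p.role])
            for p in cands
        ]
    )
    return starts, ends, closeness, list(cands)


def _best_of(arrays, mask, k):
    import numpy as np

    starts, _ends, closeness, prims = arrays
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    order = np.lexsort((starts[idx], closeness[idx]))
    return [prims[i] for i in idx[order[:k]]]


def _design_in_window(
    reference: GenomeRecord,
    profile: SiteProfile,
    window: DiagnosticWindow,
    constraints: DesignConstraints,
    cond: ThermoConditions,
    target: str,
    per_role_cap: int = 10,
    max_outer_pairs: int = 40,
) -> list[tuple[tuple, LampPrimerSet]]:
    # widen the search region so outer primers can extend past the
    # outermost diagnostic sites
    margin = max(constraints.length["F3"][1], constraints.length["B3"][1]) + 5
    lo = max(0, window.start - margin)
    hi = min(len(reference.sequence), window.end + margin)
    region = (lo, hi)

    def cands(role):
        got = enumerate_role_candidates(
            reference, profile, window, role, constraints, cond, region=region
        )
        got.sort(key=lambda p: (p.ref_start, p.ref_end))
        return got

    f3s = cands("F3")
    b3s = cands("B3")
    if not f3s or not b3s:
        return []
    inner = {
        role: _candidate_arrays(cands(role), constraints, cond)
        for role in ("F2", "B2c", "F1c", "B1")
    }

    def spec(p):
        return specific_3prime_count(p, profile, constraints.specific_3prime_window)

    pairs = []
    for f3, b3 in itertools.product(f3s, b3s):
        span = b3.ref_end - f3.ref_start
        inner_room = b3.ref_start - f3.ref_end
        if span > constraints.max_product:
            continue
        if inner_room < constraints.inner_span[0]:
            continue
        pairs.append((-(spec(f3) + spec(b3)), f3.ref_start, b3.ref_start, f3, b3))
    pairs.sort(key=lambda t: t[:3])
    out: list[tuple[tuple, LampPrimerSet]] = []
    for neg_spec, _, _, f3, b3 in pairs[:max_outer_pairs]:
        filled = _fill_inner(inner, f3, b3, constraints, per_role_cap)
        if filled is None:
            continue
        f2, f1c, b1, b2c = filled
        lf = _best_loop(reference, profile, "LF", f2.ref_end, f1c.ref_start, constraints, cond)
        lb = _best_loop(reference, profile, "LB", b1.ref_end, b2c.ref_start, constraints, cond)
        s = LampPrimerSet(
            target_species=target,
            f3=f3, f2=f2, f1c=f1c, b1=b1, b2c=b2c, b3=b3, lf=lf, lb=lb,
        )
        if validate_set(s, constraints, profile, cond):
            continue
        key = (
            neg_spec,
            round(_tm_closeness(s.core_primers(), constraints, cond), 3),
            max(
                max_self_complementary_run(p.sequence)
                for p in s.core_primers().values()
            ),
            s.product_span,
            f3.ref_start,
        )
        out.append((key, s))
    return out


def _fill_inner(inner, f3, b3, constraints, cap):
    """Pick compliant F2/F1c/B1/B2c between the outer pair, preferring
    Tm close to role targets; deterministic greedy over vectorised
    positional filters."""
    gap_lo, gap_hi = constraints.f3_f2_gap
    inner_lo, inner_hi = constraints.inner_span
    min_f1 = constraints.length["F1c"][0]
    min_b1 = constraints.length["B1"][0]
    s2, e2 = inner["F2"][0], inner["F2"][1]
    sb, eb = inner["B2c"][0], inner["B2c"][1]
    s1, e1 = inner["F1c"][0], inner["F1c"][1]
    sb1, eb1 = inner["B1"][0], inner["B1"][1]

    f2_mask = (
        (s2 >= f3.ref_end + gap_lo)
        & (s2 <= f3.ref_end + gap_hi)
        & (e2 < b3.ref_start)
    )
    for f2 in _best_of(inner["F2"], f2_mask, cap):
        b2_mask = (
            (sb >= f2.ref_end + min_f1 + min_b1)  # room for F1 and B1
            & (eb - f2.ref_start >= inner_lo)
            & (eb - f2.ref_start <= inner_hi)
            & (b3.ref_start - eb >= gap_lo)
            & (b3.ref_start - eb <= gap_hi)
        )
        for b2c in _best_of(inner["B2c"], b2_mask, cap):
            f1_mask = (s1 >= f2.ref_end) & (e1 <= b2c.ref_start - min_b1)
            for f1c in _best_of(inner["F1c"], f1_mask, cap):
                b1_pick = _best_of(
                    inner["B1"], (sb1 >= f1c.ref_end) & (eb1 <= b2c.ref_start), 1
                )
                if b1_pick:
                    return f2, f1c, b1_pick[0], b2c
    return None


def _best_loop(reference, profile, role, lo, hi, constraints, cond):
    if hi - lo < constraints.length[role][0]:
        return None
    dummy = DiagnosticWindow(lo, hi, (), 0)
    got = enumerate_role_candidates(
        reference, profile, dummy, role, constraints, cond, region=(lo, hi)
    )
    if not got:
        return None
    got.sort(
        key=lambda p: (
            abs(melting_temperature(p.sequence, cond) - constraints.tm_target[role]),
            p.ref_start,
        )
    )
    return got[0]
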