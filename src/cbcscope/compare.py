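"""Variable-site detection, CBC/hemi-CBC classification, gap-aware distances.

The central operation classifies each change at a paired site between two
sequences:

* **CBC** (compensatory base change): both partners of a base pair differ and
  both the old and the new pair are complementary (e.g. G·C → A·U). A CBC is one
  event covering its two columns.
* **hemi-CBC**: exactly one partner differs and complementarity is conserved
  (e.g. G·C → G·U).
* **uncoupled**: a change at a paired site that leaves at least one of the two
  states non-complementary.
* **loop substitution**: a change at an unpaired (single-stranded) column.
* **indel**: a column where one row holds a residue and the other a gap.

G·U wobble counts as complementary, as is standard for rRNA helices.

Two gap policies mirror the two ways divergence is quoted for spacer regions:
``COUNT_GAPS`` treats every residue-vs-gap column as one differing site with all
(unmasked) columns in the denominator; ``EXCLUDE_GAPS`` removes gap-containing
columns from both numerator and denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import UndefinedDistanceError
from .seqio import CANONICAL, GAP, PairwiseAlignment
from .structure import StructuredAlignment, is_complementary


class GapMode(enum.Enum):
    COUNT_GAPS = "count-gaps"
    EXCLUDE_GAPS = "exclude-gaps"


@dataclass(frozen=True)
class GapPolicy:
    """How gap columns enter site counts and distance denominators."""

    mode: GapMode = GapMode.COUNT_GAPS
    mask_primer: bool = True
    mask_ambiguity: bool = True


class SiteClass(enum.Enum):
    CBC = "CBC"
    HEMI_CBC = "hemi-CBC"
    UNCOUPLED = "uncoupled"
    LOOP_SUBSTITUTION = "loop-substitution"
    INDEL = "indel"


class Context(enum.Enum):
    PAIRED = "paired"
    UNPAIRED = "unpaired"


@dataclass(frozen=True)
class SiteChange:
    """One variable site (or paired couple) between the two rows."""

    columns: tuple  # one column, or both partner columns for CBC/hemi-CBC
    states_a: tuple
    states_b: tuple
    context: Context
    klass: SiteClass
    helix: Optional[str] = None

    def to_record(self) -> dict:
        return {
            "column": self.columns[0],
            "partner": self.columns[1] if len(self.columns) == 2 else "",
            "helix": self.helix or "",
            "states_a": "".join(self.states_a),
            "states_b": "".join(self.states_b),
            "context": self.context.value,
            "class": self.klass.value,
        }


@dataclass(frozen=True)
class ComparisonReport:
    """Summary of a structure-aware pairwise comparison."""

    variable_sites_with_gaps: int
    variable_sites_no_gaps: int
    class_counts: Mapping[str, int]
    per_helix: Mapping[str, int]
    distance_with_gaps: float
    distance_no_gaps: float
    changes: Sequence[SiteChange] = field(default_factory=tuple)
    ambiguous_columns: Sequence[int] = field(default_factory=tuple)

    def summary(self) -> dict:
        return {
            "variable_sites_with_gaps": self.variable_sites_with_gaps,
            "variable_sites_no_gaps": self.variable_sites_no_gaps,
            "class_counts": dict(self.class_counts),
            "per_helix": dict(self.per_helix),
            "distance_with_gaps": self.distance_with_gaps,
            "distance_no_gaps": self.distance_no_gaps,
            "ambiguous_columns": list(self.ambiguous_columns),
        }


def _excluded_columns(
    aln: PairwiseAlignment, policy: GapPolicy, masked_columns: frozenset
) -> tuple[set, list]:
    """Columns removed before any counting: masks, ambiguity, gap-vs-gap."""
    excluded: set = set()
    ambiguous: list = []
    if policy.mask_primer:
        excluded |= set(masked_columns)
    for col in range(1, len(aln) + 1):
        ca, cb = aln.column(col)
        if ca == GAP and cb == GAP:
            excluded.add(col)
            continue
        if policy.mask_ambiguity and (
            (ca != GAP and ca not in CANONICAL) or (cb != GAP and cb not in CANONICAL)
        ):
            excluded.add(col)
            ambiguous.append(col)
    return excluded, ambiguous


def variable_sites(
    aln: PairwiseAlignment, policy: GapPolicy, masked_columns: frozenset = frozenset()
) -> list[int]:
    """Columns at which the two rows differ, under the given gap policy."""
    excluded, _ = _excluded_columns(aln, policy, masked_columns)
    out = []
    for col in range(1, len(aln) + 1):
        if col in excluded:
            continue
        ca, cb = aln.column(col)
        has_gap = GAP in (ca, cb)
        if policy.mode is GapMode.EXCLUDE_GAPS and has_gap:
            continue
        if ca != cb:
            out.append(col)
    return out


def classify_pair_change(before: tuple, after: tuple) -> Optional[SiteClass]:
    """Classify the change of one base pair between two sequences.

    *before* and *after* are the (5', 3') bases of the pair in the two sequences.
    Returns ``None`` for identical pairs and for pairs involving ambiguity codes
    (the caller logs and excludes the latter). Gaps must be routed to INDEL
    upstream.
    """
    b1, b2 = before
    a1, a2 = after
    if any(x not in CANONICAL for x in (b1, b2, a1, a2)):
        return None
    changed = (b1 != a1) + (b2 != a2)
    if changed == 0:
        return None
    both_comp = is_complementary(b1, b2) and is_complementary(a1, a2)
    if not both_comp:
        return SiteClass.UNCOUPLED
    return SiteClass.CBC if changed == 2 else SiteClass.HEMI_CBC


def p_distance(
    aln: PairwiseAlignment, policy: GapPolicy, masked_columns: frozenset = frozenset()
) -> float:
    """Uncorrected fraction of differing sites under the given gap policy.

    COUNT_GAPS: (substitution + gap columns) / all retained columns.
    EXCLUDE_GAPS: substitution columns / (retained columns - gap columns).
    Masked and gap-vs-gap columns are removed before either count.
    """
    excluded, _ = _excluded_columns(aln, policy, masked_columns)
    total = subs = gaps = 0
    for col in range(1, len(aln) + 1):
        if col in excluded:
            continue
        total += 1
        ca, cb = aln.column(col)
        if GAP in (ca, cb):
            gaps += 1
        elif ca != cb:
            subs += 1
    if policy.mode is GapMode.COUNT_GAPS:
        denom, numer = total, subs + gaps
    else:
        denom, numer = total - gaps, subs
    if denom == 0:
        raise UndefinedDistanceError("no columns left in distance denominator")
    return numer / denom


def compare_structured(saln: StructuredAlignment, policy: GapPolicy = GapPolicy()) -> ComparisonReport:
    """Classify every variable column of a structured pairwise alignment.

    Each variable column receives exactly one :class:`SiteChange`; a CBC is one
    record covering its two partner columns. Per-helix tallies count substitution
    columns (residue vs residue) per helix label. The partition identity
    ``2*CBC + hemiCBC + uncoupled + loop + indel == variable sites (gaps counted)``
    holds by construction.
    """
    aln = saln.alignment
    excluded, ambiguous = _excluded_columns(aln, policy, saln.masked_columns)
    count_policy = GapPolicy(GapMode.COUNT_GAPS, policy.mask_primer, policy.mask_ambiguity)
    varcols = variable_sites(aln, count_policy, saln.masked_columns)
    varset = set(varcols)

    changes: list[SiteChange] = []
    per_helix: dict[str, int] = {}
    counts = {k: 0 for k in SiteClass}
    done: set = set()

    def helix_of(col):
        cc = saln.column_context.get(col)
        return cc.helix if cc else None

    def tally_helix(col):
        h = helix_of(col)
        if h is not None:
            per_helix[h] = per_helix.get(h, 0) + 1

    for col in varcols:
        if col in done:
            continue
        ca, cb = aln.column(col)
        cc = saln.column_context.get(col)
        if GAP in (ca, cb):
            counts[SiteClass.INDEL] += 1
            changes.append(
                SiteChange(
                    columns=(col,),
                    states_a=(ca,),
                    states_b=(cb,),
                    context=Context.PAIRED if cc else Context.UNPAIRED,
                    klass=SiteClass.INDEL,
                    helix=helix_of(col),
                )
            )
            done.add(col)
            continue
        if cc is None:
            counts[SiteClass.LOOP_SUBSTITUTION] += 1
            tally_helix(col)
            changes.append(
                SiteChange(
                    columns=(col,),
                    states_a=(ca,),
                    states_b=(cb,),
                    context=Context.UNPAIRED,
                    klass=SiteClass.LOOP_SUBSTITUTION,
                )
            )
            done.add(col)
            continue
        pcol = cc.partner_column
        pa, pb = aln.column(pcol)
        partner_usable = pcol not in excluded and GAP not in (pa, pb)
        if partner_usable:
            c1, c2 = (col, pcol) if col < pcol else (pcol, col)
            s1a, s1b = aln.column(c1)
            s2a, s2b = aln.column(c2)
            klass = classify_pair_change((s1a, s2a), (s1b, s2b))
            if klass is SiteClass.CBC:
                counts[SiteClass.CBC] += 1
                tally_helix(c1)
                tally_helix(c2)
                changes.append(
                    SiteChange(
                        columns=(c1, c2),
                        states_a=(s1a, s2a),
                        states_b=(s1b, s2b),
                        context=Context.PAIRED,
                        klass=SiteClass.CBC,
                        helix=helix_of(c1) or helix_of(c2),
                    )
                )
                done.update((c1, c2))
                continue
            if klass is SiteClass.HEMI_CBC:
                counts[SiteClass.HEMI_CBC] += 1
                tally_helix(col)
                changes.append(
                    SiteChange(
                        columns=(c1, c2),
                        states_a=(s1a, s2a),
                        states_b=(s1b, s2b),
                        context=Context.PAIRED,
                        klass=SiteClass.HEMI_CBC,
                        helix=helix_of(col),
                    )
                )
                done.add(col)  # the partner column is not variable
                continue
            # UNCOUPLED: one record per variable column of the couple
            counts[SiteClass.UNCOUPLED] += 1
            tally_helix(col)
            changes.append(
                SiteChange(
                    columns=(col, pcol),
                    states_a=(ca, pa),
                    states_b=(cb, pb),
                    context=Context.PAIRED,
                    klass=SiteClass.UNCOUPLED,
                    helix=helix_of(col),
                )
            )
            done.add(col)
        else:
            # partner is an indel/masked column: pairing cannot be conserved
            counts[SiteClass.UNCOUPLED] += 1
            tally_helix(col)
            changes.append(
                SiteChange(
                    columns=(col, pcol),
                    states_a=(ca, pa),
                    states_b=(cb, pb),
                    context=Context.PAIRED,
                    klass=SiteClass.UNCOUPLED,
                    helix=helix_of(col),
                )
            )
            done.add(col)

    no_gap_policy = GapPolicy(GapMode.EXCLUDE_GAPS, policy.mask_primer, policy.mask_ambiguity)
    var_no_gaps = variable_sites(aln, no_gap_policy, saln.masked_columns)

    def safe_distance(pol):
        try:
            return p_distance(aln, pol, saln.masked_columns)
        except UndefinedDistanceError:
            return float("nan")

    return ComparisonReport(
        variable_sites_with_gaps=len(varset),
        variable_sites_no_gaps=len(var_no_gaps),
        class_counts={k.value: v for k, v in counts.items()},
        per_helix=per_helix,
        distance_with_gaps=safe_distance(count_policy),
        distance_no_gaps=safe_distance(no_gap_policy),
        changes=tuple(changes),
        ambiguous_columns=tuple(ambiguous),
    )
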