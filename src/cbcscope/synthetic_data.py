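"""Ground-truth generators for every pipeline stage.

Each generator takes a single integer seed (no global random state), is fully
deterministic for fixed seed + parameters, and returns its planted truth so the
detectors can be tested in a closed loop: planted CBC/hemi-CBC/uncoupled/loop/
indel counts, intron coordinates, clade-diagnostic columns and ITS2 motif
knockouts must all be recovered exactly.

Defaults encode the study conditions this toolkit targets: a 2,724-nt rDNA
cistron (SSU + ITS1 + 5.8S + ITS2 + 5' LSU), SSU queries carrying five or six
group I introns of several hundred nt, an SSU divergence of ~39 variable sites
including eight CBCs and seven hemi-CBCs, and an ITS2 alignment whose divergence
is 35.5% with gaps counted and ~23% without.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import CapacityError, ParameterError, TopologyError
from .seqio import AnnotatedSequence, GAP, Interval, MultipleAlignment, PairwiseAlignment
from .structure import COMPLEMENTARY, SecondaryStructure, StructuredAlignment, map_structure
from .synapomorphy import Phylogeny

BASES = "ACGU"
#: Watson-Crick pairs only; stems built from these stay unambiguous under
#: the wobble-inclusive complementarity test.
WC_PAIRS = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"))

#: Study-condition region lengths (nt); they sum to 2,724.
DEFAULT_REGION_LENGTHS = {
    "SSU": 1767,
    "ITS1": 180,
    "5.8S": 160,
    "ITS2": 248,
    "LSU": 369,
}

#: Study-condition intron complements. "planctonica-like": five SSU + one LSU
#: intron summing to a 5,052-nt cistron; "fina-like": six SSU + one LSU intron
#: summing to 5,416 nt.
DEFAULT_INTRONS_PLANCTONICA = {"SSU": [398, 412, 350, 430, 360], "LSU": [378]}
DEFAULT_INTRONS_FINA = {"SSU": [390, 400, 350, 420, 380, 372], "LSU": [380]}


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of one generator call (JSON-serialisable)."""

    seed: int
    planted: Sequence[dict] = field(default_factory=tuple)
    params: Mapping = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "planted": list(self.planted), "params": dict(self.params)},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(seed=d["seed"], planted=tuple(d["planted"]), params=d["params"])

    def count(self, kind: str) -> int:
        return sum(1 for p in self.planted if p["kind"] == kind)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_seq(rng, n: int) -> list[str]:
    return [BASES[k] for k in rng.integers(0, 4, size=n)]


# ---------------------------------------------------------------------------
# templates


def make_template(
    seed: int,
    n_helices: int = 3,
    helix_len: int = 5,
    loop_len: int = 4,
    spacer_len: int = 6,
) -> tuple[AnnotatedSequence, SecondaryStructure]:
    """A pseudoknot-free stem-loop template with all-complementary stems.

    Layout: spacer, then for each helix a 5' strand, loop, 3' strand, spacer.
    Helices are labelled ``H1..Hn`` on every paired position.
    """
    if n_helices < 1:
        raise ParameterError("n_helices must be >= 1")
    if helix_len < 1 or loop_len < 0 or spacer_len < 0:
        raise ParameterError("helix_len >= 1, loop_len >= 0, spacer_len >= 0 required")
    rng = _rng(seed)
    residues: list[str] = []
    pairs: set = set()
    labels: dict[int, str] = {}
    residues.extend(_random_seq(rng, spacer_len))
    for h in range(1, n_helices + 1):
        stem = [WC_PAIRS[k] for k in rng.integers(0, len(WC_PAIRS), size=helix_len)]
        start5 = len(residues) + 1
        residues.extend(b5 for b5, _ in stem)
        residues.extend(_random_seq(rng, loop_len))
        start3 = len(residues) + 1
        residues.extend(b3 for _, b3 in reversed(stem))
        for k in range(helix_len):
            i = start5 + k
            j = start3 + (helix_len - 1 - k)
            pairs.add((i, j))
            labels[i] = labels[j] = f"H{h}"
        residues.extend(_random_seq(rng, spacer_len))
    seq = AnnotatedSequence(
        id=f"template-{seed}",
        residues="".join(residues),
        regions={"ALL": (1, len(residues))},
    )
    st = SecondaryStructure(seq_id=seq.id, pairs=frozenset(pairs), helix_labels=labels)
    return seq, st


# ---------------------------------------------------------------------------
# planted site changes


_CBC_TARGETS = {p: [q for q in WC_PAIRS if q[0] != p[0] and q[1] != p[1]] for p in WC_PAIRS}
#: The single complementarity-preserving one-sided change for each WC pair
#: (always a move into the G.U wobble).
_HEMI_TARGETS = {
    ("G", "C"): ("G", "U"),
    ("C", "G"): ("U", "G"),
    ("A", "U"): ("G", "U"),
    ("U", "A"): ("U", "G"),
}


def plant_changes(
    seq: AnnotatedSequence,
    st: SecondaryStructure,
    counts: Mapping[str, int],
    seed: int,
) -> tuple[AnnotatedSequence, SyntheticTruth]:
    """Plant substitutions of each class (and single-column indels) into *seq*.

    *counts* maps class names (``CBC``, ``HEMI_CBC``, ``UNCOUPLED``,
    ``LOOP_SUBSTITUTION``, ``INDEL``) to requested event counts. Paired classes
    consume whole base pairs; loop substitutions and indels consume unpaired
    positions (never the first or last residue, never primer-masked positions),
    all mutually non-overlapping. Indels are single-column events: a deletion
    from, or an insertion into, the mutant sequence.

    Returns the mutant sequence and a truth object whose ``params`` carry the
    true gapped alignment rows (``row_a`` = template, ``row_b`` = mutant), so
    detectors can be tested without re-alignment ambiguity.
    """
    rng = _rng(seed)
    counts = {k: int(v) for k, v in counts.items()}
    for k, v in counts.items():
        if v < 0:
            raise ParameterError(f"negative count for {k}")
    n = len(seq)
    partner = st.partner
    paired_pairs = sorted(st.pairs)
    unpaired = [
        p
        for p in range(2, n)  # never the terminal residues
        if p not in partner and p not in seq.primer_mask
    ]

    n_pair_events = counts.get("CBC", 0) + counts.get("HEMI_CBC", 0) + counts.get("UNCOUPLED", 0)
    if n_pair_events > len(paired_pairs):
        short = [k for k in ("CBC", "HEMI_CBC", "UNCOUPLED") if counts.get(k, 0)]
        raise CapacityError(
            f"{n_pair_events} paired-site events requested but only "
            f"{len(paired_pairs)} base pairs available (classes {short})"
        )
    n_single = counts.get("LOOP_SUBSTITUTION", 0) + counts.get("INDEL", 0)
    # indels must not be adjacent to each other or to loop substitutions, so
    # demand headroom of one position between consecutive picks
    if 2 * n_single > len(unpaired) + 1:
        raise CapacityError(
            f"{n_single} single-stranded events requested but only "
            f"{len(unpaired)} unpaired positions available (LOOP_SUBSTITUTION/INDEL)"
        )

    chosen_pairs = [
        paired_pairs[k]
        for k in rng.choice(len(paired_pairs), size=n_pair_events, replace=False)
    ]
    rng.shuffle(chosen_pairs)
    # spread single-site picks so no two are adjacent (keeps events separable)
    picks: list[int] = []
    pool = list(unpaired)
    rng.shuffle(pool)
    for p in pool:
        if len(picks) == n_single:
            break
        if all(abs(p - q) > 1 for q in picks):
            picks.append(p)
    if len(picks) < n_single:
        raise CapacityError("could not place non-adjacent single-stranded events")

    mutant = list(seq.residues)
    planted: list[dict] = []
    idx = 0

    def wc(i, j):
        return (seq.residues[i - 1], seq.residues[j - 1])

    for _ in range(counts.get("CBC", 0)):
        i, j = chosen_pairs[idx]
        idx += 1
        before = wc(i, j)
        options = _CBC_TARGETS[before]
        after = options[int(rng.integers(0, len(options)))]
        mutant[i - 1], mutant[j - 1] = after
        planted.append({"kind": "CBC", "positions": [i, j], "before": list(before), "after": list(after)})
    for _ in range(counts.get("HEMI_CBC", 0)):
        i, j = chosen_pairs[idx]
        idx += 1
        before = wc(i, j)
        after = _HEMI_TARGETS[before]
        mutant[i - 1], mutant[j - 1] = after
        planted.append(
            {"kind": "HEMI_CBC", "positions": [i, j], "before": list(before), "after": list(after)}
        )
    for _ in range(counts.get("UNCOUPLED", 0)):
        i, j = chosen_pairs[idx]
        idx += 1
        before = wc(i, j)
        side = int(rng.integers(0, 2))
        fixed = before[1 - side]
        choices = [
            b
            for b in BASES
            if b != before[side]
            and ((b, fixed) if side == 0 else (fixed, b)) not in COMPLEMENTARY
        ]
        nb = choices[int(rng.integers(0, len(choices)))]
        after = (nb, fixed) if side == 0 else (fixed, nb)
        mutant[i - 1], mutant[j - 1] = after
        planted.append(
            {"kind": "UNCOUPLED", "positions": [i, j], "before": list(before), "after": list(after)}
        )

    k = 0
    for _ in range(counts.get("LOOP_SUBSTITUTION", 0)):
        p = picks[k]
        k += 1
        old = seq.residues[p - 1]
        nb = [b for b in BASES if b != old][int(rng.integers(0, 3))]
        mutant[p - 1] = nb
        planted.append({"kind": "LOOP_SUBSTITUTION", "positions": [p], "before": old, "after": nb})
    deletions: set = set()
    insertions: dict[int, str] = {}  # insert after template position p
    for _ in range(counts.get("INDEL", 0)):
        p = picks[k]
        k += 1
        if rng.integers(0, 2) == 0:
            deletions.add(p)
            planted.append(
                {"kind": "INDEL", "positions": [p], "before": seq.residues[p - 1], "after": GAP}
            )
        else:
            ins = BASES[int(rng.integers(0, 4))]
            insertions[p] = ins
            planted.append({"kind": "INDEL", "positions": [p], "before": GAP, "after": ins})

    # build the true alignment and the mutant residue string
    row_a, row_b = [], []
    for p in range(1, n + 1):
        a = seq.residues[p - 1]
        b = GAP if p in deletions else mutant[p - 1]
        row_a.append(a)
        row_b.append(b)
        if p in insertions:
            row_a.append(GAP)
            row_b.append(insertions[p])
    row_a, row_b = "".join(row_a), "".join(row_b)

    mutant_seq = AnnotatedSequence(
        id=f"{seq.id}-mut{seed}",
        residues=row_b.replace(GAP, ""),
        primer_mask=seq.primer_mask,
    )
    truth = SyntheticTruth(
        seed=seed,
        planted=tuple(planted),
        params={
            "counts": counts,
            "row_a": row_a,
            "row_b": row_b,
            "template_id": seq.id,
            "mutant_id": mutant_seq.id,
        },
    )
    return mutant_seq, truth


def structured_pair(
    seed: int,
    counts: Mapping[str, int],
    n_helices: int = 6,
    helix_len: int = 6,
    loop_len: int = 8,
    spacer_len: int = 10,
) -> tuple[StructuredAlignment, SyntheticTruth]:
    """Convenience: template + planted mutant, returned as a StructuredAlignment.

    The alignment rows are the *true* planted rows (row_a = template), with the
    template structure mapped onto the columns, ready for ``compare_structured``.
    """
    seq, st = make_template(seed, n_helices=n_helices, helix_len=helix_len,
                            loop_len=loop_len, spacer_len=spacer_len)
    _, truth = plant_changes(seq, st, counts, seed=seed + 1)
    aln = PairwiseAlignment(
        row_a=truth.params["row_a"],
        row_b=truth.params["row_b"],
        id_a=seq.id,
        id_b=truth.params["mutant_id"],
    )
    saln = map_structure(st, aln, reference_row="a", primer_mask=seq.primer_mask)
    return saln, truth


# ---------------------------------------------------------------------------
# clade alignments


def make_clade_alignment(
    tree_newick: str,
    nhs_spec: Mapping[str, int],
    n_neutral: int,
    seed: int,
    clades: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[MultipleAlignment, SyntheticTruth]:
    """An alignment with clade-diagnostic columns planted for each named clade.

    *nhs_spec* maps a clade name to the number of diagnostic columns to plant;
    *clades* maps names to tip sets (a name used directly as a comma-separated
    tip list also works). At each diagnostic column all clade members carry a
    derived state absent from every other tip; neutral columns are identical
    across all taxa.
    """
    tree = Phylogeny.from_newick(tree_newick)
    tips = sorted(tree.tips)
    clade_sets: dict[str, frozenset] = {}
    for name in nhs_spec:
        if clades and name in clades:
            clade_sets[name] = frozenset(clades[name])
        else:
            clade_sets[name] = frozenset(t.strip() for t in name.split(","))
    for name, cl in clade_sets.items():
        if not tree.is_monophyletic(cl):
            raise TopologyError(f"clade {name!r} {sorted(cl)} is not monophyletic in the tree")
    rng = _rng(seed)
    total = n_neutral + sum(nhs_spec.values())
    if total < 1:
        raise ParameterError("alignment needs at least one column")
    order = list(range(1, total + 1))
    rng.shuffle(order)
    assignment: dict[int, str] = {}
    pos = 0
    for name, cnt in nhs_spec.items():
        for _ in range(cnt):
            assignment[order[pos]] = name
            pos += 1

    rows = {t: [] for t in tips}
    planted = []
    for col in range(1, total + 1):
        if col not in assignment:
            b = BASES[int(rng.integers(0, 4))]
            for t in tips:
                rows[t].append(b)
            continue
        name = assignment[col]
        cl = clade_sets[name]
        anc = BASES[int(rng.integers(0, 4))]
        der = [b for b in BASES if b != anc][int(rng.integers(0, 3))]
        for t in tips:
            rows[t].append(der if t in cl else anc)
        planted.append(
            {"kind": "NHS", "positions": [col], "clade": sorted(cl),
             "before": anc, "after": der}
        )
    maln = MultipleAlignment(rows={t: "".join(rows[t]) for t in tips})
    truth = SyntheticTruth(
        seed=seed,
        planted=tuple(planted),
        params={"tree": tree_newick.strip(), "n_neutral": n_neutral,
                "nhs_spec": dict(nhs_spec)},
    )
    return maln, truth


# ---------------------------------------------------------------------------
# intron-bearing rDNA


def make_rdna(
    seed: int,
    region_lengths: Optional[Mapping[str, int]] = None,
    intron_lengths: Optional[Mapping[str, Sequence[int]]] = None,
) -> tuple[AnnotatedSequence, AnnotatedSequence]:
    """An intron-bearing rDNA query and its intron-free reference.

    The reference is a random cistron with the given region lengths (defaults:
    the 2,724-nt study layout); the query is the same cistron with random-interior
    group I intron-like insertion blocks placed inside the named regions
    (defaults: the five-SSU + one-LSU planctonica-like complement). Planted
    boundary bases are constrained so the optimal alignment placement of each
    block — hence its recovered coordinates — is unique.

    The query's ``introns`` annotation records the planted intervals in query
    coordinates; both records carry region annotations in their own coordinates.
    """
    region_lengths = dict(DEFAULT_REGION_LENGTHS if region_lengths is None else region_lengths)
    if intron_lengths is None:
        intron_lengths = DEFAULT_INTRONS_PLANCTONICA
    intron_lengths = {k: list(v) for k, v in intron_lengths.items()}
    for reg in intron_lengths:
        if reg not in region_lengths:
            raise ParameterError(f"introns requested in unknown region {reg!r}")
    rng = _rng(seed)

    regions: dict[str, Interval] = {}
    pos = 0
    for name, ln in region_lengths.items():
        if ln < 1:
            raise ParameterError(f"region {name!r} has non-positive length")
        regions[name] = (pos + 1, pos + ln)
        pos += ln
    ref_res = "".join(_random_seq(rng, pos))
    reference = AnnotatedSequence(id=f"ref-{seed}", residues=ref_res, regions=regions)

    # insertion points in reference coordinates: strictly interior to the
    # region and >= min_sep apart so adjacent insertion blocks cannot merge
    # into a single alignment gap run
    min_sep = 20
    events: list[tuple[int, int]] = []  # (ref position after which to insert, length)
    for reg, lens in intron_lengths.items():
        s, e = regions[reg]
        k = len(lens)
        if k == 0:
            continue
        for ln in lens:
            if ln < 1:
                raise ParameterError("intron length must be >= 1")
        lo, hi = s + 1, e - 2  # admissible insertion points (after position p)
        span = hi - lo - (k - 1) * min_sep
        if span < k - 1 or hi < lo:
            raise ParameterError(
                f"region {reg!r} too short for {k} introns {min_sep} nt apart"
            )
        raw = np.sort(rng.choice(np.arange(lo, lo + span + 1), size=k, replace=False))
        spots = [int(p) + i * min_sep for i, p in enumerate(raw)]
        events.extend(zip(spots, lens))
    events.sort()

    q_parts: list[str] = []
    introns: list[Interval] = []
    prev = 0
    qlen = 0
    for p, ln in events:
        q_parts.append(ref_res[prev:p])
        qlen += p - prev
        block = _random_seq(rng, ln)
        # unique-placement constraints at the block boundaries
        after_base = ref_res[p] if p < len(ref_res) else None
        before_base = ref_res[p - 1]
        if after_base is not None and block[0] == after_base:
            block[0] = BASES[(BASES.index(after_base) + 1) % 4]
        if block[-1] == before_base:
            block[-1] = BASES[(BASES.index(before_base) + 1) % 4]
        if len(block) > 1 and after_base is not None and block[0] == after_base:
            block[0] = BASES[(BASES.index(after_base) + 2) % 4]
        q_parts.append("".join(block))
        introns.append((qlen + 1, qlen + ln))
        qlen += ln
        prev = p
    q_parts.append(ref_res[prev:])
    query_res = "".join(q_parts)

    # region annotations shifted into query coordinates
    q_regions: dict[str, Interval] = {}
    for name, (s, e) in regions.items():
        shift_s = sum(ln for p, ln in events if p < s)
        shift_e = sum(ln for p, ln in events if p <= e - 1)
        q_regions[name] = (s + shift_s, e + shift_e)
    query = AnnotatedSequence(
        id=f"query-{seed}", residues=query_res, regions=q_regions, introns=introns
    )
    return query, reference


# ---------------------------------------------------------------------------
# divergent spacer alignments (ITS2-style)


def make_divergent_pair(
    seed: int,
    n_columns: int = 248,
    n_substitutions: int = 48,
    n_gap_columns: int = 40,
) -> tuple[PairwiseAlignment, SyntheticTruth]:
    """A spacer alignment with planted substitution and single-gap columns.

    Defaults encode the study-condition ITS2 divergence: 248 columns with 48
    substitutions and 40 gap columns give (48+40)/248 = 35.5% with gaps counted
    and 48/208 = 23.1% with gap columns excluded.
    """
    if n_substitutions + n_gap_columns > n_columns:
        raise CapacityError("more planted columns than alignment columns")
    rng = _rng(seed)
    base = _random_seq(rng, n_columns)
    cols = rng.choice(n_columns, size=n_substitutions + n_gap_columns, replace=False)
    sub_cols = set(int(c) + 1 for c in cols[:n_substitutions])
    gap_cols = set(int(c) + 1 for c in cols[n_substitutions:])
    row_a, row_b, planted = [], [], []
    for col in range(1, n_columns + 1):
        a = base[col - 1]
        if col in sub_cols:
            b = [x for x in BASES if x != a][int(rng.integers(0, 3))]
            planted.append({"kind": "SUBSTITUTION", "positions": [col], "before": a, "after": b})
        elif col in gap_cols:
            if rng.integers(0, 2) == 0:
                a, b = a, GAP
            else:
                a, b = GAP, a
            planted.append({"kind": "INDEL", "positions": [col], "before": a, "after": b})
        else:
            b = a
        row_a.append(a)
        row_b.append(b)
    aln = PairwiseAlignment(
        row_a="".join(row_a), row_b="".join(row_b),
        id_a=f"spacer-{seed}-a", id_b=f"spacer-{seed}-b",
    )
    truth = SyntheticTruth(
        seed=seed,
        planted=tuple(planted),
        params={"n_columns": n_columns, "n_substitutions": n_substitutions,
                "n_gap_columns": n_gap_columns},
    )
    return aln, truth


# ---------------------------------------------------------------------------
# ITS2 records with motif knockouts


def make_its2(
    seed: int, knockouts: Sequence[str] = ()
) -> tuple[AnnotatedSequence, SecondaryStructure, SyntheticTruth]:
    """A four-helix ITS2-like record with the canonical motifs planted.

    *knockouts* may contain ``"uu"``, ``"a_rich"``, ``"ggu"``, ``"branch"``; each
    removes exactly the corresponding motif. Helix I is y-shaped (two child
    stems) unless ``"branch"`` is knocked out; helix II carries a U-U 1x1
    internal loop unless ``"uu"`` is knocked out (the 5' mismatch base becomes
    A); the II-III spacer is A-rich unless ``"a_rich"`` is knocked out; the 5'
    strand of helix III carries ``GGU`` unless ``"ggu"`` is knocked out (GAU).
    """
    bad = set(knockouts) - {"uu", "a_rich", "ggu", "branch"}
    if bad:
        raise ParameterError(f"unknown knockouts {sorted(bad)}")
    rng = _rng(seed)
    residues: list[str] = []
    pairs: set = set()

    def add_spacer(n):
        # spacers deliberately A-poor so the A-rich check cannot fire by accident
        residues.extend("CGUG"[int(k)] for k in rng.integers(0, 4, size=n))

    def add_stem_open(n, pairs_from=WC_PAIRS):
        """Open n stem pairs; returns the closer bases to emit later."""
        closers = []
        for _ in range(n):
            b5, b3 = pairs_from[int(rng.integers(0, len(pairs_from)))]
            residues.append(b5)
            closers.append((len(residues), b3))
        return closers

    def close_stem(closers):
        for i5, b3 in reversed(closers):
            residues.append(b3)
            pairs.add((i5, len(residues)))

    def add_literal_stem_open(text):
        closers = []
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for c in text:
            residues.append(c)
            closers.append((len(residues), comp[c]))
        return closers

    add_spacer(4)
    # helix I: outer stem, then either two child stems (y-shape) or one long stem
    outer = add_stem_open(4)
    if "branch" in knockouts:
        inner = add_stem_open(6)
        add_spacer(4)
        close_stem(inner)
    else:
        add_spacer(2)
        child1 = add_stem_open(3)
        add_spacer(4)
        close_stem(child1)
        add_spacer(2)
        child2 = add_stem_open(3)
        add_spacer(4)
        close_stem(child2)
        add_spacer(2)
    close_stem(outer)
    add_spacer(4)

    # helix II: stem with a 1x1 internal loop of facing pyrimidines
    ii_outer = add_stem_open(4)
    mm5 = "A" if "uu" in knockouts else "U"
    residues.append(mm5)
    mm5_pos = len(residues)
    ii_inner = add_stem_open(4)
    add_spacer(4)
    close_stem(ii_inner)
    residues.append("U")  # 3' mismatch base faces mm5
    close_stem(ii_outer)

    # II-III spacer with or without the A-rich window
    add_spacer(2)
    if "a_rich" in knockouts:
        add_spacer(5)
    else:
        residues.extend("AAAAA")
    add_spacer(2)

    # helix III: 5' strand carries GGU (or GAU when knocked out) before the apex
    # helix III 5' strand must not form "GGU" by chance: keep U off the 5' side
    no_u5 = (("A", "U"), ("G", "C"), ("C", "G"))
    iii_lead = add_stem_open(2, pairs_from=no_u5)
    triplet = "GAU" if "ggu" in knockouts else "GGU"
    iii_trip = add_literal_stem_open(triplet)
    iii_tail = add_stem_open(3, pairs_from=no_u5)
    add_spacer(4)
    close_stem(iii_tail)
    close_stem(iii_trip)
    close_stem(iii_lead)
    add_spacer(4)

    # helix IV: a plain short stem-loop
    iv = add_stem_open(4)
    add_spacer(4)
    close_stem(iv)
    add_spacer(3)

    seq = AnnotatedSequence(
        id=f"its2-{seed}",
        residues="".join(residues),
        regions={"ITS2": (1, len(residues))},
    )
    st = SecondaryStructure(seq_id=seq.id, pairs=frozenset(pairs))
    truth = SyntheticTruth(
        seed=seed,
        planted=(
            {"kind": "MOTIF", "name": "uu", "present": "uu" not in knockouts,
             "positions": [mm5_pos]},
            {"kind": "MOTIF", "name": "a_rich", "present": "a_rich" not in knockouts},
            {"kind": "MOTIF", "name": "ggu", "present": "ggu" not in knockouts},
            {"kind": "MOTIF", "name": "branch", "present": "branch" not in knockouts},
        ),
        params={"knockouts": sorted(knockouts)},
    )
    return seq, st, truth
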