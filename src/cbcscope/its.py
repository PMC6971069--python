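"""ITS1/ITS2 utilities: boundary location, ITS2 motif verification, helix distances.

Eukaryotic ITS2 folds into a conserved four-helix layout whose hallmarks are a
pyrimidine-pyrimidine (typically U-U) mismatch in helix II, an A-rich stretch
between helices II and III, and a "GGU" triplet on the 5' strand of helix III
near its apex; in Sphaeroplealean green algae helix I is additionally branched
(y-shaped). These motifs, verified on a supplied secondary structure, are what
this module reports. Helices are numbered I, II, III, ... by 5' order of their
outermost pair; folding itself is accepted from input (energy-minimisation
folding is an external step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align

from .compare import GapPolicy, p_distance
from .errors import UndefinedDistanceError, UnresolvableBoundaryError
from .seqio import AnnotatedSequence, GAP, Interval, PairwiseAlignment
from .structure import SecondaryStructure

PYRIMIDINES = frozenset("CU")


@dataclass(frozen=True)
class MotifParams:
    """Tunable thresholds for the A-rich region check."""

    a_window: int = 4  # minimum window length (nt)
    a_frac: float = 0.75  # minimum fraction of A within the window


@dataclass(frozen=True)
class MotifReport:
    """Presence/location of the canonical ITS2 structural motifs."""

    uu_mismatch_helix_II: bool
    uu_mismatch_position: Optional[tuple] = None  # (5' pos, 3' pos)
    a_rich_region: bool = False
    a_rich_interval: Optional[Interval] = None
    ggu_motif: bool = False
    ggu_position: Optional[int] = None
    branched_helix_I: bool = False
    helix_count: int = 0
    warning: Optional[str] = None

    def to_json(self) -> dict:
        return {
            "uu_mismatch_helix_II": self.uu_mismatch_helix_II,
            "uu_mismatch_position": list(self.uu_mismatch_position)
            if self.uu_mismatch_position
            else None,
            "a_rich_region": self.a_rich_region,
            "a_rich_interval": list(self.a_rich_interval) if self.a_rich_interval else None,
            "ggu_motif": self.ggu_motif,
            "ggu_position": self.ggu_position,
            "branched_helix_I": self.branched_helix_I,
            "helix_count": self.helix_count,
            "warning": self.warning,
        }


# ---------------------------------------------------------------------------
# helix trees


def outermost_pairs(st: SecondaryStructure) -> list[tuple]:
    """Pairs not enclosed by any other pair, in 5' order: one per helix domain."""
    pairs = sorted(st.pairs)
    out, horizon = [], 0
    for i, j in pairs:
        if i > horizon:
            out.append((i, j))
            horizon = j
    return out


def subtree_pairs(st: SecondaryStructure, root: tuple) -> list[tuple]:
    """All pairs nested within *root* (inclusive), sorted."""
    i0, j0 = root
    return sorted((i, j) for i, j in st.pairs if i0 <= i and j <= j0)


def _children(pairs: Sequence[tuple], parent: tuple) -> list[tuple]:
    """Outermost pairs strictly inside *parent*."""
    i0, j0 = parent
    inner = [(i, j) for i, j in sorted(pairs) if i0 < i and j < j0]
    out, horizon = [], 0
    for i, j in inner:
        if i > horizon:
            out.append((i, j))
            horizon = j
    return out


def is_branched(st: SecondaryStructure, root: tuple) -> bool:
    """True if the helix domain rooted at *root* contains a multiloop (>=2 branches)."""
    pairs = subtree_pairs(st, root)
    stack = [root]
    while stack:
        node = stack.pop()
        kids = _children(pairs, node)
        if len(kids) >= 2:
            return True
        stack.extend(kids)
    return False


# ---------------------------------------------------------------------------
# boundary location


def locate_its2(
    seq: AnnotatedSequence,
    flank_58s: Optional[str] = None,
    flank_lsu: Optional[str] = None,
) -> Interval:
    """The ITS2 interval of *seq*, from annotation or by matching flanking genes.

    The primary path returns the annotated ``ITS2`` region. When absent, the 3'
    end of a supplied 5.8S reference and the 5' start of an LSU reference are
    located by local alignment and ITS2 is the interval between them.
    """
    if "ITS2" in seq.regions:
        return seq.regions["ITS2"]
    if flank_58s is None or flank_lsu is None:
        raise UnresolvableBoundaryError(
            f"{seq.id}: no ITS2 annotation and no flanking 5.8S/LSU references"
        )
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    up = aligner.align(seq.residues, flank_58s.upper().replace("T", "U"))[0]
    down = aligner.align(seq.residues, flank_lsu.upper().replace("T", "U"))[0]
    end_58s = int(up.aligned[0][-1][1])  # 0-based exclusive end on seq
    start_lsu = int(down.aligned[0][0][0])  # 0-based start on seq
    start, end = end_58s + 1, start_lsu
    if start > end:
        raise UnresolvableBoundaryError(
            f"{seq.id}: flank matches leave no ITS2 interval ({start} > {end})"
        )
    return (start, end)


# ---------------------------------------------------------------------------
# motif checks


def _uu_mismatch(residues: str, st: SecondaryStructure, helix_root: tuple):
    """First 1x1 internal loop in the helix with two facing pyrimidines."""
    pairs = set(subtree_pairs(st, helix_root))
    for a, b in sorted(pairs):
        if (a + 2, b - 2) in pairs and (a + 1, b - 1) not in pairs:
            partner = st.partner
            if a + 1 not in partner and b - 1 not in partner:
                b5, b3 = residues[a], residues[b - 2]  # positions a+1 and b-1, 1-based
                if b5 in PYRIMIDINES and b3 in PYRIMIDINES:
                    return (a + 1, b - 1)
    return None


def _a_rich(residues: str, start: int, end: int, params: MotifParams):
    """First window of >= a_window nt with A fraction >= a_frac in [start, end]."""
    w = params.a_window
    if end - start + 1 < w:
        return None
    text = residues[start - 1 : end]
    for k in range(len(text) - w + 1):
        window = text[k : k + w]
        if window.count("A") / w >= params.a_frac:
            return (start + k, start + k + w - 1)
    return None


def _ggu(residues: str, st: SecondaryStructure, helix_root: tuple):
    """Position of 'GGU' on the 5' strand of the helix, outermost i to innermost i."""
    pairs = subtree_pairs(st, helix_root)
    i0 = helix_root[0]
    i_inner = max(i for i, _ in pairs)
    strand = residues[i0 - 1 : i_inner]
    k = strand.find("GGU")
    return i0 + k if k >= 0 else None


def check_motifs(
    residues: str, st: SecondaryStructure, params: MotifParams = MotifParams()
) -> MotifReport:
    """Verify the four canonical ITS2 motifs on a supplied structure.

    Helices are numbered by 5' order of their outermost pair; with fewer than
    three helices all motifs are reported absent with a warning.
    """
    roots = outermost_pairs(st)
    n = len(roots)
    if n < 3:
        return MotifReport(
            uu_mismatch_helix_II=False,
            helix_count=n,
            warning=f"only {n} helices found; motif checks need the four-helix layout",
        )
    helix_I, helix_II, helix_III = roots[0], roots[1], roots[2]
    uu = _uu_mismatch(residues, st, helix_II)
    a_iv = _a_rich(residues, helix_II[1] + 1, helix_III[0] - 1, params)
    ggu = _ggu(residues, st, helix_III)
    return MotifReport(
        uu_mismatch_helix_II=uu is not None,
        uu_mismatch_position=uu,
        a_rich_region=a_iv is not None,
        a_rich_interval=a_iv,
        ggu_motif=ggu is not None,
        ggu_position=ggu,
        branched_helix_I=is_branched(st, helix_I),
        helix_count=n,
    )


# ---------------------------------------------------------------------------
# helix-region distance (ITS1-style analysis over the common helices)


def helix_region_distance(
    aln: PairwiseAlignment, helix_columns, policy: GapPolicy = GapPolicy()
) -> float:
    """p-distance restricted to a set of alignment columns (the common helices)."""
    cols = sorted(set(helix_columns))
    if not cols:
        raise UndefinedDistanceError("empty helix column set")
    if cols[0] < 1 or cols[-1] > len(aln):
        raise UndefinedDistanceError("helix columns outside alignment")
    sub = PairwiseAlignment(
        row_a="".join(aln.row_a[c - 1] for c in cols),
        row_b="".join(aln.row_b[c - 1] for c in cols),
        id_a=aln.id_a,
        id_b=aln.id_b,
    )
    return p_distance(sub, policy)
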