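"""Secondary-structure representation, parsing, template transfer, and a toy fold.

Structures are pseudoknot-free (nested) sets of base pairs on the ungapped
sequence, 1-based, optionally carrying per-position helix labels in the style of
the eukaryotic SSU rRNA helix nomenclature ("43", "49", "E23_4", ...). Labels are
free text read from a sidecar table; no numbering scheme is hard-coded.

Template transfer is how the study-style workflow builds a structure for a new
sequence: a curated structure on a close homolog is pushed through a pairwise
alignment, keeping (but flagging) transferred pairs whose query bases no longer
pair, so that downstream classification can call them "uncoupled" rather than
silently dropping the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import ConsistencyError, FormatError, ParameterError, PseudoknotError
from .seqio import CANONICAL, GAP, PairwiseAlignment

Pair = tuple[int, int]

#: Complementary base pairs in RNA helices: Watson-Crick plus the G·U wobble,
#: which is standard in rRNA stems.
COMPLEMENTARY = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


def is_complementary(b1: str, b2: str) -> Optional[bool]:
    """True iff b1·b2 is A·U, G·C or G·U (either orientation).

    Returns ``None`` (indeterminate) if either base is an IUPAC ambiguity code.
    """
    if b1 not in CANONICAL or b2 not in CANONICAL:
        return None
    return (b1, b2) in COMPLEMENTARY


def _check_nested(pairs: frozenset) -> None:
    seen: dict[int, Pair] = {}
    for i, j in pairs:
        if not (0 < i < j):
            raise FormatError(f"invalid pair ({i},{j}): need 1 <= i < j")
        for p in (i, j):
            if p in seen:
                raise FormatError(f"position {p} occurs in more than one pair")
            seen[p] = (i, j)
    ordered = sorted(pairs)
    # stack check: a close must match the most recent open
    stack: list[Pair] = []
    events = sorted([(i, 0, (i, j)) for i, j in pairs] + [(j, 1, (i, j)) for i, j in pairs])
    for _, kind, pair in events:
        if kind == 0:
            stack.append(pair)
        else:
            if not stack or stack[-1] != pair:
                raise PseudoknotError(f"crossing pairs involving {pair}")
            stack.pop()
    del ordered


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested base-pair set with optional helix labels.

    ``pairs`` are (i, j) with i < j on the ungapped sequence; ``helix_labels``
    maps paired positions to label text.
    """

    seq_id: str
    pairs: frozenset
    helix_labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        pairs = frozenset(tuple(p) for p in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        _check_nested(pairs)
        paired = {p for ij in pairs for p in ij}
        for pos in self.helix_labels:
            if pos not in paired:
                raise FormatError(f"helix label at unpaired position {pos}")
        object.__setattr__(self, "helix_labels", dict(self.helix_labels))

    @property
    def partner(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i], out[j] = j, i
        return out

    def max_position(self) -> int:
        return max((j for _, j in self.pairs), default=0)

    def to_dotbracket(self, length: int) -> str:
        if length < self.max_position():
            raise ConsistencyError("sequence shorter than structure")
        chars = ["."] * length
        for i, j in self.pairs:
            chars[i - 1], chars[j - 1] = "(", ")"
        return "".join(chars)


def parse_dotbracket(text: str, seq_id: str = "") -> SecondaryStructure:
    """Parse a Vienna dot-bracket string into a pair set."""
    pairs, stack = set(), []
    for pos, c in enumerate(text.strip(), start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise FormatError(f"unmatched ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c in ".-":
            continue
        elif c in "[]{}<>":
            raise PseudoknotError(f"pseudoknot bracket {c!r} at position {pos} not supported")
        else:
            raise FormatError(f"unexpected character {c!r} at position {pos}")
    if stack:
        raise FormatError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(seq_id=seq_id, pairs=frozenset(pairs))


def parse_structure(path, dialect: str = None, helix_sidecar=None) -> SecondaryStructure:
    """Read a structure from a CT or dot-bracket file.

    *dialect* is ``"ct"`` or ``"dotbracket"``; if omitted it is inferred from the
    file suffix (``.ct`` vs anything else). A helix-label sidecar TSV (columns:
    position, helix) may be supplied; crossing pairs raise
    :class:`PseudoknotError` in either dialect.
    """
    path = Path(path)
    if dialect is None:
        dialect = "ct" if path.suffix.lower() == ".ct" else "dotbracket"
    if dialect == "ct":
        st = _parse_ct(path)
    elif dialect == "dotbracket":
        st = _parse_dotbracket_file(path)
    else:
        raise ParameterError(f"unknown structure dialect {dialect!r}")
    if helix_sidecar is not None:
        labels = read_helix_labels(helix_sidecar)
        st = SecondaryStructure(seq_id=st.seq_id, pairs=st.pairs, helix_labels=labels)
    return st


def _parse_dotbracket_file(path: Path) -> SecondaryStructure:
    seq_id, db = "", None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            seq_id = line[1:].split()[0] if len(line) > 1 else ""
        elif set(line) <= set(".()[]{}<>-"):
            db = line
        # a bare sequence line is tolerated and ignored
    if db is None:
        raise FormatError(f"{path}: no dot-bracket line found")
    return parse_dotbracket(db, seq_id=seq_id)


def _parse_ct(path: Path) -> SecondaryStructure:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: bad CT header {lines[0]!r}") from exc
    seq_id = header[1] if len(header) > 1 else ""
    pairs = set()
    body = lines[1 : n + 1]
    if len(body) < n:
        raise FormatError(f"{path}: CT header declares {n} rows, found {len(body)}")
    for ln in body:
        cols = ln.split()
        if len(cols) < 5:
            raise FormatError(f"{path}: short CT row {ln!r}")
        try:
            idx, pairidx = int(cols[0]), int(cols[4])
        except ValueError as exc:
            raise FormatError(f"{path}: bad CT row {ln!r}") from exc
        if pairidx > 0:
            if pairidx == idx:
                raise FormatError(f"{path}: position {idx} paired with itself")
            pairs.add((min(idx, pairidx), max(idx, pairidx)))
    return SecondaryStructure(seq_id=seq_id, pairs=frozenset(pairs))


def write_ct(st: SecondaryStructure, residues: str, path) -> None:
    partner = st.partner
    with open(path, "w") as fh:
        fh.write(f"{len(residues)} {st.seq_id}\n")
        for i, base in enumerate(residues, start=1):
            fh.write(f"{i} {base} {i - 1} {(i + 1) % (len(residues) + 1)} {partner.get(i, 0)} {i}\n")


def read_helix_labels(path) -> dict[int, str]:
    """Read a helix-label sidecar TSV (columns: position, helix)."""
    df = pd.read_csv(path, sep="\t", dtype={"helix": str})
    missing = {"position", "helix"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return {int(r.position): str(r.helix) for r in df.itertuples(index=False)}


def write_helix_labels(labels: Mapping[int, str], path) -> None:
    pd.DataFrame(
        {"position": sorted(labels), "helix": [labels[p] for p in sorted(labels)]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mapping structures onto alignments


@dataclass(frozen=True)
class ColumnContext:
    """Pairing context of one alignment column under the reference structure."""

    partner_column: int
    helix: Optional[str] = None


@dataclass(frozen=True)
class StructuredAlignment:
    """A pairwise alignment whose columns carry the reference row's pairing context.

    ``column_context`` maps a 1-based column to its :class:`ColumnContext`;
    columns absent from the map are unpaired. ``masked_columns`` are columns to
    exclude from site counting (e.g. the primer-binding region).
    """

    alignment: PairwiseAlignment
    column_context: Mapping[int, ColumnContext]
    reference_row: str = "a"
    masked_columns: frozenset = frozenset()

    def __post_init__(self):
        ctx = dict(self.column_context)
        for col, cc in ctx.items():
            back = ctx.get(cc.partner_column)
            if back is None or back.partner_column != col:
                raise ConsistencyError(f"asymmetric partner relation at column {col}")
        object.__setattr__(self, "column_context", ctx)
        object.__setattr__(self, "masked_columns", frozenset(self.masked_columns))


def map_structure(
    st: SecondaryStructure,
    aln: PairwiseAlignment,
    reference_row: str = "a",
    primer_mask: frozenset = frozenset(),
) -> StructuredAlignment:
    """Project a structure on the (ungapped) reference row onto alignment columns.

    *primer_mask* holds 1-based positions on the ungapped reference sequence; they
    are translated to alignment columns and recorded as masked.
    """
    if reference_row not in ("a", "b"):
        raise ParameterError("reference_row must be 'a' or 'b'")
    pos2col = aln.position_to_column(reference_row)
    n_ref = len(pos2col)
    if st.max_position() > n_ref:
        raise ConsistencyError(
            f"structure position {st.max_position()} exceeds reference length {n_ref}"
        )
    ref_id = aln.id_a if reference_row == "a" else aln.id_b
    if st.seq_id and ref_id not in ("a", "b") and st.seq_id != ref_id:
        raise ConsistencyError(f"structure is for {st.seq_id!r}, reference row is {ref_id!r}")
    ctx: dict[int, ColumnContext] = {}
    for i, j in st.pairs:
        ci, cj = pos2col[i], pos2col[j]
        ctx[ci] = ColumnContext(partner_column=cj, helix=st.helix_labels.get(i))
        ctx[cj] = ColumnContext(partner_column=ci, helix=st.helix_labels.get(j))
    masked = frozenset(pos2col[p] for p in primer_mask if p in pos2col)
    return StructuredAlignment(
        alignment=aln, column_context=ctx, reference_row=reference_row, masked_columns=masked
    )


@dataclass(frozen=True)
class TransferFlag:
    """One noteworthy event during template transfer."""

    kind: str  # "dropped_gap" | "non_complementary"
    template_pair: Pair
    query_pair: Optional[Pair] = None


def transfer_structure(
    template: SecondaryStructure, aln: PairwiseAlignment
) -> tuple[SecondaryStructure, list[TransferFlag]]:
    """Transfer a template structure (on row_a) onto the query (row_b).

    A template pair survives iff the query holds residues at both partner columns;
    pairs lost to query gaps are reported as ``dropped_gap`` flags. Surviving
    pairs whose query bases are not complementary are kept but flagged
    ``non_complementary`` so downstream comparison can classify them as uncoupled
    sites. Helix labels are inherited position-wise.
    """
    saln = map_structure(template, aln, reference_row="a")
    qpos2col = aln.position_to_column("b")
    col2qpos = {c: p for p, c in qpos2col.items()}
    tpos2col = aln.position_to_column("a")
    query = aln.degapped("b")
    pairs, labels, flags = set(), {}, []
    for i, j in sorted(template.pairs):
        ci, cj = tpos2col[i], tpos2col[j]
        qi, qj = col2qpos.get(ci), col2qpos.get(cj)
        if qi is None or qj is None:
            flags.append(TransferFlag(kind="dropped_gap", template_pair=(i, j)))
            continue
        pairs.add((qi, qj))
        if i in template.helix_labels:
            labels[qi] = template.helix_labels[i]
        if j in template.helix_labels:
            labels[qj] = template.helix_labels[j]
        if is_complementary(query[qi - 1], query[qj - 1]) is False:
            flags.append(
                TransferFlag(kind="non_complementary", template_pair=(i, j), query_pair=(qi, qj))
            )
    qid = aln.id_b
    return SecondaryStructure(seq_id=qid, pairs=frozenset(pairs), helix_labels=labels), flags


# ---------------------------------------------------------------------------
# toy maximum-pairing fold (test fallback, not a thermodynamic model)


def fold_max_pairing(seq: str, min_loop: int = 3) -> SecondaryStructure:
    """Nested structure maximising the number of complementary pairs (Nussinov DP).

    This is a combinatorial stand-in used to build test structures; it is *not* an
    energy model. Pairs require ``j - i > min_loop``. Traceback is deterministic:
    at each subproblem the 5' base is paired with the smallest admissible partner
    that achieves the optimum, and left unpaired only when no pairing does.
    """
    if not seq:
        raise ParameterError("fold_max_pairing: empty sequence")
    if min_loop < 0:
        raise ParameterError("min_loop must be >= 0")
    n = len(seq)
    best = [[0] * (n + 1) for _ in range(n + 2)]  # best[i][j], 1-based inclusive

    def ok(i, j):
        return j - i > min_loop and is_complementary(seq[i - 1], seq[j - 1]) is True

    for span in range(1, n):
        for i in range(1, n - span + 1):
            j = i + span
            b = best[i + 1][j]  # i unpaired
            for k in range(i + 1, j + 1):
                if ok(i, k):
                    cand = 1 + best[i + 1][k - 1] + (best[k + 1][j] if k < j else 0)
                    if cand > b:
                        b = cand
            best[i][j] = b

    pairs = set()
    stack = [(1, n)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = best[i][j]
        paired = False
        for k in range(i + 1, j + 1):
            if ok(i, k):
                cand = 1 + best[i + 1][k - 1] + (best[k + 1][j] if k < j else 0)
                if cand == target and target > 0:
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    if k < j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return SecondaryStructure(seq_id="", pairs=frozenset(pairs))
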