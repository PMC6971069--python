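"""Sequence I/O, region handling, pairwise alignment and group I intron excision.

Coordinates are 1-based inclusive throughout, matching the base numbering used in
rRNA structure diagrams. Sequences are held as RNA (``T`` is normalised to ``U`` on
input); IUPAC ambiguity codes are retained, never expanded. Lower-case input runs
mark primer-binding positions and are recorded in ``primer_mask``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .errors import FormatError, ParameterError, RegionLookupError

#: IUPAC nucleotide codes on the RNA alphabet (after T→U normalisation).
IUPAC_RNA = frozenset("ACGURYSWKMBDHVN")
#: Unambiguous bases.
CANONICAL = frozenset("ACGU")
GAP = "-"

Interval = tuple[int, int]


@dataclass(frozen=True)
class AnnotatedSequence:
    """An rDNA sequence with region, intron and primer-mask annotations.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : str
        Upper-case RNA residues (IUPAC codes allowed).
    regions : mapping of str to (int, int)
        Named 1-based inclusive intervals, e.g. ``{"SSU": (1, 1767)}``.
    introns : sequence of (int, int)
        Mutually non-overlapping 1-based inclusive intron intervals.
    primer_mask : frozenset of int
        1-based positions that were lower-case on input (primer-binding region).
    """

    id: str
    residues: str
    regions: Mapping[str, Interval] = field(default_factory=dict)
    introns: Sequence[Interval] = field(default_factory=tuple)
    primer_mask: frozenset = frozenset()

    def __post_init__(self):
        bad = [(i + 1, c) for i, c in enumerate(self.residues) if c not in IUPAC_RNA]
        if bad:
            pos, c = bad[0]
            raise FormatError(f"{self.id}: non-IUPAC character {c!r} at position {pos}")
        n = len(self.residues)
        for name, (s, e) in self.regions.items():
            if not (1 <= s <= e <= n):
                raise FormatError(f"{self.id}: region {name}=[{s},{e}] outside [1,{n}]")
        ivs = sorted(self.introns)
        for s, e in ivs:
            if not (1 <= s <= e <= n):
                raise FormatError(f"{self.id}: intron [{s},{e}] outside [1,{n}]")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.id}: overlapping intron intervals")
        object.__setattr__(self, "introns", tuple(ivs))
        object.__setattr__(self, "regions", dict(self.regions))
        object.__setattr__(self, "primer_mask", frozenset(self.primer_mask))

    def __len__(self) -> int:
        return len(self.residues)


def _normalise(raw: str, seq_id: str) -> tuple[str, frozenset]:
    mask = frozenset(i + 1 for i, c in enumerate(raw) if c.islower())
    residues = raw.upper().replace("T", "U")
    bad = [(i + 1, c) for i, c in enumerate(residues) if c not in IUPAC_RNA]
    if bad:
        pos, c = bad[0]
        raise FormatError(f"{seq_id}: non-IUPAC character {c!r} at position {pos}")
    return residues, mask


def read_fasta(path) -> list[AnnotatedSequence]:
    """Read a (multi-)FASTA file into :class:`AnnotatedSequence` records.

    ``T``/``t`` is normalised to ``U``; lower-case runs populate ``primer_mask``.
    Empty records and non-IUPAC characters raise :class:`FormatError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        residues, mask = _normalise(raw, rec.id)
        records.append(AnnotatedSequence(id=rec.id, residues=residues, primer_mask=mask))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(seqs: Iterable[AnnotatedSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            chars = [c.lower() if (i + 1) in s.primer_mask else c for i, c in enumerate(s.residues)]
            fh.write(f">{s.id}\n{''.join(chars)}\n")


def read_regions_tsv(path) -> dict[str, dict[str, Interval]]:
    """Read a region annotation table (columns: seq_id, region, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "region": str})
    missing = {"seq_id", "region", "start", "end"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, dict[str, Interval]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.seq_id, {})[row.region] = (int(row.start), int(row.end))
    return out


def annotate(seq: AnnotatedSequence, regions: Mapping[str, Interval]) -> AnnotatedSequence:
    """Return a copy of *seq* with *regions* merged into its annotations."""
    merged = dict(seq.regions)
    merged.update(regions)
    return replace(seq, regions=merged)


def extract_region(seq: AnnotatedSequence, name: str) -> AnnotatedSequence:
    """Slice out a named region, clipping and re-basing intron/mask annotations."""
    if name not in seq.regions:
        raise RegionLookupError(f"{seq.id}: unknown region {name!r} (have {sorted(seq.regions)})")
    s, e = seq.regions[name]
    introns = []
    for a, b in seq.introns:
        a2, b2 = max(a, s), min(b, e)
        if a2 <= b2:
            introns.append((a2 - s + 1, b2 - s + 1))
    mask = frozenset(p - s + 1 for p in seq.primer_mask if s <= p <= e)
    return AnnotatedSequence(
        id=seq.id,
        residues=seq.residues[s - 1 : e],
        regions={name: (1, e - s + 1)},
        introns=introns,
        primer_mask=mask,
    )


# ---------------------------------------------------------------------------
# pairwise alignment


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap global alignment scores (defaults chosen for rDNA-scale identity)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length; columns are 1-based."""

    row_a: str
    row_b: str
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise FormatError(
                f"alignment rows of unequal length ({len(self.row_a)} vs {len(self.row_b)})"
            )

    def __len__(self) -> int:
        return len(self.row_a)

    def column(self, col: int) -> tuple[str, str]:
        """The (row_a, row_b) states at 1-based column *col*."""
        return self.row_a[col - 1], self.row_b[col - 1]

    def degapped(self, row: str) -> str:
        text = self.row_a if row == "a" else self.row_b
        return text.replace(GAP, "")

    def position_to_column(self, row: str) -> dict[int, int]:
        """Map ungapped 1-based positions of a row to alignment columns."""
        text = self.row_a if row == "a" else self.row_b
        out, pos = {}, 0
        for col, c in enumerate(text, start=1):
            if c != GAP:
                pos += 1
                out[pos] = col
        return out


def align_global(
    a: AnnotatedSequence, b: AnnotatedSequence, params: AlignParams = AlignParams()
) -> PairwiseAlignment:
    """Global affine-gap alignment of two sequences (deterministic for fixed params)."""
    if not a.residues or not b.residues:
        raise ParameterError("align_global: empty input sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(a.residues, b.residues)[0]
    return PairwiseAlignment(row_a=str(aln[0]), row_b=str(aln[1]), id_a=a.id, id_b=b.id)


def excise_introns(
    aln: PairwiseAlignment, min_insert: int = 50, query_row: str = "a"
) -> tuple[AnnotatedSequence, list[Interval]]:
    """Remove group I intron insertion blocks from the query row of *aln*.

    A group I intron appears as a long block of residues in the query facing gaps
    in an intron-free reference. Every maximal run of at least *min_insert*
    consecutive columns where the reference is gapped and the query holds residues
    is excised and reported as one intron, in 1-based coordinates on the original
    (un-excised) query sequence.

    Returns the intron-free query as an :class:`AnnotatedSequence` and the list of
    excised intervals. Excision is idempotent: an intron-free query comes back
    unchanged with an empty interval list.
    """
    if query_row not in ("a", "b"):
        raise ParameterError("query_row must be 'a' or 'b'")
    if min_insert < 1:
        raise ParameterError("min_insert must be >= 1")
    q = aln.row_a if query_row == "a" else aln.row_b
    r = aln.row_b if query_row == "a" else aln.row_a
    qid = aln.id_a if query_row == "a" else aln.id_b

    introns: list[Interval] = []
    kept: list[str] = []
    qpos = 0
    run_start = None  # query position of first residue in current insertion run
    run_chars: list[str] = []

    def flush():
        nonlocal run_start, run_chars
        if run_start is not None:
            if len(run_chars) >= min_insert:
                introns.append((run_start, run_start + len(run_chars) - 1))
            else:
                kept.extend(run_chars)
            run_start, run_chars = None, []

    # Runs below min_insert are alignment slop, not introns: keep their residues.
    # Because excised blocks are removed wholesale, original-coordinate bookkeeping
    # only needs the query position counter.
    for qc, rc in zip(q, r):
        if qc != GAP:
            qpos += 1
        if rc == GAP and qc != GAP:
            if run_start is None:
                run_start = qpos
            run_chars.append(qc)
        else:
            flush()
            if qc != GAP:
                kept.append(qc)
    flush()

    # Short runs flushed late keep residues in order because flush() precedes the
    # append of the current column's residue.
    kept_seq = "".join(kept)
    return AnnotatedSequence(id=qid, residues=kept_seq), introns


def reinsert_introns(excised: str, introns: Sequence[Interval], blocks: Sequence[str]) -> str:
    """Inverse of :func:`excise_introns` given the excised residue blocks."""
    out = list(excised)
    for (s, _), block in sorted(zip(introns, blocks)):
        out[s - 1 : s - 1] = block
    return "".join(out)


# ---------------------------------------------------------------------------
# multiple alignments (for synapomorphy scans)


@dataclass(frozen=True)
class MultipleAlignment:
    """Named gapped rows of equal length (aligned multi-FASTA in memory)."""

    rows: Mapping[str, str]

    def __post_init__(self):
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise FormatError("multiple alignment rows of unequal length")
        object.__setattr__(self, "rows", dict(self.rows))

    def __len__(self) -> int:
        return next(iter(map(len, self.rows.values())), 0)

    @property
    def tip_names(self) -> list[str]:
        return list(self.rows)

    def state(self, tip: str, column: int) -> str:
        if tip not in self.rows:
            raise RegionLookupError(f"tip {tip!r} absent from alignment")
        return self.rows[tip][column - 1]


def read_alignment_fasta(path) -> MultipleAlignment:
    """Read an aligned multi-FASTA (gaps allowed) into a :class:`MultipleAlignment`."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        row = raw.upper().replace("T", "U")
        bad = [(i + 1, c) for i, c in enumerate(row) if c not in IUPAC_RNA and c != GAP]
        if bad:
            pos, c = bad[0]
            raise FormatError(f"{rec.id}: non-IUPAC character {c!r} at column {pos}")
        rows[rec.id] = row
    if not rows:
        raise FormatError(f"{path}: no FASTA records")
    return MultipleAlignment(rows=rows)


def write_alignment_fasta(maln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in maln.rows.items():
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# trees and reports


def read_tree(path):
    """Parse a Newick tree with uniquely named tips into a :class:`Phylogeny`."""
    from .synapomorphy import Phylogeny  # local import avoids a module cycle

    return Phylogeny.from_newick_file(path)


def write_report(report: Sequence[Mapping], path, format: str = "tsv") -> None:
    """Write a list-of-records report as TSV or JSON (lossless round-trip)."""
    records = [dict(r) for r in report]
    if format == "tsv":
        pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
    elif format == "json":
        Path(path).write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ParameterError(f"unknown report format {format!r}")


def read_report(path, format: str = "tsv") -> list[dict]:
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        return df.to_dict(orient="records")
    if format == "json":
        return json.loads(Path(path).read_text())
    raise ParameterError(f"unknown report format {format!r}")
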