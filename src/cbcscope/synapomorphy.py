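"""Clade-diagnostic character mapping on a supplied phylogeny.

A state fixed in a clade is *synapomorphic* when it differs from every state in
the clade's sister group, and a *non-homoplasious synapomorphy* (NHS) when it
additionally occurs in no tip outside the clade at all. Paired sites are handled
as a unit so a clade-defining base-pair replacement can be reported as a CBC or
hemi-CBC synapomorphy. "Derived" is decided by direct comparison with the sister
group and outside taxa, not by ancestral-state reconstruction: this mirrors how
such diagnostic changes are read off comparative structure diagrams.

Gaps count as a fifth state, so diagnostic indels are reported (flagged
``is_indel``). A clade comprising every tip has no outside and is defined as
not synapomorphic rather than an error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .errors import FormatError, RegionLookupError, TopologyError
from .seqio import GAP, MultipleAlignment
from .structure import is_complementary

#: Sentinel returned when a clade does not share a single state at a column.
POLYMORPHIC = object()


class Phylogeny:
    """A rooted tree with uniquely named tips, queried by tip-name sets."""

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
        if any(lb is None for lb in labels):
            raise FormatError("tree has unnamed tips")
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate tip names in tree")
        self._tips = frozenset(labels)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"unparseable Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick_file(cls, path) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text())

    @property
    def tips(self) -> frozenset:
        return self._tips

    def _leafset(self, node) -> frozenset:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def _mrca(self, clade: frozenset):
        unknown = clade - self._tips
        if unknown:
            raise RegionLookupError(f"tips absent from tree: {sorted(unknown)}")
        return self._tree.mrca(taxon_labels=list(clade))

    def is_monophyletic(self, clade) -> bool:
        clade = frozenset(clade)
        if not clade:
            return False
        node = self._mrca(clade)
        return self._leafset(node) == clade

    def sister_tips(self, clade) -> Optional[frozenset]:
        """Tips of the sister group of a monophyletic clade (None at the root)."""
        clade = frozenset(clade)
        node = self._mrca(clade)
        if self._leafset(node) != clade:
            raise TopologyError(f"clade {sorted(clade)} is not monophyletic")
        parent = node.parent_node
        if parent is None:
            return None
        out = frozenset()
        for child in parent.child_nodes():
            if child is not node:
                out |= self._leafset(child)
        return out


class SynapomorphyClass(enum.Enum):
    NHS = "NHS"
    HOMOPLASIOUS_SYNAPOMORPHY = "homoplasious-synapomorphy"
    AUTAPOMORPHY = "autapomorphy"
    NOT_SYNAPOMORPHIC = "not-synapomorphic"


class PairedClass(enum.Enum):
    CBC = "CBC"
    HEMI_CBC = "hemi-CBC"


@dataclass(frozen=True)
class SynapomorphyCall:
    """Classification of one column (or partner-column couple) for one clade."""

    columns: tuple
    clade: frozenset
    derived_state: Optional[tuple]
    klass: SynapomorphyClass
    paired_klass: Optional[PairedClass] = None
    is_indel: bool = False

    def to_record(self) -> dict:
        return {
            "column": self.columns[0],
            "partner": self.columns[1] if len(self.columns) == 2 else "",
            "clade": ",".join(sorted(self.clade)),
            "derived_state": "".join(self.derived_state) if self.derived_state else "",
            "class": self.klass.value,
            "paired_class": self.paired_klass.value if self.paired_klass else "",
            "is_indel": self.is_indel,
        }


def clade_state(maln: MultipleAlignment, column: int, clade):
    """Shared state of the clade at a column, or :data:`POLYMORPHIC`."""
    states = {maln.state(t, column) for t in clade}
    return states.pop() if len(states) == 1 else POLYMORPHIC


def _states(maln: MultipleAlignment, column: int, tips) -> set:
    return {maln.state(t, column) for t in tips}


def classify_synapomorphy(
    maln: MultipleAlignment, column: int, clade, tree: Phylogeny
) -> SynapomorphyCall:
    """Classify a single column as NHS / homoplasious / autapomorphic / neither."""
    clade = frozenset(clade)
    if not tree.is_monophyletic(clade):
        raise TopologyError(f"clade {sorted(clade)} is not monophyletic")
    not_call = SynapomorphyCall(
        columns=(column,), clade=clade, derived_state=None,
        klass=SynapomorphyClass.NOT_SYNAPOMORPHIC,
    )
    if clade == tree.tips:
        return not_call  # no outside group to polarise against
    s = clade_state(maln, column, clade)
    if s is POLYMORPHIC:
        return not_call
    sister = tree.sister_tips(clade)
    # derived means the sister group is not fixed for s (a polymorphic sister
    # sharing s still leaves the clade's fixation diagnostic)
    if sister and _states(maln, column, sister) == {s}:
        return not_call
    outside = tree.tips - clade
    if len(clade) == 1:
        klass = SynapomorphyClass.AUTAPOMORPHY
    elif s not in _states(maln, column, outside):
        klass = SynapomorphyClass.NHS
    else:
        klass = SynapomorphyClass.HOMOPLASIOUS_SYNAPOMORPHY
    return SynapomorphyCall(
        columns=(column,), clade=clade, derived_state=(s,), klass=klass, is_indel=s == GAP
    )


def classify_paired_synapomorphy(
    maln: MultipleAlignment, columns: tuple, clade, tree: Phylogeny
) -> SynapomorphyCall:
    """Classify a partner-column couple as a unit (CBC / hemi-CBC synapomorphy).

    The clade must share a fixed base-pair at the couple. The pair is
    synapomorphic when absent from the sister group, and NHS when absent from
    every outside tip. ``paired_klass`` is CBC when both sides differ from the
    sister pair with complementarity conserved on both, hemi-CBC when exactly
    one side differs with complementarity conserved; otherwise it is left unset.
    """
    c1, c2 = columns
    clade = frozenset(clade)
    if not tree.is_monophyletic(clade):
        raise TopologyError(f"clade {sorted(clade)} is not monophyletic")
    not_call = SynapomorphyCall(
        columns=(c1, c2), clade=clade, derived_state=None,
        klass=SynapomorphyClass.NOT_SYNAPOMORPHIC,
    )
    if clade == tree.tips:
        return not_call
    s1, s2 = clade_state(maln, c1, clade), clade_state(maln, c2, clade)
    if s1 is POLYMORPHIC or s2 is POLYMORPHIC:
        return not_call
    pair = (s1, s2)
    sister = tree.sister_tips(clade) or frozenset()
    sister_pairs = {(maln.state(t, c1), maln.state(t, c2)) for t in sister}
    if sister_pairs == {pair}:
        return not_call
    outside = tree.tips - clade
    outside_pairs = {(maln.state(t, c1), maln.state(t, c2)) for t in outside}
    if len(clade) == 1:
        klass = SynapomorphyClass.AUTAPOMORPHY
    elif pair not in outside_pairs:
        klass = SynapomorphyClass.NHS
    else:
        klass = SynapomorphyClass.HOMOPLASIOUS_SYNAPOMORPHY

    paired_klass = None
    if len(sister_pairs) == 1:
        t1, t2 = next(iter(sister_pairs))
        if GAP not in pair and GAP not in (t1, t2):
            changed = (s1 != t1) + (s2 != t2)
            conserved = is_complementary(s1, s2) and is_complementary(t1, t2)
            if conserved and changed == 2:
                paired_klass = PairedClass.CBC
            elif conserved and changed == 1:
                paired_klass = PairedClass.HEMI_CBC
    return SynapomorphyCall(
        columns=(c1, c2), clade=clade, derived_state=pair, klass=klass,
        paired_klass=paired_klass, is_indel=GAP in pair,
    )


def scan(
    maln: MultipleAlignment,
    tree: Phylogeny,
    clades: Mapping[str, Sequence[str]],
    paired_columns: Sequence[tuple] = (),
) -> list[SynapomorphyCall]:
    """Classify every column (and paired couple) against every requested clade.

    Returns the calls that are synapomorphic or autapomorphic, in deterministic
    (column, clade) order; not-synapomorphic results are omitted. When
    *paired_columns* couples are supplied their member columns are reported only
    as part of the couple, not again as single sites.
    """
    clade_sets = {name: frozenset(tips) for name, tips in clades.items()}
    for name, cl in clade_sets.items():
        if not tree.is_monophyletic(cl):
            raise TopologyError(f"clade {name!r} {sorted(cl)} is not monophyletic")
    in_couple = {c for couple in paired_columns for c in couple}
    calls = []
    for column in range(1, len(maln) + 1):
        if column in in_couple:
            continue
        for name in sorted(clade_sets):
            call = classify_synapomorphy(maln, column, clade_sets[name], tree)
            if call.klass is not SynapomorphyClass.NOT_SYNAPOMORPHIC:
                calls.append(call)
    for couple in sorted(tuple(sorted(c)) for c in paired_columns):
        for name in sorted(clade_sets):
            call = classify_paired_synapomorphy(maln, couple, clade_sets[name], tree)
            if call.klass is not SynapomorphyClass.NOT_SYNAPOMORPHIC:
                calls.append(call)
    return calls


def read_clades_tsv(path) -> dict[str, frozenset]:
    """Read clade definitions (columns: clade_name, tips as comma-separated list)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"clade_name", "tips"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return {
        r.clade_name: frozenset(t.strip() for t in r.tips.split(",") if t.strip())
        for r in df.itertuples(index=False)
    }
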