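"""Curation of cystine-dense peptide (CDP) libraries from source proteins.

A CDP motif is a short (30-50 residue) cysteine-bounded window of a larger
protein carrying an even number of cysteines (6, 8, or 10 by default) that
can pair into intra-chain disulfides.  This module extracts such windows
from caller-supplied protein records, annotates N-linked glycosylation
sequons and native-protein context, and assembles a screening library by
taxonomy-weighted sampling so that no single over-represented class
dominates the library.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: class label assigned to records whose lineage is missing or unparsable
UNKNOWN_CLASS = "UNKNOWN"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValidationError("sequence must be non-empty")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValidationError(
            f"sequence contains non-canonical letters: {sorted(bad)!r}"
        )


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A source protein with optional lineage and annotation.

    ``taxonomy`` is an ordered lineage, at least (kingdom, class) when
    known; an empty tuple means the lineage is missing or corrupt and the
    record is treated as class :data:`UNKNOWN_CLASS` during sampling.
    """

    id: str
    sequence: str
    taxonomy: tuple[str, ...] = ()
    annotation: str | None = None

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)

    @property
    def tax_class(self) -> str:
        """The second lineage level, or :data:`UNKNOWN_CLASS` if absent."""
        if len(self.taxonomy) >= 2 and self.taxonomy[1]:
            return self.taxonomy[1]
        return UNKNOWN_CLASS


@dataclasses.dataclass(frozen=True)
class CdpMotif:
    """A cysteine-bounded window of a parent protein.

    Coordinates are 0-based half-open into the parent sequence; the window
    begins and ends on a cysteine and carries ``cys_count`` cysteines in
    total.
    """

    parent_id: str
    start: int
    end: int
    cys_count: int
    sequence: str

    def validate(self, parent_sequence: str) -> None:
        """Re-check every structural invariant against the parent."""
        if parent_sequence[self.start : self.end] != self.sequence:
            raise ValidationError("motif sequence does not match parent slice")
        if not (self.sequence.startswith("C") and self.sequence.endswith("C")):
            raise ValidationError("motif must begin and end with C")
        if self.sequence.count("C") != self.cys_count:
            raise ValidationError("cys_count does not match sequence")


class ContextCategory(str, enum.Enum):
    """Fraction of the native protein occupied by the displayed peptide."""

    LT25 = "LT25"          # < 25 %
    P25TO50 = "P25TO50"    # 25-50 %
    GE50 = "GE50"          # >= 50 %


@dataclasses.dataclass(frozen=True)
class PeptideAnnotation:
    glycosite_positions: tuple[int, ...]
    context_fraction: float
    context_category: ContextCategory


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def scan_cysteine_motifs(
    protein: ProteinRecord,
    allowed_counts: Iterable[int] = (6, 8, 10),
    min_len: int = 30,
    max_len: int = 50,
    collapse_nested: bool = True,
) -> list[CdpMotif]:
    """Enumerate cysteine-bounded windows with an allowed cysteine count.

    Every window that starts and ends on a cysteine, whose length lies in
    ``[min_len, max_len]`` and whose total cysteine count is in
    ``allowed_counts`` is reported.  With ``collapse_nested`` (default) a
    window strictly contained in another reported window of the same parent
    is dropped, so the output approximates maximal cysteine-dense segments.
    Output is deterministic, sorted by ``(start, end)``.
    """
    allowed = set(allowed_counts)
    if not allowed:
        raise ValidationError("allowed_counts must be non-empty")
    if min_len > max_len:
        raise ValidationError("min_len must be <= max_len")
    seq = protein.sequence
    _check_sequence(seq)

    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    # prefix count of C up to (exclusive) each index, for O(1) window counts
    prefix = np.zeros(len(seq) + 1, dtype=int)
    for i in cys:
        prefix[i + 1] = 1
    prefix = np.cumsum(prefix)

    windows: list[tuple[int, int]] = []
    for a in cys:
        for b in cys:
            length = b - a + 1
            if length < min_len:
                continue
            if length > max_len:
                break
            if prefix[b + 1] - prefix[a] in allowed:
                windows.append((a, b + 1))

    if collapse_nested:
        windows = [
            (s, e)
            for (s, e) in windows
            if not any(
                (s2 <= s and e <= e2) and (s2, e2) != (s, e)
                for (s2, e2) in windows
            )
        ]

    windows.sort()
    return [
        CdpMotif(
            parent_id=protein.id,
            start=s,
            end=e,
            cys_count=int(prefix[e] - prefix[s]),
            sequence=seq[s:e],
        )
        for s, e in windows
    ]


def find_glycosites(sequence: str, canonical_mode: bool = False) -> list[int]:
    """Positions of N-linked glycosylation sequons (N-X-S/T).

    Returns every 0-based position ``i`` with ``sequence[i] == 'N'`` and
    ``sequence[i+2]`` in ``{S, T}``; overlapping sequons are all reported.
    With ``canonical_mode`` the middle residue must additionally not be
    proline (N-X-S/T, X != P), the rule under which the sequon is actually
    glycosylated in vivo.
    """
    _check_sequence(sequence)
    out = []
    for i in range(len(sequence) - 2):
        if sequence[i] != "N" or sequence[i + 2] not in "ST":
            continue
        if canonical_mode and sequence[i + 1] == "P":
            continue
        out.append(i)
    return out


def context_category(
    peptide_length: int, protein_length: int
) -> tuple[float, ContextCategory]:
    """Fraction of the native protein the peptide spans, and its category.

    Boundaries are assigned upward: exactly 25 % falls in ``P25TO50`` and
    exactly 50 % in ``GE50``.
    """
    if peptide_length <= 0 or protein_length <= 0:
        raise ValidationError("lengths must be positive")
    if peptide_length > protein_length:
        raise ValidationError("peptide cannot be longer than its protein")
    fraction = peptide_length / protein_length
    if fraction < 0.25:
        cat = ContextCategory.LT25
    elif fraction < 0.5:
        cat = ContextCategory.P25TO50
    else:
        cat = ContextCategory.GE50
    return fraction, cat


def annotate_peptide(
    motif: CdpMotif, protein_length: int, canonical_mode: bool = False
) -> PeptideAnnotation:
    """Glycosites plus native-protein context for one motif."""
    fraction, cat = context_category(len(motif.sequence), protein_length)
    return PeptideAnnotation(
        glycosite_positions=tuple(find_glycosites(motif.sequence, canonical_mode)),
        context_fraction=fraction,
        context_category=cat,
    )


# ---------------------------------------------------------------------------
# Taxonomy-weighted sampling
# ---------------------------------------------------------------------------

def _allocate_proportional(
    n: int,
    weights: dict[str, float],
    capacities: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Allocate ``n`` draws across classes proportionally to their
    weights, respecting class sizes.

    Fractional targets are rounded by systematic (PPS) sampling so each
    class's expected allocation equals its target exactly; overflow past
    a class's capacity is redistributed among the remaining classes.
    """
    alloc = {cls: 0 for cls in weights}
    active = [cls for cls in weights if capacities[cls] > 0]
    remaining = n
    while remaining > 0:
        w = np.array([weights[cls] for cls in active], dtype=float)
        targets = remaining * w / w.sum()
        base = np.floor(targets).astype(int)
        frac = targets - base
        extra = np.zeros(len(active), dtype=int)
        r = remaining - int(base.sum())
        if r > 0:
            # systematic selection of r units with P(class) = frac
            cum = np.cumsum(frac)
            points = (rng.random() + np.arange(r)) * cum[-1] / r
            picked = np.searchsorted(cum, points, side="left")
            np.add.at(extra, np.minimum(picked, len(active) - 1), 1)
        step = base + extra
        overflow = 0
        next_active = []
        for i, cls in enumerate(active):
            room = capacities[cls] - alloc[cls]
            take = min(int(step[i]), room)
            overflow += int(step[i]) - take
            alloc[cls] += take
            if capacities[cls] - alloc[cls] > 0:
                next_active.append(cls)
        remaining = overflow
        if remaining > 0 and step.sum() == 0:
            # degenerate targets (all < 1 and nothing picked): force one
            remaining -= 1
            pick = next_active[int(rng.integers(len(next_active)))]
            alloc[pick] += 1
            next_active = [c for c in next_active if capacities[c] - alloc[c] > 0]
        active = next_active
    return alloc


def taxonomy_weighted_sample(
    candidates: Sequence[ProteinRecord],
    class_weights: Mapping[str, float],
    n: int,
    seed: int,
    default_weight: float = 1.0,
) -> list[str]:
    """Sample ``n`` candidate ids without replacement, flattening classes.

    Classes are first flattened to equal mass and then re-weighted: the
    draw is allocated across taxonomic classes proportionally to
    ``class_weights`` (so each candidate's inclusion probability is its
    class weight divided by the class's candidate count, up to capacity),
    then filled uniformly without replacement within each class.  A huge
    class cannot swamp the draw.  Records with missing lineage fall in
    class :data:`UNKNOWN_CLASS` at ``default_weight``.  Deterministic for
    a fixed seed; output follows the input candidate order.
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    if n > len(candidates):
        raise ValidationError("cannot sample more candidates than supplied")
    if any(w <= 0 for w in class_weights.values()):
        raise ValidationError("all class weights must be positive")

    members: dict[str, list[int]] = {}
    for i, rec in enumerate(candidates):
        members.setdefault(rec.tax_class, []).append(i)
    weights = {
        cls: float(class_weights.get(cls, default_weight)) for cls in members
    }
    capacities = {cls: len(idx) for cls, idx in members.items()}
    rng = np.random.default_rng(seed)
    alloc = _allocate_proportional(n, weights, capacities, rng)
    chosen: list[int] = []
    for cls in members:
        k = alloc[cls]
        if k:
            chosen.extend(
                rng.choice(members[cls], size=k, replace=False).tolist()
            )
    return [candidates[i].id for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# FASTA / TSV interfaces
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA; ``taxonomy=kingdom;class`` may appear in
    the description and is parsed into the record lineage."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxonomy: tuple[str, ...] = ()
        for field in rec.description.split():
            if field.startswith("taxonomy="):
                taxonomy = tuple(field[len("taxonomy="):].split(";"))
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), taxonomy=taxonomy)
        )
    return records


def write_motif_fasta(motifs: Iterable[CdpMotif], path: str | Path) -> None:
    """Write motifs as FASTA with ``parent|start-end`` headers."""
    recs = [
        SeqRecord(
            Seq(m.sequence),
            id=f"{m.parent_id}|{m.start}-{m.end}",
            description="",
        )
        for m in motifs
    ]
    SeqIO.write(recs, str(path), "fasta")


def apply_blocklist(
    records: Sequence[ProteinRecord], blocked_ids: Iterable[str]
) -> list[ProteinRecord]:
    """Drop records whose id appears in a caller-supplied blocklist
    (e.g. regulated toxins)."""
    blocked = set(blocked_ids)
    return [r for r in records if r.id not in blocked]


def annotation_table(
    motifs: Sequence[CdpMotif],
    proteins: Mapping[str, ProteinRecord],
    canonical_mode: bool = False,
) -> pd.DataFrame:
    """Tabulate motif annotations for export as TSV."""
    rows = []
    for m in motifs:
        parent = proteins[m.parent_id]
        ann = annotate_peptide(m, len(parent.sequence), canonical_mode)
        taxonomy = parent.taxonomy
        rows.append(
            {
                "id": f"{m.parent_id}|{m.start}-{m.end}",
                "parent_id": m.parent_id,
                "start": m.start,
                "end": m.end,
                "cys_count": m.cys_count,
                "length": len(m.sequence),
                "glycosites": ",".join(map(str, ann.glycosite_positions)),
                "context_fraction": ann.context_fraction,
                "context_category": ann.context_category.value,
                "kingdom": taxonomy[0] if taxonomy else "",
                "class": parent.tax_class,
            }
        )
    return pd.DataFrame(rows)
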