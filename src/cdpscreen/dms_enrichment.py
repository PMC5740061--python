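"""Site-saturation mutagenesis (SSM) enrichment scoring.

An SSM library holds every single-residue substitution of a parent
peptide, here excluding cysteine substitutions so the disulfide scaffold
is preserved.  Reads are assigned to variants by full-length exact
identity (the variants differ by a single residue, so any mismatch
tolerance would cross-map them), and a variant's selection phenotype is
the log2 fold-change of its population frequency after selection versus
the input pool, normalized to the wild type's fold-change:

    E_v = log2( f_v,sel / f_v,in ) - log2( f_wt,sel / f_wt,in )

with frequencies smoothed by a pseudocount.  The wild-type cell of the
position x substitution matrix is identically 0 by construction.

Position numbering is 1-based into the displayed peptide, which begins
after the "GS" left behind by protease cleavage of the expression tag.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: TB1G1, the designed three-helix TEAD-binding parent peptide of the
#: affinity-maturation screen (40 residues, 6 cysteines; numbering starts
#: after the GS left behind by expression-tag cleavage)
TB1G1_SEQUENCE = "PDEYIERAKECCKKGDIQCCLRYFEESGDPNVMLICLFCP"

#: heat-map row order: substitutions grouped by chemical category
CHEMICAL_CATEGORIES: tuple[tuple[str, str], ...] = (
    ("nonpolar_aliphatic", "AVLIM"),
    ("aromatic", "FWY"),
    ("polar_uncharged", "STNQ"),
    ("positively_charged", "KRH"),
    ("negatively_charged", "DE"),
    ("special", "GPC"),
)

HEATMAP_ROW_ORDER: tuple[str, ...] = tuple(
    aa for _, group in CHEMICAL_CATEGORIES for aa in group
)


@dataclasses.dataclass(frozen=True)
class SsmVariant:
    """One single-residue substitution of the wild-type peptide."""

    position: int          # 1-based
    wt_aa: str
    mut_aa: str
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def build_ssm_library(
    wt_sequence: str, excluded_substitutions: Iterable[str] = ("C",)
) -> list[SsmVariant]:
    """Enumerate every single substitution of the wild type.

    At each position one variant per amino acid that is neither excluded
    (cysteine by default) nor the wild-type residue; wild-type cysteines
    ARE mutagenized to non-cysteine residues.  Ordered by position, then
    alphabetical substitution.
    """
    if not wt_sequence:
        raise ValueError("wild-type sequence must be non-empty")
    bad = set(wt_sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-canonical residues in wild type: {sorted(bad)}")
    excluded = set(excluded_substitutions)
    variants = []
    for pos0, wt_aa in enumerate(wt_sequence):
        for mut in AMINO_ACIDS:
            if mut == wt_aa or mut in excluded:
                continue
            seq = wt_sequence[:pos0] + mut + wt_sequence[pos0 + 1 :]
            variants.append(
                SsmVariant(position=pos0 + 1, wt_aa=wt_aa, mut_aa=mut, sequence=seq)
            )
    return variants


def count_exact_matches(
    reads: Iterable[str], references: Mapping[str, str]
) -> tuple[pd.Series, int]:
    """Assign reads to references by full-length exact identity.

    Returns (counts per reference id, number of unassigned reads).  Every
    read increments exactly one tally, so assigned + unassigned equals
    the number of reads.
    """
    seq_to_id: dict[str, str] = {}
    for vid, seq in references.items():
        if seq in seq_to_id:
            raise ValueError(
                f"duplicate reference sequence for ids {seq_to_id[seq]!r} and {vid!r}"
            )
        seq_to_id[seq] = vid
    counts = {vid: 0 for vid in references}
    unassigned = 0
    for read in reads:
        vid = seq_to_id.get(read)
        if vid is None:
            unassigned += 1
        else:
            counts[vid] += 1
    return pd.Series(counts, name="count"), unassigned


def enrichment_scores(
    counts: pd.DataFrame,
    wt_id: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Wild-type-normalized log2 enrichment per tracked sequence.

    ``counts`` has one row per tracked sequence (variants plus wild type)
    and columns ``input`` and ``round2``.  With V tracked sequences and
    column totals N,

        E_v = log2(((n_v,R2 + pc) / (N_R2 + pc*V)) /
                   ((n_v,in + pc) / (N_in + pc*V)))  -  [same for wt]

    so E_wt = 0 identically.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if wt_id not in counts.index:
        raise ValueError(f"wild-type id {wt_id!r} absent from counts")
    if counts.loc[wt_id, "input"] <= 0:
        raise ValueError("wild type must have nonzero input count")
    v = len(counts)
    raw = {}
    for col in ("input", "round2"):
        n = counts[col].astype(float)
        raw[col] = (n + pseudocount) / (n.sum() + pseudocount * v)
    log_ratio = np.log2(raw["round2"] / raw["input"])
    e = log_ratio - log_ratio.loc[wt_id]
    return e.rename("E")


def enrichment_matrix(
    variants: Sequence[SsmVariant],
    scores: pd.Series,
    wt_sequence: str,
) -> pd.DataFrame:
    """Pivot variant scores into the heat-map layout.

    Rows are substitutions in fixed chemical-category order, columns are
    1-based positions.  Wild-type identity cells are 0; variants without
    a score are NaN.
    """
    n_pos = len(wt_sequence)
    mat = pd.DataFrame(
        np.nan,
        index=list(HEATMAP_ROW_ORDER),
        columns=list(range(1, n_pos + 1)),
    )
    for var in variants:
        if var.id in scores.index:
            mat.loc[var.mut_aa, var.position] = scores[var.id]
    for pos0, wt_aa in enumerate(wt_sequence):
        if wt_aa in mat.index:
            mat.loc[wt_aa, pos0 + 1] = 0.0
    return mat


def position_average(matrix: pd.DataFrame, wt_sequence: str) -> pd.Series:
    """Arithmetic mean enrichment over the defined non-wild-type
    substitution cells at each position; NaN where no data exist."""
    out = {}
    for pos0, wt_aa in enumerate(wt_sequence):
        pos = pos0 + 1
        col = matrix[pos].drop(labels=[wt_aa], errors="ignore")
        vals = col.dropna()
        out[pos] = float(vals.mean()) if len(vals) else np.nan
    return pd.Series(out, name="position_average")


def tidy_scores(
    variants: Sequence[SsmVariant],
    scores: pd.Series,
    counts: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format export: position, wt_aa, mut_aa, E, n_input, n_round2."""
    rows = []
    for var in variants:
        if var.id not in scores.index:
            continue
        rows.append(
            {
                "position": var.position,
                "wt_aa": var.wt_aa,
                "mut_aa": var.mut_aa,
                "E": scores[var.id],
                "n_input": counts.loc[var.id, "input"],
                "n_round2": counts.loc[var.id, "round2"],
            }
        )
    return pd.DataFrame(rows)
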