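"""Surface protein-content quantitation from FACS sort-seq data.

Cells displaying a peptide library are sorted into a small number of
contiguous fluorescence gates (default four: lowest, low, high, highest)
and each gate is sequenced.  A peptide's read fraction within a gate,
scaled by that gate's sorted-cell count, estimates how many cells carrying
the peptide fell in the gate; the cell-weighted mean of the gate median
fluorescences is then a unitless estimate of the average surface
fluorescence of a cell expressing the peptide (the *protein content
score*, S).  Re-running the sort after limited trypsinization and
expressing the treated score as a percentage of the untreated one yields a
*trypsin resistance score* (T), a proxy for fold stability.

All public functions operate on pandas objects: read counts as a
``peptides x bins`` DataFrame and bin statistics as a DataFrame with
columns ``bin``, ``cell_count``, ``median_fluor`` (one row per gate, in
increasing fluorescence order).
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_BIN_ORDER = ("lowest", "low", "high", "highest")

#: default QC thresholds; the thresholds actually used for a given screen
#: are a reporting choice and must be set explicitly to match it
DEFAULT_PER_SAMPLE_MIN = 20
DEFAULT_MIN_INPUT_READS = 50


class BinMismatchError(ValueError):
    """Read-count bins do not match the supplied bin statistics."""


def _validate_bins(counts: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    bins = bins.set_index("bin") if "bin" in bins.columns else bins
    missing = set(counts.columns) - set(bins.index)
    if missing:
        raise BinMismatchError(f"bins missing statistics: {sorted(missing)}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    bins = bins.loc[list(counts.columns)]
    # a gate that sorted no cells is legal only if it also has no reads;
    # it carries no information and is dropped from the weighted mean
    empty = bins["cell_count"] <= 0
    if empty.any():
        if counts.loc[:, empty.to_numpy()].to_numpy().any():
            raise BinMismatchError("bin with zero sorted cells has reads")
        bins = bins[~empty]
    if (bins["cell_count"] <= 0).any() or (bins["median_fluor"] <= 0).any():
        raise ValueError("cell counts and median fluorescences must be positive")
    return bins


def content_score(
    counts: pd.DataFrame,
    bins: pd.DataFrame,
    log_domain: bool = False,
) -> pd.DataFrame:
    """Per-peptide protein content scores from one sorted sample.

    Within each gate ``b`` the peptide's read fraction ``f_ib`` estimates
    its share of the gate's ``C_b`` sorted cells, ``c_ib = f_ib * C_b``;
    the score is the cell-weighted mean of gate median fluorescences,

        S_i = sum_b c_ib * M_b / sum_b c_ib.

    With ``log_domain`` the weighted mean is taken over ``log10 M_b`` and
    ``10**mean`` reported.  Gates with zero total reads contribute zero
    estimated cells.  Peptides with no estimated cells anywhere are
    flagged undefined (``S`` is NaN, ``defined`` False) rather than
    scored zero.

    Returns a DataFrame indexed by peptide with columns ``S``,
    ``total_reads``, ``defined``.
    """
    binstats = _validate_bins(counts, bins)
    total_reads = counts.sum(axis=1).to_numpy()
    counts = counts[list(binstats.index)]
    r = counts.to_numpy(dtype=float)
    bin_totals = r.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(bin_totals > 0, r / bin_totals, 0.0)
    cells = frac * binstats["cell_count"].to_numpy()
    weight_sum = cells.sum(axis=1)
    m = binstats["median_fluor"].to_numpy()
    values = np.log10(m) if log_domain else m
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (cells * values).sum(axis=1) / weight_sum
    if log_domain:
        s = 10.0 ** s
    defined = weight_sum > 0
    s = np.where(defined, s, np.nan)
    return pd.DataFrame(
        {"S": s, "total_reads": total_reads, "defined": defined},
        index=counts.index,
    )


def estimated_cells(counts: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """The intermediate ``c_ib`` matrix (estimated cells per peptide/gate).

    For every gate with nonzero reads the column sums exactly to that
    gate's sorted-cell count (cell conservation).
    """
    binstats = _validate_bins(counts, bins)
    counts = counts[list(binstats.index)]
    r = counts.to_numpy(dtype=float)
    bin_totals = r.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(bin_totals > 0, r / bin_totals, 0.0)
    return pd.DataFrame(
        frac * binstats["cell_count"].to_numpy(),
        index=counts.index,
        columns=counts.columns,
    )


def trypsin_resistance(
    scores_treated: pd.DataFrame,
    scores_untreated: pd.DataFrame,
    floor: float | None = None,
    bins: pd.DataFrame | None = None,
) -> pd.Series:
    """Trypsin resistance T = 100 * S_treated / S_untreated, per peptide.

    Undefined (NaN) wherever either score is undefined or the untreated
    score falls below ``floor``; scores above 100 % are legitimate
    ("super-resistant") and passed through.  The default floor is 1 % of
    the smallest gate median when ``bins`` is given, else 0.
    """
    if floor is None:
        floor = 0.0 if bins is None else 0.01 * float(
            (bins.set_index("bin") if "bin" in bins.columns else bins)[
                "median_fluor"
            ].min()
        )
    s_u = scores_untreated["S"]
    s_t = scores_treated["S"].reindex(s_u.index)
    t = 100.0 * s_t / s_u
    t[~scores_untreated["defined"].astype(bool) | (s_u < floor)] = np.nan
    return t.rename("T")


def qc_filter(
    sample_counts: Mapping[str, pd.DataFrame],
    per_sample_min: int = DEFAULT_PER_SAMPLE_MIN,
    min_input_reads: int = DEFAULT_MIN_INPUT_READS,
    input_samples: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Read-abundance QC across samples.

    ``sample_counts`` maps a sample key (e.g. ``"untreated_rep1"``) to its
    peptide x bin count table.  A peptide passes a sample if its summed
    reads there reach ``per_sample_min``; it passes overall if it passes
    every sample and its summed reads over the ``input_samples`` (default:
    all samples) reach ``min_input_reads``.

    Returns a DataFrame with one boolean column per sample, an
    ``input_reads`` column, and ``pass_overall``.
    """
    if per_sample_min < 0 or min_input_reads < 0:
        raise ValueError("thresholds must be non-negative")
    totals = pd.DataFrame(
        {name: table.sum(axis=1) for name, table in sample_counts.items()}
    ).fillna(0)
    passes = totals >= per_sample_min
    input_cols = list(input_samples) if input_samples else list(totals.columns)
    input_reads = totals[input_cols].sum(axis=1)
    out = passes.copy()
    out["input_reads"] = input_reads
    out["pass_overall"] = passes.all(axis=1) & (input_reads >= min_input_reads)
    return out


def replicate_stats(
    scores_a: pd.Series,
    scores_b: pd.Series,
    log_domain: bool = False,
) -> tuple[pd.Series, float]:
    """Average two replicate score vectors and report their concordance.

    The average is the arithmetic mean of the per-peptide values defined
    in both replicates (geometric mean in ``log_domain``); R-squared is
    the squared Pearson correlation over the common defined peptides,
    computed in the configured domain.
    """
    common = scores_a.dropna().index.intersection(scores_b.dropna().index)
    if len(common) < 2:
        raise ValueError("need at least 2 peptides defined in both replicates")
    a = scores_a.loc[common].astype(float)
    b = scores_b.loc[common].astype(float)
    if log_domain:
        la, lb = np.log10(a), np.log10(b)
        avg = 10.0 ** ((la + lb) / 2.0)
        r = np.corrcoef(la, lb)[0, 1]
    else:
        avg = (a + b) / 2.0
        r = np.corrcoef(a, b)[0, 1]
    return avg, float(r * r)


def signal_to_noise(
    fluor_positive: np.ndarray, fluor_negative: np.ndarray
) -> float:
    """Ratio of median fluorescence in a stained (signal) vs unstained
    (noise) population; the display assay's sensitivity readout."""
    pos = np.asarray(fluor_positive, dtype=float)
    neg = np.asarray(fluor_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both populations must be non-empty")
    noise = float(np.median(neg))
    if noise <= 0:
        raise ValueError("noise median must be positive")
    return float(np.median(pos)) / noise


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> dict[tuple[str, int], pd.DataFrame]:
    """Read a long-format counts TSV (peptide_id, bin, condition,
    replicate, reads) into per-(condition, replicate) wide tables."""
    long = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, int], pd.DataFrame] = {}
    for (cond, rep), grp in long.groupby(["condition", "replicate"]):
        wide = grp.pivot_table(
            index="peptide_id", columns="bin", values="reads", fill_value=0
        )
        order = [b for b in DEFAULT_BIN_ORDER if b in wide.columns]
        out[(str(cond), int(rep))] = wide[order] if order else wide
    return out


def read_binstats_tsv(path: str | Path) -> dict[tuple[str, int], pd.DataFrame]:
    """Read a bin-statistics TSV (bin, condition, replicate, cell_count,
    median_fluor) into per-(condition, replicate) tables."""
    long = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, int], pd.DataFrame] = {}
    for (cond, rep), grp in long.groupby(["condition", "replicate"]):
        out[(str(cond), int(rep))] = grp[
            ["bin", "cell_count", "median_fluor"]
        ].reset_index(drop=True)
    return out


def write_quant_tsv(
    table: pd.DataFrame, path: str | Path, sidecar: Mapping | None = None
) -> None:
    """Write the quantitation table as TSV, with an optional JSON sidecar
    (e.g. replicate R-squared values) next to it."""
    table.to_csv(path, sep="\t", index=True, index_label="peptide_id")
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
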