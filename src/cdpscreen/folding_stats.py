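"""Folding classification and concordance statistics.

Two independent folding readouts are compared: a *surface* call splitting
peptides into high-content/trypsin-resistant (HC/TR) vs
low-content/trypsin-sensitive (LC/TS) by a line in (log10 content score,
resistance %) space, and a *solution* call from reversed-phase HPLC of the
secreted peptide (1-2 clean peaks in both native and reduced runs = well
folded; 3 or more peaks = poorly folded; no detectable material = not
secreted).  Their agreement is tested by permutation (shuffling the HPLC
labels), 2x2 contingency tables are compared by Pearson chi-square, and
enrichment of well-folded peptides among the bins of the sort is measured
with an unweighted (Kolmogorov-Smirnov running sum) gene-set enrichment
analysis.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
import math
import warnings
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_PERM = 1_000_000  # minimal attainable p = 1e-6


class SurfaceClass(str, enum.Enum):
    HC_TR = "HC_TR"
    LC_TS = "LC_TS"


class HplcClass(str, enum.Enum):
    PEAKS_1_2 = "PEAKS_1_2"
    PEAKS_3PLUS = "PEAKS_3PLUS"
    PEAKS_0 = "PEAKS_0"


@dataclasses.dataclass(frozen=True)
class SurfaceClassBoundary:
    """Line ``T = slope * log10(S) + intercept`` splitting score space.

    ``hc_above`` states which side is HC/TR (default: at or above the
    line).  The cutoff is an analysis choice, not a measured constant, so
    the parameters always come from configuration.
    """

    slope: float
    intercept: float
    hc_above: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("boundary parameters must be finite")


def classify_surface(
    s_untreated: pd.Series, t: pd.Series, boundary: SurfaceClassBoundary
) -> pd.Series:
    """HC/TR vs LC/TS call per peptide; points exactly on the boundary
    line are assigned to the HC/TR side.  Peptides with undefined S or T
    are left unclassified (None)."""
    s = s_untreated.astype(float)
    tt = t.reindex(s.index).astype(float)
    margin = tt - boundary.slope * np.log10(s) - boundary.intercept
    if not boundary.hc_above:
        margin = -margin
    labels = pd.Series(
        np.where(margin >= 0, SurfaceClass.HC_TR.value, SurfaceClass.LC_TS.value),
        index=s.index,
        dtype=object,
    )
    labels[~np.isfinite(margin)] = None
    return labels


def fit_boundary(
    s_untreated: pd.Series,
    t: pd.Series,
    reference_labels: pd.Series,
    slope_grid: np.ndarray | None = None,
    intercept_grid: np.ndarray | None = None,
) -> SurfaceClassBoundary:
    """Calibration helper: grid-search (slope, intercept) to best match a
    supplied reference HC/TR classification column."""
    x = np.log10(s_untreated.astype(float))
    y = t.reindex(s_untreated.index).astype(float)
    ref = reference_labels.reindex(s_untreated.index) == SurfaceClass.HC_TR.value
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, ref = x[ok], y[ok], ref[ok]
    if slope_grid is None:
        slope_grid = np.linspace(-200, 0, 81)
    if intercept_grid is None:
        intercept_grid = np.linspace(0, 500, 101)
    best, best_acc = (0.0, 0.0), -1.0
    for m in slope_grid:
        margin0 = y - m * x
        for c in intercept_grid:
            acc = np.mean((margin0 - c >= 0) == ref)
            if acc > best_acc:
                best_acc, best = acc, (float(m), float(c))
    return SurfaceClassBoundary(slope=best[0], intercept=best[1])


# ---------------------------------------------------------------------------
# HPLC peak classification
# ---------------------------------------------------------------------------

def classify_hplc(
    native_peaks: Sequence[tuple[float, float]],
    reduced_peaks: Sequence[tuple[float, float]],
    detection_floor: float = 0.0,
    dominant_frac: float = 0.5,
    minor_frac: float = 0.05,
) -> HplcClass:
    """Classify a secreted peptide by its chromatographic peak pattern.

    Peaks are (retention_time, area) pairs per condition.  A peptide with
    native total area below ``detection_floor`` failed to secrete
    (PEAKS_0).  Otherwise, in each condition peaks with area at least
    ``minor_frac`` of the condition total are counted; the peptide is
    well folded (PEAKS_1_2) only if in BOTH conditions the largest peak
    reaches ``dominant_frac`` of the total and at most one other counted
    peak exists.  Anything else is PEAKS_3PLUS.  The call is invariant to
    uniform rescaling of all areas (the floor excepted).
    """
    if not (0 < minor_frac <= 1 and 0 < dominant_frac <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    if minor_frac >= dominant_frac:
        raise ValueError("dominant_frac must exceed minor_frac")
    native_areas = np.array([a for _, a in native_peaks], dtype=float)
    if (native_areas < 0).any():
        raise ValueError("peak areas must be non-negative")
    if native_areas.sum() < detection_floor or native_areas.sum() == 0:
        return HplcClass.PEAKS_0

    def clean(peaks: Sequence[tuple[float, float]]) -> bool:
        areas = np.array([a for _, a in peaks], dtype=float)
        total = areas.sum()
        if total <= 0:
            return False
        counted = areas[areas >= minor_frac * total]
        return counted.max() >= dominant_frac * total and len(counted) <= 2

    if len(reduced_peaks) == 0:
        raise ValueError("reduced-condition peaks missing for secreted peptide")
    return (
        HplcClass.PEAKS_1_2
        if clean(native_peaks) and clean(reduced_peaks)
        else HplcClass.PEAKS_3PLUS
    )


def classify_hplc_table(
    peaks: pd.DataFrame, detection_floor: float = 0.0, **kwargs
) -> pd.Series:
    """Vector version over a tidy peak table with columns
    ``peptide_id``, ``condition`` (native/reduced), ``rt``, ``area``."""
    out = {}
    for pid, grp in peaks.groupby("peptide_id"):
        native = list(
            grp.loc[grp["condition"] == "native", ["rt", "area"]].itertuples(
                index=False, name=None
            )
        )
        reduced = list(
            grp.loc[grp["condition"] == "reduced", ["rt", "area"]].itertuples(
                index=False, name=None
            )
        )
        out[pid] = classify_hplc(native, reduced, detection_floor, **kwargs).value
    return pd.Series(out, name="hplc_class")


# ---------------------------------------------------------------------------
# Permutation concordance test
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ConcordanceResult:
    observed: float
    p_value: float
    n_permutations: int
    seed: int | None
    statistic: str
    exhaustive: bool = False


def matched_fraction(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of peptides whose two binary folding calls agree."""
    return float(np.mean(a == b))


def matthews_correlation(a: np.ndarray, b: np.ndarray) -> float:
    tp = np.sum(a & b)
    tn = np.sum(~a & ~b)
    fp = np.sum(~a & b)
    fn = np.sum(a & ~b)
    denom = math.sqrt(
        float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    )
    return 0.0 if denom == 0 else float((tp * tn - fp * fn) / denom)


_STATISTICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "matched_fraction": matched_fraction,
    "mcc": matthews_correlation,
}


def concordance_permutation_test(
    surface_labels: Sequence[bool],
    hplc_labels: Sequence[bool],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    statistic: str = "matched_fraction",
    exhaustive: bool = False,
) -> ConcordanceResult:
    """Permutation test of surface-vs-solution folding concordance.

    Both inputs are binary per-peptide indicators (surface: HC/TR; HPLC:
    well folded, i.e. 1-2 peaks).  The null distribution is generated by
    uniformly shuffling the HPLC label vector; the Monte-Carlo p-value
    uses the add-one form ``(1 + #{null >= observed}) / (1 + n_perm)`` so
    its floor is ``1/(n_perm+1)``.

    For the default matched-fraction statistic the shuffled statistic is
    a deterministic function of the hypergeometric overlap between the
    two positive sets, so the null is sampled directly from that
    distribution (exactly equivalent to explicit shuffles, far faster);
    other statistics fall back to explicit shuffling.  With
    ``exhaustive=True`` the exact tail fraction over all distinct label
    arrangements is returned instead (feasible for small n).
    """
    a = np.asarray(surface_labels, dtype=bool)
    b = np.asarray(hplc_labels, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be equal-length 1-D")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat_fn = _STATISTICS[statistic]
    obs = stat_fn(a, b)
    n = a.size

    if b.all() or not b.any():
        warnings.warn(
            "HPLC label vector has a single class; every permutation ties "
            "the observed statistic and p = 1",
            stacklevel=2,
        )

    if exhaustive:
        total = tied = 0
        for perm in set(itertools.permutations(b.tolist())):
            # distinct multiset arrangements, each equally likely
            weight = 1
            total += weight
            if stat_fn(a, np.array(perm, dtype=bool)) >= obs - 1e-12:
                tied += weight
        return ConcordanceResult(
            observed=obs,
            p_value=tied / total,
            n_permutations=total,
            seed=seed,
            statistic=statistic,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    if statistic == "matched_fraction":
        n1, m1 = int(a.sum()), int(b.sum())
        # overlap of the two positive sets under a uniform shuffle
        k = rng.hypergeometric(n1, n - n1, m1, size=n_perm)
        null = (n - n1 - m1 + 2 * k) / n
        exceed = int(np.sum(null >= obs - 1e-12))
    else:
        exceed = 0
        bb = b.copy()
        for _ in range(n_perm):
            rng.shuffle(bb)
            if stat_fn(a, bb) >= obs - 1e-12:
                exceed += 1
    return ConcordanceResult(
        observed=obs,
        p_value=(1 + exceed) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
        statistic=statistic,
    )


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

def chi_square_2x2(
    table: Sequence[Sequence[float]], yates: bool = False
) -> tuple[float, float]:
    """Two-tailed Pearson chi-square on a 2x2 contingency table (df = 1).

    Continuity correction off by default; all four margins must be
    positive.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Bin enrichment and unweighted GSEA
# ---------------------------------------------------------------------------

def bin_enrichment_ranks(
    reads_bin: pd.Series, reads_input: pd.Series, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Rank peptides within one sorted bin by log2 enrichment vs input.

    enrichment = log2( ((r_bin + pc) / (N_bin + pc*P)) /
                       ((r_in  + pc) / (N_in  + pc*P)) )

    with P the number of peptides.  Sorted descending; ties broken by
    peptide id.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if len(reads_bin) == 0 or len(reads_input) == 0:
        raise ValueError("empty count tables")
    common = reads_bin.index.intersection(reads_input.index)
    rb = reads_bin.loc[common].astype(float)
    ri = reads_input.loc[common].astype(float)
    p_count = len(common)
    fb = (rb + pseudocount) / (rb.sum() + pseudocount * p_count)
    fi = (ri + pseudocount) / (ri.sum() + pseudocount * p_count)
    enr = np.log2(fb / fi).rename("log2_enrichment")
    out = enr.reset_index().rename(columns={"index": "peptide_id"})
    out.columns = ["peptide_id", "log2_enrichment"]
    return out.sort_values(
        ["log2_enrichment", "peptide_id"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclasses.dataclass(frozen=True)
class GseaResult:
    es: float
    p_value: float
    n_permutations: int
    seed: int | None
    leading_edge: tuple[str, ...]


def _running_sum_extremum(
    member_positions: np.ndarray, n: int, g: int
) -> tuple[float, int]:
    """Signed maximum-magnitude deviation of the KS running sum, and the
    0-based list position where it occurs.

    ``member_positions`` are the sorted 0-based ranks of set members.
    The running sum gains 1/g at a member and loses 1/(n-g) at a
    non-member, so its extrema can only occur immediately after a member
    (local max candidates) or immediately before one (local min
    candidates), which allows O(g) evaluation.
    """
    k = np.arange(1, g + 1)
    # value just after the k-th member
    highs = k / g - (member_positions + 1 - k) / (n - g)
    # value just before the k-th member
    lows = (k - 1) / g - (member_positions - (k - 1)) / (n - g)
    # the end of the list returns to 0; a trailing minimum below all lows
    # cannot occur because the sum rises monotonically back to 0 only at
    # members -- after the last member it only decreases, reaching its
    # lowest point at the end, which is 0.
    i_hi = int(np.argmax(highs))
    i_lo = int(np.argmin(lows))
    hi, lo = float(highs[i_hi]), float(lows[i_lo])
    if hi >= -lo:
        return hi, int(member_positions[i_hi])
    return lo, int(member_positions[i_lo])


def _null_es(n: int, g: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """|ES| null sample: signed extrema for random size-g sets, batched.

    Random member positions are drawn by ranking uniform keys; the
    extremum formulas of :func:`_running_sum_extremum` vectorize across
    permutations.
    """
    keys = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(keys, g - 1, axis=1)[:, :g], axis=1)
    k = np.arange(1, g + 1)
    highs = k / g - (pos + 1 - k) / (n - g)
    lows = (k - 1) / g - (pos - (k - 1)) / (n - g)
    hi = highs.max(axis=1)
    lo = lows.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def gsea_unweighted(
    ranked_ids: Sequence[str],
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> GseaResult:
    """Unweighted gene-set enrichment analysis over a ranked list.

    The running sum adds 1/G at set members and subtracts 1/(N-G) at
    non-members; ES is the signed maximum-magnitude deviation, so
    |ES| <= 1 with equality when the set occupies one extreme of the
    list.  The p-value is two-sided on |ES| against ``n_perm`` random
    same-size sets, in add-one form.  The leading edge is the members at
    or before the extremum for positive ES, at or after it for negative
    ES.
    """
    ids = list(ranked_ids)
    n, g = len(ids), len(gene_set)
    if g == 0 or g >= n:
        raise ValueError("gene_set must be a non-empty strict subset of the list")
    missing = gene_set - set(ids)
    if missing:
        raise ValueError(f"gene_set members absent from ranked list: {sorted(missing)[:5]}")

    positions = np.sort([i for i, x in enumerate(ids) if x in gene_set])
    es, ext_pos = _running_sum_extremum(positions, n, g)
    if es >= 0:
        edge = tuple(ids[p] for p in positions if p <= ext_pos)
    else:
        edge = tuple(ids[p] for p in positions if p >= ext_pos)

    rng = np.random.default_rng(seed)
    null = _null_es(n, g, n_perm, rng)
    exceed = int(np.sum(np.abs(null) >= abs(es) - 1e-12))
    return GseaResult(
        es=es,
        p_value=(1 + exceed) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
        leading_edge=edge,
    )
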