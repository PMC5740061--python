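"""Seeded generators emulating the screen's data-generating process.

The sort-seq generator models the physical chain the analysis inverts:
each peptide has a true mean surface fluorescence drawn from a two-
component (folded / unfolded) log-normal mixture; individual cells
scatter log-normally around their peptide's mean with an additive
autofluorescence floor; cells are sorted into four contiguous gates cut
at quantiles of the pooled fluorescence; and each gate is sequenced by
multinomial read sampling proportional to the gate's peptide cell
counts.  A trypsin condition rescales each peptide's signal by a latent
survival factor.  HPLC class labels are drawn from a per-folding-state
confusion matrix, creating (or, with uniform rows, destroying) the
surface/solution concordance the statistics module tests.  An SSM
generator applies planted per-variant log2 effects over two rounds of
selection.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .dms_enrichment import build_ssm_library

GATE_NAMES = ("lowest", "low", "high", "highest")

HPLC_CLASSES = ("PEAKS_1_2", "PEAKS_3PLUS", "PEAKS_0")


@dataclasses.dataclass(frozen=True)
class SortSeqSimConfig:
    """Study conditions for the sort-seq simulation.

    Fluorescence is parameterized in log10 arbitrary units.  Defaults:
    2000 peptides, 40 % folded with mean log10 fluorescence 3.5 vs 2.3
    unfolded (component SD 0.4, spanning the roughly two-decade dynamic
    range typical of surface stains), per-cell scatter SD 0.2, four
    gates cut at the pooled 25/50/75 % quantiles, 400,000 sorted cells
    and 2 x 10^6 reads per gate.  Folded peptides survive limited
    trypsinization largely intact (survival uniform on [0.6, 1.1]);
    unfolded ones are mostly cleaved (uniform on [0.05, 0.35]).
    """

    n_peptides: int = 2000
    folded_fraction: float = 0.4
    folded_mean_log10: float = 3.5
    folded_sd_log10: float = 0.4
    unfolded_mean_log10: float = 2.3
    unfolded_sd_log10: float = 0.4
    cell_noise_sd_log10: float = 0.2
    gate_quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
    total_cells: int = 400_000
    reads_per_gate: int = 2_000_000
    survival_folded_range: tuple[float, float] = (0.6, 1.1)
    survival_unfolded_range: tuple[float, float] = (0.05, 0.35)
    autofluor_floor_frac: float = 0.01  # of the folded-component mean
    seed: int = 0

    def __post_init__(self) -> None:
        q = self.gate_quantiles
        if not all(0 < a < 1 for a in q) or any(
            b <= a for a, b in zip(q, q[1:])
        ):
            raise ValueError("gate quantiles must be strictly increasing in (0,1)")
        if not 0 <= self.folded_fraction <= 1:
            raise ValueError("folded_fraction must lie in [0,1]")
        if self.n_peptides <= 0 or self.total_cells <= 0 or self.reads_per_gate <= 0:
            raise ValueError("counts must be positive")

    @property
    def autofluor_floor(self) -> float:
        return self.autofluor_floor_frac * 10.0 ** self.folded_mean_log10

    @property
    def gate_names(self) -> tuple[str, ...]:
        n = len(self.gate_quantiles) + 1
        return GATE_NAMES if n == 4 else tuple(f"gate{i}" for i in range(n))


def draw_truth(config: SortSeqSimConfig) -> pd.DataFrame:
    """Latent per-peptide state: folding, true mean fluorescence, and
    trypsin survival factor."""
    rng = np.random.default_rng(config.seed)
    n = config.n_peptides
    folded = rng.random(n) < config.folded_fraction
    mu = np.where(
        folded,
        rng.normal(config.folded_mean_log10, config.folded_sd_log10, n),
        rng.normal(config.unfolded_mean_log10, config.unfolded_sd_log10, n),
    )
    survival = np.where(
        folded,
        rng.uniform(*config.survival_folded_range, n),
        rng.uniform(*config.survival_unfolded_range, n),
    )
    sd = config.cell_noise_sd_log10
    # mean of the per-cell log-normal plus the autofluorescence floor
    true_mean = config.autofluor_floor + 10.0 ** mu * np.exp(
        0.5 * (sd * np.log(10.0)) ** 2
    )
    return pd.DataFrame(
        {
            "peptide_id": [f"pep{i:05d}" for i in range(n)],
            "folded": folded,
            "mu_log10": mu,
            "true_mean_fluor": true_mean,
            "survival": survival,
        }
    ).set_index("peptide_id")


def _draw_cells(
    truth: pd.DataFrame,
    config: SortSeqSimConfig,
    rng: np.random.Generator,
    signal_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantiate the sorted cell population: which peptide each cell
    carries and its total fluorescence (signal + autofluorescence)."""
    n = len(truth)
    scale = np.ones(n) if signal_scale is None else np.asarray(signal_scale, float)
    cell_counts = rng.multinomial(config.total_cells, np.full(n, 1.0 / n))
    pep_of_cell = np.repeat(np.arange(n), cell_counts)
    mu = truth["mu_log10"].to_numpy()[pep_of_cell]
    noise = rng.normal(0.0, config.cell_noise_sd_log10, pep_of_cell.size)
    with np.errstate(divide="ignore"):
        log_signal = mu + np.log10(np.where(scale[pep_of_cell] > 0,
                                            scale[pep_of_cell], np.nan)) + noise
    signal = np.where(np.isnan(log_signal), 0.0, 10.0 ** np.nan_to_num(log_signal))
    fluor = config.autofluor_floor + signal
    return pep_of_cell, fluor


def _sort_and_sequence(
    pep_of_cell: np.ndarray,
    fluor: np.ndarray,
    truth: pd.DataFrame,
    config: SortSeqSimConfig,
    rng: np.random.Generator,
    cuts: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gate the cells at fixed fluorescence boundaries and draw reads
    multinomially within each gate; returns (read counts, bin stats,
    per-gate true cell counts)."""
    n = len(truth)
    gate_of_cell = np.searchsorted(cuts, fluor, side="right")
    n_gates = len(config.gate_quantiles) + 1
    names = config.gate_names

    gate_cells = np.zeros((n, n_gates), dtype=np.int64)
    np.add.at(gate_cells, (pep_of_cell, gate_of_cell), 1)

    stats_rows, counts_cols = [], {}
    for g, name in enumerate(names):
        in_gate = gate_of_cell == g
        c_b = int(in_gate.sum())
        m_b = float(np.median(fluor[in_gate])) if c_b else np.nan
        stats_rows.append({"bin": name, "cell_count": c_b, "median_fluor": m_b})
        if c_b == 0:
            warnings.warn(
                f"gate {name!r} received no cells; it yields zero reads",
                stacklevel=3,
            )
            counts_cols[name] = np.zeros(n, dtype=np.int64)
            continue
        p = gate_cells[:, g] / c_b
        counts_cols[name] = rng.multinomial(config.reads_per_gate, p)

    reads = pd.DataFrame(counts_cols, index=truth.index)
    binstats = pd.DataFrame(stats_rows)
    truth_cells = pd.DataFrame(gate_cells, index=truth.index, columns=list(names))
    return reads, binstats, truth_cells


def _simulate_sort(
    truth: pd.DataFrame,
    config: SortSeqSimConfig,
    rng: np.random.Generator,
    signal_scale: np.ndarray | None = None,
    cuts: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """One sort of the library.  Gate boundaries are set once, on the
    untreated pooled fluorescence (``cuts=None`` cuts this population at
    the configured quantiles); a treated condition re-uses the same
    boundaries, as a cytometer gate does."""
    pep_of_cell, fluor = _draw_cells(truth, config, rng, signal_scale)
    if cuts is None:
        cuts = np.quantile(fluor, config.gate_quantiles)
    reads, binstats, cells = _sort_and_sequence(
        pep_of_cell, fluor, truth, config, rng, cuts
    )
    return reads, binstats, cells, cuts


def untreated_gate_cuts(truth: pd.DataFrame, config: SortSeqSimConfig) -> np.ndarray:
    """The gate boundaries the untreated sort of this run would set
    (replays the untreated cell draw deterministically)."""
    rng = np.random.default_rng((config.seed, 1))
    _, fluor = _draw_cells(truth, config, rng)
    return np.quantile(fluor, config.gate_quantiles)


def simulate_sortseq(
    config: SortSeqSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Untreated sort of a fresh library.

    Returns (read counts [peptide x gate], bin stats, truth table).  The
    truth table carries the latent state plus the per-gate true cell
    counts (columns ``cells_<gate>``).
    """
    truth = draw_truth(config)
    rng = np.random.default_rng((config.seed, 1))
    reads, binstats, cells, _ = _simulate_sort(truth, config, rng)
    truth = truth.join(cells.add_prefix("cells_"))
    return reads, binstats, truth


def simulate_trypsin_condition(
    truth: pd.DataFrame, config: SortSeqSimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-sort the same library after trypsinization: each peptide's
    signal is scaled by its survival factor (cells of a fully cleaved
    peptide sit at the autofluorescence floor).  The untreated run's
    gate boundaries are re-used so both conditions share a fluorescence
    scale."""
    cuts = untreated_gate_cuts(truth, config)
    rng = np.random.default_rng((config.seed, 2))
    reads, binstats, _, _ = _simulate_sort(
        truth, config, rng, signal_scale=truth["survival"].to_numpy(), cuts=cuts
    )
    return reads, binstats


def simulate_replicate(
    truth: pd.DataFrame, config: SortSeqSimConfig, replicate: int
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """An independent complete replicate (untreated + trypsin sorts) of
    the same underlying library, gated on its own untreated pool."""
    out = {}
    cuts = None
    for cond, tag, scale in (
        ("untreated", 1, None),
        ("trypsin", 2, truth["survival"].to_numpy()),
    ):
        rng = np.random.default_rng((config.seed, 100 * replicate + tag))
        reads, binstats, _, cuts = _simulate_sort(
            truth, config, rng, signal_scale=scale, cuts=cuts
        )
        out[cond] = (reads, binstats)
    return out


# ---------------------------------------------------------------------------
# HPLC labels
# ---------------------------------------------------------------------------

def diagonal_confusion(accuracy: float) -> np.ndarray:
    """2x3 confusion with P(PEAKS_1_2 | folded) = P(PEAKS_3PLUS |
    unfolded) = ``accuracy`` and no secretion failures."""
    return np.array(
        [[accuracy, 1 - accuracy, 0.0], [1 - accuracy, accuracy, 0.0]]
    )


def simulate_hplc_labels(
    truth: pd.DataFrame, confusion: np.ndarray, seed: int
) -> pd.Series:
    """Draw each peptide's HPLC class from the row of its folding state.

    ``confusion`` is 2x3 row-stochastic (rows: folded, unfolded; columns:
    PEAKS_1_2, PEAKS_3PLUS, PEAKS_0).  An identity-like matrix plants
    strong surface/solution concordance; uniform rows give the null.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (2, 3) or not np.allclose(confusion.sum(axis=1), 1.0):
        raise ValueError("confusion must be 2x3 row-stochastic")
    rng = np.random.default_rng(seed)
    rows = np.where(truth["folded"].to_numpy(), 0, 1)
    u = rng.random(len(truth))
    cum = np.cumsum(confusion, axis=1)
    idx = (u[:, None] > cum[rows]).sum(axis=1)
    return pd.Series(
        [HPLC_CLASSES[i] for i in idx], index=truth.index, name="hplc_class"
    )


# ---------------------------------------------------------------------------
# SSM selection
# ---------------------------------------------------------------------------

def simulate_ssm_selection(
    wt_sequence: str,
    planted_effects: pd.Series,
    rounds: int = 2,
    depth: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-round selection of an SSM library with planted effects.

    ``planted_effects`` maps variant id (plus ``"WT"``) to a log2
    selection effect; any tracked sequence absent from it gets 0.  The
    pool starts uniform; each round multiplies a variant's relative
    abundance by ``2**(effect/rounds)`` and the pool is re-observed by
    multinomial sampling at ``depth`` reads, so the expected estimated
    enrichment score (input vs final round, wild-type-normalized) equals
    the planted effect.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not np.all(np.isfinite(planted_effects.to_numpy(dtype=float))):
        raise ValueError("planted effects must be finite")
    variants = build_ssm_library(wt_sequence)
    ids = ["WT"] + [v.id for v in variants]
    effects = pd.Series(0.0, index=ids)
    effects.update(planted_effects.astype(float))
    rng = np.random.default_rng(seed)
    v = len(ids)
    freq = np.full(v, 1.0 / v)
    table = {"input": rng.multinomial(depth, freq)}
    step = 2.0 ** (effects.to_numpy() / rounds)
    for r in range(1, rounds + 1):
        freq = freq * step
        freq /= freq.sum()
        table[f"round{r}"] = rng.multinomial(depth, freq)
    return pd.DataFrame(table, index=ids)


# ---------------------------------------------------------------------------
# Library sequence fixtures
# ---------------------------------------------------------------------------

_NON_CYS = np.array(list("ADEFGHIKLMNPQRSTVWY"))


def simulate_library_sequences(
    n: int,
    length_range: tuple[int, int] = (150, 300),
    cys_count_choices: tuple[int, ...] = (6, 8, 10),
    glycosite_rate: float = 0.3,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Random proteins, each with one planted cysteine-bounded motif.

    The background is cysteine-free so every cysteine in a protein
    belongs to its planted motif; with ``glycosite_rate`` a sequon
    (N-x-S) is written inside the motif.  Returns ``(records, truth)``
    where records are ``(id, sequence)`` pairs and the truth table lists
    the planted coordinates.
    """
    lo, hi = length_range
    if lo < 70 or hi < lo:
        raise ValueError("length_range must satisfy 70 <= lo <= hi")
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for i in range(n):
        total_len = int(rng.integers(lo, hi + 1))
        motif_len = int(rng.integers(30, 51))
        cys_count = int(rng.choice(cys_count_choices))
        inner = rng.choice(_NON_CYS, size=motif_len - 2)
        # place the remaining cysteines strictly inside the window
        inner_pos = rng.choice(motif_len - 2, size=cys_count - 2, replace=False)
        inner[inner_pos] = "C"
        motif = "C" + "".join(inner) + "C"
        glyco_pos = -1
        if rng.random() < glycosite_rate:
            candidates = [
                j
                for j in range(1, motif_len - 3)
                if "C" not in motif[j : j + 3]
            ]
            if candidates:
                glyco_pos = int(rng.choice(candidates))
                motif = motif[:glyco_pos] + "N" + motif[glyco_pos + 1] + "S" + motif[glyco_pos + 3 :]
        start = int(rng.integers(0, total_len - motif_len + 1))
        flank_left = "".join(rng.choice(_NON_CYS, size=start))
        flank_right = "".join(rng.choice(_NON_CYS, size=total_len - motif_len - start))
        seq = flank_left + motif + flank_right
        pid = f"prot{i:04d}"
        records.append((pid, seq))
        rows.append(
            {
                "id": pid,
                "motif_start": start,
                "motif_end": start + motif_len,
                "cys_count": motif.count("C"),
                "glycosite_pos": glyco_pos,
            }
        )
    return records, pd.DataFrame(rows)
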