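"""Pointwise repeated-measures ANOVA with cluster-based permutation correction.

The condition-averaged PLV time series (one value per pair x design cell x
window) is tested window-by-window with a fully within-pairs 2 x 2 rmANOVA
(factors TEMPO and FAMILIARITY).  Runs of at least two consecutive windows
with p < 0.01 form clusters whose mass is the summed F.  The null
distribution of the maximum cluster mass is obtained by re-shuffling the
assignment of trials to the four cells within each pair and re-running the
whole pointwise analysis; cluster p-values use the add-one convention
(b + 1)/(m + 1).

For a fully within-pairs design with two-level factors, each effect's
F(1, n-1) equals the square of the paired t statistic on the corresponding
within-pair contrast, which is how the statistics are computed here
(vectorized across windows and permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

EFFECTS = ("TEMPO", "FAMILIARITY", "interaction")

# Within-pair contrasts over the canonical cell order
# (cong-fam, cong-unfam, incong-fam, incong-unfam); each row yields the
# marginal difference whose one-sample t equals the effect's rmANOVA F**0.5.
_CONTRASTS = np.array([
    [0.5, 0.5, -0.5, -0.5],    # TEMPO: congruent - incongruent
    [0.5, -0.5, 0.5, -0.5],    # FAMILIARITY: familiar - unfamiliar
    [0.5, -0.5, -0.5, 0.5],    # interaction
])


@dataclass(frozen=True)
class PermutationConfig:
    """Parameters of the cluster permutation test."""

    n_perm: int = 1000
    cluster_alpha: float = 0.01
    min_run: int = 2
    cluster_p: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for a in (self.cluster_alpha, self.cluster_p):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")


@dataclass
class Cluster:
    """Contiguous supra-threshold run of windows."""

    effect: str
    start: int                 # first window index (inclusive)
    end: int                   # last window index (inclusive)
    mass: float                # summed F over the run
    p_cluster: float = np.nan

    def length(self) -> int:
        return self.end - self.start + 1


def rmanova_2x2(cell_means: np.ndarray):
    """Fully within-pairs 2 x 2 rmANOVA.

    ``cell_means``: (n_pairs, 4) in canonical cell order — or any leading
    shape (..., n_pairs, 4); the statistics are vectorized over the leading
    axes.  Returns (F, p) dicts keyed by effect, each entry shaped like the
    leading axes, with df (1, n_pairs - 1).  Constant data yield F = 0.
    """
    cells = np.asarray(cell_means, float)
    if cells.shape[-1] != 4:
        raise ValueError("expected 4 design cells on the last axis")
    n = cells.shape[-2]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(cells).any():
        raise ValueError("incomplete design cells (NaN cell means)")
    F, p = {}, {}
    for eff, c in zip(EFFECTS, _CONTRASTS):
        d = cells @ c                      # (..., n_pairs)
        mean = d.mean(axis=-1)
        var = d.var(axis=-1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = n * mean ** 2 / var
        f = np.where(var > 0, f, 0.0)
        F[eff] = f
        p[eff] = sstats.f.sf(f, 1, n - 1)
    return F, p


def pointwise_rmanova(series: np.ndarray):
    """rmANOVA at every window of a (n_pairs, 4, n_windows) condition series.

    Returns (F, p) dicts of length-n_windows arrays per effect.
    """
    series = np.asarray(series, float)
    if series.ndim != 3 or series.shape[1] != 4:
        raise ValueError("expected (n_pairs, 4, n_windows)")
    return rmanova_2x2(series.transpose(2, 0, 1))  # (n_windows, n_pairs, 4)


def form_clusters(p_series, F_series, config: PermutationConfig,
                  effect: str = "") -> list[Cluster]:
    """Maximal runs of >= min_run consecutive windows with p < cluster_alpha."""
    p_series = np.asarray(p_series, float)
    F_series = np.asarray(F_series, float)
    if p_series.shape != F_series.shape:
        raise ValueError("p and F series must be aligned")
    below = p_series < config.cluster_alpha
    clusters = []
    for start, end in _runs(below):
        if end - start + 1 >= config.min_run:
            clusters.append(Cluster(
                effect=effect, start=int(start), end=int(end),
                mass=float(F_series[start:end + 1].sum()),
            ))
    return clusters


def _runs(mask: np.ndarray):
    """(start, end) inclusive index pairs of True runs in a boolean vector."""
    m = np.asarray(mask, bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size - 1)
    return list(zip(starts, ends))


def _max_cluster_mass(p_row, F_row, config: PermutationConfig) -> float:
    best = 0.0
    below = p_row < config.cluster_alpha
    for start, end in _runs(below):
        if end - start + 1 >= config.min_run:
            best = max(best, float(F_row[start:end + 1].sum()))
    return best


def _cell_means_permuted(X: np.ndarray, labels: np.ndarray, perm_labels: np.ndarray):
    """Cell means under permuted labels.

    ``X``: (n_trials, n_windows); ``perm_labels``: (n_perm, n_trials) of cell
    ids 0..3.  Returns (n_perm, 4, n_windows).  Trial counts per cell are
    preserved because permutations merely reorder the original labels.
    """
    n_perm = perm_labels.shape[0]
    counts = np.bincount(labels, minlength=4).astype(float)
    out = np.empty((n_perm, 4, X.shape[-1]))
    for c in range(4):
        out[:, c, :] = ((perm_labels == c).astype(float) @ X) / counts[c]
    return out


def permutation_test(
    trial_data: list,
    config: PermutationConfig | None = None,
) -> dict:
    """Cluster-based permutation test of the pointwise 2 x 2 rmANOVA.

    ``trial_data``: one entry per pair, each a tuple
    ``(values, cells)`` with ``values`` the trial-level ROI-averaged PLV
    (n_trials, n_windows) and ``cells`` the design-cell id (0..3) per trial.

    Condition labels are re-shuffled across trials *within* each pair; per
    permutation the maximum cluster mass over the whole series is recorded
    separately for each effect (0 when no cluster forms).  Observed clusters
    get ``p_cluster = (#null >= mass + 1) / (n_perm + 1)``.

    Returns a dict with observed ``F``/``p`` series, the ``clusters`` per
    effect, and the ``null_masses`` distributions.
    """
    config = config or PermutationConfig()
    rng = np.random.default_rng(config.seed)
    n_pairs = len(trial_data)
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")

    observed_cells = []
    n_windows = None
    for values, cells in trial_data:
        values = np.asarray(values, float)
        cells = np.asarray(cells, int)
        if np.bincount(cells, minlength=4).min() < 1:
            raise ValueError("every pair needs at least one trial per cell")
        if n_windows is None:
            n_windows = values.shape[-1]
        observed_cells.append(_cell_means_permuted(
            values, cells, cells[None, :])[0])
    series = np.stack(observed_cells)          # (n_pairs, 4, n_windows)
    F_obs, p_obs = pointwise_rmanova(series)
    clusters = {eff: form_clusters(p_obs[eff], F_obs[eff], config, eff)
                for eff in EFFECTS}

    # null distribution: within-pair label reshuffles
    perm_cells = np.empty((config.n_perm, n_pairs, 4, n_windows))
    for k, (values, cells) in enumerate(trial_data):
        values = np.asarray(values, float)
        cells = np.asarray(cells, int)
        perm_labels = np.stack(
            [rng.permutation(cells) for _ in range(config.n_perm)])
        perm_cells[:, k] = _cell_means_permuted(values, cells, perm_labels)

    Fp, pp = rmanova_2x2(perm_cells.transpose(0, 3, 1, 2))  # (n_perm, n_windows)
    null_masses = {}
    for eff in EFFECTS:
        masses = np.array([
            _max_cluster_mass(pp[eff][i], Fp[eff][i], config)
            for i in range(config.n_perm)
        ])
        null_masses[eff] = masses
        for cl in clusters[eff]:
            b = int((masses >= cl.mass).sum())
            cl.p_cluster = (b + 1) / (config.n_perm + 1)

    return {
        "F": F_obs, "p": p_obs, "clusters": clusters,
        "null_masses": null_masses, "config": config,
        "significant": {
            eff: [cl for cl in clusters[eff] if cl.p_cluster <= config.cluster_p]
            for eff in EFFECTS
        },
    }


def paired_t(values_a, values_b):
    """Two-sided paired-samples t-test across pairs.

    Returns (t, p, df).  Zero variance of the differences is flagged by
    t = inf (nonzero mean) or t = 0, p = 1 (identical data).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t expects two equal-length 1-d arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0, n - 1
        return float(np.sign(d.mean()) * np.inf), 0.0, n - 1
    t, p = sstats.ttest_rel(a, b)
    return float(t), float(p), n - 1


def cluster_report(result: dict, grid=None, band: str = "", roi: str = "",
                   analysis: str = "real"):
    """Flatten a permutation-test result into a tidy table.

    One row per cluster with effect, window-index span, time span (window
    centers and, when a grid is given, the covered data range), mass and
    p_cluster.
    """
    rows = []
    for eff, cls in result["clusters"].items():
        for cl in cls:
            row = {
                "analysis": analysis, "band": band, "roi": roi, "effect": eff,
                "start_idx": cl.start, "end_idx": cl.end,
                "mass": cl.mass, "p_cluster": cl.p_cluster,
            }
            if grid is not None:
                centers = grid.centers
                row["start_s"] = centers[cl.start]
                row["end_s"] = centers[cl.end]
                row["data_from_s"], row["data_to_s"] = grid.coverage(
                    centers[cl.start], centers[cl.end])
            rows.append(row)
    return pd.DataFrame(rows)
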