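"""Population-level statistics.

Three analyses quantify how adaptation reshapes the joint activity of
a recorded population:

* pairwise spike-count (noise) correlations at fixed stimulus,
* the projected-PC variance ratio: principal components are fitted to
  the unadapted trial-by-neuron matrix, both conditions are projected
  onto those axes, and the per-axis ratio of projected variances
  (unadapt / adapt) summarizes decorrelation — a mean ratio above 1
  over the components capturing 90% of the unadapted variance means
  shared variability shrank after adaptation,
* cross-validated linear-discriminant decoding of two neighboring
  stimuli, reported as accuracy above the 50% chance level.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

from .trials import TrialTable


# --------------------------------------------------------------------------
# noise correlations
# --------------------------------------------------------------------------

@dataclass
class NoiseCorrelationResult:
    matrix: np.ndarray          # neurons x neurons, stimulus-averaged r_sc
    included: np.ndarray        # boolean mask of neurons passing rate filter
    mean_rsc: float             # mean over included off-diagonal pairs


def noise_correlations(table: TrialTable, min_peak_rate: float = 5.0,
                       z_threshold: float = 3.0,
                       min_trials: int = 3) -> NoiseCorrelationResult:
    """Stimulus-averaged pairwise spike-count correlations.

    For every stimulus, each neuron pair's Pearson correlation is
    computed over trials after excluding, per pair, trials in which
    either neuron's |z-scored rate| exceeds ``z_threshold``; the pair's
    r_sc is the average across stimuli. Neurons whose peak rate (max
    over stimuli of the trial-mean rate) is below ``min_peak_rate``
    spikes/s are excluded. Entries are NaN when no stimulus leaves
    ``min_trials`` usable trials.
    """
    rates = table.rates()
    angles = table.angles
    n = table.n_neurons
    peak = np.full(n, -np.inf)
    for a in angles:
        peak = np.maximum(peak, rates[table.stimulus_angle == a].mean(axis=0))
    included = peak >= min_peak_rate

    per_stim = []
    for a in angles:
        r = rates[table.stimulus_angle == a]
        if r.shape[0] < min_trials:
            continue
        sd = r.std(axis=0, ddof=0)
        z = np.zeros_like(r)
        ok_sd = sd > 0
        z[:, ok_sd] = (r[:, ok_sd] - r[:, ok_sd].mean(axis=0)) / sd[ok_sd]
        good = np.abs(z) <= z_threshold            # trials x neurons
        mat = np.full((n, n), np.nan)
        for i in range(n):
            if not included[i]:
                continue
            for j in range(i, n):
                if not included[j]:
                    continue
                keep = good[:, i] & good[:, j]
                if keep.sum() < min_trials:
                    continue
                ri, rj = r[keep, i], r[keep, j]
                if ri.std() == 0 or rj.std() == 0:
                    continue
                c = stats.pearsonr(ri, rj).statistic
                mat[i, j] = mat[j, i] = c
        per_stim.append(mat)
    if not per_stim:
        raise ValueError("no stimulus has enough trials")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        matrix = np.nanmean(np.stack(per_stim), axis=0)
    off = ~np.eye(n, dtype=bool)
    vals = matrix[off & included[:, None] & included[None, :]]
    mean_rsc = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else np.nan
    return NoiseCorrelationResult(matrix=matrix, included=included,
                                  mean_rsc=mean_rsc)


# --------------------------------------------------------------------------
# projected-PC variance ratio
# --------------------------------------------------------------------------

@dataclass
class PCRatioResult:
    ratios: np.ndarray          # full-data per-PC variance ratio (un/adapt)
    n_pcs_90: int               # PCs capturing 90% of unadapted variance
    mean_ratio: float           # mean over subsampled repeats
    resample_sd: float          # s.d. of the repeat means
    p_greater_1: float          # one-sided Wilcoxon across the leading PCs
    kept_neurons: np.ndarray    # mask after the variance outlier filter


def _pc_ratio_once(u: np.ndarray, a: np.ndarray,
                   var_fraction: float) -> tuple[np.ndarray, int, float]:
    """Per-PC variance ratios for one (centered) pair of trial matrices."""
    uc = u - u.mean(axis=0)
    ac = a - a.mean(axis=0)
    # PCs of the unadapted condition via SVD of the centered matrix
    _, s, vt = np.linalg.svd(uc, full_matrices=False)
    var_u = (s ** 2) / (uc.shape[0] - 1)
    proj_a = ac @ vt.T
    var_a = proj_a.var(axis=0, ddof=1)
    explained = np.cumsum(var_u) / var_u.sum()
    n90 = int(np.searchsorted(explained, var_fraction) + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = var_u / var_a
    lead = ratios[:n90]
    return ratios, n90, float(np.mean(lead[np.isfinite(lead)]))


def pc_variance_ratio(unadapt: TrialTable, adapt: TrialTable,
                      var_fraction: float = 0.9, n_reps: int = 100,
                      subsample_fraction: float = 0.8,
                      seed: int | None = 0) -> PCRatioResult:
    """Projected-PC variance ratio between conditions.

    Neurons whose response variance exceeds the across-neuron mean by
    more than 2 s.d. (outliers that would dominate the PCA) are removed.
    Trial counts are equalized by subsampling the larger condition. PCs
    are fitted to the unadapted trials-by-neurons matrix; both
    conditions (each centered on its own per-neuron means, so ratios
    reflect variance structure rather than mean-rate shifts) are
    projected onto them and per-axis variance ratios (unadapt / adapt)
    are formed. ``mean_ratio`` averages, over ``n_reps`` paired
    subsampled repeats, the mean ratio across the leading PCs capturing
    ``var_fraction`` of the unadapted variance.
    """
    if unadapt.n_neurons != adapt.n_neurons:
        raise ValueError("conditions must share the neuron set and order")
    rng = np.random.default_rng(seed)
    u_rates = unadapt.rates()
    a_rates = adapt.rates()
    var = u_rates.var(axis=0, ddof=1)
    keep = var <= var.mean() + 2 * var.std(ddof=1) if len(var) > 1 \
        else np.ones(len(var), dtype=bool)
    u_rates, a_rates = u_rates[:, keep], a_rates[:, keep]

    n = min(u_rates.shape[0], a_rates.shape[0])
    if n < u_rates.shape[1]:
        warnings.warn("fewer trials than neurons; PCs limited by trial count")
    u_idx = rng.permutation(u_rates.shape[0])[:n]
    # equal counts are subsampled with one index set so that identical
    # conditions yield variance ratios of exactly 1
    a_idx = u_idx if a_rates.shape[0] == u_rates.shape[0] \
        else rng.permutation(a_rates.shape[0])[:n]
    u_full, a_full = u_rates[u_idx], a_rates[a_idx]
    ratios, n90, _ = _pc_ratio_once(u_full, a_full, var_fraction)

    n_sub = max(int(round(subsample_fraction * n)), 2)
    rep_means = np.empty(n_reps)
    for r in range(n_reps):
        # one index set applied to both conditions: identical conditions
        # then give a ratio of exactly 1 in every repeat
        idx = rng.permutation(n)[:n_sub]
        _, _, rep_means[r] = _pc_ratio_once(u_full[idx], a_full[idx],
                                            var_fraction)
    lead = ratios[:n90]
    lead = lead[np.isfinite(lead)]
    if len(lead) >= 2 and not np.allclose(lead, 1.0):
        p_greater = float(stats.wilcoxon(lead - 1.0,
                                         alternative="greater").pvalue)
    else:
        p_greater = 1.0
    return PCRatioResult(ratios=ratios, n_pcs_90=n90,
                         mean_ratio=float(rep_means.mean()),
                         resample_sd=float(rep_means.std(ddof=1))
                         if n_reps > 1 else 0.0,
                         p_greater_1=p_greater, kept_neurons=keep)


# --------------------------------------------------------------------------
# linear-discriminant decoding
# --------------------------------------------------------------------------

@dataclass
class DecoderResult:
    accuracy_above_chance: float    # percent, chance (50%) subtracted
    accuracies: np.ndarray          # per-iteration test accuracies (percent)
    sem: float                      # s.e.m. over iterations
    chance: float = 50.0
    train_fraction: float = 0.7


def lda_decode(table: TrialTable, stimulus_pair: tuple[float, float],
               condition: str | None = None, train_fraction: float = 0.7,
               n_iterations: int = 500, seed: int | None = 0,
               min_trials_per_class: int = 10) -> DecoderResult:
    """Two-class LDA decoding of neighboring stimuli, above chance.

    Trials of the two stimuli are split into stratified random 70/30
    train/test sets ``n_iterations`` times; a linear discriminant with
    shrinkage-regularized pooled covariance (Ledoit-Wolf) is fitted on
    each training set and scored on the held-out set. The mean accuracy
    minus the 50% chance level is reported in percent.
    """
    sub = table.select(condition=condition, stimuli=list(stimulus_pair))
    y = sub.stimulus_angle
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("decoding needs exactly two stimulus classes")
    for c in classes:
        if np.sum(y == c) < min_trials_per_class:
            raise ValueError(
                f"need >= {min_trials_per_class} trials per class")
    X = sub.counts.astype(float)
    y = (y == classes[1]).astype(int)   # discrete class labels for sklearn
    splitter = StratifiedShuffleSplit(n_splits=n_iterations,
                                      train_size=train_fraction,
                                      random_state=seed)
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    acc = np.empty(n_iterations)
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        clf.fit(X[tr], y[tr])
        acc[k] = clf.score(X[te], y[te]) * 100.0
    return DecoderResult(
        accuracy_above_chance=float(acc.mean() - 50.0), accuracies=acc,
        sem=float(acc.std(ddof=1) / np.sqrt(n_iterations)),
        train_fraction=train_fraction)


def neighboring_pairs(angles: np.ndarray) -> list[tuple[float, float]]:
    """Adjacent stimulus pairs on the (equally spaced) stimulus circle."""
    a = np.sort(np.asarray(angles, dtype=float))
    return [(float(a[i]), float(a[i + 1])) for i in range(len(a) - 1)]
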