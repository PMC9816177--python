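"""End-to-end experiment orchestration.

Three experiment drivers mirror the study designs:

* ``run_fixation`` — passive-fixation adaptation: interleaved
  unadapted/adapted trials, per-neuron tuning statistics, noise
  correlations, the projected-PC variance ratio and decoding of
  neighboring stimuli,
* ``run_freeview`` — free-viewing sessions: fixation detection,
  pseudo-trial extraction, covariate confound checks, per-condition
  decoding of the two test stimuli and the PC variance ratio,
* ``run_scenes`` — natural-scene surrogates: sliding-window feature
  maps, scanpath simulation and iso-/cross-feature saccade tallies.

Each driver returns a SessionReport whose summary values are all
recomputed from the generated intermediates (no hidden state) and
traceable to the seeds echoed in the report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as synth
from .eye_events import (covariate_comparison, detect_fixations,
                         extract_pseudo_trials)
from .image_features import feature_map, feature_map_dataframe
from .population import (lda_decode, neighboring_pairs,
                         noise_correlations, pc_variance_ratio)
from .saccade_sim import (SaccadeModel, cross_feature_fraction,
                          fit_saccade_model, simulate_scanpath)
from .trials import ADAPT, UNADAPT, TrialTable
from .tuning import classify_tuning, evaluate_selectivity, sliding_tuning


@dataclass
class SessionReport:
    experiment: str
    seed: int
    config: dict
    summary: dict
    tuning_table: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None
    per_image: pd.DataFrame | None = None
    underpowered: bool = False

    def save(self, out_dir: str | Path) -> Path:
        """Write the report as JSON plus CSV tables; returns the JSON path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (("tuning_table", self.tuning_table),
                         ("covariates", self.covariates),
                         ("per_image", self.per_image)):
            if df is not None:
                df.to_csv(out / f"{self.experiment}_{name}.csv", index=False)
        payload = {"experiment": self.experiment, "seed": self.seed,
                   "config": self.config, "summary": self.summary,
                   "underpowered": self.underpowered}
        path = out / f"{self.experiment}_report.json"
        path.write_text(json.dumps(payload, indent=1, default=_jsonable))
        return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=_jsonable))


def _circular_diff(a: float, b: float, period: float) -> float:
    """Signed circular difference a - b in (-period/2, period/2]."""
    d = (a - b) % period
    return d - period if d > period / 2 else d


# --------------------------------------------------------------------------
# passive fixation
# --------------------------------------------------------------------------

def run_fixation(pop_cfg: synth.PopulationConfig,
                 decode_pairs: list[tuple[float, float]] | None = None,
                 decode_iterations: int = 500, n_pca_reps: int = 100,
                 alpha: float = 0.05, time_resolved: bool = False,
                 min_peak_rate: float = 10.0) -> SessionReport:
    """Passive-fixation adaptation experiment on generated data.

    Tabulates per-neuron selectivity in both conditions, the fraction of
    initially untuned neurons that become tuned, the mean selectivity
    and preferred-angle changes, optional tuning-latency changes, and
    the population statistics (noise correlations, PC variance ratio,
    decoding of a neighboring stimulus pair).
    """
    unadapt, adapt, gt = synth.generate_population(pop_cfg)
    feature = pop_cfg.feature
    rows = []
    for k in range(pop_cfg.n_neurons):
        res_u = evaluate_selectivity(unadapt, k, alpha=alpha)
        res_a = evaluate_selectivity(adapt, k, alpha=alpha)
        cls = classify_tuning(
            color_result=res_u if feature == "color" else None,
            orientation_result=res_u if feature == "orientation" else None,
            min_peak_rate=min_peak_rate)
        rows.append({
            "neuron": k,
            "csi_unadapt": res_u.csi, "csi_adapt": res_a.csi,
            "p_unadapt": res_u.p_value, "p_adapt": res_a.p_value,
            "preferred_unadapt": res_u.preferred_angle,
            "preferred_adapt": res_a.preferred_angle,
            "peak_rate_unadapt": res_u.peak_rate,
            "peak_rate_adapt": res_a.peak_rate,
            "class": cls,
            "true_kappa": gt.kappa[k],
            "true_preferred": gt.preferred_angle[k]})
    table = pd.DataFrame(rows)
    included = table["peak_rate_unadapt"] >= min_peak_rate

    dcsi = (table.csi_adapt - table.csi_unadapt)[included]
    untuned_u = included & (table.p_unadapt >= alpha)
    newly_tuned = untuned_u & (table.p_adapt < alpha)
    both_sig = included & (table.p_unadapt < alpha) & (table.p_adapt < alpha)
    dpref = [abs(_circular_diff(a, b, pop_cfg.period))
             for a, b in zip(table.preferred_adapt[both_sig],
                             table.preferred_unadapt[both_sig])]
    dfr = (table.peak_rate_adapt - table.peak_rate_unadapt)[included] \
        / table.peak_rate_unadapt[included] * 100.0

    nc_u = noise_correlations(unadapt.select(condition=UNADAPT))
    nc_a = noise_correlations(adapt.select(condition=ADAPT))
    pcr = pc_variance_ratio(unadapt, adapt, n_reps=n_pca_reps,
                            seed=pop_cfg.seed)
    if decode_pairs is None:
        # four evenly spaced neighboring pairs around the stimulus circle;
        # the session decode statistic is their mean
        pairs = neighboring_pairs(pop_cfg.stimulus_angles)
        decode_pairs = [pairs[k] for k in
                        range(0, len(pairs), max(len(pairs) // 4, 1))][:4]
    acc_u, acc_a = [], []
    for pair in decode_pairs:
        acc_u.append(lda_decode(unadapt, pair, n_iterations=decode_iterations,
                                seed=pop_cfg.seed).accuracy_above_chance)
        acc_a.append(lda_decode(adapt, pair, n_iterations=decode_iterations,
                                seed=pop_cfg.seed).accuracy_above_chance)

    summary = {
        "n_neurons_included": int(included.sum()),
        "delta_csi_mean": float(dcsi.mean()),
        "delta_firing_rate_pct": float(dfr.mean()),
        "fraction_newly_tuned": (float(newly_tuned.sum() / untuned_u.sum())
                                 if untuned_u.sum() else float("nan")),
        "delta_preferred_deg_mean": (float(np.mean(dpref)) if dpref
                                     else float("nan")),
        "mean_rsc_unadapt": nc_u.mean_rsc, "mean_rsc_adapt": nc_a.mean_rsc,
        "pc_mean_ratio": pcr.mean_ratio,
        "pc_ratio_resample_sd": pcr.resample_sd,
        "pc_n_pcs_90": pcr.n_pcs_90,
        "pc_ratio_p_greater_1": pcr.p_greater_1,
        "decode_pairs": [list(p) for p in decode_pairs],
        "decode_above_chance_unadapt": float(np.mean(acc_u)),
        "decode_above_chance_adapt": float(np.mean(acc_a)),
        "decode_improvement": float(np.mean(acc_a) - np.mean(acc_u)),
    }
    if time_resolved:
        summary["delta_tuning_latency_ms"] = _latency_shift(pop_cfg, alpha)
    return SessionReport(
        experiment=f"fixation-{feature}-test", seed=pop_cfg.seed,
        config=_config_dict(pop_cfg), summary=summary, tuning_table=table)


def _latency_shift(pop_cfg: synth.PopulationConfig, alpha: float) -> float:
    """Mean adapted-minus-unadapted tuning latency over tuned neurons."""
    bu, ba, bin_starts, angles, gt = \
        synth.generate_population_timecourse(pop_cfg)
    deltas = []
    for k in range(pop_cfg.n_neurons):
        if gt.kappa[k] == 0:
            continue
        tc_u = sliding_tuning(bu[:, k, :], bin_starts, angles,
                              period=pop_cfg.period, alpha=alpha)
        tc_a = sliding_tuning(ba[:, k, :], bin_starts, angles,
                              period=pop_cfg.period, alpha=alpha)
        if tc_u.tuning_latency_ms is not None \
                and tc_a.tuning_latency_ms is not None:
            deltas.append(tc_a.tuning_latency_ms - tc_u.tuning_latency_ms)
    return float(np.mean(deltas)) if deltas else float("nan")


# --------------------------------------------------------------------------
# free viewing
# --------------------------------------------------------------------------

DEFAULT_RF_EXTENT = (1.0, 4.0, -4.0, -1.0)   # RF box relative to gaze (deg)


def run_freeview(pop_cfg: synth.PopulationConfig,
                 eye_cfg: synth.EyeTraceConfig,
                 rf_extent: tuple = DEFAULT_RF_EXTENT,
                 test_angles: tuple[float, float] = (45.0, 67.5),
                 decode_iterations: int = 500,
                 n_pca_reps: int = 100,
                 min_trials: int = 10) -> SessionReport:
    """Free-viewing adaptation experiment on a generated session."""
    session = synth.generate_freeview_session(pop_cfg, eye_cfg, test_angles)
    fixations = detect_fixations(session.trace, layout=eye_cfg.layout)

    def counts_for(fix):
        best, best_ov = None, 0.0
        for (on, off), c in session.counts.items():
            ov = min(off, fix.offset_ms) - max(on, fix.onset_ms)
            if ov > best_ov:
                best, best_ov = c, ov
        return best

    trials = extract_pseudo_trials(fixations, eye_cfg.layout, rf_extent,
                                   counts_for=counts_for)
    trials = [t for t in trials if t.spike_counts is not None]
    angle_of = {"test1": test_angles[0], "test2": test_angles[1]}
    tables = {}
    for cond in (UNADAPT, ADAPT):
        sub = [t for t in trials if t.condition == cond]
        if sub:
            tables[cond] = TrialTable(
                counts=np.stack([t.spike_counts for t in sub]),
                condition=np.full(len(sub), cond, dtype=object),
                stimulus_angle=np.array([angle_of[t.test_stimulus]
                                         for t in sub]),
                period=pop_cfg.period, window_ms=(0.0, 1000.0),
                feature=pop_cfg.feature, seed=pop_cfg.seed)
    n_u = tables[UNADAPT].n_trials if UNADAPT in tables else 0
    n_a = tables[ADAPT].n_trials if ADAPT in tables else 0
    underpowered = min(n_u, n_a) < min_trials

    covars = covariate_comparison(trials) if trials else None
    summary = {"n_fixations": len(fixations), "n_trials_unadapt": n_u,
               "n_trials_adapt": n_a, "test_angles": list(test_angles)}
    if not underpowered:
        pcr = pc_variance_ratio(tables[UNADAPT], tables[ADAPT],
                                n_reps=n_pca_reps, seed=pop_cfg.seed)
        summary.update({"pc_mean_ratio": pcr.mean_ratio,
                        "pc_ratio_resample_sd": pcr.resample_sd,
                        "pc_n_pcs_90": pcr.n_pcs_90})
        # decoding needs both test stimuli in both conditions
        can_decode = all(
            (tables[c].stimulus_angle == a).sum() >= 2
            for c in (UNADAPT, ADAPT) for a in test_angles)
        if can_decode:
            dec_u = lda_decode(tables[UNADAPT], test_angles,
                               n_iterations=decode_iterations,
                               seed=pop_cfg.seed, min_trials_per_class=2)
            dec_a = lda_decode(tables[ADAPT], test_angles,
                               n_iterations=decode_iterations,
                               seed=pop_cfg.seed, min_trials_per_class=2)
            summary.update({
                "decode_above_chance_unadapt": dec_u.accuracy_above_chance,
                "decode_above_chance_adapt": dec_a.accuracy_above_chance,
                "decode_improvement": (dec_a.accuracy_above_chance
                                       - dec_u.accuracy_above_chance)})
    return SessionReport(
        experiment="freeview", seed=pop_cfg.seed,
        config={"population": _config_dict(pop_cfg),
                "eye": _config_dict(eye_cfg)},
        summary=summary, covariates=covars, underpowered=underpowered)


# --------------------------------------------------------------------------
# natural-scene surrogates
# --------------------------------------------------------------------------

def default_saccade_model(seed: int = 0, n: int = 2000) -> SaccadeModel:
    """Saccade statistics used when no measured saccades are supplied:
    gamma-distributed amplitudes (mean ~3 deg) and uniform directions."""
    rng = np.random.default_rng(seed)
    amp = rng.gamma(shape=2.0, scale=1.5, size=n)
    direc = rng.uniform(0.0, 360.0, size=n)
    return fit_saccade_model(np.column_stack([amp, direc]))


def run_scenes(n_images: int = 20, n_saccades: int = 300,
               scene_cfg: synth.SceneConfig | None = None,
               model: SaccadeModel | None = None, deg_to_px: float = 10.0,
               patch_size: int = 50, seed: int = 0,
               compute_feature_maps: bool = True,
               feature_map_stride: int = 25) -> SessionReport:
    """Scanpath simulation over generated patch-structured scenes."""
    base = scene_cfg or synth.SceneConfig()
    model = model or default_saccade_model(seed)
    rng = np.random.default_rng(seed)
    scanpaths = []
    map_rows = []
    for i in range(n_images):
        cfg_i = dataclasses.replace(base, seed=seed + i)
        image, _ = synth.generate_scene(cfg_i)
        if compute_feature_maps:
            feats = feature_map(image, window=patch_size,
                                stride=feature_map_stride)
            df = feature_map_dataframe(feats)
            map_rows.append({"image": i,
                             "n_oriented": int((df.label == "oriented").sum()),
                             "n_colored": int((df.label == "colored").sum()),
                             "n_neither": int((df.label == "neither").sum()),
                             "mean_osi": float(df.osi.mean())})
        scanpaths.append(simulate_scanpath(
            model, image, n_saccades=n_saccades, deg_to_px=deg_to_px,
            patch_size=patch_size, rng=rng))
    summary_tr = cross_feature_fraction(scanpaths)
    per_image = summary_tr.per_image
    if map_rows:
        per_image = per_image.merge(pd.DataFrame(map_rows), on="image")
    summary = {
        "n_images": n_images, "n_saccades_per_image": n_saccades,
        "n_transitions": summary_tr.n_transitions,
        "iso_pct": summary_tr.iso_pct, "cross_pct": summary_tr.cross_pct,
        "other_pct": summary_tr.other_pct,
        "cross_pct_feature_only": summary_tr.cross_pct_feature_only}
    return SessionReport(
        experiment="scenes", seed=seed,
        config=_config_dict(base), summary=summary, per_image=per_image)
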